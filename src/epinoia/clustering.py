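"""Co-expression modules and meta-traits.

Traits are grouped into multi-trait complexes with the weighted
co-expression network recipe: Pearson correlation, soft-thresholded
unsigned adjacency ``|r|^beta``, topological-overlap dissimilarity,
average-linkage hierarchical clustering with a top-down branch cut, and a
first-principal-component "meta-trait" per module.  The meta-trait is the
unit of the downstream epistasis scan: pooling correlated traits boosts
the signal of epistatic effects shared across a module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datamodel import ClusterSet, ExpressionMatrix, MetaTraitMatrix, ValidationError


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson trait-trait correlation over samples (unit diagonal)."""
    v = expr.values.to_numpy(dtype=float)
    if v.shape[1] < 3:
        raise ValidationError("need at least 3 samples for correlations")
    sd = v.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [expr.traits[i] for i in dead[:5]]
        raise ValidationError(f"zero-variance traits: {names}")
    cor = np.corrcoef(v)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(np.clip(cor, -1.0, 1.0), index=expr.traits, columns=expr.traits)


def adjacency(cor: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``a_ij = |cor_ij|^beta``."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    adj = np.abs(cor.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def tom_dissimilarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological-overlap dissimilarity ``1 - TOM`` (zero diagonal).

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_{u != i,j} a_iu a_uj`` counts shared neighbours and
    ``k_i = sum_{u != i} a_iu`` is the connectivity of node i.
    """
    a = adj.to_numpy(dtype=float)
    # (A @ A)_ij includes u = i and u = j; remove them (unit diagonal).
    l = a @ a - 2.0 * a
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom  # diagonal may be 0/0; overwritten below
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(np.clip(d, 0.0, 1.0), index=adj.index, columns=adj.columns)


def _recursive_split(d: np.ndarray, idx: np.ndarray, min_size: int,
                     gap: float) -> list[np.ndarray]:
    """Split a cluster when its dendrogram root separates two branches of
    at least ``min_size`` whose mutual dissimilarity clearly exceeds the
    within-branch dissimilarity (separation > ``gap`` of the cluster's
    dissimilarity spread)."""
    if idx.size < 2 * min_size:
        return [idx]
    sub = d[np.ix_(idx, idx)]
    Z = linkage(squareform(sub, checks=False), method="average")
    two = fcluster(Z, t=2, criterion="maxclust")
    ia, ib = np.flatnonzero(two == 1), np.flatnonzero(two == 2)
    if min(ia.size, ib.size) < min_size:
        return [idx]
    off = sub[~np.eye(idx.size, dtype=bool)]
    spread = off.max() - off.min()
    if spread <= 0:
        return [idx]
    between = sub[np.ix_(ia, ib)].mean()

    def within(g: np.ndarray) -> float:
        m = sub[np.ix_(g, g)]
        return m[~np.eye(g.size, dtype=bool)].mean()

    separation = (between - max(within(ia), within(ib))) / spread
    if separation <= gap:
        return [idx]
    return (_recursive_split(d, idx[ia], min_size, gap)
            + _recursive_split(d, idx[ib], min_size, gap))


def detect_modules(dissim: pd.DataFrame, min_module_size: int = 5,
                   cut_height_quantile: float = 0.99,
                   split_gap: float = 0.05) -> ClusterSet:
    """Average-linkage clustering with a top-down branch cut.

    A static cut at the given quantile of merge heights gives a rough
    segmentation; clusters whose dendrogram root cleanly separates two
    sub-branches of at least ``min_module_size`` (height gap >
    ``split_gap`` relative to the root) are split recursively; clusters
    below the minimum size are merged into the module with the nearest
    average dissimilarity.
    """
    traits = list(dissim.index)
    n = len(traits)
    d = dissim.to_numpy(dtype=float)
    if n < max(2, min_module_size):
        return ClusterSet(pd.Series(1, index=traits), min_module_size)

    Z = linkage(squareform(d, checks=False), method="average")
    cut = float(np.quantile(Z[:, 2], cut_height_quantile))
    labels0 = fcluster(Z, t=cut, criterion="distance")

    clusters: list[np.ndarray] = []
    for lab in np.unique(labels0):
        idx = np.flatnonzero(labels0 == lab)
        clusters.extend(_recursive_split(d, idx, min_module_size, split_gap))

    # merge undersized clusters into the nearest (mean-dissimilarity) cluster
    clusters.sort(key=len, reverse=True)
    while len(clusters) > 1:
        sizes = np.array([c.size for c in clusters])
        small = np.flatnonzero(sizes < min_module_size)
        if small.size == 0:
            break
        i = small[np.argmin(sizes[small])]
        dist = [d[np.ix_(clusters[i], c)].mean() if j != i else np.inf
                for j, c in enumerate(clusters)]
        j = int(np.argmin(dist))
        clusters[j] = np.concatenate([clusters[j], clusters.pop(i)])

    clusters.sort(key=lambda c: (-c.size, c.min()))
    labels = pd.Series(0, index=traits, dtype=int)
    for m, idx in enumerate(clusters, start=1):
        labels.iloc[idx] = m
    return ClusterSet(labels, min_module_size)


def compute_meta_traits(expr: ExpressionMatrix, clusters: ClusterSet,
                        prefix: str = "M") -> MetaTraitMatrix:
    """First-PC meta-trait per module.

    Traits are standardized (zero mean, unit sd over samples) before the
    PCA, so the variance-explained is on the correlation scale.  The PC
    sign is fixed so the score correlates positively with the module's
    mean standardized expression.
    """
    scores = {}
    varexp = {}
    for m in clusters.module_ids:
        members = clusters.members(m)
        if len(members) < 2:
            raise ValidationError(f"module {m} has fewer than 2 traits")
        x = expr.values.loc[members].to_numpy(dtype=float)
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = [members[i] for i in np.flatnonzero(sd == 0)[:5]]
            raise ValidationError(f"zero-variance traits in module {m}: {bad}")
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        # rows are standardized traits; PC scores live over samples
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        score = s[0] * vt[0] / np.sqrt(x.shape[1])
        mean_profile = xs.mean(axis=0)
        if np.dot(score, mean_profile) < 0:
            score = -score
        scores[f"{prefix}{m}"] = score
        varexp[f"{prefix}{m}"] = float(s[0] ** 2 / np.sum(s ** 2))
    values = pd.DataFrame(scores, index=expr.samples).T
    values.columns = expr.samples
    return MetaTraitMatrix(values, pd.Series(varexp))


def write_clusters(clusters: ClusterSet, path, sep: str = "\t") -> None:
    out = clusters.labels.rename("module").rename_axis("trait").reset_index()
    out.to_csv(path, sep=sep, index=False)


def write_meta_traits(meta: MetaTraitMatrix, path, sep: str = "\t",
                      sample_sep: str = ":") -> None:
    out = meta.values.copy()
    out.columns = [f"{l}{sample_sep}{k}" for l, k in meta.values.columns]
    out.to_csv(path, sep=sep, index=True, index_label="meta_trait")
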