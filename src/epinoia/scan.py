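"""Two-stage hierarchical epistasis scan with tree-structured FDR control.

Stage one tests every (trait-unit, framework-marker-pair) combination,
where framework markers are a sparse skeleton spaced about 10 cM apart.
All stage-one hypotheses form a single family tested by the
Benjamini-Hochberg (BH) step-up procedure at a within-family level
``q* = q / (2 delta)``.  Each rejected stage-one hypothesis opens a
family of stage-two hypotheses: the same trait unit against every pair
of dense "secondary" markers drawn from the two framework regions.  The
full-tree FDR is bounded by ``2 * delta * pi * q*``, with the universal
bound ``delta <= 1.44``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (ExpressionMatrix, GeneticMap, GenotypeMatrix,
                        MetaTraitMatrix, ValidationError)
from .noia import MISSING, AliasedPairError, fit_many, locus_coding

#: universal upper bound on the family-specific factor delta
DELTA_BOUND = 1.44


# ---------------------------------------------------------------------------
# framework-marker selection

@dataclass(frozen=True)
class FrameworkPlan:
    """Sparse framework skeleton plus the region of each framework marker.

    Regions partition each chromosome's markers by nearest framework
    marker (in cM, ties to the earlier one); every framework marker
    belongs to its own region.
    """

    framework: list[str]
    regions: dict[str, list[str]]
    spacing_cm: float

    @property
    def n_framework(self) -> int:
        return len(self.framework)

    def framework_pairs(self) -> list[tuple[str, str]]:
        f = self.framework
        return [(f[i], f[j]) for i in range(len(f)) for j in range(i + 1, len(f))]


def select_framework_markers(gmap: GeneticMap, spacing_cm: float = 10.0) -> FrameworkPlan:
    """Greedy per-chromosome skeleton: keep the first marker, then the
    first marker at least ``spacing_cm`` beyond the last kept one."""
    if gmap.n_markers == 0:
        raise ValidationError("empty genetic map")
    framework: list[str] = []
    regions: dict[str, list[str]] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome_markers(chrom)
        pos = sub["position_cm"].to_numpy(float)
        names = list(sub.index)
        chosen = [0]
        for i in range(1, len(names)):
            if pos[i] - pos[chosen[-1]] >= spacing_cm:
                chosen.append(i)
        fw_pos = pos[chosen]
        for i, name in enumerate(names):
            d = np.abs(fw_pos - pos[i])
            nearest = chosen[int(np.argmin(d))]  # argmin is stable: ties -> earlier
            regions.setdefault(names[nearest], []).append(name)
        framework.extend(names[c] for c in chosen)
    return FrameworkPlan(framework, regions, spacing_cm)


# ---------------------------------------------------------------------------
# BH step-up

def bh_select(pvalues: np.ndarray, q_level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up; returns a boolean reject mask.

    Rejects the k smallest p-values where k is the largest index with
    ``p_(k) <= k * q / m`` (stable sort, so ties are deterministic).
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = q_level * np.arange(1, m + 1) / m
    ok = np.flatnonzero(ps <= thresh)
    if ok.size:
        k = ok[-1] + 1
        reject[order[:k]] = True
    return reject


# ---------------------------------------------------------------------------
# tree-level arithmetic

def full_tree_level(q: float, delta: float) -> float:
    """Within-family BH level ``q* = q / (2 delta)`` for a two-level tree."""
    if not (0 < q < 1):
        raise ValidationError(f"q must be in (0, 1), got {q}")
    if delta < 1:
        raise ValidationError(f"delta must be >= 1, got {delta}")
    return q / (2.0 * delta)


def fdr_bound(q_star: float, delta: float, pi_hat: float = 1.0) -> float:
    """Full-tree FDR bound ``2 * delta * pi * q*`` (two tree levels)."""
    return 2.0 * delta * pi_hat * q_star


# ---------------------------------------------------------------------------
# vectorized pair-scan engine

class PairScanEngine:
    """Fits the two-locus model for many (trait, marker-pair) combinations.

    Traits and genotypes are aligned once; each pair then costs one QR
    solve shared across all traits.  Pairs whose additive codes are
    (near-)collinear are skipped and logged, as are pairs with too few
    jointly observed samples.
    """

    def __init__(self, traits: pd.DataFrame, geno: GenotypeMatrix,
                 min_samples: int = 5, alias_corr: float = 0.99):
        if not isinstance(traits.columns, pd.MultiIndex):
            raise ValidationError("trait matrix needs (line, replicate) sample columns")
        lines = traits.columns.get_level_values(0)
        unknown = sorted(set(lines) - set(geno.lines))
        if unknown:
            raise ValidationError(f"samples reference unknown lines: {unknown[:5]}")
        self.traits = traits
        self.trait_ids = list(traits.index)
        self.Y = traits.to_numpy(dtype=float)
        self.n_samples = self.Y.shape[1]
        self.min_samples = min_samples
        self.alias_corr = alias_corr
        line_idx = geno.values.index.get_indexer(lines)
        self.G = geno.values.to_numpy()[line_idx, :]        # samples x markers
        self.marker_pos = {m: j for j, m in enumerate(geno.markers)}
        self.has_missing = bool((self.G == MISSING).any())
        self.skipped: list[dict] = []
        if not self.has_missing:
            # frequency-centered codes precomputed on the full sample
            codes = np.empty(self.G.shape, dtype=float)
            self._poly = np.ones(self.G.shape[1], dtype=bool)
            for j in range(self.G.shape[1]):
                g = self.G[:, j]
                try:
                    c = locus_coding(g, marker=str(j))
                except Exception:
                    self._poly[j] = False
                    codes[:, j] = np.nan
                    continue
                codes[:, j] = c.codes(g)
            self._codes = codes

    def _design_full(self, a: str, b: str):
        ja, jb = self.marker_pos[a], self.marker_pos[b]
        if not (self._poly[ja] and self._poly[jb]):
            raise AliasedPairError("monomorphic marker")
        xa = self._codes[:, ja]
        xb = self._codes[:, jb]
        r = np.corrcoef(xa, xb)[0, 1]
        if abs(r) > self.alias_corr:
            raise AliasedPairError(f"|r|={abs(r):.3f}")
        X = np.column_stack([np.ones(xa.size), xa, xb, xa * xb])
        return X, None

    def _design_masked(self, a: str, b: str):
        ja, jb = self.marker_pos[a], self.marker_pos[b]
        ga, gb = self.G[:, ja], self.G[:, jb]
        mask = (ga != MISSING) & (gb != MISSING)
        if int(mask.sum()) < self.min_samples:
            raise ValueError(f"only {int(mask.sum())} usable samples")
        ca = locus_coding(ga[mask], a)
        cb = locus_coding(gb[mask], b)
        xa, xb = ca.codes(ga[mask]), cb.codes(gb[mask])
        r = np.corrcoef(xa, xb)[0, 1]
        if abs(r) > self.alias_corr:
            raise AliasedPairError(f"|r|={abs(r):.3f}")
        X = np.column_stack([np.ones(xa.size), xa, xb, xa * xb])
        return X, mask

    def scan_pairs(self, pairs, trait_subset=None) -> pd.DataFrame:
        """Fit all given marker pairs; returns one row per (pair, trait)."""
        if trait_subset is None:
            rows_idx = np.arange(len(self.trait_ids))
        else:
            pos = {t: i for i, t in enumerate(self.trait_ids)}
            rows_idx = np.array([pos[t] for t in trait_subset])
        Y = self.Y[rows_idx]
        ids = [self.trait_ids[i] for i in rows_idx]
        out: list[dict] = []
        for a, b in pairs:
            try:
                if self.has_missing:
                    X, mask = self._design_masked(a, b)
                    Yp = Y[:, mask]
                else:
                    X, _ = self._design_full(a, b)
                    Yp = Y
                res = fit_many(Yp, X)
            except (AliasedPairError, ValueError) as exc:
                self.skipped.append({"marker_a": a, "marker_b": b, "reason": str(exc)})
                continue
            coef = res["coef"]
            for t in range(len(ids)):
                out.append({
                    "trait": ids[t], "marker_a": a, "marker_b": b,
                    "r": coef[0, t], "a_a": coef[1, t], "a_b": coef[2, t],
                    "i_ab": coef[3, t], "pvalue": res["pvalue"][t],
                    "h2_a": res["h2_a"][t], "h2_b": res["h2_b"][t],
                    "h2_ab": res["h2_ab"][t], "h2_total": res["h2_total"][t],
                    "n": res["n"],
                })
        cols = ["trait", "marker_a", "marker_b", "r", "a_a", "a_b", "i_ab",
                "pvalue", "h2_a", "h2_b", "h2_ab", "h2_total", "n"]
        return pd.DataFrame(out, columns=cols)


def _trait_frame(traits) -> pd.DataFrame:
    if isinstance(traits, MetaTraitMatrix):
        return traits.values
    if isinstance(traits, ExpressionMatrix):
        return traits.values
    return traits


# ---------------------------------------------------------------------------
# scan report

@dataclass
class ScanReport:
    """All hypotheses tested in one hierarchical (or direct) scan."""

    q: float
    q_star: float
    delta: float
    pi_hat: float
    bound: float
    discoveries: pd.DataFrame      # level, trait, markers, p, effects, h2
    level1: pd.DataFrame           # all level-1 nodes with reject flag
    n_level1: int
    n_level1_rejected: int
    n_level2: int
    n_level2_rejected: int
    n_families: int                # level-2 families actually tested
    family_sizes: list[int] = field(default_factory=list)
    family_rejections: list[int] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    @property
    def n_discoveries(self) -> int:
        return len(self.discoveries)

    @property
    def total_tests(self) -> int:
        return self.n_level1 + self.n_level2

    def realized_delta_factors(self) -> list[float]:
        """Per-family factor R^(1/R) over families with >= 1 rejection
        (the level-1 family included); bounded by e^(1/e) ~ 1.4447."""
        counts = [self.n_level1_rejected] + list(self.family_rejections)
        return [r ** (1.0 / r) for r in counts if r >= 1]

    def summary_dict(self) -> dict:
        return {
            "q": self.q, "q_star": self.q_star, "delta": self.delta,
            "pi_hat": self.pi_hat, "fdr_bound": self.bound,
            "n_level1": self.n_level1, "n_level1_rejected": self.n_level1_rejected,
            "n_level2": self.n_level2, "n_level2_rejected": self.n_level2_rejected,
            "n_families": self.n_families, "total_tests": self.total_tests,
            "n_discoveries": self.n_discoveries, "n_skipped": len(self.skipped),
        }

    def write(self, tsv_path, json_path=None, sep: str = "\t") -> None:
        self.discoveries.to_csv(tsv_path, sep=sep, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# the two-stage procedure

def level1_scan(traits, geno: GenotypeMatrix, plan: FrameworkPlan,
                engine: PairScanEngine | None = None) -> pd.DataFrame:
    """Stage one: every trait unit against every framework-marker pair."""
    tf = _trait_frame(traits)
    engine = engine or PairScanEngine(tf, geno)
    return engine.scan_pairs(plan.framework_pairs())


def level2_family_pairs(parent_pair: tuple[str, str],
                        plan: FrameworkPlan) -> list[tuple[str, str]]:
    """Secondary pairs of a rejected framework pair: the cross product of
    the two regions, excluding the already-tested parent pair."""
    f1, f2 = parent_pair
    r1 = plan.regions.get(f1, [])
    r2 = plan.regions.get(f2, [])
    return [(u, v) for u in r1 for v in r2 if (u, v) != (f1, f2)]


def run_hierarchical(traits, geno: GenotypeMatrix, gmap: GeneticMap,
                     q: float = 0.1, delta: float | None = None,
                     spacing_cm: float = 10.0, pi_hat: float = 1.0,
                     plan: FrameworkPlan | None = None,
                     min_samples: int = 5, alias_corr: float = 0.99) -> ScanReport:
    """Full two-stage scan: framework screen, BH, dense follow-up, BH.

    ``delta`` defaults to the universal bound 1.44; pass a permutation
    estimate from :func:`estimate_delta` for a sharper within-family
    level.
    """
    delta = DELTA_BOUND if delta is None else float(delta)
    q_star = full_tree_level(q, delta)
    plan = plan or select_framework_markers(gmap, spacing_cm)
    tf = _trait_frame(traits)
    engine = PairScanEngine(tf, geno, min_samples=min_samples, alias_corr=alias_corr)

    l1 = engine.scan_pairs(plan.framework_pairs())
    l1 = l1.assign(rejected=bh_select(l1["pvalue"].to_numpy(), q_star), level=1)

    fam_sizes: list[int] = []
    fam_rejections: list[int] = []
    l2_frames: list[pd.DataFrame] = []
    n_level2 = 0
    for _, parent in l1[l1["rejected"]].iterrows():
        pairs = level2_family_pairs((parent["marker_a"], parent["marker_b"]), plan)
        if not pairs:
            fam_sizes.append(0)
            fam_rejections.append(0)
            continue
        fam = engine.scan_pairs(pairs, trait_subset=[parent["trait"]])
        n_level2 += len(fam)
        rej = bh_select(fam["pvalue"].to_numpy(), q_star)
        fam = fam.assign(rejected=rej, level=2,
                         parent_a=parent["marker_a"], parent_b=parent["marker_b"])
        fam_sizes.append(len(fam))
        fam_rejections.append(int(rej.sum()))
        l2_frames.append(fam)

    l2 = pd.concat(l2_frames, ignore_index=True) if l2_frames else pd.DataFrame(
        columns=list(l1.columns) + ["parent_a", "parent_b"])
    disc = pd.concat([l1[l1["rejected"]], l2[l2["rejected"]]], ignore_index=True)
    disc = disc.drop(columns=["rejected"])
    return ScanReport(
        q=q, q_star=q_star, delta=delta, pi_hat=pi_hat,
        bound=fdr_bound(q_star, delta, pi_hat),
        discoveries=disc, level1=l1,
        n_level1=len(l1), n_level1_rejected=int(l1["rejected"].sum()),
        n_level2=n_level2, n_level2_rejected=int(l2["rejected"].sum()) if len(l2) else 0,
        n_families=len(fam_sizes), family_sizes=fam_sizes,
        family_rejections=fam_rejections, skipped=engine.skipped,
    )


def run_direct(traits, geno: GenotypeMatrix, gmap: GeneticMap, q: float = 0.1,
               pairs: list[tuple[str, str]] | None = None,
               min_samples: int = 5, alias_corr: float = 0.99) -> ScanReport:
    """Direct (non-hierarchical) scan: all dense marker pairs in one BH
    family at level ``q``.  Used as the baseline the two-stage procedure
    is compared against."""
    tf = _trait_frame(traits)
    engine = PairScanEngine(tf, geno, min_samples=min_samples, alias_corr=alias_corr)
    if pairs is None:
        ms = [m for m in gmap.markers if m in engine.marker_pos]
        pairs = [(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))]
    res = engine.scan_pairs(pairs)
    rej = bh_select(res["pvalue"].to_numpy(), q)
    res = res.assign(rejected=rej, level=1)
    disc = res[res["rejected"]].drop(columns=["rejected"])
    return ScanReport(
        q=q, q_star=q, delta=1.0, pi_hat=1.0, bound=q,
        discoveries=disc.reset_index(drop=True), level1=res,
        n_level1=len(res), n_level1_rejected=int(rej.sum()),
        n_level2=0, n_level2_rejected=0, n_families=0,
        skipped=engine.skipped,
    )


# ---------------------------------------------------------------------------
# permutation estimate of delta

def estimate_delta(traits, geno: GenotypeMatrix, gmap: GeneticMap,
                   q: float = 0.1, reps: int = 10000, seed: int = 0,
                   spacing_cm: float = 10.0) -> tuple[float, float]:
    """Permutation estimate of the family-specific factor delta.

    Line labels of the trait matrix are permuted relative to the
    genotypes (a full-null resample preserving the replicate structure),
    the two-level procedure is run, and the realized per-family factor
    ``R^(1/R)`` is averaged over families with at least one rejection.
    Returns (mean, standard error) over resamples that produced at least
    one discovery; raises if every resample is degenerate.
    """
    if reps < 100:
        raise ValidationError("need at least 100 permutation resamples")
    tf = _trait_frame(traits)
    rng = np.random.default_rng(seed)
    lines = list(dict.fromkeys(tf.columns.get_level_values(0)))
    plan = select_framework_markers(gmap, spacing_cm)
    factors: list[float] = []
    for _ in range(reps):
        perm = rng.permutation(lines)
        relabel = dict(zip(lines, perm))
        cols = pd.MultiIndex.from_tuples(
            [(relabel[l], k) for l, k in tf.columns], names=tf.columns.names)
        tperm = pd.DataFrame(tf.to_numpy(), index=tf.index, columns=cols)
        report = run_hierarchical(tperm, geno, gmap, q=q, delta=DELTA_BOUND, plan=plan)
        realized = report.realized_delta_factors()
        if realized:
            factors.append(float(np.mean(realized)))
    if not factors:
        raise ValidationError("all permutation resamples had zero discoveries")
    factors_arr = np.asarray(factors)
    se = float(factors_arr.std(ddof=1) / np.sqrt(factors_arr.size)) if factors_arr.size > 1 else 0.0
    return float(factors_arr.mean()), se
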