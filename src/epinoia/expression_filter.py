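"""EM mixture filter for unexpressed traits.

Array platforms report a background intensity for genes that are not
expressed in the tissue at all; the distribution of per-trait mean
intensities is then bimodal.  A two-component univariate normal mixture is
fitted by EM to the trait means, and traits assigned to the lower-mean
("unexpressed") component with posterior probability > 0.5 are removed
before clustering and mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the last iterate in ``fit``."""

    def __init__(self, message: str, fit: "MixtureFit"):
        super().__init__(message)
        self.fit = fit


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate normal mixture, means ordered mu1 < mu2."""

    means: np.ndarray        # (2,), mu1 < mu2
    sds: np.ndarray          # (2,), > 0
    weights: np.ndarray      # (2,), sum to 1
    log_likelihoods: np.ndarray  # per-iteration observed-data log-likelihood
    converged: bool
    degenerate: bool = False  # data supported no second component

    def posterior_lower(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of the lower-mean component per value."""
        if self.degenerate:
            return np.zeros(np.shape(x), dtype=float)
        x = np.asarray(x, dtype=float)
        logp = np.stack([
            np.log(self.weights[k]) + norm.logpdf(x, self.means[k], self.sds[k])
            for k in (0, 1)])
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        return p[0] / p.sum(axis=0)

    def expressed_mask(self, x: np.ndarray) -> np.ndarray:
        return self.posterior_lower(x) <= 0.5


def fit_normal_mixture(x: np.ndarray, tol: float = 1e-8, max_iter: int = 500,
                       seed: int = 0) -> MixtureFit:
    """Fit a two-component normal mixture to 1-D data by EM.

    Initialization is k-means with a fixed seed for reproducibility.  The
    observed-data log-likelihood is tracked per iteration and is
    guaranteed non-decreasing (a property test relies on this).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    var = float(np.var(x))
    if n < 4 or var < 1e-12 * (1.0 + float(np.mean(x)) ** 2):
        mu = float(np.mean(x))
        return MixtureFit(means=np.array([mu, mu]),
                          sds=np.array([1.0, 1.0]),
                          weights=np.array([0.5, 0.5]),
                          log_likelihoods=np.array([]),
                          converged=True, degenerate=True)

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    lab = order.argsort()[km.labels_]  # 0 = lower-mean cluster
    means = np.array([x[lab == k].mean() for k in (0, 1)])
    floor = np.sqrt(var) * 1e-4
    sds = np.array([max(x[lab == k].std(), floor) for k in (0, 1)])
    weights = np.array([(lab == k).mean() for k in (0, 1)])
    weights = np.clip(weights, 1e-6, None)
    weights /= weights.sum()

    loglik = []
    for _ in range(max_iter):
        logp = np.stack([np.log(weights[k]) + norm.logpdf(x, means[k], sds[k])
                         for k in (0, 1)])
        m = logp.max(axis=0)
        ll = float(np.sum(m + np.log(np.exp(logp - m).sum(axis=0))))
        loglik.append(ll)
        resp = np.exp(logp - m)
        resp /= resp.sum(axis=0)
        nk = resp.sum(axis=1)
        weights = np.clip(nk / n, 1e-9, None)
        weights /= weights.sum()
        means = resp @ x / nk
        sds = np.sqrt(np.maximum((resp * (x - means[:, None]) ** 2).sum(axis=1) / nk,
                                 floor ** 2))
        if len(loglik) > 1 and abs(loglik[-1] - loglik[-2]) < tol * (1 + abs(loglik[-2])):
            order = np.argsort(means)
            return MixtureFit(means[order], sds[order], weights[order],
                              np.asarray(loglik), converged=True,
                              degenerate=bool(abs(means[0] - means[1]) < floor))
    order = np.argsort(means)
    fit = MixtureFit(means[order], sds[order], weights[order],
                     np.asarray(loglik), converged=False)
    raise EMConvergenceError(f"EM did not converge in {max_iter} iterations", fit)


def filter_expressed_traits(expr: ExpressionMatrix, n_components: int = 2,
                            tol: float = 1e-8, max_iter: int = 500,
                            seed: int = 0) -> tuple[ExpressionMatrix, MixtureFit]:
    """Drop traits whose mean intensity belongs to the background component.

    The per-trait summary statistic is the mean over all samples.  Returns
    the retained traits and the mixture fit (reusable via
    ``fit.expressed_mask`` — reapplying the same fit to already-filtered
    data removes nothing, so the filter is idempotent).
    """
    if n_components != 2:
        raise ValueError("only a two-component mixture is supported")
    means = expr.values.mean(axis=1).to_numpy()
    fit = fit_normal_mixture(means, tol=tol, max_iter=max_iter, seed=seed)
    if fit.degenerate:
        return expr, fit
    keep = fit.expressed_mask(means)
    kept = ExpressionMatrix(expr.values.loc[keep])
    return kept, fit
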