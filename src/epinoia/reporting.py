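"""Diagnostic tables for scan output (kept numeric; plotting optional)."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: p-values of exactly zero are capped here before taking logs
PVALUE_FLOOR = 1e-300


def pvalue_qq_data(pvalues: np.ndarray, null_dist: str = "uniform") -> pd.DataFrame:
    """Quantile-quantile table of -log(p) against the null distribution.

    Under the null, -log(p) of uniform p-values is Exp(1), so both the
    "uniform" and "exponential" conventions produce the same theoretical
    quantiles -log((i - 0.5) / n); the observed series is the sorted
    -log(p).  Zero p-values are capped at a floor and counted in the
    ``capped`` column.
    """
    if null_dist not in ("uniform", "exponential"):
        raise ValueError("null_dist must be 'uniform' or 'exponential'")
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    capped = p < PVALUE_FLOOR
    p = np.clip(p, PVALUE_FLOOR, 1.0)
    obs = np.sort(-np.log(p))[::-1]
    n = p.size
    exp = -np.log((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected_neglogp": exp, "observed_neglogp": obs,
                         "capped": np.sort(capped)[::-1]})
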