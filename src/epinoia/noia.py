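"""Two-locus NOIA model for RIL populations.

In a RIL population every line is homozygous, so a locus has two genotype
classes and the single-locus genotypic value is ``G = R + x * a`` with
``x in {-1, +1}`` under balanced allele frequencies.  The statistical NOIA
parameterization recenters the codes at the *observed* frequencies
(``code(P1) = -2 p2``, ``code(P2) = 2 p1``), which keeps the additive and
epistatic effect estimates orthogonal regardless of segregation
distortion.  Two loci combine by a Kronecker construction into the design
``(1, x_A, x_B, x_A x_B)``; the epistasis test is the t-test on the
interaction coefficient, and the heritability of each effect is its
(sequential) sum of squares over the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .datamodel import MISSING, P1, P2


class MonomorphicMarkerError(ValueError):
    """Only one parental allele observed: no additive contrast exists."""


class AliasedPairError(ValueError):
    """Two loci (near-)perfectly linked: the epistasis term is inestimable."""


class DegenerateTraitError(ValueError):
    """Trait has zero variance in the fitted sample."""


@dataclass(frozen=True)
class LocusCoding:
    """Frequency-centered additive codes for one RIL locus.

    Invariants: ``p1*code_p1 + p2*code_p2 = 0`` (zero mean in the fitted
    sample) and ``code_p2 - code_p1 = 2`` (the +/-1 span of the balanced
    design).
    """

    marker: str
    p1: float
    p2: float
    code_p1: float
    code_p2: float

    def codes(self, genotypes: np.ndarray) -> np.ndarray:
        """Map stored allele codes {0,1,-1} to reals (missing -> NaN)."""
        g = np.asarray(genotypes)
        out = np.full(g.shape, np.nan, dtype=float)
        out[g == P1] = self.code_p1
        out[g == P2] = self.code_p2
        return out


def locus_coding(genotypes: np.ndarray, marker: str = "") -> LocusCoding:
    """Statistical NOIA coding from observed allele frequencies."""
    g = np.asarray(genotypes)
    n1 = int(np.sum(g == P1))
    n2 = int(np.sum(g == P2))
    if n1 == 0 or n2 == 0:
        raise MonomorphicMarkerError(f"marker {marker!r} is monomorphic in the sample")
    p1 = n1 / (n1 + n2)
    p2 = 1.0 - p1
    return LocusCoding(marker, p1, p2, code_p1=-2.0 * p2, code_p2=2.0 * p1)


@dataclass(frozen=True)
class NOIADesign:
    """n x 4 design (intercept, x_A, x_B, x_A x_B) over usable samples."""

    X: np.ndarray
    sample_mask: np.ndarray  # which of the input samples were usable
    coding_a: LocusCoding
    coding_b: LocusCoding


def build_design(genotypes_a: np.ndarray, genotypes_b: np.ndarray,
                 min_samples: int = 5,
                 marker_a: str = "A", marker_b: str = "B") -> NOIADesign:
    """Kronecker-style two-locus design on the jointly observed samples.

    Samples missing either genotype are dropped; codings use frequencies
    observed in the retained sample.
    """
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    mask = (ga != MISSING) & (gb != MISSING)
    if int(mask.sum()) < min_samples:
        raise ValueError(f"only {int(mask.sum())} usable samples (< {min_samples})")
    ca = locus_coding(ga[mask], marker_a)
    cb = locus_coding(gb[mask], marker_b)
    xa = ca.codes(ga[mask])
    xb = cb.codes(gb[mask])
    X = np.column_stack([np.ones(xa.size), xa, xb, xa * xb])
    return NOIADesign(X, mask, ca, cb)


@dataclass(frozen=True)
class NOIAFit:
    """OLS fit of the two-locus model to one expression trait."""

    marker_a: str
    marker_b: str
    r: float          # reference point (intercept)
    a_a: float        # additive effect of locus A
    a_b: float        # additive effect of locus B
    i_ab: float       # epistasis coefficient
    se: np.ndarray    # standard errors of the four coefficients
    pvalue: float     # two-sided t-test on i_ab
    df: int
    resid_var: float
    h2_a: float
    h2_b: float
    h2_ab: float
    h2_total: float   # model R^2 (sums of the three effect h2 terms)
    n: int
    orthogonal: bool  # False when LD makes the decomposition sequential
    trait: str = ""

    def to_record(self) -> dict:
        return {
            "trait": self.trait, "marker_a": self.marker_a, "marker_b": self.marker_b,
            "r": self.r, "a_a": self.a_a, "a_b": self.a_b, "i_ab": self.i_ab,
            "pvalue": self.pvalue, "h2_a": self.h2_a, "h2_b": self.h2_b,
            "h2_ab": self.h2_ab, "h2_total": self.h2_total, "n": self.n,
        }


def _qr_stats(X: np.ndarray):
    """QR pieces reused across traits sharing a design."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * diag.max()):
        raise AliasedPairError("rank-deficient design (aliased pair)")
    Rinv = solve_triangular(R, np.eye(4))
    xtx_inv_diag = (Rinv ** 2).sum(axis=1)
    return Q, R, xtx_inv_diag


def fit_many(Y: np.ndarray, X: np.ndarray):
    """Vectorized OLS of many traits on one shared 4-column design.

    Y is (n_traits, n_samples).  Returns dict of per-trait arrays:
    coefficients, interaction p-value and the heritability decomposition
    (sequential sums of squares in the order intercept, A, B, AxB, which
    equals the marginal decomposition under an orthogonal design).
    """
    n = X.shape[0]
    Q, R, xtx_inv_diag = _qr_stats(X)
    QtY = Q.T @ Y.T                       # (4, T)
    coef = solve_triangular(R, QtY)       # (4, T)
    yty = np.einsum("ij,ij->i", Y, Y)
    rss = np.maximum(yty - np.einsum("ij,ij->j", QtY, QtY), 0.0)
    df = n - 4
    sigma2 = rss / df
    ss_total = yty - n * Y.mean(axis=1) ** 2
    ss_total = np.where(ss_total <= 0, np.nan, ss_total)
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))   # (4, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef[3] / se[3]
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    h2 = QtY[1:] ** 2 / ss_total          # (3, T): A, B, AxB
    return {
        "coef": coef, "se": se, "pvalue": pval, "df": df, "sigma2": sigma2,
        "h2_a": h2[0], "h2_b": h2[1], "h2_ab": h2[2],
        "h2_total": h2.sum(axis=0), "ss_total": ss_total, "n": n,
    }


def fit_noia(y: np.ndarray, design: NOIADesign, trait: str = "",
             alias_corr: float = 0.99) -> NOIAFit:
    """Fit the two-locus NOIA model to one trait by ordinary least squares."""
    y = np.asarray(y, dtype=float)[design.sample_mask] if y.size == design.sample_mask.size \
        else np.asarray(y, dtype=float)
    X = design.X
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if np.var(y) == 0:
        raise DegenerateTraitError(f"trait {trait!r} has zero variance")
    r_ab = np.corrcoef(X[:, 1], X[:, 2])[0, 1]
    if abs(r_ab) > alias_corr:
        raise AliasedPairError(
            f"loci {design.coding_a.marker}/{design.coding_b.marker} "
            f"are aliased (|r| = {abs(r_ab):.3f})")
    out = fit_many(y[None, :], X)
    coef = out["coef"][:, 0]
    return NOIAFit(
        marker_a=design.coding_a.marker, marker_b=design.coding_b.marker,
        r=float(coef[0]), a_a=float(coef[1]), a_b=float(coef[2]), i_ab=float(coef[3]),
        se=out["se"][:, 0], pvalue=float(out["pvalue"][0]), df=int(out["df"]),
        resid_var=float(out["sigma2"][0]),
        h2_a=float(out["h2_a"][0]), h2_b=float(out["h2_b"][0]),
        h2_ab=float(out["h2_ab"][0]), h2_total=float(out["h2_total"][0]),
        n=int(out["n"]), orthogonal=bool(abs(r_ab) < 0.1), trait=trait,
    )


def epistasis_pvalue(fit: NOIAFit) -> float:
    """Two-sided p-value for H0: i_AB = 0 (the tested epistasis effect)."""
    return fit.pvalue
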