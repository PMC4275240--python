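"""Core data containers for RIL epistasis mapping.

Three tabular inputs drive the pipeline: a genetic map (marker positions in
centiMorgans), a genotype matrix over a recombinant inbred line (RIL)
population (homozygous, so every marker carries one of two parental
alleles), and a normalized expression matrix whose samples are
(line, replicate) pairs.  All containers wrap pandas objects and validate
their invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: integer codes used to store parental alleles internally
P1 = 0
P2 = 1
MISSING = -1


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions: ``marker_id -> (chromosome, position in cM)``.

    The table is sorted by (chromosome, position); positions must be
    strictly increasing within a chromosome and marker ids unique.
    """

    table: pd.DataFrame  # index: marker_id; columns: chromosome, position_cm

    def __post_init__(self) -> None:
        t = self.table
        if not {"chromosome", "position_cm"}.issubset(t.columns):
            raise ValidationError("map table needs 'chromosome' and 'position_cm' columns")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate marker ids: {dups}")
        if (t["position_cm"] < 0).any():
            raise ValidationError("cM positions must be non-negative")
        t = t.sort_values(["chromosome", "position_cm"], kind="stable")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_cm"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"positions not strictly increasing on chromosome {chrom}")
        object.__setattr__(self, "table", t)

    @property
    def markers(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict = {}
        for c in self.table["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def chromosome_of(self, marker: str) -> str:
        return self.table.at[marker, "chromosome"]

    def position_of(self, marker: str) -> float:
        return float(self.table.at[marker, "position_cm"])

    def chromosome_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines x markers matrix of parental-origin alleles.

    Values are stored as int8: 0 (parent 1), 1 (parent 2) or -1 (missing).
    RIL populations are homozygous, so no heterozygote state exists.
    """

    values: pd.DataFrame  # index: line_id; columns: marker_id; int8 in {0,1,-1}

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate line ids")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate marker columns")
        arr = v.to_numpy()
        bad = ~np.isin(arr, (P1, P2, MISSING))
        if bad.any():
            raise ValidationError(f"genotype codes outside {{P1, P2, missing}}: "
                                  f"{np.unique(arr[bad])[:5].tolist()}")
        v = v.astype(np.int8)
        v.index = v.index.astype(str).rename("line")
        v.columns = v.columns.astype(str)
        object.__setattr__(self, "values", v)

    @property
    def lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_lines(self) -> int:
        return len(self.values)

    def aligned_to(self, gmap: GeneticMap) -> "GenotypeMatrix":
        """Reorder columns to the map's marker order; error on unknown markers."""
        unknown = [m for m in self.values.columns if m not in gmap.table.index]
        if unknown:
            raise ValidationError(f"markers absent from map: {unknown[:5]}")
        return GenotypeMatrix(self.values[[m for m in gmap.markers if m in self.values.columns]])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Traits x samples matrix of normalized expression intensities.

    Columns form a MultiIndex ``(line_id, replicate)`` with replicate >= 1.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.columns, pd.MultiIndex) or v.columns.nlevels != 2:
            raise ValidationError("expression columns must be a (line, replicate) MultiIndex")
        if v.index.duplicated().any():
            raise ValidationError("duplicate trait ids")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate (line, replicate) samples")
        reps = v.columns.get_level_values(1)
        if (np.asarray(reps, dtype=int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        cols = pd.MultiIndex.from_arrays(
            [v.columns.get_level_values(0).astype(str),
             v.columns.get_level_values(1).astype(int)],
            names=("line", "replicate"))
        v = v.copy()
        v.columns = cols
        v.index = v.index.astype(str).rename("trait")
        object.__setattr__(self, "values", v)

    @property
    def traits(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_traits(self) -> int:
        return len(self.values)

    @property
    def samples(self) -> pd.MultiIndex:
        return self.values.columns

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def check_lines(self, geno: GenotypeMatrix) -> None:
        known = set(geno.lines)
        unknown = sorted({l for l in self.values.columns.get_level_values(0) if l not in known})
        if unknown:
            raise ValidationError(f"expression samples reference unknown lines: {unknown[:5]}")

    def subset(self, traits) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(traits)])

    def averaged_over_replicates(self) -> "ExpressionMatrix":
        """Collapse replicates to per-line means (replicate index 1)."""
        mean = self.values.T.groupby(level="line", sort=False).mean().T
        mean.columns = pd.MultiIndex.from_arrays(
            [mean.columns, np.ones(len(mean.columns), dtype=int)],
            names=("line", "replicate"))
        return ExpressionMatrix(mean)


@dataclass(frozen=True)
class ClusterSet:
    """Trait -> module assignment; module label 0 means unassigned."""

    labels: pd.Series  # index: trait_id; int module label
    min_module_size: int = 2

    def __post_init__(self) -> None:
        lab = self.labels.astype(int)
        mods = sorted(set(lab) - {0})
        if mods and mods != list(range(1, len(mods) + 1)):
            raise ValidationError("module labels must be contiguous 1..K")
        object.__setattr__(self, "labels", lab)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


@dataclass(frozen=True)
class MetaTraitMatrix:
    """Per-module meta-traits: first-PC scores over samples.

    Each meta-trait has zero mean over samples; ``variance_explained`` is
    the leading-eigenvalue share of the module's (standardized) variance.
    """

    values: pd.DataFrame          # index: meta-trait id; columns: (line, replicate)
    variance_explained: pd.Series  # index: meta-trait id, values in (0, 1]

    def __post_init__(self) -> None:
        ve = self.variance_explained
        if ((ve <= 0) | (ve > 1 + 1e-12)).any():
            raise ValidationError("variance explained must lie in (0, 1]")
        center = self.values.to_numpy().mean(axis=1)
        scale = np.abs(self.values.to_numpy()).max(axis=1) + 1e-30
        if np.any(np.abs(center) / scale > 1e-6):
            raise ValidationError("meta-traits must have zero mean over samples")

    @property
    def samples(self) -> pd.MultiIndex:
        return self.values.columns
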