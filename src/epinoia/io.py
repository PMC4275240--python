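"""Delimited-text readers and writers for the three tabular inputs.

All files are header-carrying delimited text (tab by default).  Expression
sample headers encode the line and replicate as ``line:replicate``; a
header without the separator is taken as replicate 1 of that line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (MISSING, P1, P2, ExpressionMatrix, GeneticMap,
                        GenotypeMatrix, ValidationError)

DEFAULT_MISSING = ("NA", "", "-", "NaN")


def read_genetic_map(path, sep: str = "\t") -> GeneticMap:
    """Read a map file with columns (marker, chromosome, cM position)."""
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValidationError("map file needs three columns: marker, chromosome, cM")
    df = df.iloc[:, :3]
    df.columns = ["marker", "chromosome", "position_cm"]
    table = pd.DataFrame({
        "chromosome": df["chromosome"].astype(str).to_numpy(),
        "position_cm": df["position_cm"].astype(float).to_numpy(),
    }, index=pd.Index(df["marker"].astype(str), name="marker"))
    return GeneticMap(table)


def write_genetic_map(gmap: GeneticMap, path, sep: str = "\t") -> None:
    out = gmap.table.reset_index()
    out.columns = ["marker", "chromosome", "position_cm"]
    out.to_csv(path, sep=sep, index=False)


def read_genotypes(path, gmap: GeneticMap, alleles: tuple[str, str] = ("A", "B"),
                   missing=DEFAULT_MISSING, sep: str = "\t") -> GenotypeMatrix:
    """Read a lines x markers allele table and align it to the map order.

    ``alleles`` gives the file's codes for the two parental states; any
    other non-missing code (e.g. a heterozygote call) is an error.
    """
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    a1, a2 = (str(a) for a in alleles)
    mapping = {a1: P1, a2: P2}
    for m in missing:
        mapping.setdefault(str(m), MISSING)
    arr = df.to_numpy(dtype=object)
    coded = np.full(arr.shape, MISSING, dtype=np.int8)
    flat = pd.Series(arr.ravel()).fillna("NA").astype(str).str.strip()
    unknown = sorted(set(flat) - set(mapping))
    if unknown:
        raise ValidationError(
            f"allele codes outside the two-parent alphabet {alleles}: {unknown[:5]}")
    coded[:] = flat.map(mapping).to_numpy(dtype=np.int8).reshape(arr.shape)
    geno = GenotypeMatrix(pd.DataFrame(coded, index=df.index, columns=df.columns.astype(str)))
    return geno.aligned_to(gmap)


def write_genotypes(geno: GenotypeMatrix, path, alleles: tuple[str, str] = ("A", "B"),
                    missing: str = "NA", sep: str = "\t") -> None:
    rev = {P1: alleles[0], P2: alleles[1], MISSING: missing}
    out = geno.values.replace(rev)
    out.to_csv(path, sep=sep, index=True, index_label="line")


def parse_sample_header(name: str, sample_sep: str = ":") -> tuple[str, int]:
    name = str(name)
    if sample_sep in name:
        line, _, rep = name.rpartition(sample_sep)
        return line, int(rep)
    return name, 1


def read_expression(path, sep: str = "\t", sample_sep: str = ":",
                    geno: GenotypeMatrix | None = None) -> ExpressionMatrix:
    """Read a traits x samples intensity table.

    Sample headers are ``line{sample_sep}replicate``.  If ``geno`` is
    given, every sample's line must exist in it.
    """
    df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    df.index = df.index.astype(str)
    parsed = [parse_sample_header(c, sample_sep) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(parsed, names=("line", "replicate"))
    expr = ExpressionMatrix(df.astype(float))
    if geno is not None:
        expr.check_lines(geno)
    return expr


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t",
                     sample_sep: str = ":") -> None:
    out = expr.values.copy()
    out.columns = [f"{l}{sample_sep}{k}" for l, k in expr.values.columns]
    out.to_csv(path, sep=sep, index=True, index_label="trait")
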