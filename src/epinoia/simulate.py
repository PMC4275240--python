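"""Synthetic RIL data and the power/FDR/heritability experiment runner.

The generator emulates a two-parent RIL eQTL study: genotypes follow a
Markov chain along each chromosome (Haldane map function, with the RIL
switch probability ``R = 2r / (1 + 2r)`` reflecting the accumulation of
recombination over repeated selfing), and expression traits come in
clusters of fifteen with correlation 0.4 inside non-epistatic clusters.
Two of four clusters are epistatic: 13 of their 15 traits share a
cluster-specific marker pair carrying NOIA effects (0-2 main effects of
0.4 plus an interaction coefficient around -0.2) on top of independent
Gaussian noise with standard deviation 2.5.  The experiment runner
repeats simulation + scan + scoring to estimate detection power, FDR and
epistatic heritability, for meta-trait or single-trait analysis and for
the hierarchical or the direct testing scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .clustering import compute_meta_traits
from .datamodel import (ClusterSet, ExpressionMatrix, GeneticMap,
                        GenotypeMatrix, ValidationError)
from .scan import ScanReport, run_direct, run_hierarchical

# ---------------------------------------------------------------------------
# map functions


def haldane_r(d_cm: float) -> float:
    """Recombination fraction per meiosis at distance d (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_switch_prob(d_cm: float) -> float:
    """Probability that adjacent markers differ in a selfed RIL:
    ``R = 2r / (1 + 2r)``; 0 at d=0 and 0.5 as d -> infinity."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# synthetic maps


def dense_ril_map(n_chromosomes: int = 3, regions_per_chromosome: int = 4,
                  markers_per_region: int = 6, region_spacing_cm: float = 10.0,
                  marker_spacing_cm: float = 0.9) -> GeneticMap:
    """Map used by the simulation study: dense regions around framework
    markers.  Each region holds ``markers_per_region`` markers starting at
    the framework position, spaced ``marker_spacing_cm`` apart (kept well
    inside half the region spacing so nearest-framework assignment keeps
    regions intact)."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for reg in range(regions_per_chromosome):
            base = reg * region_spacing_cm
            for j in range(markers_per_region):
                rows.append((f"c{c}r{reg + 1}m{j + 1}", f"chr{c}",
                             base + j * marker_spacing_cm))
    table = pd.DataFrame({"chromosome": [r[1] for r in rows],
                          "position_cm": [r[2] for r in rows]},
                         index=pd.Index([r[0] for r in rows], name="marker"))
    return GeneticMap(table)


def study_scale_map() -> GeneticMap:
    """Synthetic 493-marker, 5-chromosome map at study scale.

    Marker density mimics a cleaned RIL SFP map: ~90 cM chromosomes with
    sub-cM spacing, yielding 47 framework markers at 10 cM spacing.
    """
    chrom_spec = [("chr1", 99, 1.0), ("chr2", 99, 1.0),
                  ("chr3", 99, 0.9), ("chr4", 99, 0.9), ("chr5", 97, 0.9)]
    rows = []
    for chrom, n, step in chrom_spec:
        for j in range(n):
            rows.append((f"{chrom}m{j + 1:03d}", chrom, j * step))
    table = pd.DataFrame({"chromosome": [r[1] for r in rows],
                          "position_cm": [r[2] for r in rows]},
                         index=pd.Index([r[0] for r in rows], name="marker"))
    return GeneticMap(table)


# ---------------------------------------------------------------------------
# genotype simulation


def simulate_ril_genotypes(gmap: GeneticMap, n_lines: int,
                           rng: np.random.Generator) -> GenotypeMatrix:
    """Markov-chain RIL genotypes along each chromosome.

    The first marker of a chromosome is parent-1/parent-2 with equal
    probability; each subsequent marker switches parental origin with
    probability ``R(d)`` for the map distance d to its predecessor.
    """
    cols = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome_markers(chrom)
        pos = sub["position_cm"].to_numpy(float)
        switch = ril_switch_prob(np.diff(pos))
        g = np.empty((n_lines, len(pos)), dtype=np.int8)
        g[:, 0] = rng.random(n_lines) < 0.5
        if len(pos) > 1:
            flips = rng.random((n_lines, len(pos) - 1)) < switch[None, :]
            g[:, 1:] = g[:, [0]] ^ np.cumsum(flips, axis=1).astype(np.int8) % 2
        for j, m in enumerate(sub.index):
            cols[m] = g[:, j]
    lines = [f"L{i + 1:03d}" for i in range(n_lines)]
    values = pd.DataFrame(cols, index=lines)[gmap.markers]
    return GenotypeMatrix(values)


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation experiment."""

    n_lines: int = 211
    n_replicates: int = 2
    n_chromosomes: int = 3
    regions_per_chromosome: int = 4
    markers_per_region: int = 6
    region_spacing_cm: float = 10.0
    marker_spacing_cm: float = 0.9
    n_clusters: int = 4
    traits_per_cluster: int = 15
    n_epistatic_clusters: int = 2
    epistatic_fraction: float = 13.0 / 15.0
    within_cluster_cor: float = 0.4
    correlate_epistatic_noise: bool = False
    trait_sd: float = 2.5
    baseline_mean: float = 8.0
    main_effect: float = 0.4
    n_main_effects: int = 2
    epistasis: float = -0.20
    q: float = 0.2
    delta: float = 1.44
    mode: str = "meta"            # "meta" or "single"
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.epistatic_fraction <= 1 and 0 <= self.within_cluster_cor < 1):
            raise ValidationError("fractions/correlations out of range")
        if self.trait_sd <= 0:
            raise ValidationError("trait sd must be positive")
        if self.n_main_effects not in (0, 1, 2):
            raise ValidationError("n_main_effects must be 0, 1 or 2")
        if self.mode not in ("meta", "single"):
            raise ValidationError("mode must be 'meta' or 'single'")

    def make_map(self) -> GeneticMap:
        return dense_ril_map(self.n_chromosomes, self.regions_per_chromosome,
                             self.markers_per_region, self.region_spacing_cm,
                             self.marker_spacing_cm)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class GroundTruth:
    """Which traits/clusters are epistatic and where the effects sit."""

    table: pd.DataFrame            # per trait: cluster, epistatic, markers, coefs
    epistatic_clusters: list[int]
    cluster_pairs: dict[int, tuple[str, str]]

    def epistatic_units(self, mode: str) -> set[str]:
        if mode == "meta":
            return {f"M{c}" for c in self.epistatic_clusters}
        return set(self.table.index[self.table["epistatic"]])


def implanted_pairs(gmap: GeneticMap, n_pairs: int,
                    markers_per_region: int = 6) -> list[tuple[str, str]]:
    """Cluster-level marker pairs, alternating inter- and intra-chromosomal.

    Pairs sit on framework markers (the first marker of a region); the
    intra-chromosomal pair spans two regions 2 x region-spacing apart so
    the loci are linked but far from aliased.
    """
    by_chrom: dict[str, list[str]] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome_markers(chrom)
        by_chrom[chrom] = list(sub.index)
    chroms = list(by_chrom)
    pairs: list[tuple[str, str]] = []
    # inter-chromosomal: second region's framework marker on two chromosomes
    region_stride = markers_per_region
    for k in range(n_pairs):
        if k % 2 == 0:
            c1, c2 = chroms[k % len(chroms)], chroms[(k + 1) % len(chroms)]
            pairs.append((by_chrom[c1][region_stride], by_chrom[c2][region_stride]))
        else:
            c = chroms[(k + 2) % len(chroms)]
            pairs.append((by_chrom[c][0], by_chrom[c][2 * region_stride]))
    return pairs


def simulate_traits(geno: GenotypeMatrix, config: SimulationConfig,
                    rng: np.random.Generator,
                    gmap: GeneticMap | None = None
                    ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Cluster-correlated traits with implanted NOIA effects.

    Epistatic traits get ``a_A x_A + a_B x_B + i x_A x_B`` on +/-1 coded
    genotypes of their cluster's shared marker pair; noise is Gaussian
    with sd ``trait_sd``, sharing a cluster factor (correlation
    ``within_cluster_cor``) inside non-epistatic clusters.
    """
    gmap = gmap or config.make_map()
    missing = [m for m in gmap.markers if m not in geno.values.columns]
    if missing:
        raise ValidationError(f"genotypes not simulated on the config map: {missing[:3]}")
    n_samples = geno.n_lines * config.n_replicates
    samples = pd.MultiIndex.from_tuples(
        [(l, k) for l in geno.lines for k in range(1, config.n_replicates + 1)],
        names=("line", "replicate"))
    line_pos = {l: i for i, l in enumerate(geno.lines)}
    sample_line = np.array([line_pos[l] for l, _ in samples])

    pairs = implanted_pairs(gmap, config.n_epistatic_clusters,
                            config.markers_per_region)
    n_epi_traits = round(config.epistatic_fraction * config.traits_per_cluster)

    rows = []
    truth_rows = []
    cluster_pairs: dict[int, tuple[str, str]] = {}
    epi_clusters: list[int] = []
    rho = config.within_cluster_cor
    for c in range(1, config.n_clusters + 1):
        epistatic_cluster = c <= config.n_epistatic_clusters
        if epistatic_cluster:
            ma, mb = pairs[c - 1]
            cluster_pairs[c] = (ma, mb)
            epi_clusters.append(c)
            xa = np.where(geno.values[ma].to_numpy() == 1, 1.0, -1.0)[sample_line]
            xb = np.where(geno.values[mb].to_numpy() == 1, 1.0, -1.0)[sample_line]
        factor = rng.standard_normal(n_samples)
        correlated = rho > 0 and (not epistatic_cluster or config.correlate_epistatic_noise)
        for t in range(config.traits_per_cluster):
            eps = rng.standard_normal(n_samples)
            if correlated:
                noise = config.trait_sd * (np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps)
            else:
                noise = config.trait_sd * eps
            trait_id = f"T{c:02d}_{t + 1:02d}"
            is_epi = epistatic_cluster and t < n_epi_traits
            if is_epi:
                a_a = config.main_effect if config.n_main_effects >= 1 else 0.0
                a_b = config.main_effect if config.n_main_effects >= 2 else 0.0
                signal = a_a * xa + a_b * xb + config.epistasis * xa * xb
                rows.append(config.baseline_mean + signal + noise)
                truth_rows.append((trait_id, c, True, ma, mb, a_a, a_b, config.epistasis))
            else:
                rows.append(config.baseline_mean + noise)
                truth_rows.append((trait_id, c, False, "", "", 0.0, 0.0, 0.0))
    trait_ids = [r[0] for r in truth_rows]
    expr = ExpressionMatrix(pd.DataFrame(np.vstack(rows), index=trait_ids, columns=samples))
    truth = pd.DataFrame(truth_rows, columns=["trait", "cluster", "epistatic",
                                              "marker_a", "marker_b", "a_a", "a_b",
                                              "i_ab"]).set_index("trait")
    return expr, GroundTruth(truth, epi_clusters, cluster_pairs)


def true_cluster_set(config: SimulationConfig, truth: GroundTruth) -> ClusterSet:
    labels = pd.Series(truth.table["cluster"].to_numpy(), index=truth.table.index)
    return ClusterSet(labels.astype(int), min_module_size=2)


# ---------------------------------------------------------------------------
# scoring


def score_run(truth: GroundTruth, report: ScanReport, mode: str = "meta") -> dict:
    """Unit-level power and false discovery proportion for one run.

    A trait/meta-trait is detected if it appears in at least one
    discovery at either level; it is a true positive iff it is epistatic
    in the ground truth.  Power = TP / #epistatic units; the per-run
    false discovery proportion uses the max(1, detections) convention.
    Heritability statistics average over true-positive discoveries.
    """
    epi_units = truth.epistatic_units(mode)
    detected = set(report.discoveries["trait"]) if len(report.discoveries) else set()
    tp_units = detected & epi_units
    fp_units = detected - epi_units
    power = len(tp_units) / max(1, len(epi_units))
    fdp = len(fp_units) / max(1, len(detected))
    if len(report.discoveries):
        tp_rows = report.discoveries[report.discoveries["trait"].isin(epi_units)]
    else:
        tp_rows = pd.DataFrame(columns=["h2_ab", "h2_total"])
    return {
        "power": power, "fdp": fdp,
        "n_detected": len(detected), "n_true_positive": len(tp_units),
        "n_false_positive": len(fp_units),
        "h2_ab": float(tp_rows["h2_ab"].mean()) if len(tp_rows) else np.nan,
        "h2_total": float(tp_rows["h2_total"].mean()) if len(tp_rows) else np.nan,
        "n_discoveries": report.n_discoveries,
    }


# ---------------------------------------------------------------------------
# experiment runners


@dataclass(frozen=True)
class SimulationSummary:
    """Replicate-averaged performance of one experiment configuration."""

    power: float
    power_se: float
    fdr: float
    fdr_se: float
    h2_ab: float
    h2_ab_se: float
    h2_total: float
    n_reps: int
    per_rep: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"power": self.power, "power_se": self.power_se,
                "fdr": self.fdr, "fdr_se": self.fdr_se,
                "h2_ab": self.h2_ab, "h2_ab_se": self.h2_ab_se,
                "h2_total": self.h2_total, "n_reps": self.n_reps}

    def write(self, json_path, tsv_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        if tsv_path is not None:
            self.per_rep.to_csv(tsv_path, sep="\t", index=False)


def _se(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def _one_rep(config: SimulationConfig, gmap: GeneticMap, child_seed,
             direct: bool) -> dict:
    rng = np.random.default_rng(child_seed)
    geno = simulate_ril_genotypes(gmap, config.n_lines, rng)
    expr, truth = simulate_traits(geno, config, rng, gmap=gmap)
    if config.mode == "meta":
        clusters = true_cluster_set(config, truth)
        units = compute_meta_traits(expr, clusters)
    else:
        units = expr
    if direct:
        report = run_direct(units, geno, gmap, q=config.q)
    else:
        report = run_hierarchical(units, geno, gmap, q=config.q, delta=config.delta)
    return score_run(truth, report, config.mode)


def _run(config: SimulationConfig, direct: bool) -> SimulationSummary:
    gmap = config.make_map()
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    rows = []
    for i, child in enumerate(children):
        try:
            res = _one_rep(config, gmap, child, direct)
        except Exception as exc:  # individual failures logged and excluded
            rows.append({"rep": i, "failed": str(exc)})
            continue
        res["rep"] = i
        rows.append(res)
    per_rep = pd.DataFrame(rows)
    if "power" not in per_rep.columns or not per_rep["power"].notna().any():
        raise RuntimeError("all simulation replicates failed")
    ok = per_rep[per_rep["power"].notna()]
    power = ok["power"].to_numpy(float)
    fdp = ok["fdp"].to_numpy(float)
    h2ab = ok["h2_ab"].to_numpy(float)
    return SimulationSummary(
        power=float(power.mean()), power_se=_se(power),
        fdr=float(fdp.mean()), fdr_se=_se(fdp),
        h2_ab=float(np.nanmean(h2ab)) if np.isfinite(h2ab).any() else np.nan,
        h2_ab_se=_se(h2ab),
        h2_total=float(np.nanmean(ok["h2_total"].to_numpy(float)))
        if np.isfinite(ok["h2_total"].to_numpy(float)).any() else np.nan,
        n_reps=len(ok), per_rep=per_rep)


def run_experiment(config: SimulationConfig) -> SimulationSummary:
    """Simulate + hierarchical scan + scoring over ``config.n_reps``."""
    return _run(config, direct=False)


def run_direct_comparison(config: SimulationConfig) -> SimulationSummary:
    """Same simulated data and seeds, but direct BH over all marker pairs."""
    return _run(config, direct=True)
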