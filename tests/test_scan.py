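"""Framework selection, BH, hierarchical families and FDR bound."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from epinoia import (DELTA_BOUND, ValidationError, bh_select, estimate_delta,
                     fdr_bound, full_tree_level, level2_family_pairs,
                     run_direct, run_hierarchical, select_framework_markers,
                     study_scale_map)
from epinoia.datamodel import GeneticMap
from epinoia.simulate import (SimulationConfig, dense_ril_map,
                              simulate_ril_genotypes, simulate_traits,
                              true_cluster_set)
from epinoia.clustering import compute_meta_traits


def grid_map(positions, chrom="1"):
    table = pd.DataFrame({"chromosome": [chrom] * len(positions),
                          "position_cm": list(positions)},
                         index=pd.Index([f"m{i}" for i in range(len(positions))],
                                        name="marker"))
    return GeneticMap(table)


class TestFrameworkSelection:
    def test_even_ten_cm_grid_all_selected(self):
        plan = select_framework_markers(grid_map(range(0, 100, 10)), 10.0)
        assert plan.framework == [f"m{i}" for i in range(10)]
        assert all(len(v) == 1 for v in plan.regions.values())

    def test_greedy_skips_close_markers(self):
        plan = select_framework_markers(grid_map([0, 3, 6, 9, 12]), 10.0)
        assert plan.framework == ["m0", "m4"]

    def test_regions_partition_markers_nearest_tie_to_earlier(self):
        plan = select_framework_markers(grid_map([0, 5, 10]), 10.0)
        assert plan.framework == ["m0", "m2"]
        # m1 at 5 cM is equidistant; the tie goes to the earlier marker
        assert plan.regions["m0"] == ["m0", "m1"]
        assert plan.regions["m2"] == ["m2"]
        all_assigned = sorted(m for r in plan.regions.values() for m in r)
        assert all_assigned == ["m0", "m1", "m2"]

    def test_study_scale_map_yields_47_framework_markers(self):
        gmap = study_scale_map()
        assert gmap.n_markers == 493
        plan = select_framework_markers(gmap, 10.0)
        assert plan.n_framework == 47
        assert len(plan.framework_pairs()) == math.comb(47, 2) == 1081


def bh_oracle(pvals, q):
    """Exhaustive step-up oracle: the largest self-consistent rejection
    set (every p in the set at or below |set| * q / m)."""
    m = len(pvals)
    best = frozenset()
    for r in range(1, m + 1):
        for subset in itertools.combinations(range(m), r):
            if max(pvals[i] for i in subset) <= r * q / m and r > len(best):
                best = frozenset(subset)
    return best


class TestBH:
    def test_worked_example(self):
        rej = bh_select(np.array([0.001, 0.02, 0.8]), 0.05)
        assert list(rej) == [True, True, False]

    def test_all_ones_and_all_zeros(self):
        assert not bh_select(np.ones(5), 0.05).any()
        assert bh_select(np.zeros(5), 0.05).all()
        assert bh_select(np.array([]), 0.05).size == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 13)
        p = np.round(rng.uniform(0, 0.4, m), 3)
        rej = bh_select(p, 0.2)
        assert frozenset(np.flatnonzero(rej)) == bh_oracle(p, 0.2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        ours = bh_select(p, 0.1)
        ref = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        assert np.array_equal(ours, ref)


class TestTreeArithmetic:
    def test_q_star_formula(self):
        assert full_tree_level(0.1, 1.015) == pytest.approx(0.1 / 2.03)
        assert full_tree_level(0.1, 1.015) == pytest.approx(0.04926, abs=5e-5)
        assert full_tree_level(0.2, 1.0) == pytest.approx(0.1)

    def test_q_star_monotone_in_delta(self):
        deltas = [1.0, 1.1, 1.3, DELTA_BOUND]
        qs = [full_tree_level(0.1, d) for d in deltas]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_invalid_q_rejected(self):
        with pytest.raises(ValidationError):
            full_tree_level(0.0, 1.0)
        with pytest.raises(ValidationError):
            full_tree_level(1.5, 1.0)

    def test_bound_arithmetic_and_monotonicity(self):
        assert fdr_bound(0.05, 1.0, 1.0) == pytest.approx(0.10)
        assert fdr_bound(0.05, 1.0, 0.6) < fdr_bound(0.05, 1.0, 1.0)


@pytest.fixture(scope="module")
def plan():
    return select_framework_markers(dense_ril_map(), 10.0)


class TestLevel2Families:
    def test_simulation_regions_have_six_markers(self, plan):
        assert plan.n_framework == 12
        assert all(len(plan.regions[f]) == 6 for f in plan.framework)

    def test_family_size_35(self, plan):
        f1, f2 = plan.framework[0], plan.framework[5]
        fam = level2_family_pairs((f1, f2), plan)
        assert len(fam) == 6 * 6 - 1
        assert (f1, f2) not in fam

    def test_singleton_regions_empty_family(self):
        plan = select_framework_markers(grid_map(range(0, 40, 10)), 10.0)
        fam = level2_family_pairs((plan.framework[0], plan.framework[1]), plan)
        assert fam == []


@pytest.fixture(scope="module")
def planted_scan(planted_dataset):
    config, gmap, geno, expr, truth, meta, clusters = planted_dataset
    report = run_hierarchical(meta, geno, gmap, q=0.1, delta=1.44)
    return truth, report


class TestHierarchicalScan:
    def test_level1_counts(self, planted_dataset):
        config, gmap, geno, expr, truth, meta, clusters = planted_dataset
        report = run_hierarchical(meta, geno, gmap, q=0.1)
        assert report.n_level1 == 4 * math.comb(12, 2)

    def test_planted_pair_and_family_discovered(self, planted_scan):
        truth, report = planted_scan
        disc = report.discoveries
        assert len(disc) > 0
        pair = truth.cluster_pairs[1]
        l1 = disc[disc["level"] == 1]
        hit = ((l1["marker_a"] == pair[0]) & (l1["marker_b"] == pair[1])
               & (l1["trait"] == "M1"))
        assert hit.any()
        # most of the secondary family follows the framework rejection
        fam = disc[(disc["level"] == 2) & (disc["trait"] == "M1")
                   & (disc["parent_a"] == pair[0]) & (disc["parent_b"] == pair[1])]
        assert len(fam) >= 0.5 * 35

    def test_totals_conserved(self, planted_scan):
        _, report = planted_scan
        assert report.n_discoveries == (report.n_level1_rejected
                                        + report.n_level2_rejected)
        assert report.n_level2_rejected == sum(report.family_rejections)
        assert report.n_families == report.n_level1_rejected
        assert len(report.family_sizes) == report.n_families
        assert report.total_tests == report.n_level1 + sum(report.family_sizes)

    def test_subtree_only_under_rejected_parents(self, planted_scan):
        _, report = planted_scan
        l1 = report.level1
        rejected = {(r["trait"], r["marker_a"], r["marker_b"])
                    for _, r in l1[l1["rejected"]].iterrows()}
        l2 = report.discoveries[report.discoveries["level"] == 2]
        for _, row in l2.iterrows():
            assert (row["trait"], row["parent_a"], row["parent_b"]) in rejected

    def test_pure_noise_near_zero_discoveries(self):
        config = SimulationConfig(n_lines=120, seed=3, n_epistatic_clusters=0)
        gmap = config.make_map()
        rng = np.random.default_rng(10)
        geno = simulate_ril_genotypes(gmap, config.n_lines, rng)
        expr, truth = simulate_traits(geno, config, rng, gmap=gmap)
        meta = compute_meta_traits(expr, true_cluster_set(config, truth))
        report = run_hierarchical(meta, geno, gmap, q=0.1)
        assert report.n_discoveries <= 2

    def test_direct_scan_single_family(self, planted_dataset):
        config, gmap, geno, expr, truth, meta, clusters = planted_dataset
        report = run_direct(meta, geno, gmap, q=0.2)
        # aliased (tightly linked) pairs are skipped and logged
        n_pairs = math.comb(gmap.n_markers, 2) - len(report.skipped)
        assert report.n_level1 == 4 * n_pairs
        assert all({"marker_a", "marker_b", "reason"} <= set(s) for s in report.skipped)
        assert report.n_level2 == 0
        pair = truth.cluster_pairs[1]
        hits = ((report.discoveries["marker_a"] == pair[0])
                & (report.discoveries["marker_b"] == pair[1]))
        assert hits.any()


@pytest.fixture(scope="module")
def null_fixture():
    config = SimulationConfig(n_lines=60, n_clusters=2, seed=9,
                              n_epistatic_clusters=0)
    gmap = config.make_map()
    rng = np.random.default_rng(9)
    geno = simulate_ril_genotypes(gmap, config.n_lines, rng)
    expr, truth = simulate_traits(geno, config, rng, gmap=gmap)
    meta = compute_meta_traits(expr, true_cluster_set(config, truth))
    return meta, geno, gmap


class TestDeltaEstimation:
    def test_within_published_bound_and_deterministic(self, null_fixture):
        meta, geno, gmap = null_fixture
        d1, se1 = estimate_delta(meta, geno, gmap, q=0.5, reps=100, seed=4)
        d2, _ = estimate_delta(meta, geno, gmap, q=0.5, reps=100, seed=4)
        assert 1.0 <= d1 <= DELTA_BOUND + 1e-9
        assert se1 >= 0
        assert d1 == d2

    def test_too_few_reps_rejected(self, null_fixture):
        meta, geno, gmap = null_fixture
        with pytest.raises(ValidationError):
            estimate_delta(meta, geno, gmap, reps=10)


from hypothesis import given, settings, strategies as st


class TestBHProperties:
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10),
           st.floats(0.01, 0.5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_step_up_matches_oracle_on_random_families(self, pvals, q):
        p = np.array(pvals)
        rej = bh_select(p, q)
        assert frozenset(np.flatnonzero(rej)) == bh_oracle(p, q)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30),
           st.floats(0.01, 0.5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rejections_below_threshold(self, pvals, q):
        p = np.array(pvals)
        rej = bh_select(p, q)
        k = int(rej.sum())
        if k:
            assert p[rej].max() <= k * q / len(p) + 1e-12
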