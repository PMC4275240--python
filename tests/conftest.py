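import numpy as np
import pandas as pd
import pytest

from epinoia import (ExpressionMatrix, GeneticMap, SimulationConfig,
                     compute_meta_traits, simulate_ril_genotypes,
                     simulate_traits, true_cluster_set)


@pytest.fixture(scope="session")
def toy_map() -> GeneticMap:
    table = pd.DataFrame(
        {"chromosome": ["1", "1", "2"], "position_cm": [0.0, 12.5, 3.0]},
        index=pd.Index(["m1", "m2", "m3"], name="marker"))
    return GeneticMap(table)


def make_expression(values: np.ndarray, traits=None, lines=None, reps=1):
    n_traits, n_samples = values.shape
    traits = traits or [f"t{i}" for i in range(n_traits)]
    n_lines = n_samples // reps
    lines = lines or [f"L{i}" for i in range(n_lines)]
    cols = pd.MultiIndex.from_tuples(
        [(l, k) for l in lines for k in range(1, reps + 1)],
        names=("line", "replicate"))
    return ExpressionMatrix(pd.DataFrame(values, index=traits, columns=cols))


@pytest.fixture(scope="session")
def planted_dataset():
    """One simulated dataset with a strong implanted epistatic pair.

    Returns (config, map, genotypes, expression, truth, meta-traits,
    clusters) for reuse across scan/CLI tests.
    """
    config = SimulationConfig(n_lines=211, n_reps=1, seed=7,
                              epistasis=-0.5, n_main_effects=2)
    gmap = config.make_map()
    rng = np.random.default_rng(42)
    geno = simulate_ril_genotypes(gmap, config.n_lines, rng)
    expr, truth = simulate_traits(geno, config, rng, gmap=gmap)
    clusters = true_cluster_set(config, truth)
    meta = compute_meta_traits(expr, clusters)
    return config, gmap, geno, expr, truth, meta, clusters
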