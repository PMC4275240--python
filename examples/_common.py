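"""Shared helper for the example scripts."""

import numpy as np
import pandas as pd

from epinoia import ExpressionMatrix


def make_expression(values: np.ndarray, reps: int = 1) -> ExpressionMatrix:
    n_traits, n_samples = values.shape
    n_lines = n_samples // reps
    cols = pd.MultiIndex.from_tuples(
        [(f"L{i:03d}", k) for i in range(n_lines) for k in range(1, reps + 1)],
        names=("line", "replicate"))
    index = [f"t{i:03d}" for i in range(n_traits)]
    return ExpressionMatrix(pd.DataFrame(values, index=index, columns=cols))
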