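"""Published accuracy matrices shipped as CSV fixtures.

These are the printed visual-vs-estimated contingency tables from the
2018 training and 2019 validation campaigns; they let every accuracy
rule be recomputed exactly without the (undeposited) field imagery.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

MATRIX_NAMES = (
    "accuracy_2018_proximal_ordinal",
    "accuracy_2018_proximal_binary",
    "accuracy_2018_aerial_binary",
    "accuracy_2019_proximal_ordinal",
    "accuracy_2019_proximal_binary",
    "accuracy_2019_aerial_binary",
)


def load_published_matrix(name: str) -> tuple[tuple, np.ndarray]:
    """Return (levels, counts) for one shipped contingency matrix."""
    if name not in MATRIX_NAMES:
        raise KeyError(f"unknown matrix {name!r}; choose from {MATRIX_NAMES}")
    ref = resources.files("canopywilt.data").joinpath(f"{name}.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    if df.columns.str.isdigit().all():
        levels = tuple(int(c) for c in df.columns)
    else:
        levels = tuple(df.columns)
    return levels, df.to_numpy(dtype=int)
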