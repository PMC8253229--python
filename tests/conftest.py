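"""Shared fixtures: synthetic fields and tables generated at test time."""

import numpy as np
import pandas as pd
import pytest

import canopywilt as cw


def extract_field_table(n_plots: int, seed: int) -> pd.DataFrame:
    """Render a field, crop it, extract indices, and join the truth scores."""
    cfg = cw.FieldSimConfig(n_plots=n_plots, seed=seed)
    mosaic, layout, truth = cw.render_field(cfg)
    plots = cw.crop_plots(mosaic, layout)
    rows = []
    for plot in plots[:n_plots]:
        plot = cw.mask_dark_fill(plot, 0)
        rows.append({"plot_id": plot.plot_id, **cw.extract_indices(plot).as_dict()})
    return pd.DataFrame(rows).merge(truth[["plot_id", "score"]], on="plot_id")


@pytest.fixture(scope="session")
def field_table_168():
    """Extracted indices + truth for a 168-plot rendered field (study scale)."""
    return extract_field_table(168, seed=42)


@pytest.fixture(scope="session")
def sim_table_800():
    """Directly simulated 800-row index table from the default generating model."""
    return cw.simulate_index_table(cw.FieldSimConfig(n_plots=800, seed=7))


@pytest.fixture
def green_image():
    return cw.PlotImage(np.full((10, 10, 3), (0, 255, 0), dtype=np.uint8))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
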