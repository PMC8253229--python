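"""Synthetic peanut-canopy imagery and index tables with known truth.

Two generator tiers:

* **Pixel tier** — :func:`render_canopy` paints elliptical leaf blobs over
  bright sandy soil.  Canopy cover shrinks and leaf hue slides from green
  (~115 deg) toward yellow (~62 deg) as the wilting score rises, emulating
  the visual contrast between a turgid plant (green, no bare ground) and a
  severely wilted one (light green/yellow leaves, soil fully visible).
  :func:`render_field` tiles plot renders into a mosaic with black gutters
  plus the matching grid layout and truth table, exercising the whole
  rotate/crop/mask/extract pipeline.

* **Table tier** — :func:`simulate_index_table` draws index vectors from
  plausible ranges and samples ordinal scores from a *known*
  cumulative-logit generating model, giving exact generative truth for
  parameter-recovery and selection tests.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError
from .imaging import GridLayout, PlotImage
from .indices import INDEX_COLUMNS, circular_mean_deg, compute_csi
from .models import OrdinalLogisticModel, predict_ordinal

SCORES = (0, 1, 2, 3, 4, 5)


@dataclass
class CanopyRenderParams:
    """Appearance of one rendered plot as a function of the wilting score.

    Cover fractions and hue centers decrease with the score; per-plot
    Gaussian jitter (``cover_sd``, ``hue_center_sd``) reproduces the large
    plot-to-plot variation real fields show within one visual score.
    """

    image_size: tuple[int, int] = (64, 64)
    leaf_cover_by_score: tuple = (0.95, 0.85, 0.72, 0.58, 0.42, 0.28)
    leaf_hue_by_score: tuple = (115.0, 108.0, 98.0, 88.0, 75.0, 62.0)
    cover_sd: float = 0.06
    hue_center_sd: float = 6.0
    hue_jitter_sd: float = 8.0  # per-blob hue spread, degrees
    leaf_intensity_by_score: tuple = (0.26, 0.28, 0.30, 0.32, 0.34, 0.36)
    intensity_jitter_sd: float = 0.04
    leaf_saturation: float = 0.60
    saturation_jitter_sd: float = 0.08
    # dry sandy loam, brighter than the foliage in both channel-mean
    # intensity and CIE lightness (midday bare soil)
    soil_rgb: tuple = (170, 140, 110)
    leaf_radius_range: tuple = (3, 7)
    max_blobs: int = 6000

    def __post_init__(self) -> None:
        covers = np.asarray(self.leaf_cover_by_score)
        hues = np.asarray(self.leaf_hue_by_score)
        if not ((covers >= 0) & (covers <= 1)).all() or (np.diff(covers) > 0).any():
            raise ValueError("cover fractions must lie in [0,1] and not increase with score")
        if not ((hues > 0) & (hues < 180)).all() or (np.diff(hues) > 0).any():
            raise ValueError("hue centers must lie in (0,180) and not increase with score")


#: Generating model used by default for index-table simulation: wilting is
#: driven by senescence (CSI up), reddening (a* up) and green-cover loss
#: (GA down), with thresholds spreading mass over all six levels.
DEFAULT_GENERATING_MODEL = OrdinalLogisticModel(
    thresholds=[-4.0, -2.0, -0.3, 1.2, 3.0],
    coefficients={"csi": -0.06, "a_star": -0.18, "ga": 6.0},
    levels=SCORES,
)


@dataclass
class FieldSimConfig:
    """Study-scale defaults mirror the 168-plot field with all six scores."""

    n_plots: int = 168
    level_distribution: tuple = (0.10, 0.25, 0.25, 0.20, 0.12, 0.08)
    generating_model: OrdinalLogisticModel = field(
        default_factory=lambda: DEFAULT_GENERATING_MODEL
    )
    noise_sd: float = 0.02  # relative measurement noise on each index
    seed: int = 0

    def __post_init__(self) -> None:
        dist = np.asarray(self.level_distribution, dtype=float)
        if self.n_plots < 1:
            raise ValueError("n_plots must be at least 1")
        if abs(dist.sum() - 1.0) > 1e-9 or (dist < 0).any():
            raise ValueError("level_distribution must be a probability vector")


def hsi_to_rgb(hue_deg: float, saturation: float, intensity: float) -> np.ndarray:
    """Inverse of the arccos-form HSI triple; returns a uint8 sRGB triplet."""
    h = hue_deg % 360.0
    s = float(np.clip(saturation, 0.0, 1.0))
    i = float(np.clip(intensity, 0.0, 1.0))
    h_rad = math.radians(h % 120.0)
    shift = int(h // 120.0)  # 0: RG sector, 1: GB, 2: BR
    c1 = i * (1 - s)
    c2 = i * (1 + s * math.cos(h_rad) / math.cos(math.radians(60.0) - h_rad))
    c3 = 3.0 * i - (c1 + c2)
    sector = [(c2, c3, c1), (c1, c2, c3), (c3, c1, c2)][shift]
    return np.clip(np.round(np.array(sector) * 255.0), 0, 255).astype(np.uint8)


def _ellipse_mask(h, w, cy, cx, ry, rx, angle, rows, cols):
    dy, dx = rows - cy, cols - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def render_canopy(
    score: int,
    params: CanopyRenderParams | None = None,
    seed: int | np.random.Generator = 0,
    plot_id: str = "",
) -> tuple[PlotImage, dict]:
    """Render one plot at the given wilting score.

    Leaf blobs accumulate until the plot's target cover fraction is
    reached.  Returns the image plus ground-truth appearance stats
    (realized cover fraction, circular-mean leaf hue, target cover).
    """
    if score not in SCORES:
        raise ValueError(f"score must be in {SCORES}, got {score}")
    params = params or CanopyRenderParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = params.image_size
    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:] = np.asarray(params.soil_rgb, dtype=np.uint8)
    target = float(np.clip(
        params.leaf_cover_by_score[score] + rng.normal(0.0, params.cover_sd), 0.05, 0.98
    ))
    hue_center = params.leaf_hue_by_score[score] + rng.normal(0.0, params.hue_center_sd)
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    leaf_mask = np.zeros((h, w), dtype=bool)
    hues: list[float] = []
    r_lo, r_hi = params.leaf_radius_range
    attempts = 0
    while leaf_mask.mean() < target:
        if attempts >= params.max_blobs:
            raise GenerationError(
                f"cover target {target:.2f} unreachable within {params.max_blobs} blobs"
            )
        attempts += 1
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(r_lo, r_hi, size=2)
        angle = rng.uniform(0, math.pi)
        blob = _ellipse_mask(h, w, cy, cx, ry, rx, angle, rows, cols)
        hue = float(np.clip(hue_center + rng.normal(0.0, params.hue_jitter_sd), 30.0, 150.0))
        sat = float(np.clip(
            params.leaf_saturation + rng.normal(0.0, params.saturation_jitter_sd), 0.15, 0.95
        ))
        inten = float(np.clip(
            params.leaf_intensity_by_score[score] + rng.normal(0.0, params.intensity_jitter_sd),
            0.08, 0.8,
        ))
        pixels[blob] = hsi_to_rgb(hue, sat, inten)
        new = blob & ~leaf_mask
        if new.any():
            hues.extend([hue] * int(new.sum()))
        leaf_mask |= blob
    stats = {
        "target_cover": target,
        "realized_cover": float(leaf_mask.mean()),
        "mean_leaf_hue": circular_mean_deg(np.array(hues)) if hues else float("nan"),
    }
    return PlotImage(pixels, plot_id=plot_id, source="aerial"), stats


def render_field(
    config: FieldSimConfig, params: CanopyRenderParams | None = None, gutter_px: int = 4
) -> tuple[PlotImage, GridLayout, pd.DataFrame]:
    """Tile per-plot renders into one mosaic with black gutters.

    Returns the mosaic, the matching :class:`GridLayout`, and a truth
    table (plot_id, score, realized cover, mean leaf hue).  Cropping the
    mosaic with the layout recovers each plot render exactly.
    """
    params = params or CanopyRenderParams()
    rng = np.random.default_rng(config.seed)
    scores = rng.choice(SCORES, size=config.n_plots, p=config.level_distribution)
    n_cols = int(math.ceil(math.sqrt(config.n_plots)))
    n_rows = int(math.ceil(config.n_plots / n_cols))
    ph, pw = params.image_size
    H = n_rows * ph + (n_rows - 1) * gutter_px
    W = n_cols * pw + (n_cols - 1) * gutter_px
    mosaic = np.zeros((H, W, 3), dtype=np.uint8)
    records = []
    for i in range(n_rows * n_cols):
        row, col = divmod(i, n_cols)
        plot_id = f"R{row + 1}C{col + 1}"
        score = int(scores[i]) if i < config.n_plots else 0
        plot, stats = render_canopy(score, params, rng, plot_id=plot_id)
        r0 = row * (ph + gutter_px)
        c0 = col * (pw + gutter_px)
        mosaic[r0:r0 + ph, c0:c0 + pw] = plot.pixels
        if i < config.n_plots:
            records.append({"plot_id": plot_id, "score": score, **stats})
    layout = GridLayout(
        origin_row=0, origin_col=0, plot_height_px=ph, plot_width_px=pw,
        n_rows=n_rows, n_cols=n_cols, row_gap_px=gutter_px, col_gap_px=gutter_px,
    )
    return (
        PlotImage(mosaic, source="aerial", plot_id="field"),
        layout,
        pd.DataFrame.from_records(records),
    )


#: Plausible sampling ranges for the direct index simulator: (mean, sd, lo, hi)
_INDEX_RANGES = {
    "intensity": (0.35, 0.08, 0.0, 1.0),
    "hue": (90.0, 18.0, 0.0, 359.9),
    "saturation": (0.45, 0.15, 0.0, 1.0),
    "lightness": (42.0, 9.0, 0.0, 100.0),
    "a_star": (-8.0, 6.0, -60.0, 60.0),
    "b_star": (22.0, 7.0, -60.0, 80.0),
    "u_star": (-5.0, 7.0, -60.0, 80.0),
    "v_star": (26.0, 8.0, -60.0, 80.0),
}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_index_table(config: FieldSimConfig) -> pd.DataFrame:
    """Index table with scores sampled from the known generating model.

    GA/GGA respect the band-subset invariant and CSI is computed from
    them, never drawn.  Measurement noise (``noise_sd``, relative to each
    index's spread) is added *after* the scores are sampled, then indices
    are clipped back to their legal ranges and CSI recomputed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_plots
    cols = {
        name: _truncated_normal(rng, *_INDEX_RANGES[name], size=n)
        for name in _INDEX_RANGES
    }
    ga = np.clip(rng.beta(3.0, 1.6, size=n), 0.02, 0.99)
    gga = ga * rng.beta(2.0, 2.5, size=n)
    cols["ga"], cols["gga"] = ga, gga
    cols["csi"] = np.array([compute_csi(g, gg) for g, gg in zip(ga, gga)])
    table = pd.DataFrame(cols)[list(INDEX_COLUMNS)]

    probs = np.stack([
        predict_ordinal(config.generating_model, row).probabilities
        for row in table.to_dict("records")
    ])
    levels = np.asarray(config.generating_model.levels)
    draws = rng.random(n)
    cum = probs.cumsum(axis=1)
    table["score"] = levels[(draws[:, None] < cum).argmax(axis=1)]

    if config.noise_sd > 0:
        for name, (_, sd, lo, hi) in _INDEX_RANGES.items():
            table[name] = np.clip(
                table[name] + rng.normal(0.0, config.noise_sd * sd, size=n), lo, hi
            )
        ga_noise = rng.normal(0.0, config.noise_sd * 0.2, size=n)
        table["ga"] = np.clip(table["ga"] + ga_noise, 0.01, 1.0)
        table["gga"] = np.clip(table["gga"] + rng.normal(0.0, config.noise_sd * 0.2, size=n),
                               0.0, table["ga"])
        table["csi"] = [compute_csi(g, gg) for g, gg in zip(table["ga"], table["gga"])]
    table["status"] = ["turgid" if s <= 1 else "wilted" for s in table["score"]]
    return table
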