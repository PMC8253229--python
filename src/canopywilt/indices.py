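"""The 11 RGB color-space indices used for wilting estimation.

Per-pixel conversions (HSI, CIE-Lab, CIE-Luv) feed per-plot summaries:
channel-space means for intensity/saturation/lightness/a*/b*/u*/v*, a
circular mean for hue, and the three vegetation fractions

* GA  (green area):   fraction of pixels with hue in the 60-120 degree band,
* GGA (greener area): fraction with hue in the stricter 80-120 degree band,
* CSI (crop senescence index): ``100 * (GA - GGA) / GA``.

The bands live on the angular hue scale where red sits at 0, yellow at 60
and green at 120 degrees (the HSI hue also reported in the ``hue`` column);
band boundaries are closed.  Larger CSI means a yellower, more senescent
canopy.  All CIE conversions assume the sRGB transfer function and the
D65 white point (2-degree observer) — the consumer-camera default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .errors import DegenerateImageError
from .imaging import PlotImage

logger = logging.getLogger(__name__)

#: Column order used in every index table this package reads or writes.
INDEX_COLUMNS = (
    "intensity",
    "hue",
    "saturation",
    "lightness",
    "a_star",
    "b_star",
    "u_star",
    "v_star",
    "ga",
    "gga",
    "csi",
)

GA_BAND = (60.0, 120.0)
GGA_BAND = (80.0, 120.0)

# tolerance so boundary hues (e.g. pure green at exactly 120 deg) are not
# dropped by floating-point round-off; the bands are closed intervals
_BAND_EPS = 1e-9


def _band_fraction(hue: np.ndarray, chromatic: np.ndarray, band: tuple) -> float:
    lo, hi = band
    inside = chromatic & (hue >= lo - _BAND_EPS) & (hue <= hi + _BAND_EPS)
    return float(np.mean(inside))


@dataclass
class ColorIndexVector:
    """The 11 per-plot indices, in the units the field literature uses."""

    intensity: float  # [0, 1]
    hue: float  # degrees [0, 360); NaN when every pixel is achromatic
    saturation: float  # [0, 1]
    lightness: float  # L* [0, 100]
    a_star: float
    b_star: float
    u_star: float
    v_star: float
    ga: float  # fraction [0, 1]
    gga: float  # fraction [0, 1]
    csi: float  # [0, 100]

    def __post_init__(self) -> None:
        if not (0.0 <= self.gga <= self.ga <= 1.0) and not np.isnan(self.ga):
            raise ValueError(
                f"GGA ({self.gga}) must lie in [0, GA] with GA ({self.ga}) in [0, 1]"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_COLUMNS}

    @classmethod
    def from_mapping(cls, mapping) -> "ColorIndexVector":
        return cls(**{name: float(mapping[name]) for name in INDEX_COLUMNS})


def _as_unit_rgb(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.max(initial=0.0) > 255.0 or arr.min(initial=0.0) < 0.0:
        raise ValueError("channel values must lie in [0, 255]")
    return arr.reshape(-1, 3) / 255.0


def rgb_to_hsi(pixels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical HSI triple: intensity (channel mean), hue (arccos form), saturation.

    Accepts one sRGB triplet or an (N, 3) array of them, channels in [0, 255].
    Hue is in degrees with red at 0 and green at 120; achromatic pixels
    (saturation 0) get hue NaN.
    """
    rgb = _as_unit_rgb(pixels)
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    intensity = rgb.mean(axis=1)
    minc = rgb.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(intensity > 0, 1.0 - minc / intensity, 0.0)
        saturation = np.clip(saturation, 0.0, 1.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cosine = np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosine))
    hue = np.where(b <= g, theta, 360.0 - theta)
    # achromatic = equal channels; guard against float round-off in saturation
    achromatic = (saturation <= 1e-12) | (den == 0)
    hue = np.where(~achromatic, hue % 360.0, np.nan)
    if np.asarray(pixels).ndim == 1:
        return intensity[0], hue[0], saturation[0]
    return intensity, hue, saturation


def rgb_to_lab(pixels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sRGB -> linear RGB -> XYZ (D65) -> CIE-Lab; returns (L*, a*, b*)."""
    rgb = _as_unit_rgb(pixels)
    lab = skcolor.rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)
    if np.asarray(pixels).ndim == 1:
        return lab[0, 0], lab[0, 1], lab[0, 2]
    return lab[:, 0], lab[:, 1], lab[:, 2]


def rgb_to_luv(pixels) -> tuple[np.ndarray, np.ndarray]:
    """sRGB -> CIE-Luv via u'v' chromaticity, D65 white; returns (u*, v*)."""
    rgb = _as_unit_rgb(pixels)
    luv = skcolor.rgb2luv(rgb.reshape(1, -1, 3)).reshape(-1, 3)
    if np.asarray(pixels).ndim == 1:
        return luv[0, 1], luv[0, 2]
    return luv[:, 1], luv[:, 2]


def lab_hue_angle(a_star, b_star):
    """CIE-Lab hue angle ``atan2(b*, a*)`` in degrees wrapped to [0, 360)."""
    return np.degrees(np.arctan2(b_star, a_star)) % 360.0


def _included_or_raise(image: PlotImage) -> np.ndarray:
    pix = image.included_pixels()
    if pix.shape[0] == 0:
        raise DegenerateImageError(
            f"plot {image.plot_id or '<unnamed>'} has no included pixels"
        )
    return pix


def compute_ga_gga(image: PlotImage) -> tuple[float, float]:
    """Green-area and greener-area fractions over the included pixels."""
    pix = _included_or_raise(image)
    _, hue, _ = rgb_to_hsi(pix)
    chromatic = ~np.isnan(hue)
    hue = np.where(chromatic, hue, -1.0)
    return _band_fraction(hue, chromatic, GA_BAND), _band_fraction(hue, chromatic, GGA_BAND)


def compute_csi(ga: float, gga: float) -> float:
    """Crop senescence index ``100 * (GA - GGA) / GA``; 0 (warned) when GA = 0."""
    if gga > ga + 1e-12:
        raise ValueError(f"GGA ({gga}) exceeds GA ({ga}); band subset violated")
    if ga <= 0.0:
        logger.warning("GA is zero; CSI is undefined and reported as 0")
        return 0.0
    return float(100.0 * (ga - gga) / ga)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Vector-mean direction of angles in degrees, wrapped to [0, 360)."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    ang = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)
    return 0.0 if ang >= 360.0 - 1e-9 else ang


def extract_indices(image: PlotImage) -> ColorIndexVector:
    """Compute the full 11-index vector for one plot image.

    Means are taken over included pixels only; hue is the circular mean
    over chromatic pixels (NaN if the plot is entirely achromatic).
    """
    pix = _included_or_raise(image)
    intensity, hue, saturation = rgb_to_hsi(pix)
    lightness, a_star, b_star = rgb_to_lab(pix)
    u_star, v_star = rgb_to_luv(pix)
    chromatic = ~np.isnan(hue)
    mean_hue = circular_mean_deg(hue[chromatic]) if chromatic.any() else float("nan")
    valid_hue = np.where(chromatic, hue, -1.0)
    ga = _band_fraction(valid_hue, chromatic, GA_BAND)
    gga = _band_fraction(valid_hue, chromatic, GGA_BAND)
    return ColorIndexVector(
        intensity=float(intensity.mean()),
        hue=mean_hue,
        saturation=float(saturation.mean()),
        lightness=float(lightness.mean()),
        a_star=float(a_star.mean()),
        b_star=float(b_star.mean()),
        u_star=float(u_star.mean()),
        v_star=float(v_star.mean()),
        ga=ga,
        gga=gga,
        csi=compute_csi(ga, gga),
    )
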