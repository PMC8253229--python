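"""Plot-image I/O, mosaic rotation, grid cropping and dark-fill masking.

Aerial field mosaics are rotated so crop rows run parallel to the image
axes, then individual plot rows are cut out by an explicit pixel grid
(``GridLayout``).  Black padding introduced by rotation (the "hallow"
around obliquely cropped rows) is excluded from the pixel mask so it
cannot bias per-plot color-index means.

Coordinate convention: row-major, origin at the top-left, 0-based,
half-open rectangles ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DegenerateImageError, ImageFormatError, LayoutError

SOURCES = ("proximal", "aerial")


@dataclass
class PlotImage:
    """An 8-bit sRGB raster for one plot row plus an inclusion mask.

    ``mask`` is True where a pixel participates in index computation;
    rotation padding and dark fill are excluded by setting it False.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray = None  # (H, W) bool
    plot_id: str = ""
    source: str = "proximal"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError(
                f"expected an (H, W, 3) RGB raster, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ImageFormatError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise ImageFormatError(
                f"mask shape {self.mask.shape} != image shape {self.pixels.shape[:2]}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_included(self) -> int:
        return int(self.mask.sum())

    def included_pixels(self) -> np.ndarray:
        """Return the included pixels as an (N, 3) uint8 array."""
        return self.pixels[self.mask]


@dataclass
class GridLayout:
    """Pixel geometry of the plot grid on a (rotated) field mosaic."""

    origin_row: int
    origin_col: int
    plot_height_px: int
    plot_width_px: int
    n_rows: int
    n_cols: int
    row_gap_px: int = 0
    col_gap_px: int = 0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.plot_height_px <= 0 or self.plot_width_px <= 0:
            raise LayoutError("plot dimensions must be strictly positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutError("grid must contain at least one plot")
        if self.row_gap_px < 0 or self.col_gap_px < 0:
            raise LayoutError("gaps must be nonnegative")

    def rect(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open rectangle (r0, r1, c0, c1) of plot (row, col), 0-based."""
        r0 = self.origin_row + row * (self.plot_height_px + self.row_gap_px)
        c0 = self.origin_col + col * (self.plot_width_px + self.col_gap_px)
        return r0, r0 + self.plot_height_px, c0, c0 + self.plot_width_px

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {getattr(self, k)}" for k in self.__dataclass_fields__]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GridLayout":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in cls.__dataclass_fields__:
                raise LayoutError(f"unknown layout key {key!r} in {path}")
            cast = float if key == "rotation_deg" else int
            kwargs[key] = cast(value.strip())
        return cls(**kwargs)


def load_plot_image(path: str | Path, source: str = "proximal") -> PlotImage:
    """Read a JPEG/PNG plot image into a :class:`PlotImage` with all-true mask.

    16-bit inputs are rescaled to 8-bit.  Grayscale or CMYK files raise
    :class:`ImageFormatError`; unreadable paths raise ``OSError``.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise OSError(f"could not read image file {path}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ImageFormatError(f"{path} is grayscale; an RGB image is required")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageFormatError(f"{path} is not an RGB image (shape {arr.shape})")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ImageFormatError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return PlotImage(arr, plot_id=path.stem, source=source)


def save_plot_image(image: PlotImage, directory: str | Path) -> Path:
    """Write ``image`` as ``{plot_id}.png`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{image.plot_id or 'plot'}.png"
    iio.imwrite(out, image.pixels)
    return out


def _rotation_geometry(shape: tuple[int, int], angle_deg: float):
    h, w = shape
    theta = math.radians(angle_deg)
    c, s = abs(math.cos(theta)), abs(math.sin(theta))
    h2 = int(round(h * c + w * s))
    w2 = int(round(w * c + h * s))
    return h2, w2, theta


def rotate_mosaic(image: PlotImage, angle_deg: float) -> PlotImage:
    """Rotate counter-clockwise by ``angle_deg`` with nearest-neighbor sampling.

    The canvas expands to hold the rotated content; padding pixels are
    black and excluded from the mask.  Multiples of 90 degrees are exact.
    """
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    a = angle_deg % 360.0
    if a == 0.0:
        return replace(image, pixels=image.pixels.copy(), mask=image.mask.copy())
    if a % 90.0 == 0.0:
        k = int(a // 90)
        return replace(
            image,
            pixels=np.ascontiguousarray(np.rot90(image.pixels, k)),
            mask=np.ascontiguousarray(np.rot90(image.mask, k)),
        )
    h, w = image.shape
    h2, w2, theta = _rotation_geometry(image.shape, a)
    cy1, cx1 = (h - 1) / 2.0, (w - 1) / 2.0
    cy2, cx2 = (h2 - 1) / 2.0, (w2 - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(h2), np.arange(w2), indexing="ij")
    x2, y2 = cc - cx2, rr - cy2
    # inverse map: visually-CCW rotation with the row axis pointing down
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    x1 = cos_t * x2 - sin_t * y2 + cx1
    y1 = sin_t * x2 + cos_t * y2 + cy1
    rs = np.rint(y1).astype(np.int64)
    cs = np.rint(x1).astype(np.int64)
    inside = (rs >= 0) & (rs < h) & (cs >= 0) & (cs < w)
    rs_c, cs_c = rs.clip(0, h - 1), cs.clip(0, w - 1)
    pixels = np.where(inside[..., None], image.pixels[rs_c, cs_c], 0).astype(np.uint8)
    mask = inside & image.mask[rs_c, cs_c]
    return replace(image, pixels=pixels, mask=mask)


def crop_plots(mosaic: PlotImage, layout: GridLayout) -> list[PlotImage]:
    """Cut the layout's plot rectangles out of the (pre-rotated) mosaic.

    Returns ``n_rows * n_cols`` plots in row-major order with ids
    ``R{row}C{col}`` (1-based labels); masks are inherited from the mosaic.
    """
    if layout.rotation_deg:
        mosaic = rotate_mosaic(mosaic, layout.rotation_deg)
    h, w = mosaic.shape
    plots = []
    for row in range(layout.n_rows):
        for col in range(layout.n_cols):
            r0, r1, c0, c1 = layout.rect(row, col)
            plot_id = f"R{row + 1}C{col + 1}"
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise LayoutError(
                    f"plot {plot_id} rectangle [{r0},{r1})x[{c0},{c1}) "
                    f"exceeds mosaic bounds {h}x{w}"
                )
            plots.append(
                PlotImage(
                    mosaic.pixels[r0:r1, c0:c1].copy(),
                    mosaic.mask[r0:r1, c0:c1].copy(),
                    plot_id=plot_id,
                    source=mosaic.source,
                )
            )
    return plots


def mask_dark_fill(image: PlotImage, threshold: int = 0) -> PlotImage:
    """Exclude near-black fill: pixels with ``max(R,G,B) <= threshold``.

    The default 0 removes only pure-black padding.  Raises
    :class:`DegenerateImageError` if nothing would remain included.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    dark = image.pixels.max(axis=2) <= threshold
    mask = image.mask & ~dark
    if not mask.any():
        raise DegenerateImageError(
            f"masking at threshold {threshold} excludes every pixel of "
            f"plot {image.plot_id or '<unnamed>'}"
        )
    return replace(image, pixels=image.pixels.copy(), mask=mask)
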