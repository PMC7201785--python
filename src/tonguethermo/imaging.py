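"""Thermal-image plumbing: palette rendering/inversion, I/O and preprocessing.

A radiometric camera measures a latent surface-temperature field; the
false-colour thermogram the analyst sees is that field rendered through a
palette with a fixed temperature scale.  This module converts between the two
representations (``temp_to_rgb`` / ``rgb_to_temp``), reads and writes PNG/TIFF
thermograms and CSV temperature matrices, and provides the preprocessing used
by the screening pipeline: bilinear resize to 256x256 and Gaussian smoothing.

Conventions: all pixel coordinates are 0-based row-major; rectangles are
half-open ``[r0, r0+h) x [c0, c0+w)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

try:
    import tifffile
except ImportError:  # pragma: no cover
    tifffile = None

__all__ = [
    "TemperatureField",
    "RainbowPalette",
    "ColorThermogram",
    "ROISpec",
    "temp_to_rgb",
    "rgb_to_temp",
    "resize_256",
    "gaussian_smooth",
    "mean_roi_temperature",
]


@dataclass
class TemperatureField:
    """H x W surface-temperature matrix in degrees Celsius.

    ``mm_per_pixel`` carries the spatial calibration when known (used to
    convert the physical ROI size to pixels).  ``tongue_mask`` is an optional
    boolean matrix marking tongue pixels; the synthetic generator fills it in,
    real acquisitions leave it ``None``.
    """

    values: np.ndarray
    mm_per_pixel: float | None = None
    tongue_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("temperature field must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path, mm_per_pixel: float | None = None) -> "TemperatureField":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2), mm_per_pixel=mm_per_pixel)


def _hsv_rainbow(n: int = 256) -> np.ndarray:
    """Blue-to-red HSV sweep (hue 240 deg -> 0 deg) at full saturation.

    Peak channel value is 252, matching the upper bound of the calibrated
    red-component threshold interval (a fully saturated 255 would put every
    hot pixel outside the red row).
    """
    import matplotlib.colors as mcolors

    hue = np.linspace(240.0, 0.0, n) / 360.0
    hsv = np.stack([hue, np.ones(n), np.ones(n)], axis=1)
    rgb = mcolors.hsv_to_rgb(hsv)
    return np.round(rgb * 252).astype(np.uint8)


@dataclass
class RainbowPalette:
    """256-entry RGB colour map with the temperature scale it encodes.

    Temperatures in ``[t_min, t_max]`` are linearly binned into the 256
    entries; inversion maps a pixel to the bin midpoint of its nearest entry.
    The default is a blue-to-red HSV sweep standing in for the camera
    vendor's proprietary rainbow, with a fixed 30-36 deg C scale: under that
    scale the tongue (roughly 33-37 deg C) spans the palette's green-to-red
    range, the warmest diabetic centre regions fall in the red-component
    threshold band and cool normal tongue margins in the blue one, matching
    the segmented morphology the pipeline is built around.
    """

    colors: np.ndarray = field(default_factory=_hsv_rainbow)
    t_min: float = 30.0
    t_max: float = 36.0

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        if self.colors.shape != (256, 3):
            raise ValueError("palette must have exactly 256 RGB entries")
        if not self.t_min < self.t_max:
            raise ValueError("palette scale requires t_min < t_max")
        # nearest-neighbour inversion must be single-valued on the entry set
        if len({tuple(c) for c in self.colors.tolist()}) != 256:
            raise ValueError("palette entries must be pairwise distinct")

    @property
    def step(self) -> float:
        return (self.t_max - self.t_min) / 256.0

    def bin_midpoints(self) -> np.ndarray:
        return self.t_min + (np.arange(256) + 0.5) * self.step

    def to_json(self, path: str | Path) -> None:
        payload = {
            "t_min": self.t_min,
            "t_max": self.t_max,
            "colors": self.colors.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RainbowPalette":
        payload = json.loads(Path(path).read_text())
        return cls(
            colors=np.asarray(payload["colors"], dtype=np.uint8),
            t_min=float(payload["t_min"]),
            t_max=float(payload["t_max"]),
        )


@dataclass
class ColorThermogram:
    """8-bit RGB rendering of a temperature field.

    ``palette`` records the palette/scale the image was rendered under; it is
    ``None`` for foreign images whose scale is unknown.
    """

    pixels: np.ndarray
    palette: RainbowPalette | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("thermogram must be a non-empty H x W x 3 image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"} and tifffile is not None:
            tifffile.imwrite(path, self.pixels)
        else:
            Image.fromarray(self.pixels, mode="RGB").save(path)

    @classmethod
    def load(cls, path: str | Path, palette: RainbowPalette | None = None) -> "ColorThermogram":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"} and tifffile is not None:
            arr = np.asarray(tifffile.imread(path))
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(arr, palette=palette)


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle: top-left (row, col), height, width, in pixels."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI top-left must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))

    def check_inside(self, shape: tuple[int, int]) -> None:
        if self.row + self.height > shape[0] or self.col + self.width > shape[1]:
            raise ValueError(f"ROI {self} does not fit inside image of shape {shape}")


def temp_to_rgb(fld: TemperatureField, palette: RainbowPalette | None = None) -> ColorThermogram:
    """Render a temperature field through a palette.

    Temperatures are clamped to the scale, linearly binned into 256 levels
    and mapped to the corresponding palette entry.
    """
    palette = palette or RainbowPalette()
    frac = (fld.values - palette.t_min) / (palette.t_max - palette.t_min)
    idx = np.clip(np.floor(frac * 256).astype(int), 0, 255)
    return ColorThermogram(palette.colors[idx], palette=palette)


def rgb_to_temp(img: ColorThermogram, palette: RainbowPalette | None = None) -> TemperatureField:
    """Invert a palette rendering back to approximate temperatures.

    Each pixel is assigned the bin-midpoint temperature of the palette entry
    nearest in RGB Euclidean distance, so a render/invert round trip is exact
    to within half a quantization step for in-range fields.
    """
    palette = palette or img.palette or RainbowPalette()
    px = img.pixels.reshape(-1, 3).astype(np.int32)
    pal = palette.colors.astype(np.int32)
    # squared distance to all 256 entries; ||p||^2 term constant per pixel
    d2 = (
        (px ** 2).sum(axis=1, keepdims=True)
        - 2 * px @ pal.T
        + (pal ** 2).sum(axis=1)[None, :]
    )
    idx = np.argmin(d2, axis=1)
    temps = palette.bin_midpoints()[idx].reshape(img.shape)
    return TemperatureField(temps)


def resize_256(img: ColorThermogram, size: int = 256) -> ColorThermogram:
    """Bilinear resize to ``size`` x ``size`` (the pipeline's working size)."""
    if img.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if img.shape == (size, size):
        return ColorThermogram(img.pixels.copy(), palette=img.palette)
    out = Image.fromarray(img.pixels, mode="RGB").resize(
        (size, size), resample=Image.Resampling.BILINEAR
    )
    return ColorThermogram(np.asarray(out), palette=img.palette)


def gaussian_smooth(img: ColorThermogram, sigma: float = 1.0) -> ColorThermogram:
    """Per-channel Gaussian filtering with reflect padding.

    Kernel radius is ceil(3*sigma), which captures >99.7% of the kernel mass,
    so the per-channel mean is preserved up to integer rounding.
    """
    from scipy import ndimage

    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = np.empty_like(img.pixels, dtype=float)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(
            img.pixels[..., c].astype(float), sigma=sigma,
            mode="reflect", truncate=np.ceil(3 * sigma) / sigma,
        )
    return ColorThermogram(np.clip(np.round(out), 0, 255).astype(np.uint8),
                           palette=img.palette)


def mean_roi_temperature(fld: TemperatureField, roi: ROISpec) -> float:
    """Arithmetic mean temperature over the half-open ROI rectangle."""
    roi.check_inside(fld.shape)
    return float(fld.values[roi.slices()].mean())
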