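"""RGB colour-histogram threshold segmentation of tongue thermograms.

Under a rainbow palette, warm regions render red and cool regions render
blue, so splitting the thermogram into red/green/blue colour components
isolates hot spots, midrange tissue and cold spots respectively.  A pixel
belongs to a component when each of its R, G, B channel values lies inside
that component's (min, max) interval; the default intervals are the
calibrated table from the reference study.  The red (hot-spot) component is
then converted to grayscale for texture analysis, with the measurement ROI
placed at the centre of the tongue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import reference
from .imaging import ColorThermogram, ROISpec

__all__ = [
    "ChannelThresholds",
    "ThresholdTable",
    "ComponentMask",
    "GrayImage",
    "threshold_gray",
    "segment_component",
    "segment_all",
    "red_to_gray",
    "center_roi",
]

# Rec. 601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.2989, 0.5870, 0.1140])

# Extrapolated rule for the white component seen in segmented figures but
# absent from the published threshold table; off by default.
WHITE_THRESHOLDS_MIN = 240


@dataclass(frozen=True)
class ChannelThresholds:
    """Inclusive (min, max) bounds on each RGB channel for one colour component."""

    name: str
    r: tuple[int, int]
    g: tuple[int, int]
    b: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.r, self.g, self.b):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(
                    f"invalid channel bounds ({lo}, {hi}) for component {self.name!r}"
                )

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an H x W x 3 uint8 array."""
        px = np.asarray(pixels)
        out = np.ones(px.shape[:2], dtype=bool)
        for c, (lo, hi) in enumerate((self.r, self.g, self.b)):
            out &= (px[..., c] >= lo) & (px[..., c] <= hi)
        return out


@dataclass(frozen=True)
class ComponentMask:
    """Binary membership mask for one colour component."""

    mask: np.ndarray
    name: str

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())

    def count(self) -> int:
        return int(self.mask.sum())

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray((self.mask * 255).astype(np.uint8), mode="L").save(path)


class GrayImage:
    """H x W matrix of 8-bit gray levels."""

    def __init__(self, values: np.ndarray):
        v = np.asarray(values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("gray image must be a non-empty 2-D matrix")
        if v.min() < 0 or v.max() > 255:
            raise ValueError("gray levels must lie in [0, 255]")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


class ThresholdTable:
    """The three colour-component threshold rows (red, green, blue)."""

    COMPONENTS = ("red", "green", "blue")

    def __init__(self, rows: dict[str, ChannelThresholds] | None = None):
        if rows is None:
            rows = {
                name: ChannelThresholds(name, *bounds)
                for name, bounds in reference.RGB_THRESHOLDS.items()
            }
        if set(rows) != set(self.COMPONENTS):
            raise ValueError(f"threshold table needs exactly the rows {self.COMPONENTS}")
        self.rows = rows

    def __getitem__(self, name: str) -> ChannelThresholds:
        return self.rows[name]

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {"r": list(row.r), "g": list(row.g), "b": list(row.b)}
            for name, row in self.rows.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdTable":
        payload = json.loads(Path(path).read_text())
        return cls({
            name: ChannelThresholds(name, tuple(v["r"]), tuple(v["g"]), tuple(v["b"]))
            for name, v in payload.items()
        })


def threshold_gray(img: GrayImage | np.ndarray, T: int) -> ComponentMask:
    """Single-threshold binarization: pixel -> 1 iff its gray level >= T."""
    if not 0 <= T <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    values = img.values if isinstance(img, GrayImage) else np.asarray(img)
    return ComponentMask((values >= T), name=f"gray>={T}")


def segment_component(img: ColorThermogram, th: ChannelThresholds) -> ComponentMask:
    """Segment one colour component by the triple channel-interval test."""
    return ComponentMask(th.contains(img.pixels), name=th.name)


def segment_all(
    img: ColorThermogram,
    table: ThresholdTable | None = None,
    include_white: bool = False,
) -> dict[str, ComponentMask]:
    """Segment the red, green and blue components independently.

    Masks are non-exclusive: with the default threshold table some pixels can
    satisfy more than one row.  ``include_white`` adds the extrapolated
    white-component rule (all channels >= 240).
    """
    table = table or ThresholdTable()
    out = {name: segment_component(img, table[name]) for name in table.COMPONENTS}
    if include_white:
        m = WHITE_THRESHOLDS_MIN
        white = ChannelThresholds("white", (m, 255), (m, 255), (m, 255))
        out["white"] = segment_component(img, white)
    return out


def component_fractions(masks: dict[str, ComponentMask]) -> dict[str, float]:
    return {name: m.fraction for name, m in masks.items()}


def red_to_gray(img: ColorThermogram, red_mask: ComponentMask) -> GrayImage:
    """Convert the segmented red (hot-spot) component to grayscale.

    Masked pixels get their Rec. 601 luminance rounded to the nearest
    integer; everything outside the mask is zeroed.
    """
    if red_mask.mask.shape != img.shape:
        raise ValueError("mask shape does not match image shape")
    lum = np.round(img.pixels.astype(float) @ _LUMA)
    return GrayImage(np.where(red_mask.mask, lum, 0.0))


def center_roi(
    shape: tuple[int, int],
    roi_h: int,
    roi_w: int,
    tongue_mask: ComponentMask | np.ndarray | None = None,
) -> ROISpec:
    """Place the measurement ROI at the centre of the tongue.

    Centred on the tongue-mask centroid when a non-empty mask is given,
    otherwise on the image centre; ties round toward the top-left.  The ROI
    is clamped to stay inside the image.
    """
    H, W = shape
    if roi_h > H or roi_w > W:
        raise ValueError(f"ROI {roi_h}x{roi_w} larger than image {H}x{W}")
    mask = tongue_mask.mask if isinstance(tongue_mask, ComponentMask) else tongue_mask
    if mask is not None and np.any(mask):
        rows, cols = np.nonzero(mask)
        cr, cc = rows.mean(), cols.mean()
    else:
        cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    r0 = int(np.floor(cr - roi_h / 2.0 + 0.5))
    c0 = int(np.floor(cc - roi_w / 2.0 + 0.5))
    r0 = min(max(r0, 0), H - roi_h)
    c0 = min(max(c0, 0), W - roi_w)
    return ROISpec(r0, c0, roi_h, roi_w)
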