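"""Gray-level co-occurrence matrix (GLCM) texture features for the tongue ROI.

The GLCM P(i, j) is the (optionally symmetrized, normalized) frequency with
which gray level i co-occurs with gray level j at a fixed pixel offset.  From
it the pipeline derives the Haralick-style features used to discriminate
normal from diabetic tongue thermograms: contrast, correlation, energy,
homogeneity, GLCM mean, standard deviation, variance and entropy.  Two
additional first-order moments — skewness and kurtosis — are computed
directly on the ROI pixel intensities with population moment ratios (divide
by n; no excess-kurtosis subtraction).

Degenerate inputs (constant ROI, zero variance) produce explicitly flagged
NaN values rather than silent zeros; the flags travel with the feature
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import GrayImage

__all__ = [
    "GLCMConfig",
    "GLCM",
    "TextureFeatures",
    "FEATURE_NAMES",
    "quantize",
    "compute_glcm",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "glcm_mean",
    "glcm_std",
    "glcm_variance",
    "glcm_entropy",
    "intensity_skewness",
    "intensity_kurtosis",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    "contrast", "correlation", "energy", "homogeneity", "glcm_mean",
    "std_dev", "entropy", "skewness", "variance", "kurtosis",
)


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence configuration.

    Defaults follow the most common convention: 8 gray levels, horizontal
    offset (0, 1) at distance 1, symmetric, normalized.
    """

    levels: int = 8
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("GLCM needs at least 2 gray levels")
        if self.offset == (0, 0):
            raise ValueError("GLCM offset must be nonzero")


@dataclass
class GLCM:
    """N x N co-occurrence matrix; probabilities when normalized."""

    p: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(self.p < 0):
            raise ValueError("GLCM entries must be non-negative")
        if self.normalized and abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("normalized GLCM must sum to 1")


def quantize(img: GrayImage | np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 8-bit gray levels [0, 255] into ``levels`` bins 0..levels-1."""
    if levels < 2:
        raise ValueError("need at least 2 quantization levels")
    values = img.values if isinstance(img, GrayImage) else np.asarray(img)
    return np.minimum((values.astype(int) * levels) // 256, levels - 1)


def compute_glcm(quantized: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> GLCM:
    """Count gray-level pairs (p, p + offset) over the image.

    With ``symmetric`` the transpose is added (each pair counted in both
    directions); with ``normalize`` counts become probabilities.
    """
    q = np.asarray(quantized)
    dr, dc = cfg.offset
    H, W = q.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("no valid pixel pairs at the requested offset")
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    n = cfg.levels
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n).astype(float)
    if cfg.symmetric:
        counts = counts + counts.T
    if cfg.normalize:
        counts /= counts.sum()
    return GLCM(counts, normalized=cfg.normalize)


def _check_normalized(P: GLCM) -> np.ndarray:
    if not P.normalized or abs(P.p.sum() - 1.0) > 1e-12:
        raise ValueError("feature requires a normalized GLCM")
    return P.p


def _index_grids(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = p.shape[0]
    return np.meshgrid(np.arange(n), np.arange(n), indexing="ij")


def contrast(P: GLCM) -> float:
    """Sum of P(i,j) (i - j)^2: local intensity variation."""
    p = _check_normalized(P)
    i, j = _index_grids(p)
    return float((p * (i - j) ** 2).sum())


def glcm_mean(P: GLCM) -> float:
    """Marginal mean gray level mu = sum of i P(i,j)."""
    p = _check_normalized(P)
    i, _ = _index_grids(p)
    return float((i * p).sum())


def glcm_variance(P: GLCM) -> float:
    """Marginal variance sum of P(i,j) (i - mu)^2."""
    p = _check_normalized(P)
    i, _ = _index_grids(p)
    return float((p * (i - glcm_mean(P)) ** 2).sum())


def glcm_std(P: GLCM) -> float:
    """Square root of the marginal GLCM variance."""
    return float(np.sqrt(glcm_variance(P)))


def correlation(P: GLCM) -> float:
    """Normalized cross-moment sum of P(i,j)(i - mu)(j - mu) / sigma^2.

    mu and sigma^2 are the marginal mean/variance; for a symmetric GLCM the
    two marginals coincide and the value lies in [-1, 1].  Returns NaN for a
    degenerate (single-gray-level) matrix.
    """
    p = _check_normalized(P)
    i, j = _index_grids(p)
    mu = glcm_mean(P)
    var = glcm_variance(P)
    if var <= 0:
        return float("nan")
    return float((p * (i - mu) * (j - mu)).sum() / var)


def energy(P: GLCM) -> float:
    """Sum of squared probabilities (angular second moment); 1 iff one cell."""
    p = _check_normalized(P)
    return float((p ** 2).sum())


def homogeneity(P: GLCM) -> float:
    """Sum of P(i,j) / (1 + (i - j)^2); 1 iff all mass on the diagonal."""
    p = _check_normalized(P)
    i, j = _index_grids(p)
    return float((p / (1.0 + (i - j) ** 2)).sum())


def glcm_entropy(P: GLCM, literal: bool = False) -> float:
    """GLCM entropy.

    Default is Shannon entropy -sum P ln P over nonzero cells.  ``literal``
    instead sums -ln P over nonzero cells (the unweighted form; it diverges
    on zero cells, which are therefore excluded).  Both conventions are
    documented in docs/methods.md.
    """
    p = _check_normalized(P)
    nz = p[p > 0]
    if literal:
        return float(-np.log(nz).sum())
    return float(-(nz * np.log(nz)).sum())


def _population_moments(x: np.ndarray) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pixel values")
    mu = x.mean()
    sigma = float(np.sqrt(((x - mu) ** 2).mean()))
    if sigma == 0:
        raise ValueError(
            "zero intensity variance: skewness/kurtosis are undefined for a "
            "constant ROI; enlarge the ROI or check segmentation"
        )
    return float(mu), sigma, n


def intensity_skewness(x: np.ndarray) -> float:
    """Population skewness sum (X - mu)^3 / (n sigma^3) of ROI intensities."""
    mu, sigma, n = _population_moments(x)
    x = np.asarray(x, dtype=float).ravel()
    return float(((x - mu) ** 3).sum() / (n * sigma ** 3))


def intensity_kurtosis(x: np.ndarray) -> float:
    """Population kurtosis sum (X - mu)^4 / (n sigma^4); 3 for a Gaussian."""
    mu, sigma, n = _population_moments(x)
    x = np.asarray(x, dtype=float).ravel()
    return float(((x - mu) ** 4).sum() / (n * sigma ** 4))


@dataclass
class TextureFeatures:
    """The ten texture features plus the mean ROI temperature.

    ``degenerate`` names features that were undefined on the input (constant
    ROI etc.) and carry NaN.
    """

    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    glcm_mean: float
    std_dev: float
    entropy: float
    skewness: float
    variance: float
    kurtosis: float
    mean_roi_temperature: float = float("nan")
    degenerate: frozenset[str] = field(default_factory=frozenset)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d["mean_roi_temperature"] = self.mean_roi_temperature
        return d


def extract_features(
    gray_roi: GrayImage | np.ndarray,
    field_roi: np.ndarray | None = None,
    cfg: GLCMConfig = GLCMConfig(),
    literal_entropy: bool = False,
) -> TextureFeatures:
    """Full feature vector for one ROI.

    ``gray_roi`` is the grayscale ROI crop; ``field_roi`` the matching
    temperature crop (deg C) when available.  Undefined features on
    degenerate input are flagged, never silently zeroed.
    """
    values = gray_roi.values if isinstance(gray_roi, GrayImage) else np.asarray(gray_roi)
    q = quantize(values, cfg.levels)
    P = compute_glcm(q, cfg)
    flags: set[str] = set()

    corr = correlation(P)
    if np.isnan(corr):
        flags.add("correlation")
    try:
        skew = intensity_skewness(values)
        kurt = intensity_kurtosis(values)
    except ValueError:
        skew = kurt = float("nan")
        flags.update({"skewness", "kurtosis"})

    temp = float(np.mean(field_roi)) if field_roi is not None else float("nan")
    return TextureFeatures(
        contrast=contrast(P),
        correlation=corr,
        energy=energy(P),
        homogeneity=homogeneity(P),
        glcm_mean=glcm_mean(P),
        std_dev=glcm_std(P),
        entropy=glcm_entropy(P, literal=literal_entropy),
        skewness=skew,
        variance=glcm_variance(P),
        kurtosis=kurt,
        mean_roi_temperature=temp,
        degenerate=frozenset(flags),
    )
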