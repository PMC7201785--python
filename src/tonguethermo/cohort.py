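"""Synthetic cohort and thermogram generation.

The clinical tongue-thermography data this package analyses are not publicly
available; what is published are group-wise means and SDs for every baseline
and biochemical variable, a diabetic-group Pearson correlation matrix, and a
qualitative description of the thermogram morphology (diabetic tongues show
heat concentrated at the centre and no cold/blue spots; normal tongues show
diffuse warm patterns, cooler margins and distinct cold spots; the ambient
background sits at 22-23 deg C).  This module generates subject records and
latent temperature fields with exactly that structure:

* tabular records via a Gaussian copula — the published correlation matrix
  (repaired to the nearest positive-definite matrix by eigenvalue clipping)
  drives correlated standard normals that are then transformed to each
  variable's group mean/SD;
* temperature fields as an elliptical tongue on an ambient background, with
  a radial periphery-cooling term, group-appropriate hot/cold spots and
  pixel noise, shifted so the centre-ROI mean equals the record's tongue
  surface temperature exactly.

All randomness flows through a single ``numpy`` generator per call, so equal
seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .imaging import ROISpec, TemperatureField
from .segmentation import center_roi

__all__ = [
    "GroupParams",
    "CorrelationSpec",
    "PhenotypeSpec",
    "sample_cohort",
    "sample_pooled_hba1c_tst",
    "sample_temperature_field",
    "default_roi_for_shape",
    "nearest_positive_definite",
]

# Physically admissible ranges used to clip copula draws.
_CLIP_BOUNDS: dict[str, tuple[float, float]] = {
    "spo2": (0.0, 100.0),
    "core_temp": (20.0, 42.0),
    "tst": (20.0, 42.0),
}
_DEFAULT_CLIP = (0.0, np.inf)  # anthropometrics, pressures, glycaemics


@dataclass(frozen=True)
class GroupParams:
    """Per-variable (mean, SD) for one group; defaults are the published columns."""

    normal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(reference.NORMAL_PARAMS))
    diabetic: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(reference.DIABETIC_PARAMS))

    def __post_init__(self) -> None:
        for group in (self.normal, self.diabetic):
            for var, (_, sd) in group.items():
                if sd <= 0:
                    raise ValueError(f"SD for {var!r} must be positive")

    def for_group(self, group: str) -> Mapping[str, tuple[float, float]]:
        if group == "normal":
            return self.normal
        if group == "diabetic":
            return self.diabetic
        raise ValueError(f"unknown group {group!r}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.normal)


def nearest_positive_definite(matrix: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Repair a symmetric correlation matrix by clipping eigenvalues.

    Negative eigenvalues are raised to ``eps``, the matrix is reassembled and
    rescaled back to unit diagonal.
    """
    m = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.maximum(w, eps)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


class CorrelationSpec:
    """Target Pearson correlations over a named subset of cohort variables."""

    def __init__(self, names: tuple[str, ...] | None = None,
                 matrix: np.ndarray | None = None):
        if names is None:
            names = reference.CORRELATION_VARIABLES
            matrix = np.eye(len(names))
            idx = {n: i for i, n in enumerate(names)}
            for (a, b), r in reference.CORRELATION_LOWER.items():
                matrix[idx[a], idx[b]] = matrix[idx[b], idx[a]] = r
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("correlation matrix must be square")
        if matrix.shape[0] != len(names):
            raise ValueError("correlation matrix size must match variable names")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(matrix) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(matrix), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        self.names = tuple(names)
        self.matrix = matrix

    def with_entry(self, a: str, b: str, r: float) -> "CorrelationSpec":
        m = self.matrix.copy()
        i, j = self.names.index(a), self.names.index(b)
        m[i, j] = m[j, i] = r
        return CorrelationSpec(self.names, m)

    def repaired(self) -> np.ndarray:
        return nearest_positive_definite(self.matrix)


def _clip(var: str, values: np.ndarray) -> np.ndarray:
    lo, hi = _CLIP_BOUNDS.get(var, _DEFAULT_CLIP)
    return np.clip(values, lo, hi)


def _group_margin_transform(
    z: np.ndarray, var: str, mean: float, sd: float,
    group: str, consistent_labels: bool,
) -> np.ndarray:
    """Map standard normals to the variable's margin.

    With consistent labels, the HbA1c margin is truncated at the diagnostic
    cut (diabetic >= 6.5, normal <= 6.4) via the truncated-normal quantile of
    the same copula uniform, preserving the dependence structure.
    """
    if consistent_labels and var == "hba1c":
        cut = reference.HBA1C_DIAGNOSTIC_CUT
        if group == "diabetic":
            a, b = (cut - mean) / sd, np.inf
        else:
            a, b = -np.inf, (cut - 0.1 - mean) / sd
        u = stats.norm.cdf(z)
        return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    return mean + sd * z


def sample_cohort(
    n_normal: int,
    n_diabetic: int,
    params: GroupParams | None = None,
    corr: CorrelationSpec | None = None,
    seed: int = 0,
    consistent_labels: bool = False,
) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Variables named in ``corr`` are drawn through a Gaussian copula (same
    dependence in both groups); the rest are independent.  Margins are each
    variable's group mean/SD; physically impossible values are clipped
    (SpO2 <= 100, temperatures in 20-42 deg C, non-negative otherwise).

    ``consistent_labels`` truncates the HbA1c margin at the diagnostic cut so
    every record's group label agrees with the HbA1c >= 6.5 rule; this
    deliberately shifts the HbA1c sample means away from the configured ones
    (see docs/methods.md), so it is off by default.
    """
    if n_normal < 0 or n_diabetic < 0:
        raise ValueError("group counts must be non-negative")
    params = params or GroupParams()
    corr = corr if corr is not None else CorrelationSpec()
    missing = set(corr.names) - set(params.variables)
    if missing:
        raise ValueError(f"correlation names not in params: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr.repaired())
    corr_idx = [params.variables.index(v) for v in corr.names]

    frames = []
    for group, n, prefix in (("normal", n_normal, "N"),
                             ("diabetic", n_diabetic, "D")):
        margins = params.for_group(group)
        z = rng.standard_normal((n, len(params.variables)))
        if n:
            z[:, corr_idx] = z[:, corr_idx] @ chol.T
        data = {"subject_id": [f"{prefix}{k + 1:03d}" for k in range(n)],
                "group": [group] * n}
        for v_i, var in enumerate(params.variables):
            mean, sd = margins[var]
            vals = _group_margin_transform(
                z[:, v_i], var, mean, sd, group, consistent_labels)
            data[var] = _clip(var, vals)
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    return out.astype({var: float for var in params.variables})


def pooled_moments(params: GroupParams, var: str,
                   n_normal: int, n_diabetic: int) -> tuple[float, float]:
    """Mean and SD of a variable pooled over the two-group mixture."""
    mn, sn = params.normal[var]
    md, sd_ = params.diabetic[var]
    w = n_normal / (n_normal + n_diabetic)
    mean = w * mn + (1 - w) * md
    var_ = (w * (sn ** 2 + mn ** 2) + (1 - w) * (sd_ ** 2 + md ** 2)) - mean ** 2
    return mean, float(np.sqrt(var_))


def sample_pooled_hba1c_tst(
    n: int = 140,
    r2: float = reference.POOLED_HBA1C_TST_R2,
    params: GroupParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled-cohort HbA1c / tongue-temperature scatter at a configured r^2.

    The published pooled coefficient of determination cannot be realized by
    any within-group correlation on top of the published group margins (the
    mixture geometry caps pooled r^2 near 0.51), so this mode models the
    pooled scatter directly: HbA1c follows the two-group mixture margin and
    tongue temperature is a linear response with Gaussian noise calibrated
    so the population r^2 equals the target while the pooled temperature
    mean and SD match the mixture moments.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    params = params or GroupParams()
    rng = np.random.default_rng(seed)
    n_norm = n // 2
    n_diab = n - n_norm
    groups = np.array(["normal"] * n_norm + ["diabetic"] * n_diab)

    h = np.empty(n)
    mn, sn = params.normal["hba1c"]
    md, sd_ = params.diabetic["hba1c"]
    h[:n_norm] = mn + sn * rng.standard_normal(n_norm)
    h[n_norm:] = md + sd_ * rng.standard_normal(n_diab)

    mu_h, sig_h = pooled_moments(params, "hba1c", n_norm, n_diab)
    mu_t, sig_t = pooled_moments(params, "tst", n_norm, n_diab)
    r = np.sqrt(r2)
    beta = r * sig_t / sig_h
    noise_sd = sig_t * np.sqrt(1.0 - r2)
    t = mu_t + beta * (h - mu_h) + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({
        "group": groups,
        "hba1c": _clip("hba1c", h),
        "tst": _clip("tst", t),
    })


@dataclass(frozen=True)
class PhenotypeSpec:
    """Morphology preset for synthetic tongue temperature fields.

    Semi-axes are fractions of the frame half-height/half-width.  Spot
    amplitudes are in deg C relative to the local base temperature;
    ``edge_drop`` is the centre-to-margin cooling in deg C (large for the
    normal moist tongue, small for the dry diabetic tongue — the mechanism
    behind the cold/blue spots seen only in normal thermograms).
    """

    ellipse_axes: tuple[float, float] = (0.76, 0.60)
    hotspot_count: int = 1
    hotspot_sigma: float = 0.12
    hotspot_amplitude: float = 1.5
    coldspot_count: int = 0
    coldspot_sigma: float = 0.07
    coldspot_amplitude: float = -1.5
    edge_drop: float = 1.5
    ambient: float = 22.5
    noise_sd: float = 0.08

    def __post_init__(self) -> None:
        if not (0 < self.ellipse_axes[0] and 0 < self.ellipse_axes[1]):
            raise ValueError("ellipse semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    @classmethod
    def diabetic(cls, **overrides) -> "PhenotypeSpec":
        """Single centre hot spot, no cold spots, weak margin cooling."""
        return replace(cls(), **overrides)

    @classmethod
    def normal(cls, **overrides) -> "PhenotypeSpec":
        """Scattered warm spots, cold spots, strong margin cooling."""
        base = cls(
            hotspot_count=3,
            hotspot_sigma=0.08,
            coldspot_count=2,
            edge_drop=6.0,
        )
        return replace(base, **overrides)

    @classmethod
    def for_group(cls, group: str, **overrides) -> "PhenotypeSpec":
        return cls.diabetic(**overrides) if group == "diabetic" else cls.normal(**overrides)


def default_roi_for_shape(shape: tuple[int, int]) -> tuple[int, int]:
    """Centre-ROI size in pixels: 40 x 48 at 256 x 256, scaled with the frame."""
    return (max(2, round(40 * shape[0] / 256)),
            max(2, round(48 * shape[1] / 256)))


def sample_temperature_field(
    record: pd.Series | Mapping | float,
    shape: tuple[int, int] = (256, 256),
    phenotype: PhenotypeSpec | None = None,
    seed: int = 0,
) -> TemperatureField:
    """Draw a latent temperature field for one subject.

    ``record`` is a cohort row (needs ``tst`` and, to pick the default
    phenotype, ``group``) or a bare tongue-surface temperature in deg C.
    The field is an elliptical tongue over ambient background: a radial
    cooling profile toward the margin, Gaussian hot spots (centred for the
    diabetic preset, scattered for the normal one), optional cold spots,
    and pixel noise.  After assembly the in-tongue field is shifted so the
    centre-ROI mean equals the record's temperature exactly.
    """
    if isinstance(record, (int, float, np.floating)):
        tst, group = float(record), "diabetic"
    else:
        tst = float(record["tst"])
        group = str(record.get("group", "diabetic"))
    phenotype = phenotype or PhenotypeSpec.for_group(group)

    H, W = shape
    if H < 64 or W < 64:
        raise ValueError("field shape must be at least 64 x 64")
    ar = phenotype.ellipse_axes[0] * H / 2.0
    ac = phenotype.ellipse_axes[1] * W / 2.0
    if ar >= H / 2.0 or ac >= W / 2.0:
        raise ValueError("tongue ellipse does not fit inside the frame")

    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    cr, ccen = (H - 1) / 2.0, (W - 1) / 2.0
    r_ell = np.sqrt(((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2)
    tongue = r_ell <= 1.0

    fld = phenotype.ambient + phenotype.noise_sd * rng.standard_normal((H, W))
    base = tst - phenotype.edge_drop * r_ell ** 2
    fld[tongue] = base[tongue]

    scale = min(H, W)

    def _add_spots(count: int, sigma_frac: float, amplitude: float,
                   centred: bool, radial_band: tuple[float, float]) -> None:
        sigma_px = sigma_frac * scale
        for k in range(count):
            if centred and k == 0:
                pr, pc = cr, ccen
            else:
                rho = np.sqrt(rng.uniform(radial_band[0] ** 2, radial_band[1] ** 2))
                theta = rng.uniform(0.0, 2.0 * np.pi)
                pr = cr + rho * ar * np.sin(theta)
                pc = ccen + rho * ac * np.cos(theta)
            bump = amplitude * np.exp(
                -((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * sigma_px ** 2))
            fld[tongue] += bump[tongue]

    _add_spots(phenotype.hotspot_count, phenotype.hotspot_sigma,
               phenotype.hotspot_amplitude,
               centred=(group == "diabetic"), radial_band=(0.0, 0.65))
    _add_spots(phenotype.coldspot_count, phenotype.coldspot_sigma,
               phenotype.coldspot_amplitude,
               centred=False, radial_band=(0.25, 0.75))

    fld[tongue] += phenotype.noise_sd * rng.standard_normal((H, W))[tongue]

    roi_h, roi_w = default_roi_for_shape(shape)
    roi: ROISpec = center_roi((H, W), roi_h, roi_w, tongue)
    fld[tongue] += tst - fld[roi.slices()].mean()

    # 10 x 12 mm physical ROI maps to 40 x 48 px at the working size
    return TemperatureField(fld, mm_per_pixel=0.25 * 256 / H, tongue_mask=tongue)
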