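"""End-to-end screening pipeline and computer-aided diagnosis (CAD) reports.

Ties the modules together along the study workflow: render or load a
thermogram, resize to 256x256, Gaussian-filter, segment the RGB colour
components with the calibrated threshold table, convert the red (hot-spot)
component to grayscale, fix the measurement ROI at the tongue centre,
extract GLCM texture features plus the mean ROI temperature, and classify.
Also reproduces the published performance-table arithmetic from the
published confusion matrices, flagging any internally inconsistent cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import reference
from .classify import (
    NEGATIVE,
    POSITIVE,
    ConfusionMatrix,
    CVConfig,
    CVResult,
    crossvalidate,
    metrics_from_confusion,
    roc_auc,
)
from .cohort import GroupParams, CorrelationSpec, sample_cohort, sample_temperature_field
from .imaging import ColorThermogram, RainbowPalette, ROISpec, TemperatureField, \
    gaussian_smooth, mean_roi_temperature, resize_256, rgb_to_temp, temp_to_rgb
from .segmentation import ThresholdTable, center_roi, red_to_gray, segment_all
from .texture import FEATURE_NAMES, GLCMConfig, TextureFeatures, extract_features

__all__ = [
    "PipelineConfig",
    "CADReport",
    "subject_features",
    "build_dataset",
    "run_subject",
    "reproduce_metrics",
    "evaluate_tabular",
]

logger = logging.getLogger("tonguethermo")

# Tabular inputs fed to the SVM/NB classifiers alongside the image-derived
# features: anthropometrics, body circumferences and blood pressure.
TABULAR_FEATURES: tuple[str, ...] = (
    "age", "height", "weight", "bmi", "waist", "hip", "sbp", "dbp",
)
IMAGE_FEATURES: tuple[str, ...] = ("mean_roi_temperature",) + FEATURE_NAMES


@dataclass
class PipelineConfig:
    """All pipeline settings in one serializable object."""

    palette: RainbowPalette = dc_field(default_factory=RainbowPalette)
    thresholds: ThresholdTable = dc_field(default_factory=ThresholdTable)
    roi_size: tuple[int, int] = (40, 48)
    glcm: GLCMConfig = dc_field(default_factory=GLCMConfig)
    cv: CVConfig = dc_field(default_factory=CVConfig)
    model: str = "svm"
    image_size: int = 256
    smooth_sigma: float = 1.0
    seed: int = 0

    def manifest(self) -> dict:
        payload = {
            "t_min": self.palette.t_min,
            "t_max": self.palette.t_max,
            "roi_size": list(self.roi_size),
            "glcm": {"levels": self.glcm.levels, "offset": list(self.glcm.offset),
                     "symmetric": self.glcm.symmetric},
            "cv": {"k": self.cv.k, "stratified": self.cv.stratified,
                   "seed": self.cv.seed},
            "model": self.model,
            "image_size": self.image_size,
            "smooth_sigma": self.smooth_sigma,
            "seed": self.seed,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
        return {"config": payload, "config_hash": digest}


@dataclass(frozen=True)
class CADReport:
    """Per-subject screening report."""

    subject_id: str
    mean_roi_temperature: float
    features: dict[str, float]
    predicted_class: str
    score: float
    model: str
    manifest: dict

    def to_json(self) -> str:
        return json.dumps({
            "subject_id": self.subject_id,
            "mean_roi_temperature": self.mean_roi_temperature,
            "features": self.features,
            "predicted_class": self.predicted_class,
            "score": self.score,
            "model": self.model,
            **self.manifest,
        }, indent=2)


def subject_features(
    img: ColorThermogram,
    cfg: PipelineConfig | None = None,
) -> tuple[TextureFeatures, dict]:
    """Image half of the workflow: preprocess, segment, and extract features.

    Returns the feature set plus a dict of intermediates (masks, ROI, the
    inverted temperature field) for inspection or dumping.  When the red
    component is empty the grayscale conversion falls back to the whole
    tongue with a warning.
    """
    cfg = cfg or PipelineConfig()
    img = resize_256(img, cfg.image_size)
    img = gaussian_smooth(img, cfg.smooth_sigma)
    masks = segment_all(img, cfg.thresholds)
    red = masks["red"]
    if red.count() == 0:
        logger.warning("empty red component; falling back to whole-tongue grayscale")
        from .segmentation import ComponentMask
        red = ComponentMask(np.ones(img.shape, dtype=bool), name="fallback")
    # localize the tongue as the above-background region of the inverted
    # field: the ambient background clamps to the bottom of the scale, so
    # anything more than half a degree above t_min is tongue
    fld: TemperatureField = rgb_to_temp(img, cfg.palette)
    tongue = fld.values > cfg.palette.t_min + 0.5
    roi: ROISpec = center_roi(img.shape, *cfg.roi_size,
                              tongue if tongue.any() else None)
    gray = red_to_gray(img, red)
    feats = extract_features(
        gray.values[roi.slices()], fld.values[roi.slices()], cfg.glcm)
    return feats, {"masks": masks, "roi": roi, "field": fld, "gray": gray}


def _feature_row(record: pd.Series | None, feats: TextureFeatures) -> list[float]:
    row = []
    if record is not None:
        row.extend(float(record[v]) for v in TABULAR_FEATURES)
    d = feats.as_dict()
    # degenerate (flagged NaN) features enter the classifier as 0
    row.extend(0.0 if np.isnan(d[v]) else d[v] for v in IMAGE_FEATURES)
    return row


def build_dataset(
    cohort: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    shape: tuple[int, int] = (256, 256),
    include_tabular: bool = True,
    return_images: bool = False,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, list[ColorThermogram] | None]:
    """Render every subject's thermogram and assemble the feature matrix.

    Per-subject render seeds are spawned deterministically from the pipeline
    seed.  Returns (X, y, feature table, images); labels are +1 diabetic,
    -1 normal.
    """
    cfg = cfg or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(cohort))
    rows, labels, images = [], [], []
    for (_, record), sub_seed in zip(cohort.iterrows(), seeds):
        fld = sample_temperature_field(record, shape=shape, seed=int(sub_seed))
        img = temp_to_rgb(fld, cfg.palette)
        feats, _ = subject_features(img, cfg)
        rows.append(_feature_row(record if include_tabular else None, feats))
        labels.append(POSITIVE if record["group"] == "diabetic" else NEGATIVE)
        if return_images:
            images.append(img)
    names = (TABULAR_FEATURES if include_tabular else ()) + IMAGE_FEATURES
    frame = pd.DataFrame(rows, columns=list(names))
    frame.insert(0, "subject_id", cohort["subject_id"].to_numpy()
                 if "subject_id" in cohort else np.arange(len(cohort)))
    frame.insert(1, "group", cohort["group"].to_numpy())
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    return X, y, frame, (images if return_images else None)


def evaluate_tabular(
    X: np.ndarray, y: np.ndarray,
    model: str = "svm",
    cv: CVConfig | None = None,
) -> tuple[CVResult, dict]:
    """Cross-validate a tabular classifier and report pooled metrics + AUC."""
    result = crossvalidate(model, X, y, cv or CVConfig())
    metrics = metrics_from_confusion(result.confusion)
    _, _, auc = roc_auc(result.scores, result.y_true)
    out = metrics.as_dict()
    out["auc"] = auc
    out["confusion"] = {"tp": result.confusion.tp, "fp": result.confusion.fp,
                        "tn": result.confusion.tn, "fn": result.confusion.fn}
    out["fold_accuracies"] = result.fold_accuracies
    return result, out


def run_subject(
    source: ColorThermogram | TemperatureField | str,
    model,
    cfg: PipelineConfig | None = None,
    record: pd.Series | None = None,
    subject_id: str = "subject",
) -> CADReport:
    """Full per-subject workflow ending in a screening prediction.

    ``source`` is a thermogram, a latent temperature field, or a path to a
    PNG/TIFF image or CSV temperature matrix.  ``record`` supplies the
    tabular features when the model was trained on them.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(source, str):
        if source.endswith(".csv"):
            source = TemperatureField.from_csv(source)
        else:
            source = ColorThermogram.load(source, palette=cfg.palette)
    if isinstance(source, TemperatureField):
        source = temp_to_rgb(source, cfg.palette)
    feats, _ = subject_features(source, cfg)
    x = np.asarray([_feature_row(record, feats)])
    pred = int(model.predict(x)[0])
    if hasattr(model, "decision_function"):
        score = float(model.decision_function(x)[0])
    else:
        classes = list(model.classes_)
        score = float(model.predict_proba(x)[0, classes.index(POSITIVE)])
    return CADReport(
        subject_id=subject_id,
        mean_roi_temperature=feats.mean_roi_temperature,
        features=feats.as_dict(),
        predicted_class="diabetic" if pred == POSITIVE else "normal",
        score=score,
        model=cfg.model,
        manifest=cfg.manifest(),
    )


def reproduce_metrics(rounding: str = "truncate") -> pd.DataFrame:
    """Recompute the published performance table from its confusion matrices.

    For each classifier and metric, reports the value derived from the
    published TP/FP/TN/FN counts next to the published one and whether they
    agree; the published SVM PPV does not follow from its own confusion
    matrix and is flagged as inconsistent.
    """
    rows = []
    for name, (tp, fp, tn, fn) in reference.CONFUSION_MATRICES.items():
        computed = metrics_from_confusion(
            ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn), rounding=rounding)
        published = reference.PUBLISHED_METRICS[name]
        for metric in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            got = getattr(computed, metric)
            want = published[metric]
            rows.append({
                "classifier": name,
                "metric": metric,
                "computed": got,
                "published": want,
                "consistent": abs(got - want) < 0.005,
            })
    return pd.DataFrame(rows)
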