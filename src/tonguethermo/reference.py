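"""Reference values from the clinical screening cohort this package emulates.

The original tongue-thermography study measured 140 subjects (70 normal,
70 type II diabetic, diagnosed by HbA1c >= 6.5%) with an infrared camera at
0.3 m under a fixed rainbow palette, and published group summary statistics,
a diabetic-group Pearson correlation matrix, the RGB threshold intervals used
for colour-component segmentation, and the cross-validated confusion matrices
of three classifiers.  The raw data are not public; these printed values are
the inputs that parameterize the synthetic cohort generator and the
metric-arithmetic reproduction utilities.
"""

from __future__ import annotations

# Variable order used throughout the package for cohort tables.
VARIABLES: tuple[str, ...] = (
    "age",        # years
    "height",     # cm
    "weight",     # kg
    "bmi",        # kg/m^2
    "spo2",       # %
    "core_temp",  # deg C
    "waist",      # cm
    "hip",        # cm
    "sbp",        # mmHg
    "dbp",        # mmHg
    "hba1c",      # %
    "fbs",        # mg/dL
    "ppbs",       # mg/dL
    "eag",        # mg/dL
    "tst",        # deg C, mean tongue surface temperature at the centre ROI
)

# Group-wise mean and SD for every cohort variable: {var: (mean, sd)}.
NORMAL_PARAMS: dict[str, tuple[float, float]] = {
    "age": (43.88, 10.71),
    "height": (160.90, 6.95),
    "weight": (63.48, 13.54),
    "bmi": (24.51, 4.98),
    "spo2": (97.9, 0.81),
    "core_temp": (36.87, 0.30),
    "waist": (79.57, 12.44),
    "hip": (87.22, 11.69),
    "sbp": (122.0, 15.18),
    "dbp": (76.42, 9.33),
    "hba1c": (5.27, 0.15),
    "fbs": (94.31, 10.04),
    "ppbs": (116.02, 15.15),
    "eag": (119.77, 7.21),
    "tst": (34.62, 0.77),
}

DIABETIC_PARAMS: dict[str, tuple[float, float]] = {
    "age": (47.38, 7.42),
    "height": (159.27, 10.17),
    "weight": (66.06, 11.76),
    "bmi": (26.13, 5.45),
    "spo2": (98.1, 0.68),
    "core_temp": (36.93, 0.42),
    "waist": (84.51, 14.89),
    "hip": (91.75, 17.38),
    "sbp": (122.85, 18.42),
    "dbp": (76.14, 9.82),
    "hba1c": (8.58, 2.30),
    "fbs": (148.67, 58.72),
    "ppbs": (225.32, 98.73),
    "eag": (191.1, 66.57),
    "tst": (35.23, 0.61),
}

# Diabetic-group Pearson correlations over a nine-variable subset, as
# published (lower triangle by row; row labels taken as authoritative).
CORRELATION_VARIABLES: tuple[str, ...] = (
    "age", "hip", "waist", "dbp", "hba1c", "fbs", "ppbs", "eag", "tst",
)

CORRELATION_LOWER: dict[tuple[str, str], float] = {
    ("hip", "age"): 0.458,
    ("waist", "age"): 0.305,
    ("waist", "hip"): 0.780,
    ("dbp", "age"): 0.047,
    ("dbp", "hip"): -0.108,
    ("dbp", "waist"): 0.718,
    ("hba1c", "age"): -0.082,
    ("hba1c", "hip"): 0.076,
    ("hba1c", "waist"): 0.235,
    ("hba1c", "dbp"): 0.246,
    ("fbs", "age"): -0.039,
    ("fbs", "hip"): 0.047,
    ("fbs", "waist"): 0.082,
    ("fbs", "dbp"): 0.115,
    ("fbs", "hba1c"): 0.647,
    ("ppbs", "age"): 0.007,
    ("ppbs", "hip"): 0.099,
    ("ppbs", "waist"): 0.093,
    ("ppbs", "dbp"): 0.071,
    ("ppbs", "hba1c"): 0.711,
    ("ppbs", "fbs"): 0.653,
    ("eag", "age"): -0.033,
    ("eag", "hip"): 0.003,
    ("eag", "waist"): 0.161,
    ("eag", "dbp"): 0.198,
    ("eag", "hba1c"): 0.555,
    ("eag", "fbs"): 0.834,
    ("eag", "ppbs"): 0.552,
    ("tst", "age"): -0.009,
    ("tst", "hip"): -0.036,
    ("tst", "waist"): 0.19,
    ("tst", "dbp"): 0.276,
    ("tst", "hba1c"): 0.662,
    ("tst", "fbs"): 0.435,
    ("tst", "ppbs"): 0.471,
    ("tst", "eag"): 0.270,
}

# Coefficient of determination of the pooled-cohort HbA1c vs tongue-ROI
# temperature scatter reported by the study (inconsistent with the
# diabetic-only r = 0.662; see docs/methods.md).
POOLED_HBA1C_TST_R2: float = 0.5688

# HbA1c diagnostic cut for type II diabetes (%).
HBA1C_DIAGNOSTIC_CUT: float = 6.5

# RGB colour-component segmentation intervals:
# {component: ((Rmin, Rmax), (Gmin, Gmax), (Bmin, Bmax))}.
RGB_THRESHOLDS: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = {
    "red": ((222, 252), (0, 176), (0, 122)),
    "green": ((8, 255), (165, 255), (6, 96)),
    "blue": ((0, 28), (0, 161), (0, 255)),
}

# Published 10-fold cross-validation confusion matrices (positive class =
# diabetic): {classifier: (TP, FP, TN, FN)}.
CONFUSION_MATRICES: dict[str, tuple[int, int, int, int]] = {
    "svm": (63, 3, 67, 7),
    "nb": (67, 12, 58, 3),
    "cnn": (65, 3, 67, 5),
}

# Published performance table (percentages; AUC on [0, 1]):
# {classifier: {metric: value}}.
PUBLISHED_METRICS: dict[str, dict[str, float]] = {
    "svm": {"auc": 0.92, "sensitivity": 90.0, "specificity": 95.71,
            "ppv": 91.30, "npv": 90.54, "accuracy": 92.85},
    "nb": {"auc": 0.96, "sensitivity": 95.71, "specificity": 82.85,
           "ppv": 84.81, "npv": 95.08, "accuracy": 89.28},
    "cnn": {"auc": 0.80, "sensitivity": 92.85, "specificity": 95.71,
            "ppv": 95.58, "npv": 93.05, "accuracy": 94.28},
}
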