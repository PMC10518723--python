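"""Published summary statistics for the pooled decompressive-hemicraniectomy cohort.

The source cohort (204 ischemic-stroke patients, three referral centers)
is private, but its per-feature Pearson correlations with the second
infarction growth rate (IGR II) and the matching two-sided p-values are
public. They drive the feature-selection worked example and calibrate
the synthetic generator's correlation structure.

INFVOL2 is only measurable after the second CT scan round, so any model
meant to run after the first scan must exclude it regardless of its
(strong) correlation with the target.
"""

from __future__ import annotations

import numpy as np

from anfisbpso.preprocessing import BINARY, CONTINUOUS, FeatureStats

# (name, kind, p-value, Pearson r with IGR II)
STROKE_FEATURE_TABLE: tuple[tuple[str, str, float, float], ...] = (
    ("AGE", CONTINUOUS, 0.8058, -0.0187),
    ("SBP", CONTINUOUS, 0.9253, 0.0071),
    ("DBP", CONTINUOUS, 0.6222, 0.0374),
    ("HTN", BINARY, 0.9350, 0.0062),
    ("DM", BINARY, 0.3811, 0.0664),
    ("DYSLIP", BINARY, 0.1750, -0.1027),
    ("UNCAL", BINARY, 0.0312, 0.1625),
    ("TEMPORAL", BINARY, 0.0105, 0.1926),
    ("INFVOL1", CONTINUOUS, 0.0100, -0.1936),
    ("INFVOL2", CONTINUOUS, 6.3804e-09, 0.4202),
    ("Growthrate_1", CONTINUOUS, 2.1920e-33, 0.7525),
)

#: Feature available only after the second CT scan; excluded from models
#: intended to run after the first scan.
POST_SECOND_SCAN_FEATURES: tuple[str, ...] = ("INFVOL2",)

#: The five features surviving the p<=0.05 OR |r|>=0.1 filter with
#: INFVOL2 excluded — the published model's input set.
STROKE_SELECTED_FEATURES: tuple[str, ...] = (
    "DYSLIP",
    "UNCAL",
    "TEMPORAL",
    "INFVOL1",
    "Growthrate_1",
)


def stroke_feature_stats() -> FeatureStats:
    """The cohort's published per-feature statistics as a FeatureStats."""
    names = tuple(row[0] for row in STROKE_FEATURE_TABLE)
    p = np.array([row[2] for row in STROKE_FEATURE_TABLE])
    r = np.array([row[3] for row in STROKE_FEATURE_TABLE])
    return FeatureStats(names=names, r=r, p_value=p)


def stroke_feature_kinds() -> dict[str, str]:
    return {row[0]: row[1] for row in STROKE_FEATURE_TABLE}
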