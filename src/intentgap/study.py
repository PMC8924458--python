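"""Published study quantities used as defaults and calibration targets.

These are the descriptive moments, correlations and composite weights reported
for the reference survey of university staff (n = 144 completers out of 176
starters).  They parameterise the synthetic-cohort generator and provide the
default fixed weights for the Behavioral-Intention composite; nothing here is
recomputed — these are inputs.
"""

from __future__ import annotations

from .scoring import TPBWeights

#: Completers / questionnaire starters in the reference survey.
N_COMPLETERS = 144
N_STARTERS = 176

#: "Don't know" answers on the sustainability behavior item among completers.
DK_COUNT_BEHAVIOR = 6

#: Reported mean and SD per score (centred -2..+2 scale for I/B; composite
#: scales for BI and RAI).
SCORE_MOMENTS: dict[str, tuple[float, float]] = {
    "I_H": (1.38, 0.69),
    "B_H": (0.4, 0.86),
    "I_S": (0.77, 0.93),
    "B_S": (-0.37, 1.03),
    "BI_H": (2.33, 1.45),
    "BI_S": (0.92, 1.28),
    "RAI_H": (2.12, 2.48),
    "RAI_S": (2.04, 2.02),
}

#: The ten reported pairwise Pearson correlations.
SCORE_CORRELATIONS: dict[tuple[str, str], float] = {
    ("I_H", "I_S"): 0.35,
    ("B_H", "B_S"): 0.40,
    ("I_H", "B_H"): 0.64,
    ("I_S", "B_S"): 0.57,
    ("RAI_H", "RAI_S"): 0.49,
    ("BI_H", "BI_S"): 0.12,
    ("BI_H", "RAI_H"): 0.44,
    ("BI_S", "RAI_S"): 0.23,
    ("BI_H", "I_H"): 0.41,
    ("BI_S", "I_S"): 0.55,
}

#: Calibrated Behavioral-Intention weights reported for each topic.
PUBLISHED_WEIGHTS: dict[str, TPBWeights] = {
    "health": TPBWeights(1.4, 1.0, 0.5),
    "sustainability": TPBWeights(1.6, 0.5, 0.5),
}

#: Correlation achieved by the published weight calibration, per topic.
PUBLISHED_CALIBRATION_R = {"health": 0.41, "sustainability": 0.55}

#: Size of the multiple-comparison family and its FDR level.
BH_FAMILY_SIZE = 17
BH_Q = 0.05
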