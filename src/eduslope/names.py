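"""Canonical parameter names for the cohort-sequential growth model.

The fixed-effects design has 25 columns, organised in three blocks: the
intercept block (level of performance), the linear-slope block (rate of
change per year of age) and the orthogonalised quadratic-slope block
(acceleration of change).  Cohort, education and sex interact with each
other and with both age terms; sample (test-experience proxy) enters the
intercept block only.

The same labels index true parameter vectors, design-matrix columns and
posterior draws, so everything downstream can be joined by name.
"""

from __future__ import annotations

# Intercept block (level)
INTERCEPT_LABELS = (
    "Intercept",
    "Cohort",
    "Education",
    "Sex",
    "Sample",
    "Cohort x education",
    "Cohort x sex",
    "Education x sex",
    "Cohort x education x sex",
)

# Linear-slope block (rate of decline); no sample term by design
LINEAR_LABELS = (
    "Linear slope (LS)",
    "LS x cohort",
    "LS x education",
    "LS x sex",
    "LS x cohort x education",
    "LS x cohort x sex",
    "LS x education x sex",
    "LS x cohort x education x sex",
)

# Quadratic-slope block (acceleration); no sample term, no random component
QUADRATIC_LABELS = (
    "Quadratic slope (QS)",
    "QS x cohort",
    "QS x education",
    "QS x sex",
    "QS x cohort x education",
    "QS x cohort x sex",
    "QS x education x sex",
    "QS x cohort x education x sex",
)

FIXED_EFFECT_LABELS: tuple[str, ...] = INTERCEPT_LABELS + LINEAR_LABELS + QUADRATIC_LABELS

VARIANCE_LABELS = (
    "SD intercept",
    "SD linear slope",
    "Correlation (intercept, slope)",
    "Residual error",
)

ALL_PARAMETER_LABELS: tuple[str, ...] = FIXED_EFFECT_LABELS + VARIANCE_LABELS

#: short gamma identifiers (g<level><position>) for configs and code
GAMMA_IDS = (
    "g00", "g01", "g02", "g03", "g04", "g05", "g06", "g07", "g08",
    "g10", "g11", "g12", "g13", "g14", "g15", "g16", "g17",
    "g20", "g21", "g22", "g23", "g24", "g25", "g26", "g27",
)

GAMMA_ID_TO_LABEL: dict[str, str] = dict(zip(GAMMA_IDS, FIXED_EFFECT_LABELS))
LABEL_TO_GAMMA_ID: dict[str, str] = {v: k for k, v in GAMMA_ID_TO_LABEL.items()}

VARIANCE_IDS = ("sd_u0", "sd_u1", "rho", "sd_resid")
VARIANCE_ID_TO_LABEL: dict[str, str] = dict(zip(VARIANCE_IDS, VARIANCE_LABELS))

#: the focal fixed effect: change in annual rate of decline per year of education
FOCAL_LABEL = "LS x education"

#: intercept column label (gets the wide prior centred at the T-score mean)
INTERCEPT_LABEL = "Intercept"


def normalize_gamma_name(name: str) -> str:
    """Map a gamma id ('g12') or a column label to the canonical label."""
    if name in GAMMA_ID_TO_LABEL:
        return GAMMA_ID_TO_LABEL[name]
    if name in FIXED_EFFECT_LABELS:
        return name
    raise KeyError(f"unknown fixed-effect name: {name!r}")


def normalize_param_name(name: str) -> str:
    """Map any parameter id or label (fixed effect or variance) to its label."""
    if name in VARIANCE_ID_TO_LABEL:
        return VARIANCE_ID_TO_LABEL[name]
    if name in VARIANCE_LABELS:
        return name
    return normalize_gamma_name(name)
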