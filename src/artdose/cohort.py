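"""Published reference cohort: 10 locally advanced NSCLC patients.

Planning-CT GTV volumes, prescriptions and the weekly GTV/PTV regression
pattern of a published institutional cohort treated with conventionally
fractionated (2 Gy) radio(chemo)therapy under daily cone-beam-CT guidance.
These values parameterize the default synthetic cohort so that simulated
study conditions match the clinical ones.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "REFERENCE_GTV_CM3",
    "REFERENCE_PRESCRIPTION_GY",
    "WEEKLY_GTV_CHANGE",
    "WEEKLY_PTV_CHANGE",
    "PRESTART_GTV_CHANGE",
    "mean_reference_gtv_cm3",
]

#: Planning-CT GTV volumes (cm³), one entry per patient.
REFERENCE_GTV_CM3: tuple[float, ...] = (
    261.7, 185.2, 186.8, 99.7, 179.0, 154.4, 496.8, 383.1, 124.0, 220.5,
)

#: Prescribed total dose (Gy) per patient, delivered in 2.0 Gy fractions.
REFERENCE_PRESCRIPTION_GY: tuple[float, ...] = (
    66.0, 64.0, 66.0, 60.0, 66.0, 60.0, 66.0, 60.0, 60.0, 66.0,
)

#: Mean planning→first-fraction relative GTV change (tumors may progress
#: during the planning-to-start interval).
PRESTART_GTV_CHANGE: float = +0.029

#: Mean weekly relative GTV change during treatment, weeks 1..7
#: (negative = shrinkage; maximum regression in weeks 3–4).
WEEKLY_GTV_CHANGE: tuple[float, ...] = (
    -0.016, -0.067, -0.096, -0.119, -0.074, -0.051, -0.034,
)

#: Mean weekly relative PTV change, weeks 1..7.
WEEKLY_PTV_CHANGE: tuple[float, ...] = (
    -0.024, -0.031, -0.033, -0.033, -0.031, -0.047, -0.032,
)


def mean_reference_gtv_cm3() -> float:
    """Cohort-mean planning GTV volume (cm³)."""
    return float(np.mean(REFERENCE_GTV_CM3))
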