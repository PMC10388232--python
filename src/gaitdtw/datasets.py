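"""Bundled reference dataset: an 18-volunteer total-knee-arthroplasty cohort.

Demographics (sex, age, BMI) and the normalized after-surgery gait
errors of 18 volunteers who underwent total knee arthroplasty (TKA) and
were scored with the DTW pipeline this package implements.  The errors
are already normalized to each subject's before-surgery condition, so
the before error is 1 for every volunteer by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal_io import Volunteer

__all__ = ["tka_cohort", "tka_cohort_frame", "tka_after_errors"]

# (id, sex, age [years], BMI [kg/m^2])
_COHORT_ROWS = [
    (1, "female", 65, 18.9),
    (2, "female", 60, 21.0),
    (3, "female", 58, 30.0),
    (4, "female", 66, 20.3),
    (5, "female", 59, 19.0),
    (6, "male", 70, 22.0),
    (7, "male", 63, 18.2),
    (8, "female", 72, 23.0),
    (9, "female", 68, 19.6),
    (10, "male", 74, 21.0),
    (11, "male", 76, 22.3),
    (12, "male", 65, 18.9),
    (13, "female", 69, 29.0),
    (14, "male", 77, 30.5),
    (15, "female", 59, 28.0),
    (16, "male", 78, 23.0),
    (17, "female", 69, 18.0),
    (18, "female", 76, 21.0),
]

# normalized DTW error after TKA, one per volunteer (before error = 1)
_AFTER_ERRORS = [
    0.06, 0.09, 0.11, 0.07, 0.05, 0.04, 0.08, 0.03, 0.11,
    0.09, 0.03, 0.08, 0.05, 0.06, 0.04, 0.08, 0.06, 0.03,
]


def tka_cohort() -> list[Volunteer]:
    """The 18-volunteer TKA cohort as Volunteer records."""
    return [Volunteer(id=i, sex=s, age=a, bmi=b) for i, s, a, b in _COHORT_ROWS]


def tka_cohort_frame() -> pd.DataFrame:
    """The cohort as a DataFrame with columns id, sex, age, bmi."""
    return pd.DataFrame(_COHORT_ROWS, columns=["id", "sex", "age", "bmi"])


def tka_after_errors() -> np.ndarray:
    """Normalized after-surgery DTW errors, in volunteer order."""
    return np.array(_AFTER_ERRORS, dtype=float)
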