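"""Demographic summary statistics for a study cohort.

Summarizes age (mean and sample standard deviation), the sex split and
obesity percentages from a list of volunteers.  Obesity is classified by
a configurable BMI cutoff whose default is 28 kg/m²; note this is
stricter than the WHO convention of 30 kg/m² (see the package's methods
note for the rationale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_io import Volunteer

__all__ = ["CohortSummary", "summarize", "truncate_decimals", "DEFAULT_OBESITY_BMI"]

DEFAULT_OBESITY_BMI = 28.0


def _round_pct(x: float) -> int:
    """Nearest-integer percentage, ties away from zero."""
    return int(math.floor(x + 0.5))


def truncate_decimals(x: float, ndigits: int = 2) -> float:
    """Truncate (not round) toward zero at ``ndigits`` decimals."""
    factor = 10**ndigits
    return math.trunc(x * factor) / factor


@dataclass
class CohortSummary:
    """Derived demographics: counts, age statistics, sex and obesity split.

    Percentages are rounded to the nearest integer; ``pct_obese_female``
    is computed among the obese volunteers only, and
    ``obese_subgroup_empty`` flags the degenerate case where nobody is
    obese (the percentage is then reported as 0).
    """

    n: int
    mean_age: float
    sd_age: float  # sample SD (n-1 denominator)
    pct_female: int
    pct_male: int
    pct_obese: int
    pct_obese_female: int
    obesity_bmi_threshold: float
    obese_subgroup_empty: bool = False


def summarize(
    cohort: list[Volunteer],
    obesity_bmi_threshold: float = DEFAULT_OBESITY_BMI,
) -> CohortSummary:
    """Summarize a non-empty cohort.

    Obesity is BMI >= ``obesity_bmi_threshold``.  The age SD uses the
    n−1 denominator (0 for a single volunteer).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    n = len(cohort)
    ages = np.array([v.age for v in cohort], dtype=float)
    female = np.array([v.sex == "female" for v in cohort])
    obese = np.array([v.bmi >= obesity_bmi_threshold for v in cohort])

    n_obese = int(obese.sum())
    if n_obese:
        pct_obese_female = _round_pct(100.0 * (female & obese).sum() / n_obese)
    else:
        pct_obese_female = 0
    return CohortSummary(
        n=n,
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=1)) if n > 1 else 0.0,
        pct_female=_round_pct(100.0 * female.sum() / n),
        pct_male=_round_pct(100.0 * (~female).sum() / n),
        pct_obese=_round_pct(100.0 * n_obese / n),
        pct_obese_female=pct_obese_female,
        obesity_bmi_threshold=obesity_bmi_threshold,
        obese_subgroup_empty=n_obese == 0,
    )
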