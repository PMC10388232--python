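"""Rehabilitation outcome scoring from DTW distances.

Each condition (before surgery, after surgery) is scored as the mean DTW
distance of its steps to a healthy reference step.  Because the raw
distance depends on the subject, distances are normalized to the
before-surgery condition, making the before error exactly 1.  The
outcome statistic is the improvement percentage

    improvement = round(100 * (1 - error_after))

so a subject whose post-surgery gait matches the reference perfectly
scores 100, an unchanged subject scores 0 and a worsened subject scores
a negative value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtw import dtw_distance

__all__ = [
    "ImprovementReport",
    "condition_distance",
    "improvement",
    "score_subject",
    "batch_score",
    "reports_from_errors",
]


@dataclass
class ImprovementReport:
    """Per-subject normalized errors and improvement percentage."""

    subject_id: str
    raw_distance_before: float
    raw_distance_after: float
    error_after: float
    improvement_pct: int
    error_before: float = 1.0  # by construction
    reference: str = "synthetic"  # provenance of the healthy reference


def condition_distance(reference_step, steps, aggregate: str = "mean") -> float:
    """Aggregate DTW distance of a condition's steps to the reference.

    ``steps`` is a list of (normalized) step sequences; tests of one
    condition are typically recorded several times, and their distances
    are combined by the mean (or, optionally, the median).  DTW accepts
    steps of unequal length.
    """
    if not steps:
        raise ValueError("condition_distance needs at least one step")
    distances = [dtw_distance(reference_step, s) for s in steps]
    if aggregate == "mean":
        return float(np.mean(distances))
    if aggregate == "median":
        return float(np.median(distances))
    raise ValueError("aggregate must be 'mean' or 'median'")


def improvement(error_after: float) -> int:
    """Improvement percentage from a normalized after error.

    ``round(100 * (1 - error_after))`` to the nearest integer percent
    (ties away from zero); negative if the subject worsened.
    """
    if error_after < 0:
        raise ValueError("error_after must be >= 0")
    x = 100.0 * (1.0 - error_after)
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def score_subject(
    reference_step,
    before_steps,
    after_steps,
    subject_id: str = "",
    aggregate: str = "mean",
    reference: str = "synthetic",
) -> ImprovementReport:
    """Score one subject: normalized errors and improvement percentage.

    The before-condition distance is the normalization scale, so it must
    be positive; a before condition already identical to the reference
    leaves the normalization undefined.
    """
    d_before = condition_distance(reference_step, before_steps, aggregate)
    d_after = condition_distance(reference_step, after_steps, aggregate)
    if d_before <= 0:
        raise ValueError(
            f"subject {subject_id}: before-condition distance is zero; "
            "normalization to the before condition is undefined"
        )
    error_after = d_after / d_before
    return ImprovementReport(
        subject_id=str(subject_id),
        raw_distance_before=d_before,
        raw_distance_after=d_after,
        error_after=error_after,
        improvement_pct=improvement(error_after),
        reference=reference,
    )


def reports_from_errors(errors_after, subject_ids=None) -> list[ImprovementReport]:
    """Build reports directly from already-normalized after errors.

    Useful when only the normalized errors of a cohort are available
    (before error 1 by construction, raw distances unknown).
    """
    errors_after = list(errors_after)
    if subject_ids is None:
        subject_ids = [str(i + 1) for i in range(len(errors_after))]
    return [
        ImprovementReport(
            subject_id=str(sid),
            raw_distance_before=float("nan"),
            raw_distance_after=float("nan"),
            error_after=float(e),
            improvement_pct=improvement(float(e)),
            reference="external",
        )
        for sid, e in zip(subject_ids, errors_after, strict=True)
    ]


def batch_score(reports: list[ImprovementReport]) -> tuple[pd.DataFrame, dict]:
    """Tabulate per-subject reports and summarize the improvements.

    Returns the table (rows in input order) and a summary dict with the
    min, max and mean improvement percentage.
    """
    if not reports:
        raise ValueError("batch_score needs at least one report")
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reports],
            "raw_distance_before": [r.raw_distance_before for r in reports],
            "raw_distance_after": [r.raw_distance_after for r in reports],
            "error_before": [r.error_before for r in reports],
            "error_after": [r.error_after for r in reports],
            "improvement_pct": [r.improvement_pct for r in reports],
        }
    )
    pct = table["improvement_pct"]
    summary = {
        "n": len(reports),
        "min_improvement": int(pct.min()),
        "max_improvement": int(pct.max()),
        "mean_improvement": float(pct.mean()),
    }
    return table, summary
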