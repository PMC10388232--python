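"""Data preparation for force-plate gait traces.

The raw recordings need four things before they can be compared with a
reference stance curve: trimming the low-quality beginning and end of a
recording, removing gaps left by the acquisition system, segmenting the
trace into individual foot contacts (steps), and normalizing amplitude so
that subjects of different body mass are comparable.

Conventions: indices are 0-based and intervals are half-open
``[start, end)`` throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import ForceSignal

__all__ = [
    "StepSegment",
    "trim",
    "remove_gaps",
    "detect_steps",
    "normalize_amplitude",
    "smooth",
    "DEFAULT_THRESHOLD_FRACTION",
    "DEFAULT_MIN_STEP_DURATION",
    "DEFAULT_MAX_STEP_DURATION",
]

log = logging.getLogger(__name__)

# Step detection defaults: contacts are where force exceeds 5% of the
# recording's peak, and a physiologically plausible stance lasts between
# 0.3 s and 1.5 s.  Intervals outside that band (e.g. a double foot
# placement or a partial contact at a trace edge) are rejected.
DEFAULT_THRESHOLD_FRACTION = 0.05
DEFAULT_MIN_STEP_DURATION = 0.3
DEFAULT_MAX_STEP_DURATION = 1.5


@dataclass
class StepSegment:
    """One foot-contact (stance) interval inside a parent signal."""

    parent: ForceSignal
    start_index: int  # inclusive
    end_index: int  # exclusive

    def __post_init__(self):
        if not (0 <= self.start_index < self.end_index <= self.parent.n_samples):
            raise ValueError(
                f"invalid segment [{self.start_index}, {self.end_index}) "
                f"for signal of length {self.parent.n_samples}"
            )

    @property
    def force(self) -> np.ndarray:
        return self.parent.force[self.start_index : self.end_index]

    @property
    def time(self) -> np.ndarray:
        return self.parent.time[self.start_index : self.end_index]

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def duration(self) -> float:
        return self.n_samples / self.parent.sample_rate

    @property
    def peak_force(self) -> float:
        return float(self.force.max())

    @property
    def foot_label(self) -> str:
        return self.parent.foot_label


def trim(signal: ForceSignal, keep_start: float, keep_end: float) -> ForceSignal:
    """Keep only the window ``[keep_start, keep_end)`` seconds of a trace.

    Times are measured from the first sample; the output time axis is
    re-based to start at 0.
    """
    if not (0 <= keep_start < keep_end <= signal.duration + 1e-9):
        raise ValueError(
            f"keep window [{keep_start}, {keep_end}) outside "
            f"[0, {signal.duration:g}]"
        )
    rel = signal.time - signal.time[0]
    mask = (rel >= keep_start - 1e-12) & (rel < keep_end - 1e-12)
    if mask.sum() < 2:
        raise ValueError("trim window retains fewer than 2 samples")
    t = rel[mask]
    return signal.replace(
        time=t - t[0],
        force=signal.force[mask],
        gap_mask=signal.gap_mask[mask],
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True in a boolean array."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def remove_gaps(signal: ForceSignal, max_gap: int = 5) -> ForceSignal:
    """Return a gap-free signal.

    Gap runs of at most ``max_gap`` samples that have valid samples on
    both sides are filled by linear interpolation.  Longer (or edge)
    runs split the signal; the longest contiguous valid stretch is kept
    and its time axis re-based to 0.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    gaps = signal.gap_mask.copy()
    if gaps.all():
        raise ValueError("signal consists entirely of gaps")
    if not gaps.any():
        return signal

    force = signal.force.copy()
    n = len(force)
    for start, end in _runs(gaps):
        interior = start > 0 and end < n
        if interior and (end - start) <= max_gap:
            lo, hi = force[start - 1], force[end]
            # linear ramp between the flanking valid samples
            frac = np.arange(1, end - start + 1) / (end - start + 1)
            force[start:end] = lo + frac * (hi - lo)
            gaps[start:end] = False

    if not gaps.any():
        return signal.replace(force=force, gap_mask=np.zeros(n, dtype=bool))

    # unfillable gaps remain: keep the longest clean stretch
    valid_runs = _runs(~gaps)
    start, end = max(valid_runs, key=lambda r: r[1] - r[0])
    if end - start < 2:
        raise ValueError("no contiguous valid stretch of at least 2 samples")
    t = signal.time[start:end]
    return signal.replace(
        time=t - t[0],
        force=force[start:end],
        gap_mask=np.zeros(end - start, dtype=bool),
    )


def detect_steps(
    signal: ForceSignal,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    min_duration: float = DEFAULT_MIN_STEP_DURATION,
    max_duration: float = DEFAULT_MAX_STEP_DURATION,
) -> list[StepSegment]:
    """Segment a gap-free trace into individual foot contacts.

    A contact is a maximal run of samples whose force exceeds
    ``threshold_fraction`` of the global peak.  Runs whose duration falls
    outside ``[min_duration, max_duration]`` — improper movements such as
    a double foot placement, or clipped contacts at the trace edges —
    are excluded and logged.

    The threshold is relative, so segmentation is invariant to uniform
    rescaling of the force.
    """
    if signal.gap_mask.any():
        raise ValueError("detect_steps requires a gap-free signal (run remove_gaps)")
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    peak = float(signal.force.max())
    if peak <= 0:
        return []
    level = threshold_fraction * peak
    segments, rejected = [], 0
    for start, end in _runs(signal.force > level):
        dur = (end - start) / signal.sample_rate
        if min_duration <= dur <= max_duration:
            segments.append(StepSegment(signal, start, end))
        else:
            rejected += 1
            log.info(
                "rejected contact [%d, %d) of %.3f s outside [%g, %g] s",
                start, end, dur, min_duration, max_duration,
            )
    if rejected:
        log.info("detect_steps: kept %d contacts, rejected %d", len(segments), rejected)
    return segments


def normalize_amplitude(
    segment: StepSegment, body_weight: float | None = None
) -> np.ndarray:
    """Express a step's force in dimensionless units.

    With a body weight (newtons) the samples are returned in units of
    body weight (BW), which makes curves comparable across subjects of
    different mass.  Without one, the step is scaled to unit peak.
    """
    force = segment.force
    if body_weight is not None:
        if body_weight <= 0:
            raise ValueError("body_weight must be positive")
        return force / body_weight
    peak = segment.peak_force
    if peak <= 0:
        raise ValueError("cannot peak-normalize a segment with non-positive peak")
    return force / peak


def smooth(signal: ForceSignal, window: int) -> ForceSignal:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be odd; ``window=1`` is the identity.  The output
    never leaves the input's [min, max] range and preserves constant
    signals exactly.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return signal
    if signal.gap_mask.any():
        raise ValueError("smooth requires a gap-free signal")
    kernel = np.ones(window)
    sums = np.convolve(signal.force, kernel, mode="same")
    counts = np.convolve(np.ones(signal.n_samples), kernel, mode="same")
    return signal.replace(force=sums / counts)
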