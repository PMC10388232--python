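"""Reading, validating and writing force-plate traces and cohort tables.

The canonical on-disk format is delimited text (comma, tab or semicolon)
with a header row.  A force trace has at least a time column (seconds) and
a vertical-force column (newtons, positive in compression).  Missing or
unparseable force cells are carried through as an explicit gap mask and
are never interpolated here; gap handling is a preprocessing decision.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ForceSignal",
    "Volunteer",
    "read_force_trace",
    "read_cohort_table",
    "write_force_trace",
]

_FOOT_LABELS = {"left", "right", "unknown"}
_DELIMITERS = (",", "\t", ";")

# tolerated relative mismatch between the declared sample rate and the
# median time step
_RATE_TOL = 0.01


@dataclass
class ForceSignal:
    """A uniformly sampled vertical ground-reaction-force time series.

    Attributes
    ----------
    time : np.ndarray
        Sample times in seconds, strictly increasing, uniform spacing.
    force : np.ndarray
        Vertical force in newtons (positive = compression).  Entries where
        ``gap_mask`` is True are undefined (stored as NaN).
    gap_mask : np.ndarray of bool
        True where the force value is missing.
    sample_rate : float
        Sampling frequency in Hz; must agree with the median time spacing.
    foot_label : str
        One of ``left``, ``right``, ``unknown``.
    """

    time: np.ndarray
    force: np.ndarray
    gap_mask: np.ndarray = None  # type: ignore[assignment]
    sample_rate: float = 0.0
    foot_label: str = "unknown"
    plate_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = ~np.isfinite(self.force)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.sample_rate == 0.0 and len(self.time) >= 2:
            self.sample_rate = 1.0 / float(np.median(np.diff(self.time)))
        self.validate()

    def validate(self) -> None:
        n = len(self.time)
        if len(self.force) != n or len(self.gap_mask) != n:
            raise ValueError("time, force and gap_mask must have equal length")
        if n < 2:
            raise ValueError("a force signal needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        med_dt = float(np.median(dt))
        if abs(self.sample_rate * med_dt - 1.0) > _RATE_TOL:
            raise ValueError(
                f"sample_rate {self.sample_rate:g} Hz inconsistent with "
                f"median spacing {med_dt:g} s"
            )
        if not np.all(np.isfinite(self.force[~self.gap_mask])):
            raise ValueError("non-finite force outside the gap mask")
        if self.foot_label not in _FOOT_LABELS:
            raise ValueError(f"foot_label must be one of {_FOOT_LABELS}")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Total covered duration in seconds (n / sample_rate)."""
        return self.n_samples / self.sample_rate

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())

    def replace(self, **kw) -> "ForceSignal":
        return replace(self, **kw)


@dataclass
class Volunteer:
    """One cohort member: demographics used for summary statistics."""

    id: int
    sex: str
    age: float
    bmi: float
    body_weight: float | None = None  # newtons

    def __post_init__(self):
        self.sex = _normalize_sex(self.sex)
        if self.age <= 0:
            raise ValueError(f"volunteer {self.id}: age must be positive")
        if self.bmi <= 0:
            raise ValueError(f"volunteer {self.id}: bmi must be positive")


def _normalize_sex(token: str) -> str:
    t = str(token).strip().lower()
    if t in {"female", "f"}:
        return "female"
    if t in {"male", "m"}:
        return "male"
    raise ValueError(f"unknown sex token: {token!r}")


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    counts = {d: first.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def _resolve_column(df: pd.DataFrame, key, default_name: str):
    """Column selection by name or integer position; None if absent."""
    if key is None:
        key = default_name
    if isinstance(key, int):
        return df.iloc[:, key] if key < df.shape[1] else None
    if key in df.columns:
        return df[key]
    return None


def read_force_trace(
    path: str | os.PathLike,
    column_spec: dict | None = None,
    scale: float = 1.0,
) -> ForceSignal:
    """Read one force-plate trace from a delimited text file.

    Parameters
    ----------
    path : path-like
        File with a header row; delimiter is auto-detected among
        comma / tab / semicolon.
    column_spec : dict, optional
        Maps the logical names ``time``, ``force`` (and optionally
        ``foot``, ``plate``, ``subject``) to column names or 0-based
        positions.  Defaults to columns named ``time`` and ``force``.
    scale : float
        Multiplicative factor applied to the force column (for traces
        recorded in units other than newtons).

    Rows whose force cell is blank or unparseable become flagged gaps;
    they are never silently dropped.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    spec = dict(column_spec or {})
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, skipinitialspace=True)

    time_col = _resolve_column(df, spec.get("time"), "time")
    force_col = _resolve_column(df, spec.get("force"), "force")
    if time_col is None or force_col is None:
        raise ValueError(f"{path}: missing time/force columns (have {list(df.columns)})")

    time = pd.to_numeric(time_col, errors="raise").to_numpy(dtype=float)
    force = pd.to_numeric(force_col, errors="coerce").to_numpy(dtype=float) * scale
    gaps = ~np.isfinite(force)
    if (len(force) - gaps.sum()) < 2:
        raise ValueError(f"{path}: fewer than 2 valid force samples")
    if np.any(np.diff(time) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")

    meta = {}
    for logical, attr in (("foot", "foot_label"), ("plate", "plate_id"), ("subject", "subject_id")):
        col = _resolve_column(df, spec.get(logical), logical)
        if col is not None and len(col):
            meta[attr] = str(col.iloc[0]).strip().lower() if logical == "foot" else str(col.iloc[0])
    return ForceSignal(time=time, force=force, gap_mask=gaps, **meta)


def write_force_trace(signal: ForceSignal, path: str | os.PathLike) -> None:
    """Write a trace as CSV; gaps are serialized as empty cells.

    Round-trip through :func:`read_force_trace` reproduces time, force
    and gap flags to better than 1e-6.
    """
    buf = io.StringIO()
    cols = ["time", "force"]
    header = cols + (["foot"] if signal.foot_label != "unknown" else [])
    buf.write(",".join(header) + "\n")
    for i in range(signal.n_samples):
        f = "" if signal.gap_mask[i] else format(signal.force[i], ".10g")
        row = [format(signal.time[i], ".10g"), f]
        if signal.foot_label != "unknown":
            row.append(signal.foot_label)
        buf.write(",".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort_table(path: str | os.PathLike) -> list[Volunteer]:
    """Read a cohort table (columns id, sex, age, bmi[, body_weight])."""
    df = pd.read_csv(path, sep=_sniff_delimiter(os.fspath(path)), skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"id", "sex", "age", "bmi"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        bw = row.get("body_weight")
        bw = None if bw is None or pd.isna(bw) else float(bw)
        out.append(
            Volunteer(
                id=int(row["id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                body_weight=bw,
            )
        )
    return out
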