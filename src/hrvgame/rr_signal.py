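"""RR-interval recordings: ingestion, validation, artifact filtering, iHR conversion.

The universal input of the package is a beat-to-beat RR-interval series in
milliseconds, the export dialect of chest-strap loggers (one interval per
line). Beat ``i`` is timestamped at the *end* of interval ``i``, so beat
times are the cumulative sum of the intervals and strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import (
    EmptyInputError,
    ParseError,
    UnusableRecordingError,
    ValidationError,
)

__all__ = [
    "LABEL_NORMAL",
    "LABEL_ARTIFACT",
    "LABEL_INTERPOLATED",
    "RRSeries",
    "IHRSeries",
    "FilterPolicy",
    "FilterReport",
    "read_rr_file",
    "rr_to_ihr",
    "ihr_to_rr",
    "filter_artifacts",
]

LABEL_NORMAL = "normal"
LABEL_ARTIFACT = "artifact"
LABEL_INTERPOLATED = "interpolated"
_VALID_LABELS = frozenset({LABEL_NORMAL, LABEL_ARTIFACT, LABEL_INTERPOLATED})


@dataclass(frozen=True)
class RRSeries:
    """Ordered beat-to-beat RR intervals (ms) with per-beat labels.

    ``beat_times`` (seconds) are derived as the cumulative sum of the
    intervals, which makes them strictly increasing by construction.
    """

    intervals: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if intervals.ndim != 1:
            raise ValidationError("intervals must be a 1-D sequence")
        if intervals.size and not np.all(intervals > 0):
            bad = int(np.flatnonzero(intervals <= 0)[0])
            raise ValidationError(
                f"non-positive RR interval {intervals[bad]!r} ms at beat {bad}"
            )
        if self.labels is None:
            labels = np.full(intervals.shape, LABEL_NORMAL, dtype=object)
        else:
            labels = np.asarray(self.labels, dtype=object)
        if labels.shape != intervals.shape:
            raise ValidationError("labels must align with intervals")
        unknown = set(labels.tolist()) - _VALID_LABELS
        if unknown:
            raise ValidationError(f"unknown beat labels: {sorted(unknown)}")
        object.__setattr__(self, "labels", labels)

    @property
    def beat_times(self) -> np.ndarray:
        """Time of each beat in seconds (end of its RR interval)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration(self) -> float:
        """Total recording span in seconds (from time zero)."""
        return float(self.intervals.sum() / 1000.0)

    def __len__(self) -> int:
        return int(self.intervals.size)

    def normal_intervals(self) -> np.ndarray:
        """Intervals of beats not labelled ``artifact``."""
        keep = self.labels != LABEL_ARTIFACT
        return self.intervals[keep]


@dataclass(frozen=True)
class IHRSeries:
    """Per-beat instantaneous heart rate (bpm) at beat times (s)."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if values.shape != times.shape or values.ndim != 1:
            raise ValidationError("values and times must be aligned 1-D arrays")
        if values.size and not np.all(values > 0):
            raise ValidationError("instantaneous heart rate must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return int(self.values.size)

    def sample_and_hold(self, at: np.ndarray) -> np.ndarray:
        """Zero-order-hold resampling: value of the last beat at or before ``at``.

        Matches per-beat delivery of a live sensor: between beats the display
        holds the most recent value. Times before the first beat hold the
        first value.
        """
        at = np.asarray(at, dtype=float)
        idx = np.searchsorted(self.times, at, side="right") - 1
        return self.values[np.clip(idx, 0, len(self) - 1)]


def read_rr_file(path: str | Path, dialect: str = "plain") -> RRSeries:
    """Read a plain-text RR recording (one interval in ms per line).

    Lines starting with ``#`` are comments. ``dialect="tab-annotated"``
    accepts an optional second tab-separated column carrying a beat label
    (``normal`` / ``artifact`` / ``interpolated``).
    """
    if dialect not in ("plain", "tab-annotated"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    intervals: list[float] = []
    labels: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            value = float(fields[0])
        except ValueError:
            raise ParseError(f"{path.name}: line {lineno}: not a number: {fields[0]!r}")
        if value <= 0:
            raise ValidationError(
                f"{path.name}: line {lineno}: non-positive RR interval {value} ms"
            )
        label = LABEL_NORMAL
        if dialect == "tab-annotated" and len(fields) > 1 and fields[1]:
            label = fields[1].strip()
            if label not in _VALID_LABELS:
                raise ParseError(f"{path.name}: line {lineno}: unknown label {label!r}")
        intervals.append(value)
        labels.append(label)
    if not intervals:
        raise EmptyInputError(f"{path.name}: no RR intervals found")
    return RRSeries(np.array(intervals), np.array(labels, dtype=object))


def write_rr_file(rr: RRSeries, path: str | Path, annotate: bool = False) -> None:
    """Write an RRSeries in the plain-text dialect read by :func:`read_rr_file`."""
    lines: Iterable[str]
    if annotate:
        lines = (f"{v!r}\t{lab}" for v, lab in zip(rr.intervals, rr.labels))
    else:
        lines = (repr(float(v)) for v in rr.intervals)
    Path(path).write_text("\n".join(lines) + "\n")


def rr_to_ihr(rr: RRSeries) -> IHRSeries:
    """Convert RR intervals to instantaneous heart rate, 60000 / RR (bpm)."""
    if len(rr) == 0:
        raise EmptyInputError("cannot convert an empty RR series")
    return IHRSeries(60000.0 / rr.intervals, rr.beat_times)


def ihr_to_rr(ihr: IHRSeries) -> RRSeries:
    """Inverse of :func:`rr_to_ihr`; timing is re-accumulated from the intervals."""
    if len(ihr) == 0:
        raise EmptyInputError("cannot convert an empty iHR series")
    return RRSeries(60000.0 / ihr.values)


@dataclass(frozen=True)
class FilterPolicy:
    """Parameters of the running-median artifact filter.

    A beat is rejected when it deviates from the median of the last
    ``window`` accepted beats by more than ``threshold`` (relative). The
    first two beats seed the accepted history. Rejected beats are replaced
    by linear interpolation between the nearest accepted neighbours
    (``mode="interpolate"``, keeps the tachogram contiguous for spectral
    analysis) or dropped (``mode="delete"``).
    """

    threshold: float = 0.25
    window: int = 5
    max_reject_fraction: float = 0.5
    mode: str = "interpolate"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.mode not in ("interpolate", "delete"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass(frozen=True)
class FilterReport:
    n_beats: int
    n_rejected: int

    @property
    def reject_fraction(self) -> float:
        return self.n_rejected / self.n_beats if self.n_beats else 0.0


def filter_artifacts(
    rr: RRSeries, policy: FilterPolicy | None = None
) -> tuple[RRSeries, FilterReport]:
    """Label and correct ectopic / spurious beats in an RR series.

    Returns the corrected series and a report with the rejected-beat count.
    Beats that are not rejected are never altered. Raises
    :class:`UnusableRecordingError` when more than
    ``policy.max_reject_fraction`` of beats are rejected.
    """
    if len(rr) == 0:
        raise EmptyInputError("cannot filter an empty RR series")
    policy = policy or FilterPolicy()
    values = rr.intervals
    n = len(values)
    rejected = np.zeros(n, dtype=bool)
    accepted_hist: list[float] = []
    for i, v in enumerate(values):
        if len(accepted_hist) >= 2:
            med = float(np.median(accepted_hist[-policy.window:]))
            if abs(v - med) > policy.threshold * med:
                rejected[i] = True
                continue
        accepted_hist.append(float(v))

    n_rej = int(rejected.sum())
    report = FilterReport(n_beats=n, n_rejected=n_rej)
    if n_rej / n > policy.max_reject_fraction:
        raise UnusableRecordingError(
            f"{n_rej}/{n} beats rejected "
            f"(> {policy.max_reject_fraction:.0%}); recording unusable"
        )
    if n_rej == 0:
        return rr, report

    if policy.mode == "delete":
        keep = ~rejected
        return RRSeries(values[keep], rr.labels[keep]), report

    # linear interpolation over the index axis between accepted neighbours;
    # runs at the edges hold the nearest accepted value
    out = values.copy()
    good = np.flatnonzero(~rejected)
    bad = np.flatnonzero(rejected)
    out[bad] = np.interp(bad, good, values[good])
    labels = rr.labels.copy()
    labels[bad] = LABEL_INTERPOLATED
    return RRSeries(out, labels), report
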