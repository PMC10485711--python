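"""Level geometry: calibration, reference curve, and track construction.

A level is a corridor drawn around a target iHR waveform derived from a
prerecorded RR series, on a grid of 1-second-wide columns. The player's
calibration (baseline iHR and variability half-range, measured over a short
rest window) fixes the iHR-to-screen mapping: the baseline maps to the
vertical centre of the screen, and the vertical bpm extent of the screen is
proportional to the player's own variability. Before mapping, the reference
curve is re-anchored onto the player's baseline so every player starts in
the centre of the screen and faces the same *relative* excursions — the
level-equity contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import (
    CalibrationMismatchWarning,
    InsufficientDataError,
    LevelTooShortError,
)
from .rr_signal import RRSeries, rr_to_ihr

__all__ = [
    "Calibration",
    "ReferenceCurve",
    "GridSpec",
    "Track",
    "calibrate",
    "build_reference_curve",
    "build_track",
    "write_track",
    "read_track",
]

TRACK_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class Calibration:
    """iHR-to-screen mapping parameters for one player and session.

    ``sign=+1`` moves the avatar up when iHR rises (the default);
    ``sign=-1`` inverts the axis.
    """

    baseline_ihr: float  # bpm
    half_range: float  # bpm
    sign: int = 1

    def __post_init__(self) -> None:
        if self.baseline_ihr <= 0:
            raise ValueError("baseline_ihr must be positive")
        if self.half_range <= 0:
            raise ValueError("half_range must be positive")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class ReferenceCurve:
    """Per-second target iHR values sampled from a prerecorded series."""

    target_ihr: np.ndarray  # bpm, one value per 1 s column
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.target_ihr, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("target_ihr must be a non-empty 1-D array")
        if not np.all(arr > 0):
            raise ValueError("target iHR values must be positive")
        object.__setattr__(self, "target_ihr", arr)

    @property
    def duration(self) -> int:
        return int(self.target_ihr.size)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the (invisible) game grid.

    Columns are 1 s wide. ``vertical_extent`` is the bpm span of the whole
    screen; when ``None`` it is derived from the player's calibration as
    ``2 * screen_span_multiplier * half_range``, making the screen
    proportional to the player's own variability.
    """

    column_width: float = 1.0  # s, fixed by the game design
    cell_height: float = 1.0  # grid cells per vertical unit
    corridor_half_width: float = 5.0  # bpm
    vertical_extent: float | None = None  # bpm; None = derive from calibration
    screen_span_multiplier: float = 3.0
    bonus_spacing: float = 5.0  # s
    bonus_tolerance: float = 0.1  # normalized distance

    def __post_init__(self) -> None:
        if self.corridor_half_width <= 0:
            raise ValueError("corridor_half_width must be positive")
        if self.vertical_extent is not None and (
            self.vertical_extent <= 2 * self.corridor_half_width
        ):
            raise ValueError("vertical_extent must exceed twice the corridor half-width")
        if self.bonus_spacing < 1:
            raise ValueError("bonus_spacing must be >= 1 s")

    def resolve_extent(self, cal: Calibration) -> float:
        if self.vertical_extent is not None:
            return float(self.vertical_extent)
        return 2.0 * self.screen_span_multiplier * cal.half_range


@dataclass(frozen=True)
class Track:
    """A playable level on the 1 s grid, in normalized screen coordinates.

    Per column: the target position, the open corridor ``(corridor_bottom,
    corridor_top)`` the avatar must stay inside, obstacle intervals tiling
    the space outside the corridor, and a bonus flag at the target position.
    """

    target_y: np.ndarray
    corridor_top: np.ndarray
    corridor_bottom: np.ndarray
    obstacles: tuple  # per column: tuple of (lo, hi) normalized intervals
    bonus: np.ndarray  # bool per column
    vertical_extent: float  # bpm span behind the normalization
    grid: GridSpec
    level_id: str = ""
    world_id: str = ""

    def __post_init__(self) -> None:
        ty = np.asarray(self.target_y, dtype=float)
        top = np.asarray(self.corridor_top, dtype=float)
        bot = np.asarray(self.corridor_bottom, dtype=float)
        if not (ty.shape == top.shape == bot.shape) or ty.ndim != 1:
            raise ValueError("column arrays must be aligned 1-D arrays")
        if not (np.all(bot < ty) and np.all(ty < top)):
            raise ValueError("corridor must strictly contain the target in every column")
        object.__setattr__(self, "target_y", ty)
        object.__setattr__(self, "corridor_top", top)
        object.__setattr__(self, "corridor_bottom", bot)
        object.__setattr__(
            self, "bonus", np.asarray(self.bonus, dtype=bool)
        )

    @property
    def duration(self) -> int:
        """Track length in seconds (= number of 1 s columns)."""
        return int(self.target_y.size)

    @property
    def n_bonuses(self) -> int:
        return int(self.bonus.sum())

    def column_at(self, t: float) -> int:
        """Index of the column the time ``t`` falls in (clamped at the end).

        A microsecond tolerance absorbs the floating drift of an
        accumulated tick clock at column boundaries.
        """
        return min(int(np.floor(t + 1e-6)), self.duration - 1)


def calibrate(
    rr_window: RRSeries, k: float = 2.0, floor: float = 5.0
) -> Calibration:
    """Derive the iHR-to-screen calibration from a short rest window.

    ``baseline_ihr`` is the mean per-beat iHR over the window; the
    variability half-range is ``k`` sample standard deviations of the
    per-beat iHR, floored at ``floor`` bpm so a near-constant rest window
    still yields a playable screen span.
    """
    if len(rr_window) < 10:
        raise InsufficientDataError(
            f"calibration needs >= 10 beats, got {len(rr_window)}"
        )
    ihr = rr_to_ihr(rr_window).values
    spread = float(ihr.std(ddof=1))
    return Calibration(
        baseline_ihr=float(ihr.mean()),
        half_range=max(k * spread, floor),
    )


def build_reference_curve(
    prerecorded: RRSeries, source_id: str = "", min_span: float = 10.0
) -> ReferenceCurve:
    """Sample a prerecorded series' iHR waveform onto the 1 Hz column grid.

    The per-beat iHR is linearly interpolated over beat time and sampled at
    the centre of each 1 s column; the curve has ``floor(recording span)``
    columns, the recording span counted from time zero.
    """
    span = prerecorded.duration
    if span < min_span:
        raise LevelTooShortError(
            f"recording spans {span:.1f} s; a level needs >= {min_span:g} s"
        )
    ihr = rr_to_ihr(prerecorded)
    n = int(np.floor(span))
    centers = np.arange(n) + 0.5
    values = np.interp(centers, ihr.times, ihr.values)
    return ReferenceCurve(values, source_id=source_id)


def build_track(
    curve: ReferenceCurve,
    cal: Calibration,
    grid: GridSpec | None = None,
    recenter: str = "first",
    level_id: str = "",
    world_id: str = "",
) -> Track:
    """Lay out corridor, obstacles and bonuses around a reference curve.

    ``recenter`` anchors the curve onto the player's baseline before
    mapping: ``"first"`` (default) shifts the curve so its first value equals
    the baseline — every player starts exactly in the screen centre —
    ``"mean"`` anchors the curve's mean instead, and ``"none"`` applies no
    shift. Obstacles tile the full space outside the corridor (collision
    only depends on the corridor bounds, so dense tiling is equivalent to
    sparse art placement). A bonus sits on the target every
    ``grid.bonus_spacing`` seconds.
    """
    grid = grid or GridSpec()
    extent = grid.resolve_extent(cal)
    values = curve.target_ihr
    if recenter == "first":
        shifted = values - values[0] + cal.baseline_ihr
    elif recenter == "mean":
        shifted = values - values.mean() + cal.baseline_ihr
    elif recenter == "none":
        shifted = values
    else:
        raise ValueError(f"unknown recenter mode {recenter!r}")

    y_raw = 0.5 + cal.sign * (shifted - cal.baseline_ihr) / extent
    if np.any(np.abs(y_raw - 0.5) > 1.5):
        warnings.warn(
            "reference curve maps outside three screen spans; values clipped",
            CalibrationMismatchWarning,
            stacklevel=2,
        )
    hw = grid.corridor_half_width / extent  # normalized corridor half-width
    target_y = np.clip(y_raw, hw * 1.001, 1.0 - hw * 1.001)
    top = np.minimum(target_y + hw, 1.0)
    bottom = np.maximum(target_y - hw, 0.0)

    obstacles = tuple(
        tuple(
            iv
            for iv in (((t, 1.0) if t < 1.0 else None), ((0.0, b) if b > 0.0 else None))
            if iv is not None
        )
        for t, b in zip(top, bottom)
    )
    n = values.size
    spacing = int(round(grid.bonus_spacing))
    bonus = np.zeros(n, dtype=bool)
    bonus[spacing - 1 :: spacing] = True

    return Track(
        target_y=target_y,
        corridor_top=top,
        corridor_bottom=bottom,
        obstacles=obstacles,
        bonus=bonus,
        vertical_extent=extent,
        grid=grid,
        level_id=level_id or curve.source_id,
        world_id=world_id,
    )


def write_track(track: Track, path: str | Path) -> None:
    """Serialize a track to a versioned JSON document (bit-exact round trip)."""
    doc = {
        "schema_version": TRACK_SCHEMA_VERSION,
        "level_id": track.level_id,
        "world_id": track.world_id,
        "vertical_extent": track.vertical_extent,
        "grid": asdict(track.grid),
        "columns": {
            "target_y": [v.hex() for v in track.target_y.astype(float)],
            "corridor_top": [v.hex() for v in track.corridor_top.astype(float)],
            "corridor_bottom": [v.hex() for v in track.corridor_bottom.astype(float)],
            "obstacles": [
                [[lo.hex(), hi.hex()] for lo, hi in col] for col in track.obstacles
            ],
            "bonus": track.bonus.astype(int).tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_track(path: str | Path) -> Track:
    """Read a track document written by :func:`write_track`."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != TRACK_SCHEMA_VERSION:
        from .errors import SchemaVersionError

        raise SchemaVersionError(f"unknown track schema version {version!r}")
    cols = doc["columns"]
    unhex = lambda xs: np.array([float.fromhex(x) for x in xs])
    return Track(
        target_y=unhex(cols["target_y"]),
        corridor_top=unhex(cols["corridor_top"]),
        corridor_bottom=unhex(cols["corridor_bottom"]),
        obstacles=tuple(
            tuple((float.fromhex(lo), float.fromhex(hi)) for lo, hi in col)
            for col in cols["obstacles"]
        ),
        bonus=np.array(cols["bonus"], dtype=bool),
        vertical_extent=float(doc["vertical_extent"]),
        grid=GridSpec(**doc["grid"]),
        level_id=doc["level_id"],
        world_id=doc["world_id"],
    )
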