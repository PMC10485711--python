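"""Deterministic headless game loop.

Each tick the avatar's vertical position is set by the current iHR sample
through the calibrated linear mapping; touching an obstacle cell (the space
outside the open corridor) costs a life, collecting the bonus on a column
requires passing within a tolerance of the target, and the game terminates
either when the end of the track is reached with at least one life
(``completed``) or when the last life is lost (``game_over``). A short
invulnerability window after each life loss converts continuous obstacle
contact into discrete life losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .errors import EmptyInputError, StateMachineError
from .rr_signal import IHRSeries
from .track_builder import Calibration, Track

__all__ = [
    "GameConfig",
    "GameState",
    "GameResult",
    "map_ihr_to_position",
    "step",
    "run_game",
    "baevsky_stress_index",
]

RUNNING = "running"
COMPLETED = "completed"
GAME_OVER = "game_over"


@dataclass(frozen=True)
class GameConfig:
    """Rules of the game session."""

    lives_start: int = 20
    tick_rate: float = 10.0  # Hz
    invulnerability: float = 1.0  # s of immunity after a life loss
    bonus_tolerance: float = 0.1  # normalized distance from the target

    def __post_init__(self) -> None:
        if self.lives_start < 1:
            raise ValueError("lives_start must be >= 1")
        if self.tick_rate <= 0:
            raise ValueError("tick_rate must be positive")
        if self.invulnerability < 0:
            raise ValueError("invulnerability must be >= 0")


@dataclass
class GameState:
    """Mutable-by-copy snapshot of one moment of play."""

    t: float = 0.0
    y: float = 0.5
    lives: int = 20
    bonus: int = 0
    status: str = RUNNING
    invuln_until: float = 0.0
    collected: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


@dataclass(frozen=True)
class GameResult:
    """The game's score surface, shown on the final page."""

    bonus: int
    time_played: float  # s
    avg_hr: float  # bpm
    stress_index: float
    completed: bool
    lives_left: int

    def as_dict(self) -> dict:
        return asdict(self)


def map_ihr_to_position(cal: Calibration, ihr: float, vertical_extent: float) -> float:
    """Normalized vertical position of an iHR value under a calibration.

    ``y = 0.5 + sign * (ihr - baseline) / vertical_extent``, clipped to
    [0, 1]; the baseline maps exactly to the screen centre.
    """
    y = 0.5 + cal.sign * (ihr - cal.baseline_ihr) / vertical_extent
    return float(min(1.0, max(0.0, y)))


def step(
    state: GameState,
    ihr_sample: float,
    track: Track,
    cfg: GameConfig,
    cal: Calibration,
) -> GameState:
    """Advance the game by one tick; returns a new state.

    Raises :class:`StateMachineError` when called on a terminal state.
    """
    if state.status != RUNNING:
        raise StateMachineError(f"cannot step a {state.status!r} game")
    dt = 1.0 / cfg.tick_rate
    t = state.t + dt
    col = track.column_at(t)
    y = map_ihr_to_position(cal, ihr_sample, track.vertical_extent)

    lives = state.lives
    invuln_until = state.invuln_until
    bonus = state.bonus
    collected = state.collected
    if collected.size != track.duration:
        collected = np.zeros(track.duration, dtype=bool)
    else:
        collected = collected.copy()

    in_obstacle = y >= track.corridor_top[col] or y <= track.corridor_bottom[col]
    if in_obstacle and t >= invuln_until:
        lives -= 1
        invuln_until = t + cfg.invulnerability

    if (
        track.bonus[col]
        and not collected[col]
        and abs(y - track.target_y[col]) <= cfg.bonus_tolerance
    ):
        bonus += 1
        collected[col] = True

    if lives <= 0:
        status = GAME_OVER
    elif t >= track.duration - 1e-6:
        status = COMPLETED
    else:
        status = RUNNING

    return GameState(
        t=t,
        y=y,
        lives=lives,
        bonus=bonus,
        status=status,
        invuln_until=invuln_until,
        collected=collected,
    )


def baevsky_stress_index(rr_ms: np.ndarray, bin_width: float = 50.0) -> float:
    """Histogram-based RR regularity index used as the game's stress proxy.

    ``SI = AMo / (2 * Mo * MxDMn)`` with Mo the modal RR bin centre (s),
    AMo the percentage of beats in the modal bin, and MxDMn the RR range
    (s), using ``bin_width`` ms histogram bins. The range is floored at one
    bin width so a perfectly regular series yields a finite (large) value.
    This is one conventional definition of a stress index; it is pluggable
    in :func:`run_game`.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size == 0:
        raise EmptyInputError("stress index needs at least one RR value")
    edges = np.arange(0.0, rr.max() + bin_width, bin_width)
    counts, _ = np.histogram(rr, bins=edges)
    k = int(np.argmax(counts))
    mo_s = (edges[k] + edges[k + 1]) / 2.0 / 1000.0
    amo_pct = 100.0 * counts[k] / rr.size
    mxdmn_s = max(float(rr.max() - rr.min()), bin_width) / 1000.0
    return float(amo_pct / (2.0 * mo_s * mxdmn_s))


def run_game(
    ihr_stream: IHRSeries,
    track: Track,
    cfg: GameConfig | None = None,
    cal: Calibration | None = None,
    stress_index_fn: Callable[[np.ndarray], float] = baevsky_stress_index,
    return_trace: bool = False,
):
    """Play a full game from an iHR stream; returns the :class:`GameResult`.

    The per-beat stream is resampled to the tick grid by sample-and-hold
    (the value shown between beats is the most recent one, matching live
    per-beat delivery). ``avg_hr`` averages the consumed tick samples and
    the stress index is computed from their RR equivalents (60000 / iHR).
    With ``return_trace=True`` also returns a per-tick record list.
    """
    if cal is None:
        raise ValueError("run_game requires the session calibration")
    cfg = cfg or GameConfig()
    if len(ihr_stream) == 0:
        raise EmptyInputError("empty iHR stream")
    dt = 1.0 / cfg.tick_rate
    n_ticks = int(np.ceil(track.duration / dt))
    tick_times = (np.arange(n_ticks) + 1) * dt
    samples = ihr_stream.sample_and_hold(tick_times)

    state = GameState(lives=cfg.lives_start, collected=np.zeros(track.duration, bool))
    consumed: list[float] = []
    trace: list[dict] = []
    for sample in samples:
        state = step(state, float(sample), track, cfg, cal)
        consumed.append(float(sample))
        if return_trace:
            trace.append(
                {
                    "t": state.t,
                    "ihr": float(sample),
                    "y": state.y,
                    "lives": state.lives,
                    "bonus": state.bonus,
                    "status": state.status,
                }
            )
        if state.status != RUNNING:
            break

    consumed_arr = np.array(consumed)
    result = GameResult(
        bonus=state.bonus,
        time_played=round(state.t, 9),
        avg_hr=float(consumed_arr.mean()),
        stress_index=stress_index_fn(60000.0 / consumed_arr),
        completed=state.status == COMPLETED,
        lives_left=state.lives,
    )
    if return_trace:
        return result, trace
    return result
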