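"""Synthetic RR-interval generator with respiratory sinus arrhythmia.

Builds beat-to-beat RR series from a mean interval plus a deterministic
respiratory modulation (an asymmetric sinusoid whose inhalation:exhalation
ratio shapes the within-cycle waveform), optional white beat-to-beat noise,
and transient "technique" events — the voluntary manoeuvres players use to
steer instantaneous heart rate: breath holding (apnea) lengthens RR and
widens the beat-to-beat swing, mild hyperventilation shortens RR and
suppresses the respiratory swing, muscle movements and swallowing inject
brief biphasic transients.

Also provides "player" policies (perfect and noisy trackers) that drive the
game engine without hardware, and a cohort simulator producing the
two-group, baseline/test study dataset the aggregation pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PathologicalParametersError
from .game_engine import GameConfig, run_game
from .hrv_metrics import SpectralConfig, frequency_domain_metrics, time_domain_metrics
from .rr_signal import FilterPolicy, IHRSeries, RRSeries, filter_artifacts
from .track_builder import (
    Calibration,
    GridSpec,
    Track,
    build_reference_curve,
    build_track,
    calibrate,
)

__all__ = [
    "BreathingPattern",
    "TechniqueEvent",
    "SimConfig",
    "CohortEffects",
    "generate_rr",
    "perfect_player_stream",
    "noisy_player_stream",
    "simulate_cohort",
    "null_effects",
]

EVENT_KINDS = ("apnea", "hyperventilation", "muscle", "swallow")

# amplitude multipliers of the respiratory swing while an event is active
_AMP_GAIN = {"apnea": 1.5, "hyperventilation": 0.25, "muscle": 1.0, "swallow": 1.0}
# sign of the sustained RR offset (positive lengthens RR, i.e. lowers iHR)
_OFFSET_SIGN = {"apnea": +1.0, "hyperventilation": -1.0}


@dataclass(frozen=True)
class BreathingPattern:
    """Respiratory modulation of the RR series.

    ``ie_ratio`` is the inhalation:exhalation duration ratio; values below 1
    (exhalation longer than inhalation) give the slow-rise / fast-fall RR
    waveform of paced relaxation breathing.
    """

    freq: float = 0.25  # Hz, typical resting respiratory rate (15 / min)
    amplitude: float = 40.0  # ms peak RSA modulation
    ie_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.03 < self.freq < 0.6:
            raise ValueError("breathing frequency must be in (0.03, 0.6) Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.ie_ratio <= 0:
            raise ValueError("ie_ratio must be positive")


@dataclass(frozen=True)
class TechniqueEvent:
    """A transient voluntary manoeuvre applied to the RR series."""

    kind: str
    onset: float  # s
    duration: float  # s
    magnitude: float  # ms

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown technique kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    def envelope(self, t: float) -> float:
        """Activation in [0, 1] with half-cosine on/off ramps."""
        u = t - self.onset
        if u < 0 or u > self.duration:
            return 0.0
        ramp = min(2.0, self.duration / 4.0)
        if u < ramp:
            return 0.5 * (1.0 - np.cos(np.pi * u / ramp))
        if u > self.duration - ramp:
            return 0.5 * (1.0 - np.cos(np.pi * (self.duration - u) / ramp))
        return 1.0

    def rr_offset(self, t: float) -> float:
        """Additive RR offset (ms) at time ``t``."""
        e = self.envelope(t)
        if e == 0.0:
            return 0.0
        if self.kind in _OFFSET_SIGN:
            return _OFFSET_SIGN[self.kind] * self.magnitude * e
        # muscle / swallow: brief biphasic transient over the event window
        u = (t - self.onset) / self.duration
        phase = np.sin(2.0 * np.pi * u)
        return self.magnitude * (phase if self.kind == "muscle" else -phase)

    def amp_gain(self, t: float) -> float:
        """Multiplier of the RSA amplitude at time ``t``."""
        e = self.envelope(t)
        return 1.0 + (_AMP_GAIN[self.kind] - 1.0) * e


@dataclass(frozen=True)
class SimConfig:
    """Global parameters of one synthetic recording."""

    mean_rr: float = 850.0  # ms (~71 bpm resting)
    noise_sd: float = 15.0  # ms white beat-to-beat noise
    duration: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def respiratory_waveform(phase: np.ndarray | float, ie_ratio: float) -> np.ndarray | float:
    """Asymmetric unit-amplitude respiratory waveform in [-1, 1].

    ``phase`` is the cycle fraction in [0, 1). The waveform rises over the
    inhalation fraction ``ie / (1 + ie)`` of the cycle and falls over the
    rest; at ``ie_ratio == 1`` it is a pure cosine shape.
    """
    phase = np.mod(phase, 1.0)
    fi = ie_ratio / (1.0 + ie_ratio)
    rising = -np.cos(np.pi * phase / fi)
    falling = np.cos(np.pi * (phase - fi) / (1.0 - fi))
    return np.where(phase < fi, rising, falling)


def generate_rr(
    cfg: SimConfig,
    breathing: BreathingPattern | None = None,
    events: tuple[TechniqueEvent, ...] | list[TechniqueEvent] = (),
) -> RRSeries:
    """Construct a synthetic RR series beat by beat.

    ``RR(t) = mean_rr + amplitude * waveform(freq t) * gain(t) + offsets(t)
    + N(0, noise_sd)``; the next beat time advances by the generated RR.
    Deterministic under ``cfg.seed``. Raises
    :class:`PathologicalParametersError` if any beat comes out at or below
    200 ms (physiologically impossible, a sign of bad parameters).
    """
    breathing = breathing or BreathingPattern()
    for ev in events:
        if ev.onset >= cfg.duration:
            raise ValueError(
                f"{ev.kind} event at {ev.onset} s starts beyond the "
                f"{cfg.duration} s recording"
            )
    rng = np.random.default_rng(cfg.seed)
    intervals: list[float] = []
    t = 0.0
    while t < cfg.duration:
        gain = 1.0
        offset = 0.0
        for ev in events:
            gain *= ev.amp_gain(t)
            offset += ev.rr_offset(t)
        rsa = breathing.amplitude * gain * float(
            respiratory_waveform(breathing.freq * t, breathing.ie_ratio)
        )
        rr = cfg.mean_rr + rsa + offset
        if cfg.noise_sd > 0:
            rr += rng.normal(0.0, cfg.noise_sd)
        if rr <= 200.0:
            raise PathologicalParametersError(
                f"generated RR {rr:.0f} ms at t={t:.1f} s; "
                "parameters are physiologically impossible"
            )
        intervals.append(rr)
        t += rr / 1000.0
    return RRSeries(np.array(intervals))


def perfect_player_stream(track: Track, cal: Calibration) -> IHRSeries:
    """The iHR stream that tracks the target curve exactly.

    Inverts the iHR-to-screen mapping onto each column's target position;
    one sample per column, held between columns.
    """
    ihr = cal.baseline_ihr + cal.sign * (track.target_y - 0.5) * track.vertical_extent
    return IHRSeries(ihr, np.arange(track.duration, dtype=float))


def noisy_player_stream(
    track: Track,
    cal: Calibration,
    skill: float,
    seed: int = 0,
    rho: float = 0.7,
) -> IHRSeries:
    """Perfect stream plus AR(1) tracking error; a behavioural player model.

    The error is first-order autocorrelated (coefficient ``rho``) with
    stationary SD ``(1 - skill) * cal.half_range``; ``skill=1`` reproduces
    the perfect stream exactly. Deterministic under ``seed``.
    """
    if not 0.0 <= skill <= 1.0:
        raise ValueError("skill must be in [0, 1]")
    perfect = perfect_player_stream(track, cal)
    sd = (1.0 - skill) * cal.half_range
    rng = np.random.default_rng(seed)
    n = len(perfect)
    eps = rng.standard_normal(n)
    err = np.empty(n)
    err[0] = sd * eps[0]
    c = sd * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        err[i] = rho * err[i - 1] + c * eps[i]
    values = np.maximum(perfect.values + err, 20.0)  # keep iHR physiological
    return IHRSeries(values, perfect.times)


@dataclass(frozen=True)
class CohortEffects:
    """What changes between the baseline and test phases, per group.

    Both groups get a practice-driven skill gain in the test phase; the
    experimental group additionally gets a larger gain (it was taught how to
    steer iHR) and scheduled technique events in its test recordings. The
    default schedule — sustained mild hyperventilation — shortens RR and
    suppresses the respiratory swing, so the experimental group's RR mean
    and RMSSD fall from baseline to test.
    """

    skill_gain_control: float = 0.05
    skill_gain_experimental: float = 0.15
    experimental_test_events: tuple[TechniqueEvent, ...] = (
        TechniqueEvent("hyperventilation", onset=15.0, duration=40.0, magnitude=80.0),
        TechniqueEvent("hyperventilation", onset=65.0, duration=40.0, magnitude=80.0),
    )


def null_effects() -> CohortEffects:
    """A no-group-effect configuration: identical skill gains, no events."""
    return CohortEffects(
        skill_gain_control=0.05,
        skill_gain_experimental=0.05,
        experimental_test_events=(),
    )


def _participant_physiology(rng: np.random.Generator) -> tuple[float, BreathingPattern]:
    mean_rr = float(np.clip(rng.normal(850.0, 60.0), 600.0, 1100.0))
    breathing = BreathingPattern(
        freq=float(rng.uniform(0.20, 0.30)),
        amplitude=float(np.clip(rng.normal(40.0, 8.0), 10.0, 80.0)),
        ie_ratio=1.0,
    )
    return mean_rr, breathing


def _level_tracks(rng: np.random.Generator) -> list[RRSeries]:
    """Prerecorded RR series behind the two shared levels (slow waveforms)."""
    recs = []
    for freq in (0.06, 0.09):
        recs.append(
            generate_rr(
                SimConfig(
                    mean_rr=900.0,
                    noise_sd=8.0,
                    duration=121.0,
                    seed=int(rng.integers(2**31)),
                ),
                BreathingPattern(freq=freq, amplitude=70.0),
            )
        )
    return recs


def simulate_cohort(
    n_per_group: int = 8,
    effects: CohortEffects | None = None,
    seed: int = 0,
    games_per_phase: int = 2,
    game_config: GameConfig | None = None,
    grid: GridSpec | None = None,
    keep_series: bool = False,
) -> pd.DataFrame:
    """Simulate the two-group, baseline/test pilot protocol.

    Each synthetic participant plays ``games_per_phase`` games (the same
    shared levels) in the baseline phase and again in the test phase. Per
    game, a synthetic RR recording (the participant's physiology, plus
    group/phase technique events) yields the HRV metrics, while a noisy
    player stream at the participant's current skill drives the game engine
    for the performance outcomes. Returns one row per game with the
    participant, group, phase, game outcomes and HRV metrics (plus the raw
    ``rr`` series when ``keep_series``).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    effects = effects or CohortEffects()
    game_config = game_config or GameConfig()
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)

    level_recordings = _level_tracks(rng)
    spectral = SpectralConfig(segment_length=60.0)
    policy = FilterPolicy()

    rows = []
    for g, group in enumerate(("control", "experimental")):
        for p in range(n_per_group):
            pid = f"{group[:4]}{p:02d}"
            mean_rr, breathing = _participant_physiology(rng)
            base_skill = float(rng.uniform(0.35, 0.65))
            gain = (
                effects.skill_gain_experimental
                if group == "experimental"
                else effects.skill_gain_control
            )
            # per-session calibration from a 40 s rest window
            cal_rec = generate_rr(
                SimConfig(mean_rr, 15.0, 40.0, int(rng.integers(2**31))), breathing
            )
            cal = calibrate(cal_rec)
            tracks = [
                build_track(
                    build_reference_curve(rec, source_id=f"level{i+1}"),
                    cal,
                    grid,
                )
                for i, rec in enumerate(level_recordings)
            ]
            for phase in ("baseline", "test"):
                skill = base_skill if phase == "baseline" else min(base_skill + gain, 0.98)
                events: tuple[TechniqueEvent, ...] = ()
                if phase == "test" and group == "experimental":
                    events = effects.experimental_test_events
                for game_idx in range(games_per_phase):
                    track = tracks[game_idx % len(tracks)]
                    rec = generate_rr(
                        SimConfig(
                            mean_rr,
                            15.0,
                            float(track.duration),
                            int(rng.integers(2**31)),
                        ),
                        breathing,
                        events,
                    )
                    rec, _ = filter_artifacts(rec, policy)
                    td = time_domain_metrics(rec)
                    lf, hf = frequency_domain_metrics(rec, spectral)
                    stream = noisy_player_stream(
                        track, cal, skill, seed=int(rng.integers(2**31))
                    )
                    result = run_game(stream, track, game_config, cal)
                    row = {
                        "participant": pid,
                        "group": group,
                        "phase": phase,
                        "game": game_idx,
                        "level_id": track.level_id,
                        "bonus": result.bonus,
                        "time": result.time_played,
                        "avg_hr": result.avg_hr,
                        "stress_index": result.stress_index,
                        "completed": result.completed,
                        "rr_mean": td.rr_mean,
                        "sdrr": td.sdrr,
                        "rmssd": td.rmssd,
                        "pnn50": td.pnn50,
                        "lf_power": lf,
                        "hf_power": hf,
                    }
                    if keep_series:
                        row["rr"] = rec
                    rows.append(row)
    return pd.DataFrame(rows)
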