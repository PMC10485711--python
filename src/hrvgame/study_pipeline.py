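"""Session packaging and study aggregation.

Covers the anonymized per-session export (versioned JSON documents with an
explicit ban on identifying fields) and the two-group, baseline/test
aggregation: per-phase averaging of each participant's games, group change
tables (cell means and SDs, within-group deltas, between-group
differences), exact pooling of per-group descriptive moments, and an
optional permutation test of the group-by-phase interaction as a
self-contained alternative to a parametric factorial model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyGroupError,
    EmptyInputError,
    IncompletePhaseError,
    SchemaValidationError,
    SchemaVersionError,
)
from .game_engine import GameResult
from .rr_signal import RRSeries
from .track_builder import Calibration

__all__ = [
    "SessionRecord",
    "GroupSummary",
    "write_session",
    "read_session",
    "phase_averages",
    "group_change_table",
    "pooled_descriptives",
    "permutation_interaction_test",
]

SESSION_SCHEMA_VERSION = "1.0"

#: fields that must never appear in an exported session document
FORBIDDEN_FIELDS = frozenset(
    {"name", "surname", "full_name", "email", "address", "phone", "birthdate", "dni"}
)

OUTCOME_COLUMNS = (
    "bonus",
    "time",
    "avg_hr",
    "stress_index",
    "rr_mean",
    "sdrr",
    "rmssd",
    "pnn50",
    "lf_power",
    "hf_power",
)


@dataclass(frozen=True)
class SessionRecord:
    """One game session: anonymized metadata, calibration, signal, result."""

    user_code: str
    session_id: str
    level_id: str
    start_time: float  # s, epoch or session-relative
    end_time: float
    calibration: Calibration
    rr: RRSeries
    result: GameResult
    metadata: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("end_time must be >= start_time")
        if self.metadata is None:
            object.__setattr__(self, "metadata", {})
        _check_anonymized(self.metadata)


def _check_anonymized(mapping: dict) -> None:
    for key in mapping:
        if str(key).lower() in FORBIDDEN_FIELDS:
            raise SchemaValidationError(
                f"identifying field {key!r} is not allowed in a session document"
            )


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Export a session as a versioned, anonymized JSON document."""
    doc = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "user_code": record.user_code,
        "session_id": record.session_id,
        "level_id": record.level_id,
        "start_time": record.start_time,
        "end_time": record.end_time,
        "calibration": asdict(record.calibration),
        "rr": {
            "intervals": [float(v) for v in record.rr.intervals],
            "labels": record.rr.labels.tolist(),
        },
        "result": record.result.as_dict(),
        "metadata": dict(record.metadata),
    }
    _check_anonymized(doc)
    _check_anonymized(doc["metadata"])
    Path(path).write_text(json.dumps(doc, indent=1))


def read_session(path: str | Path) -> SessionRecord:
    """Read a session document written by :func:`write_session`.

    Rejects unknown schema versions and documents carrying identifying
    fields at the top level or in the metadata block.
    """
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SESSION_SCHEMA_VERSION:
        raise SchemaVersionError(f"unknown session schema version {version!r}")
    _check_anonymized(doc)
    _check_anonymized(doc.get("metadata", {}))
    return SessionRecord(
        user_code=doc["user_code"],
        session_id=doc["session_id"],
        level_id=doc["level_id"],
        start_time=doc["start_time"],
        end_time=doc["end_time"],
        calibration=Calibration(**doc["calibration"]),
        rr=RRSeries(
            np.array(doc["rr"]["intervals"]),
            np.array(doc["rr"]["labels"], dtype=object),
        ),
        result=GameResult(**doc["result"]),
        metadata=doc.get("metadata", {}),
    )


def phase_averages(
    games: pd.DataFrame,
    games_per_phase: int = 2,
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average each participant's games within each phase.

    ``games`` holds one row per game with at least ``participant``,
    ``group``, ``phase`` and the outcome columns. Every participant must
    have exactly ``games_per_phase`` games in each phase; otherwise an
    :class:`IncompletePhaseError` names the offenders. Returns one row per
    participant and phase.
    """
    if games.empty:
        raise EmptyInputError("no game records")
    outcomes = list(outcomes or [c for c in OUTCOME_COLUMNS if c in games.columns])
    counts = games.groupby(["participant", "phase"]).size()
    bad = counts[counts != games_per_phase]
    if len(bad):
        listing = ", ".join(f"{p}/{ph} ({n} games)" for (p, ph), n in bad.items())
        raise IncompletePhaseError(
            f"expected {games_per_phase} games per phase; incomplete: {listing}"
        )
    out = (
        games.groupby(["participant", "group", "phase"], as_index=False)[outcomes]
        .mean()
        .sort_values(["participant", "phase"], kind="stable")
        .reset_index(drop=True)
    )
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Cell statistics and change scores of a two-group, two-phase study.

    ``cells``: mean and SD per group x phase per outcome.
    ``deltas``: per group, mean(test) - mean(baseline) per outcome.
    ``between_test``: experimental - control difference of test-phase means.
    ``interaction``: delta(experimental) - delta(control) — the
    group-by-phase interaction a factorial model would test.
    """

    cells: pd.DataFrame
    deltas: pd.DataFrame
    between_test: pd.Series
    interaction: pd.Series


def group_change_table(
    phase_records: pd.DataFrame, outcomes: Sequence[str] | None = None
) -> GroupSummary:
    """Build the group x phase summary from per-participant phase records."""
    outcomes = list(
        outcomes or [c for c in OUTCOME_COLUMNS if c in phase_records.columns]
    )
    for group in ("control", "experimental"):
        if not (phase_records["group"] == group).any():
            raise EmptyGroupError(f"group {group!r} has no participants")
    for phase in ("baseline", "test"):
        if not (phase_records["phase"] == phase).any():
            raise EmptyGroupError(f"phase {phase!r} has no records")

    cells = phase_records.groupby(["group", "phase"])[outcomes].agg(["mean", "std"])
    means = phase_records.groupby(["group", "phase"])[outcomes].mean()
    deltas = means.xs("test", level="phase") - means.xs("baseline", level="phase")
    between_test = (
        means.loc[("experimental", "test")] - means.loc[("control", "test")]
    )
    interaction = deltas.loc["experimental"] - deltas.loc["control"]
    return GroupSummary(
        cells=cells, deltas=deltas, between_test=between_test, interaction=interaction
    )


def pooled_descriptives(
    group_stats: Iterable[tuple[int, float, float]]
) -> tuple[int, float, float]:
    """Combine per-group (n, mean, SD) into the whole-sample (N, mean, SD).

    Uses the exact pooling identity
    ``SS_total = sum[(n_i - 1) s_i^2 + n_i (m_i - M)^2]`` with
    ``variance = SS_total / (N - 1)`` — identical to concatenating the raw
    samples, so it reconstructs an "all participants" column from per-group
    moments exactly.
    """
    stats = [(int(n), float(m), float(s)) for n, m, s in group_stats]
    if not stats or sum(n for n, _, _ in stats) == 0:
        raise EmptyInputError("no groups to pool")
    total_n = sum(n for n, _, _ in stats)
    grand_mean = sum(n * m for n, m, _ in stats) / total_n
    if total_n < 2:
        return total_n, grand_mean, 0.0
    ss = sum((n - 1) * s**2 + n * (m - grand_mean) ** 2 for n, m, s in stats)
    return total_n, grand_mean, float(np.sqrt(ss / (total_n - 1)))


def permutation_interaction_test(
    phase_records: pd.DataFrame,
    outcome: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of the group-by-phase interaction for one outcome.

    The statistic is the difference of within-participant change scores
    (test - baseline) between the groups; group labels are permuted across
    participants. Returns ``(observed statistic, two-sided p value)``.
    """
    wide = phase_records.pivot_table(
        index=["participant", "group"], columns="phase", values=outcome
    ).reset_index()
    delta = (wide["test"] - wide["baseline"]).to_numpy(dtype=float)
    is_exp = (wide["group"] == "experimental").to_numpy()
    n_exp = int(is_exp.sum())
    if n_exp == 0 or n_exp == len(delta):
        raise EmptyGroupError("both groups are required for the interaction test")

    def stat(mask: np.ndarray) -> float:
        return float(delta[mask].mean() - delta[~mask].mean())

    observed = stat(is_exp)
    rng = np.random.default_rng(seed)
    count = 0
    n = len(delta)
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_exp, replace=False)] = True
        if abs(stat(perm)) >= abs(observed) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return observed, p
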