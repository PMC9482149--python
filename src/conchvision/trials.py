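"""Behavioural trial records, the withdrawal ethogram and responder tables.

A presentation of one looming stimulus to one animal is a
:class:`TrialRecord` carrying the ordered behavioural transitions
observed during the expansion (the five-category ethogram below) and
the re-emergence time afterwards.  Trials aggregate into a
:class:`ResponseTable`: responder counts ``k`` out of ``n`` trials per
stimulus level, with one designated control row, which is the input to
threshold inference.

A trial counts as a *response* only if some transition beyond
``stop_feeding`` occurred; stop-feeding-only trials are excluded to
reduce false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry import ExpansionProfile

__all__ = [
    "Behavior",
    "TransitionEvent",
    "TrialRecord",
    "ResponseTable",
    "is_response",
    "build_response_table",
    "transitions_by_angle",
    "reemergence_summary",
    "write_trials_csv",
    "read_trials_csv",
]


class Behavior(str, Enum):
    """Ethogram categories in increasing severity order: proboscis
    actions first (1-3), then eyestalk (ommatophore) withdrawal (4-5)."""

    STOP_FEEDING = "stop_feeding"
    PARTIAL_PROBOSCIS_WITHDRAWAL = "partial_proboscis_withdrawal"
    FULL_PROBOSCIS_WITHDRAWAL = "full_proboscis_withdrawal"
    PARTIAL_EYESTALK_WITHDRAWAL = "partial_eyestalk_withdrawal"
    FULL_EYESTALK_WITHDRAWAL = "full_eyestalk_withdrawal"

    @property
    def severity(self) -> int:
        return list(Behavior).index(self)


@dataclass(frozen=True)
class TransitionEvent:
    """One behavioural transition at ``time_s`` seconds from stimulus onset."""

    category: Behavior
    time_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Behavior(self.category))
        if self.time_s < 0:
            raise ValidationError("event time must be >= 0")


@dataclass
class TrialRecord:
    """One stimulus presentation to one individual.

    ``level`` is the stimulus magnitude — Michelson contrast for the
    contrast experiment, check width in degrees for the resolution
    experiment — and is 0.0 with ``is_control=True`` for the control
    loom.  ``reemergence_s`` is None when the animal never withdrew.
    """

    individual_id: str
    experiment: str  # "contrast" | "resolution"
    stimulus_id: str
    repeat_index: int
    level: float
    is_control: bool = False
    events: list[TransitionEvent] = field(default_factory=list)
    reemergence_s: float | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("contrast", "resolution"):
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        if self.repeat_index not in (1, 2):
            raise ValidationError("repeat_index must be 1 or 2")
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("event times must be non-decreasing")
        if self.reemergence_s is not None and self.reemergence_s < 0:
            raise ValidationError("reemergence_s must be >= 0")

    @property
    def key(self) -> tuple:
        return (self.individual_id, self.stimulus_id, self.repeat_index)


def is_response(trial: TrialRecord) -> bool:
    """True iff the trial contains a transition beyond stop-feeding."""
    return any(e.category is not Behavior.STOP_FEEDING for e in trial.events)


@dataclass
class ResponseTable:
    """Responder counts per stimulus level with one control row.

    ``levels`` is a DataFrame with columns ``level, k, n, is_control``
    sorted by level with the control row first.
    """

    experiment: str
    levels: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.levels
        required = {"level", "k", "n", "is_control"}
        if not required.issubset(df.columns):
            raise ValidationError(f"response table needs columns {sorted(required)}")
        if ((df["k"] < 0) | (df["k"] > df["n"])).any():
            raise ValidationError("need 0 <= k <= n in every row")
        if len(df) and int(df["is_control"].sum()) > 1:
            raise ValidationError("at most one control row allowed")

    @property
    def control(self) -> pd.Series | None:
        ctrl = self.levels[self.levels["is_control"]]
        return None if ctrl.empty else ctrl.iloc[0]

    @property
    def treatment_levels(self) -> pd.DataFrame:
        return self.levels[~self.levels["is_control"]].reset_index(drop=True)

    def response_probabilities(self) -> pd.Series:
        return self.levels["k"] / self.levels["n"]


def build_response_table(
    trials: list[TrialRecord],
    experiment: str,
    per_individual: bool = False,
) -> ResponseTable:
    """Aggregate trials into responder counts per stimulus level.

    By default the unit is the trial (individual × repeat), matching
    responder denominators of 40 (20 animals × 2) and 38 (19 × 2).  With
    ``per_individual=True`` an individual counts as a responder at a
    level if it responded in at least one repeat.
    """
    rows = [t for t in trials if t.experiment == experiment]
    seen: set[tuple] = set()
    for t in rows:
        if t.key in seen:
            raise ValidationError(f"duplicate trial key {t.key}")
        seen.add(t.key)
    if not rows:
        return ResponseTable(
            experiment,
            pd.DataFrame(columns=["level", "k", "n", "is_control"]).astype(
                {"level": float, "k": int, "n": int, "is_control": bool}
            ),
        )
    df = pd.DataFrame(
        {
            "level": [t.level for t in rows],
            "is_control": [t.is_control for t in rows],
            "individual_id": [t.individual_id for t in rows],
            "response": [is_response(t) for t in rows],
        }
    )
    if per_individual:
        df = (
            df.groupby(["level", "is_control", "individual_id"], as_index=False)["response"]
            .max()
        )
    agg = (
        df.groupby(["level", "is_control"], as_index=False)
        .agg(k=("response", "sum"), n=("response", "size"))
        .sort_values(["is_control", "level"], ascending=[False, True])
        .reset_index(drop=True)
    )
    agg = agg[["level", "k", "n", "is_control"]]
    return ResponseTable(experiment, agg)


def transitions_by_angle(
    trials: list[TrialRecord],
    profile: ExpansionProfile,
    angle_threshold_deg: float,
    category: Behavior | None = None,
) -> float:
    """Fraction of transition events occurring after the stimulus exceeded
    ``angle_threshold_deg`` of the visual field.

    Event times are mapped to angular sizes through the expansion
    profile.  Optionally restricted to one ethogram category.  Returns 0
    with a warning when no events qualify for the denominator.
    """
    cutoff = profile.time_to_reach(angle_threshold_deg) if angle_threshold_deg > 0 else 0.0
    times = [
        e.time_s
        for t in trials
        for e in t.events
        if category is None or e.category is Behavior(category)
    ]
    if not times:
        warnings.warn("no transition events; fraction defined as 0", stacklevel=2)
        return 0.0
    return sum(tt > cutoff for tt in times) / len(times)


def reemergence_summary(trials: list[TrialRecord], aggregator: str = "median") -> pd.DataFrame:
    """Central tendency of re-emergence time per stimulus level.

    Missing re-emergence times (no withdrawal) are excluded; rows are
    ``level, reemergence_s, n_observed``.  The aggregator defaults to
    the median.
    """
    rows = [
        (t.level, t.reemergence_s)
        for t in trials
        if t.reemergence_s is not None and not t.is_control
    ]
    if not rows:
        return pd.DataFrame(columns=["level", "reemergence_s", "n_observed"])
    df = pd.DataFrame(rows, columns=["level", "reemergence_s"])
    return (
        df.groupby("level", as_index=False)
        .agg(reemergence_s=("reemergence_s", aggregator), n_observed=("reemergence_s", "size"))
        .sort_values("level")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SENTINEL = "none"  # event_category value for eventless trials

TRIALS_COLUMNS = [
    "individual_id",
    "experiment",
    "stimulus_id",
    "repeat_index",
    "level",
    "is_control",
    "event_category",
    "event_time_s",
    "reemergence_s",
]


def write_trials_csv(trials: list[TrialRecord], path: str | Path) -> Path:
    """Write trials as tidy CSV, one row per event (sentinel row when a
    trial has no events)."""
    records = []
    for t in trials:
        base = dict(
            individual_id=t.individual_id,
            experiment=t.experiment,
            stimulus_id=t.stimulus_id,
            repeat_index=t.repeat_index,
            level=t.level,
            is_control=t.is_control,
            reemergence_s=t.reemergence_s if t.reemergence_s is not None else np.nan,
        )
        if t.events:
            for e in t.events:
                records.append({**base, "event_category": e.category.value, "event_time_s": e.time_s})
        else:
            records.append({**base, "event_category": _SENTINEL, "event_time_s": np.nan})
    path = Path(path)
    pd.DataFrame(records, columns=TRIALS_COLUMNS).to_csv(path, index=False)
    return path


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    """Read back a trials CSV written by :func:`write_trials_csv`."""
    df = pd.read_csv(path)
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"trials CSV missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError("trials CSV contains no rows")
    trials: list[TrialRecord] = []
    keys = ["individual_id", "stimulus_id", "repeat_index"]
    for (ind, stim, rep), grp in df.groupby(keys, sort=False):
        first = grp.iloc[0]
        events = [
            TransitionEvent(Behavior(r.event_category), float(r.event_time_s))
            for r in grp.itertuples()
            if r.event_category != _SENTINEL
        ]
        events.sort(key=lambda e: e.time_s)
        reem = first["reemergence_s"]
        trials.append(
            TrialRecord(
                individual_id=str(ind),
                experiment=str(first["experiment"]),
                stimulus_id=str(stim),
                repeat_index=int(rep),
                level=float(first["level"]),
                is_control=bool(first["is_control"]),
                events=events,
                reemergence_s=None if pd.isna(reem) else float(reem),
            )
        )
    return trials
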