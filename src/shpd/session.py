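"""Domain model for T-maze recording sessions.

A testing session is a sequence of delayed-alternation trials on a T-maze.
Six scored behavioral events per trial (start-box placement, gate removal,
branch point, arm choice, reward, pickup) delimit six task intervals:
Delay, Run, Branch, Choice, Reward, Pickup.  Two composite intervals are
used by the interaction models: ExtendedDelay = Pickup ∪ Delay and
Response = Run ∪ Branch ∪ Choice.

All times are seconds on a single session clock; intervals are half-open
``[start, end)`` so every instant belongs to exactly one interval.  Each
trial's Pickup interval ends at the next trial's start-box time (for the
last trial, a configurable tail), which makes the intervals of a session
tile the timeline with no gaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASELINE",
    "STRESS",
    "INTERVAL_LABELS",
    "COMPOSITE_MEMBERS",
    "TrialEvents",
    "LabeledInterval",
    "SpikeTrain",
    "UnitWaveform",
    "Session",
    "SessionParseError",
    "derive_intervals",
    "session_intervals",
    "correct_trials",
    "classify_unit",
    "composite_windows",
    "composite_mask",
    "read_session",
    "write_session",
]

BASELINE = "baseline"
STRESS = "stress"
CONDITIONS = (BASELINE, STRESS)

#: the six elementary task intervals, in within-trial order
INTERVAL_LABELS = ("Delay", "Run", "Branch", "Choice", "Reward", "Pickup")

#: composite labels used by the interaction models
COMPOSITE_MEMBERS = {
    "ExtendedDelay": ("Pickup", "Delay"),
    "Response": ("Run", "Branch", "Choice"),
}

ARMS = ("left", "right")


class SessionParseError(ValueError):
    """Raised when a session file violates the format or an invariant."""

    def __init__(self, file: str, row: object, message: str):
        self.file = file
        self.row = row
        super().__init__(f"{file} (row {row}): {message}")


@dataclass(frozen=True)
class TrialEvents:
    """Scored event times of one trial.

    ``t_reward`` is ``None`` on incorrect trials (no reward is given).
    """

    trial_index: int
    condition: str
    arm: str
    correct: bool
    t_startbox: float
    t_gate: float
    t_branch: float
    t_choice: float
    t_pickup: float
    t_reward: Optional[float] = None

    def validate(self) -> None:
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        seq = [self.t_startbox, self.t_gate, self.t_branch, self.t_choice]
        if self.correct:
            if self.t_reward is None:
                raise ValueError(
                    f"trial {self.trial_index}: correct trial lacks t_reward"
                )
            seq.append(self.t_reward)
        elif self.t_reward is not None:
            raise ValueError(
                f"trial {self.trial_index}: incorrect trial must not have t_reward"
            )
        seq.append(self.t_pickup)
        diffs = np.diff(seq)
        if not np.all(diffs > 0):
            raise ValueError(
                f"trial {self.trial_index}: event times must strictly increase "
                f"(startbox < gate < branch < choice [< reward] < pickup), got {seq}"
            )


@dataclass(frozen=True)
class LabeledInterval:
    """One elementary task interval, half-open [start, end)."""

    label: str
    start: float
    end: float
    trial_index: int

    def __post_init__(self):
        if self.label not in INTERVAL_LABELS:
            raise ValueError(f"not an elementary interval label: {self.label!r}")
        if not self.start < self.end:
            raise ValueError(
                f"interval {self.label} of trial {self.trial_index}: "
                f"start {self.start} must precede end {self.end}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit within one session."""

    unit_id: str
    times: np.ndarray
    session_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"unit {self.unit_id}: spike times must strictly increase")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class UnitWaveform:
    """Extracellular waveform summary; pp_duration is peak-to-peak width in µs."""

    unit_id: str
    pp_duration_us: float
    samples: Optional[np.ndarray] = None
    sample_interval_us: Optional[float] = None


@dataclass
class Session:
    """One recording session: behavioral timeline plus spike trains."""

    session_id: str
    condition: str
    noise_db: float
    delay_length_s: float
    trials: list[TrialEvents]
    spikes: list[SpikeTrain] = field(default_factory=list)
    waveforms: dict[str, UnitWaveform] = field(default_factory=dict)
    pickup_tail_s: float = 5.0

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.trials:
            raise ValueError("session has no trials")
        prev_end = -np.inf
        for tr in self.trials:
            tr.validate()
            if tr.condition != self.condition:
                raise ValueError(
                    f"trial {tr.trial_index} condition {tr.condition!r} "
                    f"differs from session condition {self.condition!r}"
                )
            if not tr.t_startbox > prev_end:
                raise ValueError(
                    f"trial {tr.trial_index} starts at {tr.t_startbox} before the "
                    f"previous trial's pickup at {prev_end}"
                )
            prev_end = tr.t_pickup
        lo, hi = self.span
        for st in self.spikes:
            if st.n_spikes and (st.times[0] < lo or st.times[-1] > hi):
                raise ValueError(
                    f"unit {st.unit_id}: spike times fall outside the session span "
                    f"[{lo}, {hi}]"
                )

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the session timeline covered by task intervals."""
        return (self.trials[0].t_startbox, self.trials[-1].t_pickup + self.pickup_tail_s)

    def spike_train(self, unit_id: str) -> SpikeTrain:
        for st in self.spikes:
            if st.unit_id == unit_id:
                return st
        raise KeyError(f"no unit {unit_id!r} in session {self.session_id!r}")


def derive_intervals(trial: TrialEvents, pickup_end: float) -> list[LabeledInterval]:
    """Map one trial's events to its labeled intervals.

    Correct trials yield all six intervals; incorrect trials have no Reward
    and their Choice interval runs to ``t_pickup``.  ``pickup_end`` closes
    the Pickup interval (next trial's start box, or the session tail).
    """
    trial.validate()
    i = trial.trial_index
    out = [
        LabeledInterval("Delay", trial.t_startbox, trial.t_gate, i),
        LabeledInterval("Run", trial.t_gate, trial.t_branch, i),
        LabeledInterval("Branch", trial.t_branch, trial.t_choice, i),
    ]
    if trial.correct:
        out.append(LabeledInterval("Choice", trial.t_choice, trial.t_reward, i))
        out.append(LabeledInterval("Reward", trial.t_reward, trial.t_pickup, i))
    else:
        out.append(LabeledInterval("Choice", trial.t_choice, trial.t_pickup, i))
    out.append(LabeledInterval("Pickup", trial.t_pickup, pickup_end, i))
    return out


def session_intervals(session: Session) -> list[LabeledInterval]:
    """Intervals of every trial; they tile the session span contiguously."""
    out: list[LabeledInterval] = []
    trials = session.trials
    for j, tr in enumerate(trials):
        if j + 1 < len(trials):
            pickup_end = trials[j + 1].t_startbox
        else:
            pickup_end = tr.t_pickup + session.pickup_tail_s
        out.extend(derive_intervals(tr, pickup_end))
    return out


def correct_trials(session: Session) -> Session:
    """Restrict a session to analyzed trials.

    The first trial of every session is always rewarded and is excluded
    from analysis; incorrect trials are likewise dropped.
    """
    kept = [tr for tr in session.trials if tr.trial_index != 1 and tr.correct]
    return replace(session, trials=kept)


def classify_unit(w: UnitWaveform) -> str:
    """Waveform-width classification: WS (>200 µs), NS (100–200 µs), rejected.

    Only wide-spike (putative pyramidal) units enter the CI-GLM analyses.
    """
    pp = w.pp_duration_us
    if not pp > 0:
        raise ValueError(f"unit {w.unit_id}: nonpositive P-P duration {pp}")
    if pp > 200.0:
        return "WS"
    if pp >= 100.0:
        return "NS"
    return "rejected"


def composite_windows(
    intervals: Sequence[LabeledInterval], label: str
) -> list[tuple[float, float]]:
    """Half-open windows forming the union of a composite label's members."""
    if label not in COMPOSITE_MEMBERS:
        raise ValueError(
            f"{label!r} is not a composite label; expected one of "
            f"{sorted(COMPOSITE_MEMBERS)}"
        )
    members = COMPOSITE_MEMBERS[label]
    return [(iv.start, iv.end) for iv in intervals if iv.label in members]


def composite_mask(
    intervals: Sequence[LabeledInterval], label: str, times: np.ndarray
) -> np.ndarray:
    """Indicator of a composite interval evaluated at ``times``."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for lo, hi in composite_windows(intervals, label):
        mask |= (times >= lo) & (times < hi)
    return mask


# ---------------------------------------------------------------------------
# file I/O
#
# spikes.csv:    unit_id, time_s             (ascending per unit)
# trials.csv:    trial_index, condition, arm, correct, t_startbox, t_gate,
#                t_branch, t_choice, t_reward (blank on incorrect), t_pickup
# session.json:  session_id, condition, noise_db, delay_length_s, pickup_tail_s
# waveforms.csv: unit_id, pp_duration_us     (optional)
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_index", "condition", "arm", "correct",
    "t_startbox", "t_gate", "t_branch", "t_choice", "t_reward", "t_pickup",
]


def read_session(
    spike_table: str | Path,
    trial_table: str | Path,
    meta: str | Path,
    waveform_table: str | Path | None = None,
) -> Session:
    """Load a session from its plain-text tables; validates all invariants."""
    meta = Path(meta)
    with open(meta) as fh:
        m = json.load(fh)
    for key in ("session_id", "condition", "noise_db", "delay_length_s"):
        if key not in m:
            raise SessionParseError(str(meta), "-", f"missing key {key!r}")

    tdf = pd.read_csv(trial_table)
    missing = [c for c in _TRIAL_COLUMNS if c not in tdf.columns]
    if missing:
        raise SessionParseError(str(trial_table), "-", f"missing columns {missing}")
    trials = []
    for idx, row in tdf.iterrows():
        correct = bool(row["correct"])
        t_reward = None if pd.isna(row["t_reward"]) else float(row["t_reward"])
        tr = TrialEvents(
            trial_index=int(row["trial_index"]),
            condition=str(row["condition"]),
            arm=str(row["arm"]),
            correct=correct,
            t_startbox=float(row["t_startbox"]),
            t_gate=float(row["t_gate"]),
            t_branch=float(row["t_branch"]),
            t_choice=float(row["t_choice"]),
            t_pickup=float(row["t_pickup"]),
            t_reward=t_reward,
        )
        try:
            tr.validate()
        except ValueError as exc:
            raise SessionParseError(str(trial_table), int(idx) + 2, str(exc)) from exc
        trials.append(tr)

    sdf = pd.read_csv(spike_table)
    for col in ("unit_id", "time_s"):
        if col not in sdf.columns:
            raise SessionParseError(str(spike_table), "-", f"missing column {col!r}")
    spikes = []
    for unit_id, grp in sdf.groupby("unit_id", sort=True):
        try:
            spikes.append(
                SpikeTrain(
                    unit_id=str(unit_id),
                    times=grp["time_s"].to_numpy(dtype=float),
                    session_id=str(m["session_id"]),
                )
            )
        except ValueError as exc:
            raise SessionParseError(str(spike_table), str(unit_id), str(exc)) from exc

    waveforms: dict[str, UnitWaveform] = {}
    if waveform_table is not None and Path(waveform_table).exists():
        wdf = pd.read_csv(waveform_table)
        for idx, row in wdf.iterrows():
            waveforms[str(row["unit_id"])] = UnitWaveform(
                unit_id=str(row["unit_id"]),
                pp_duration_us=float(row["pp_duration_us"]),
            )

    sess = Session(
        session_id=str(m["session_id"]),
        condition=str(m["condition"]),
        noise_db=float(m["noise_db"]),
        delay_length_s=float(m["delay_length_s"]),
        trials=trials,
        spikes=spikes,
        waveforms=waveforms,
        pickup_tail_s=float(m.get("pickup_tail_s", 5.0)),
    )
    try:
        sess.validate()
    except ValueError as exc:
        raise SessionParseError(str(trial_table), "-", str(exc)) from exc
    return sess


def read_session_dir(directory: str | Path) -> Session:
    """Load a session from a directory written by :func:`write_session`."""
    d = Path(directory)
    wf = d / "waveforms.csv"
    return read_session(
        d / "spikes.csv", d / "trials.csv", d / "session.json",
        wf if wf.exists() else None,
    )


def write_session(session: Session, directory: str | Path) -> None:
    """Write a session as spikes.csv / trials.csv / session.json (+waveforms)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in session.trials:
        rows.append({
            "trial_index": tr.trial_index,
            "condition": tr.condition,
            "arm": tr.arm,
            "correct": tr.correct,
            "t_startbox": tr.t_startbox,
            "t_gate": tr.t_gate,
            "t_branch": tr.t_branch,
            "t_choice": tr.t_choice,
            "t_reward": "" if tr.t_reward is None else tr.t_reward,
            "t_pickup": tr.t_pickup,
        })
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(d / "trials.csv", index=False)

    srows = []
    for st in session.spikes:
        for t in st.times:
            srows.append({"unit_id": st.unit_id, "time_s": t})
    pd.DataFrame(srows, columns=["unit_id", "time_s"]).to_csv(
        d / "spikes.csv", index=False
    )

    with open(d / "session.json", "w") as fh:
        json.dump(
            {
                "session_id": session.session_id,
                "condition": session.condition,
                "noise_db": session.noise_db,
                "delay_length_s": session.delay_length_s,
                "pickup_tail_s": session.pickup_tail_s,
            },
            fh,
            indent=2,
        )
        fh.write("\n")

    if session.waveforms:
        pd.DataFrame(
            [
                {"unit_id": w.unit_id, "pp_duration_us": w.pp_duration_us}
                for w in session.waveforms.values()
            ]
        ).to_csv(d / "waveforms.csv", index=False)
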