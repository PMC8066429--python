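"""Session data model and on-disk bundle format.

A *session* is one recording of a head-fixed probabilistic Pavlovian
conditioning experiment: spike timestamps for a set of simultaneously
recorded units, a trial table (cue type, outcome, event times), lick
timestamps, and free-form metadata.  All times are seconds on a common
session clock; milliseconds appear only on correlogram lag axes.

The bundle format is plain UTF-8 CSV plus one JSON metadata file::

    spikes.csv  unit_id, time_s
    trials.csv  trial_id, cue, outcome, t_cue_on_s, t_cue_off_s, t_reinforcement_s
    licks.csv   time_s
    units.csv   unit_id, dv_um
    meta.json   subject, contingencies, seed, generator parameters

``t_reinforcement_s`` is empty exactly for omission trials.  Timestamps
survive a write/read round trip to better than 1 microsecond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

CUES = ("likely_reward", "likely_punishment")
OUTCOMES = ("reward", "punishment", "omission")

#: Virtual reinforcement delay for omission trials: midpoint of the 400-600 ms
#: uniform reinforcement delay, measured from cue offset.
VIRTUAL_REINFORCEMENT_DELAY_S = 0.5

_TIME_FMT = "%.9f"

TRIAL_COLUMNS = [
    "trial_id",
    "cue",
    "outcome",
    "t_cue_on_s",
    "t_cue_off_s",
    "t_reinforcement_s",
]


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit.

    Parameters
    ----------
    unit_id : str
        Unique identifier within the session.
    times : ndarray
        Strictly increasing spike times in seconds, all >= 0.
    dv_position : float, optional
        Dorsoventral recording position in micrometers (larger = more
        ventral), when known.
    session_id : str
        Identifier of the parent session.
    """

    unit_id: str
    times: np.ndarray
    dv_position: float | None = None
    session_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def shifted(self, offset_s: float) -> "SpikeTrain":
        return SpikeTrain(self.unit_id, self.times + offset_s,
                          self.dv_position, self.session_id)

    def violations(self) -> list[str]:
        out = []
        if self.n_spikes and self.times[0] < 0:
            out.append(f"unit {self.unit_id}: negative spike time")
        if self.n_spikes > 1 and not np.all(np.diff(self.times) > 0):
            out.append(f"unit {self.unit_id}: spike times not strictly increasing")
        return out


@dataclass
class LickTrain:
    """Sorted lick timestamps (seconds) of the animal in one session."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_licks(self) -> int:
        return len(self.times)

    def violations(self) -> list[str]:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            return ["licks: times not strictly increasing"]
        return []


class TrialTable:
    """Per-trial cue, outcome and event times of a Pavlovian session.

    Thin wrapper around a pandas DataFrame with columns ``trial_id``, ``cue``,
    ``outcome``, ``t_cue_on_s``, ``t_cue_off_s`` and ``t_reinforcement_s``
    (NaN for omission trials).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        for col in TRIAL_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"trial table missing column {col!r}")
        self.df = df[TRIAL_COLUMNS].copy()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.df.equals(other.df)

    def shifted(self, offset_s: float) -> "TrialTable":
        df = self.df.copy()
        for col in ("t_cue_on_s", "t_cue_off_s", "t_reinforcement_s"):
            df[col] = df[col] + offset_s
        return TrialTable(df)

    def virtual_reinforcement_times(self) -> np.ndarray:
        """Reinforcement time for every trial, substituting
        ``t_cue_off + 0.5 s`` on omission trials (used only by
        omission-response and anticipatory-window analyses)."""
        t = self.df["t_reinforcement_s"].to_numpy(dtype=float).copy()
        miss = np.isnan(t)
        t[miss] = (self.df["t_cue_off_s"].to_numpy(dtype=float)[miss]
                   + VIRTUAL_REINFORCEMENT_DELAY_S)
        return t

    def events(self, label: str) -> np.ndarray:
        """Event timestamps for a named alignment event.

        Labels: ``cue`` (all cue onsets), ``cue_reward`` / ``cue_punish``
        (onsets of the likely-reward / likely-punishment cue), ``reward`` /
        ``punishment`` (reinforcement times of the respective outcomes),
        ``omission_virtual`` (cue offset + 0.5 s on omission trials).
        """
        df = self.df
        if label == "cue":
            return df["t_cue_on_s"].to_numpy(dtype=float)
        if label == "cue_reward":
            return df.loc[df["cue"] == "likely_reward", "t_cue_on_s"].to_numpy(dtype=float)
        if label == "cue_punish":
            return df.loc[df["cue"] == "likely_punishment", "t_cue_on_s"].to_numpy(dtype=float)
        if label in ("reward", "punishment"):
            sel = df["outcome"] == label
            return df.loc[sel, "t_reinforcement_s"].to_numpy(dtype=float)
        if label == "omission_virtual":
            sel = df["outcome"] == "omission"
            return (df.loc[sel, "t_cue_off_s"].to_numpy(dtype=float)
                    + VIRTUAL_REINFORCEMENT_DELAY_S)
        raise KeyError(f"unknown event label {label!r}")

    def violations(self, check_delay_bounds: bool = False) -> list[str]:
        out = []
        df = self.df
        if df["trial_id"].duplicated().any():
            out.append("trials: duplicate trial_id")
        for i, row in df.iterrows():
            tid = row["trial_id"]
            if row["cue"] not in CUES:
                out.append(f"trial {tid}: unknown cue {row['cue']!r}")
            if row["outcome"] not in OUTCOMES:
                out.append(f"trial {tid}: unknown outcome {row['outcome']!r}")
            if not row["t_cue_on_s"] < row["t_cue_off_s"]:
                out.append(f"trial {tid}: t_cue_on >= t_cue_off")
            has_r = not np.isnan(row["t_reinforcement_s"])
            if row["outcome"] == "omission" and has_r:
                out.append(f"trial {tid}: omission trial has reinforcement time")
            if row["outcome"] != "omission" and not has_r:
                out.append(f"trial {tid}: {row['outcome']} trial missing reinforcement time")
            if has_r and row["outcome"] != "omission":
                if not row["t_cue_off_s"] < row["t_reinforcement_s"]:
                    out.append(f"trial {tid}: reinforcement precedes cue offset")
                elif check_delay_bounds:
                    delay = row["t_reinforcement_s"] - row["t_cue_off_s"]
                    if not (0.4 - 1e-9 <= delay <= 0.6 + 1e-9):
                        out.append(
                            f"trial {tid}: reinforcement delay {delay:.3f}s outside [0.4, 0.6]")
        # trials time-ordered and non-overlapping, pairwise
        ends = np.fmax(df["t_cue_off_s"].to_numpy(dtype=float),
                       np.nan_to_num(df["t_reinforcement_s"].to_numpy(dtype=float), nan=-np.inf))
        starts = df["t_cue_on_s"].to_numpy(dtype=float)
        for i in range(len(df)):
            for j in range(i + 1, len(df)):
                if starts[j] < ends[i] and starts[i] < ends[j]:
                    out.append(
                        f"trials {df['trial_id'].iloc[i]} and {df['trial_id'].iloc[j]} overlap")
        if len(df) > 1 and not np.all(np.diff(starts) > 0):
            out.append("trials: not time-ordered")
        return out


@dataclass
class Session:
    """One recording session: spike trains, trials, licks, metadata."""

    spike_trains: list[SpikeTrain]
    trials: TrialTable
    licks: LickTrain
    meta: dict = field(default_factory=dict)

    @property
    def unit_ids(self) -> list[str]:
        return [st.unit_id for st in self.spike_trains]

    def unit(self, unit_id: str) -> SpikeTrain:
        for st in self.spike_trains:
            if st.unit_id == unit_id:
                return st
        raise KeyError(f"no unit {unit_id!r} in session")

    @property
    def is_synthetic(self) -> bool:
        return bool(self.meta.get("synthetic"))


def validate_session(session: Session) -> list[str]:
    """Return a list of invariant violations (empty when the session is valid).

    Violations are data, not exceptions: each entry names the offending
    entity and the rule it breaks.  Simulator-produced sessions additionally
    have their reinforcement delays checked against the 400-600 ms bounds.
    """
    out: list[str] = []
    seen = set()
    for st in session.spike_trains:
        if st.unit_id in seen:
            out.append(f"unit {st.unit_id}: duplicate unit_id")
        seen.add(st.unit_id)
        out.extend(st.violations())
    out.extend(session.trials.violations(check_delay_bounds=session.is_synthetic))
    out.extend(session.licks.violations())
    return out


def write_session_bundle(session: Session, path) -> None:
    """Write a session to ``path`` as a plain-text bundle (see module docs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for st in session.spike_trains:
        rows.append(pd.DataFrame({"unit_id": st.unit_id, "time_s": st.times}))
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["unit_id", "time_s"]))
    spikes.to_csv(path / "spikes.csv", index=False, float_format=_TIME_FMT)

    session.trials.df.to_csv(path / "trials.csv", index=False, float_format=_TIME_FMT)
    pd.DataFrame({"time_s": session.licks.times}).to_csv(
        path / "licks.csv", index=False, float_format=_TIME_FMT)
    pd.DataFrame({
        "unit_id": [st.unit_id for st in session.spike_trains],
        "dv_um": [st.dv_position for st in session.spike_trains],
    }).to_csv(path / "units.csv", index=False, float_format="%.3f")
    with open(path / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(session.meta, fh, indent=1, sort_keys=True)


def read_session_bundle(path) -> Session:
    """Read and validate a session bundle from a directory.

    Raises
    ------
    FormatError
        If a required file is missing or malformed.
    ValidationError
        If the data violate a session invariant (e.g. unsorted spike times).
    """
    path = Path(path)
    for name in ("spikes.csv", "trials.csv", "licks.csv", "units.csv", "meta.json"):
        if not (path / name).is_file():
            raise FormatError(f"bundle at {path} is missing {name}")
    try:
        spikes = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str})
        trials_df = pd.read_csv(path / "trials.csv", dtype={"cue": str, "outcome": str})
        licks = pd.read_csv(path / "licks.csv")
        units = pd.read_csv(path / "units.csv", dtype={"unit_id": str})
        with open(path / "meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
    except (ValueError, json.JSONDecodeError) as err:
        raise FormatError(f"malformed bundle at {path}: {err}") from err

    session_id = str(meta.get("subject", ""))
    dv = dict(zip(units["unit_id"], units["dv_um"])) if len(units) else {}
    trains = []
    for unit_id in units["unit_id"]:
        t = spikes.loc[spikes["unit_id"] == unit_id, "time_s"].to_numpy(dtype=float)
        pos = dv.get(unit_id)
        trains.append(SpikeTrain(
            unit_id=str(unit_id), times=t,
            dv_position=None if pos is None or pd.isna(pos) else float(pos),
            session_id=session_id))
    stray = set(spikes["unit_id"]) - set(units["unit_id"])
    if stray:
        raise FormatError(f"spikes.csv references units missing from units.csv: {sorted(stray)}")

    session = Session(
        spike_trains=trains,
        trials=TrialTable(trials_df),
        licks=LickTrain(licks["time_s"].to_numpy(dtype=float) if len(licks) else np.empty(0)),
        meta=meta,
    )
    violations = validate_session(session)
    if violations:
        raise ValidationError(violations)
    return session


def sessions_equal(a: Session, b: Session, tol_s: float = 1e-6) -> bool:
    """Field-by-field equality of two sessions with a timestamp tolerance."""
    if a.unit_ids != b.unit_ids:
        return False
    for sa, sb in zip(a.spike_trains, b.spike_trains):
        if sa.n_spikes != sb.n_spikes:
            return False
        if sa.n_spikes and np.max(np.abs(sa.times - sb.times)) > tol_s:
            return False
        da, db = sa.dv_position, sb.dv_position
        if (da is None) != (db is None) or (da is not None and abs(da - db) > 1e-3):
            return False
    if len(a.trials) != len(b.trials):
        return False
    ta, tb = a.trials.df, b.trials.df
    if not (ta["cue"].equals(tb["cue"]) and ta["outcome"].equals(tb["outcome"])):
        return False
    for col in ("t_cue_on_s", "t_cue_off_s", "t_reinforcement_s"):
        xa, xb = ta[col].to_numpy(dtype=float), tb[col].to_numpy(dtype=float)
        both = ~(np.isnan(xa) | np.isnan(xb))
        if not np.array_equal(np.isnan(xa), np.isnan(xb)):
            return False
        if both.any() and np.max(np.abs(xa[both] - xb[both])) > tol_s:
            return False
    if a.licks.n_licks != b.licks.n_licks:
        return False
    if a.licks.n_licks and np.max(np.abs(a.licks.times - b.licks.times)) > tol_s:
        return False
    return a.meta == b.meta
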