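"""Session data model and bundle I/O.

A *session* is one recording day: a trials table, a long-format spike-event
table, and a map from units to electrode positions on the 10x10 multielectrode
array.  Bundles live on disk as three delimited text files plus a JSON
manifest, so they are language-agnostic and diffable.

All event times are in seconds on a per-trial clock zeroed at fixation
acquisition.  Every analysis window is half-open ``[start, end)`` so that
adjacent windows never double-count a spike.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

ALIGNMENT_EVENTS = ("stimulus_onset", "color_onset", "color_offset")
LOCATIONS = ("ipsi", "contra")
DIRECTIONS = ("up", "down")
OUTCOMES = ("hit", "miss", "false_alarm", "fixation_break")

#: outcomes included in analyses unless stated otherwise
DEFAULT_OUTCOMES = frozenset({"hit"})

TRIAL_COLUMNS = [
    "trial_id",
    "target_location",
    "motion_direction",
    "outcome",
    "stimulus_onset_s",
    "color_onset_s",
    "color_offset_s",
    "change_time_s",
    "response_time_s",
]
SPIKE_COLUMNS = ["unit_id", "trial_id", "spike_time_s"]
UNIT_COLUMNS = ["unit_id", "electrode_row", "electrode_col", "wired"]


class IntegrityError(ValueError):
    """Referential or schema violation in a session bundle."""


@dataclass(frozen=True)
class EpochWindow:
    """Half-open analysis window ``[start_s, end_s)`` relative to a trial event.

    Parameters
    ----------
    alignment_event
        One of ``stimulus_onset``, ``color_onset``, ``color_offset``.
    start_s, end_s
        Window edges in seconds relative to the alignment event.
    """

    alignment_event: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.alignment_event not in ALIGNMENT_EVENTS:
            raise ValueError(f"unknown alignment event {self.alignment_event!r}")
        if not self.end_s > self.start_s:
            raise ValueError("end_s must be greater than start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# The three canonical windows of the task: a sustained-attention (postcue)
# window starting 150 ms after the color cue is removed, a 500-ms window during
# the cue, and a 700-ms baseline centered on stimulus onset.
POSTCUE_WINDOW = EpochWindow("color_offset", 0.150, 0.650)
CUE_WINDOW = EpochWindow("color_onset", 0.0, 0.500)
BASELINE_WINDOW = EpochWindow("stimulus_onset", -0.350, 0.350)


@dataclass
class Session:
    """One recording session: trials, spike events and the array map."""

    session_id: str
    trials: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame

    def __post_init__(self) -> None:
        self.trials = self.trials.reset_index(drop=True)
        self.spikes = self.spikes.reset_index(drop=True)
        self.units = self.units.reset_index(drop=True)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "Session":
        """Check schema and referential integrity; raise IntegrityError."""
        for name, frame, cols in (
            ("trials", self.trials, TRIAL_COLUMNS),
            ("spikes", self.spikes, SPIKE_COLUMNS),
            ("units", self.units, UNIT_COLUMNS),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise IntegrityError(f"{name} table missing columns {missing}")

        if self.trials["trial_id"].duplicated().any():
            dup = self.trials.loc[self.trials["trial_id"].duplicated(), "trial_id"]
            raise IntegrityError(f"duplicate trial_id values: {sorted(dup.unique())}")
        if self.units["unit_id"].duplicated().any():
            dup = self.units.loc[self.units["unit_id"].duplicated(), "unit_id"]
            raise IntegrityError(f"duplicate unit_id values: {sorted(dup.unique())}")

        bad_outcome = ~self.trials["outcome"].isin(OUTCOMES)
        if bad_outcome.any():
            row = int(np.flatnonzero(bad_outcome.to_numpy())[0])
            raise IntegrityError(f"trials row {row}: unknown outcome "
                                 f"{self.trials['outcome'].iloc[row]!r}")

        order_ok = (
            (self.trials["stimulus_onset_s"] < self.trials["color_onset_s"])
            & (self.trials["color_onset_s"] < self.trials["color_offset_s"])
        )
        if not order_ok.all():
            row = int(np.flatnonzero(~order_ok.to_numpy())[0])
            raise IntegrityError(f"trials row {row}: event times out of order")

        rows = self.units["electrode_row"].to_numpy()
        cols = self.units["electrode_col"].to_numpy()
        if ((rows < 0) | (rows > 9) | (cols < 0) | (cols > 9)).any():
            raise IntegrityError("electrode position outside the 10x10 grid")

        trial_ids = set(self.trials["trial_id"])
        unit_ids = set(self.units["unit_id"])
        if len(self.spikes):
            bad_trial = ~self.spikes["trial_id"].isin(trial_ids)
            if bad_trial.any():
                row = int(np.flatnonzero(bad_trial.to_numpy())[0])
                raise IntegrityError(
                    f"spikes row {row}: trial_id "
                    f"{self.spikes['trial_id'].iloc[row]} not in trials table")
            bad_unit = ~self.spikes["unit_id"].isin(unit_ids)
            if bad_unit.any():
                row = int(np.flatnonzero(bad_unit.to_numpy())[0])
                raise IntegrityError(
                    f"spikes row {row}: unit_id "
                    f"{self.spikes['unit_id'].iloc[row]} not in units table")
        return self

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return self.session_id == other.session_id and sessions_equal(self, other)


def _frames_close(a: pd.DataFrame, b: pd.DataFrame, atol: float) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if pd.api.types.is_float_dtype(x) or pd.api.types.is_float_dtype(y):
            xv = x.to_numpy(dtype=float)
            yv = y.to_numpy(dtype=float)
            both_nan = np.isnan(xv) & np.isnan(yv)
            if not np.all(both_nan | (np.abs(xv - yv) <= atol)):
                return False
        else:
            if not (x.to_numpy() == y.to_numpy()).all():
                return False
    return True


def sessions_equal(a: Session, b: Session, time_atol: float = 1e-6) -> bool:
    """True when two sessions agree (event/spike times to ``time_atol`` seconds)."""
    return (
        _frames_close(a.trials[TRIAL_COLUMNS], b.trials[TRIAL_COLUMNS], time_atol)
        and _frames_close(a.spikes[SPIKE_COLUMNS], b.spikes[SPIKE_COLUMNS], time_atol)
        and _frames_close(a.units[UNIT_COLUMNS], b.units[UNIT_COLUMNS], 0.0)
    )


@dataclass
class CountMatrix:
    """Trials x units spike counts in one epoch window, with aligned labels.

    ``labels`` is a DataFrame (one row per kept trial) carrying
    ``target_location``, ``motion_direction`` and ``outcome``.
    """

    counts: np.ndarray
    window: EpochWindow
    trial_ids: np.ndarray
    unit_ids: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.trial_ids = np.asarray(self.trial_ids)
        self.unit_ids = np.asarray(self.unit_ids)
        if self.counts.shape != (len(self.trial_ids), len(self.unit_ids)):
            raise ValueError("counts shape inconsistent with id lists")
        if len(self.labels) != len(self.trial_ids):
            raise ValueError("labels misaligned with trial_ids")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def rates(self) -> np.ndarray:
        """Counts normalized by the window duration (spikes/s)."""
        return self.counts / self.window.duration_s

    def binary_labels(self, feature: str) -> np.ndarray:
        """Binary label vector for ``target_location`` or ``motion_direction``."""
        if feature not in ("target_location", "motion_direction"):
            raise ValueError(f"not a decodable feature: {feature!r}")
        return self.labels[feature].to_numpy()

    def condition_labels(self) -> np.ndarray:
        """4-level condition label (location x direction) per trial."""
        return (self.labels["target_location"].astype(str)
                + "|" + self.labels["motion_direction"].astype(str)).to_numpy()

    def restrict_units(self, unit_ids: Sequence) -> "CountMatrix":
        """New CountMatrix keeping ``unit_ids`` in the given order."""
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        idx = np.array([pos[u] for u in unit_ids], dtype=int)
        return CountMatrix(self.counts[:, idx], self.window, self.trial_ids,
                           np.asarray(list(unit_ids)), self.labels.copy())

    def restrict_trials(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.counts[mask], self.window, self.trial_ids[mask],
                           self.unit_ids, self.labels.loc[mask].copy())


def extract_counts(session: Session, window: EpochWindow,
                   include_outcomes: Iterable[str] = DEFAULT_OUTCOMES) -> CountMatrix:
    """Count spikes per (trial, unit) inside a half-open epoch window.

    Spike times are aligned to the window's alignment event per trial; a spike
    exactly at ``end_s`` is excluded.  Trials whose outcome is not in
    ``include_outcomes`` are dropped, as are trials whose alignment event time
    is missing (logged as a warning).
    """
    include_outcomes = set(include_outcomes)
    unknown = include_outcomes - set(OUTCOMES)
    if unknown:
        raise ValueError(f"unknown outcomes {sorted(unknown)}")

    trials = session.trials
    keep = trials["outcome"].isin(include_outcomes).to_numpy()
    event = trials[window.alignment_event + "_s"].to_numpy(dtype=float)
    unresolved = keep & ~np.isfinite(event)
    if unresolved.any():
        logger.warning("extract_counts: dropping %d trial(s) with missing %s",
                       int(unresolved.sum()), window.alignment_event)
        keep &= np.isfinite(event)

    kept = trials.loc[keep]
    trial_ids = kept["trial_id"].to_numpy()
    unit_ids = session.units["unit_id"].to_numpy()
    t_index = {t: i for i, t in enumerate(trial_ids)}
    u_index = {u: i for i, u in enumerate(unit_ids)}

    counts = np.zeros((len(trial_ids), len(unit_ids)), dtype=np.int64)
    if len(session.spikes):
        sp = session.spikes
        trial_pos = sp["trial_id"].map(t_index)
        ok = trial_pos.notna().to_numpy()
        if ok.any():
            trial_pos = trial_pos.to_numpy()[ok].astype(int)
            unit_pos = sp["unit_id"].map(u_index).to_numpy()[ok].astype(int)
            t0 = event[keep][trial_pos]
            rel = sp["spike_time_s"].to_numpy()[ok] - t0
            in_win = (rel >= window.start_s) & (rel < window.end_s)
            np.add.at(counts, (trial_pos[in_win], unit_pos[in_win]), 1)

    labels = kept[["target_location", "motion_direction", "outcome"]].copy()
    return CountMatrix(counts, window, trial_ids, unit_ids, labels)


# -- bundle I/O -------------------------------------------------------------

_FILES = {"trials": "trials.csv", "spikes": "spikes.csv", "units": "array_map.csv"}


def write_session(session: Session, path: str | Path) -> None:
    """Write a session bundle (three CSV files + manifest.json) to ``path``."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials[TRIAL_COLUMNS].to_csv(path / _FILES["trials"], index=False,
                                         float_format="%.9f")
    session.spikes[SPIKE_COLUMNS].to_csv(path / _FILES["spikes"], index=False,
                                         float_format="%.9f")
    session.units[UNIT_COLUMNS].to_csv(path / _FILES["units"], index=False)
    manifest = {
        "session_id": session.session_id,
        "schema_version": SCHEMA_VERSION,
        "files": dict(_FILES),
        "n_trials": int(session.n_trials),
        "n_units": int(session.n_units),
        "columns": {"trials": TRIAL_COLUMNS, "spikes": SPIKE_COLUMNS,
                    "units": UNIT_COLUMNS},
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_session(path: str | Path) -> Session:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    for key, fname in _FILES.items():
        if not (path / fname).exists():
            raise FileNotFoundError(f"bundle file missing: {fname}")

    trials = pd.read_csv(path / _FILES["trials"],
                         dtype={"trial_id": np.int64, "target_location": str,
                                "motion_direction": str, "outcome": str})
    spikes = pd.read_csv(path / _FILES["spikes"],
                         dtype={"unit_id": np.int64, "trial_id": np.int64,
                                "spike_time_s": float})
    units = pd.read_csv(path / _FILES["units"],
                        dtype={"unit_id": np.int64, "electrode_row": np.int64,
                               "electrode_col": np.int64, "wired": bool})
    session = Session(str(manifest["session_id"]), trials, spikes, units)
    return session.validate()
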