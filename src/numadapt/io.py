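"""Domain containers and persistence.

The epoch store is a single HDF5 file:

    /epochs/data    float32, trials x channels x samples, microvolt
    /epochs/events  structured table (participant, block, trial, adaptation,
                    numerosity)
    /montage/labels, /montage/pos
    attrs: sfreq (Hz), t0_ms (epoch start relative to test onset)

Behavioral data is a plain CSV with columns participant, block, trial,
adaptation, true_numerosity, estimate.  All times are in milliseconds with
0 = test-sequence onset; sample windows are half-open [start, stop).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage

__all__ = [
    "EpochArray",
    "write_epochs",
    "read_epochs",
    "read_behavior",
    "write_behavior",
    "validate_behavior",
    "write_results",
    "read_results",
    "CONDITIONS",
    "NUMEROSITIES",
]

CONDITIONS = ("High", "Low")
NUMEROSITIES = (14, 16, 18, 20, 22)

_EVENT_COLUMNS = ["participant", "block", "trial", "adaptation", "numerosity"]

_BEHAVIOR_COLUMNS = [
    "participant", "block", "trial", "adaptation", "true_numerosity", "estimate",
]


@dataclass
class EpochArray:
    """Epoched multichannel EEG: trials x channels x samples, microvolt."""

    data: np.ndarray
    events: pd.DataFrame  # one row per trial
    montage: Montage
    sfreq: float = 500.0
    t0: float = -500.0  # epoch start, ms relative to test onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite samples")
        if self.data.shape[1] != len(self.montage):
            raise ValueError(
                f"channel axis ({self.data.shape[1]}) does not match montage "
                f"({len(self.montage)})"
            )
        self.events = self.events.reset_index(drop=True)
        missing = [c for c in _EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table missing columns: {missing}")
        if len(self.events) != self.data.shape[0]:
            raise ValueError("events rows do not match number of trials")
        bad_cond = set(self.events["adaptation"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown adaptation labels: {sorted(bad_cond)}")
        bad_num = set(self.events["numerosity"]) - set(NUMEROSITIES)
        if bad_num:
            raise ValueError(f"unknown numerosities: {sorted(bad_num)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to test onset."""
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def time_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Sample slice for the half-open window [start_ms, stop_ms)."""
        i0 = int(round((start_ms - self.t0) / 1000.0 * self.sfreq))
        i1 = int(round((stop_ms - self.t0) / 1000.0 * self.sfreq))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"window [{start_ms}, {stop_ms}) ms outside epoch "
                f"[{self.t0}, {self.t0 + self.n_samples * 1000.0 / self.sfreq}) ms"
            )
        return slice(i0, i1)

    def select(self, mask: np.ndarray) -> "EpochArray":
        """Trial subset; events follow in lockstep."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            events=self.events.loc[mask].reset_index(drop=True),
        )

    def copy_with(self, data: np.ndarray) -> "EpochArray":
        return replace(self, data=data)


def write_epochs(epochs: EpochArray, path: "str | Path") -> None:
    """Write the one-file HDF5 epoch store (float32 data)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("epochs")
        grp.create_dataset("data", data=epochs.data.astype(np.float32))
        ev = epochs.events
        dt = np.dtype(
            [
                ("participant", np.int32),
                ("block", np.int32),
                ("trial", np.int32),
                ("adaptation", "S8"),
                ("numerosity", np.int32),
            ]
        )
        table = np.zeros(len(ev), dtype=dt)
        table["participant"] = ev["participant"]
        table["block"] = ev["block"]
        table["trial"] = ev["trial"]
        table["adaptation"] = [c.encode() for c in ev["adaptation"]]
        table["numerosity"] = ev["numerosity"]
        grp.create_dataset("events", data=table)
        mg = f.create_group("montage")
        mg.create_dataset(
            "labels", data=np.array([l.encode() for l in epochs.montage.labels])
        )
        mg.create_dataset("pos", data=epochs.montage.positions)
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["t0_ms"] = float(epochs.t0)


def read_epochs(path: "str | Path") -> EpochArray:
    """Read the HDF5 epoch store; missing attributes are rejected by name."""
    with h5py.File(path, "r") as f:
        for attr in ("sfreq", "t0_ms"):
            if attr not in f.attrs:
                raise ValueError(f"epoch store {path} missing attribute {attr!r}")
        for ds in ("epochs/data", "epochs/events", "montage/labels", "montage/pos"):
            if ds not in f:
                raise ValueError(f"epoch store {path} missing dataset {ds!r}")
        data = f["epochs/data"][()]
        table = f["epochs/events"][()]
        labels = tuple(l.decode() for l in f["montage/labels"][()])
        pos = f["montage/pos"][()]
        sfreq = float(f.attrs["sfreq"])
        t0 = float(f.attrs["t0_ms"])
    events = pd.DataFrame(
        {
            "participant": table["participant"].astype(int),
            "block": table["block"].astype(int),
            "trial": table["trial"].astype(int),
            "adaptation": [c.decode() for c in table["adaptation"]],
            "numerosity": table["numerosity"].astype(int),
        }
    )
    return EpochArray(
        data=data, events=events, montage=Montage(labels, pos), sfreq=sfreq, t0=t0
    )


def validate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the six-column behavioral table; returns it untouched."""
    missing = [c for c in _BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavioral table missing columns: {missing}")
    bad = set(table["true_numerosity"]) - set(NUMEROSITIES)
    if bad:
        raise ValueError(f"true_numerosity outside {NUMEROSITIES}: {sorted(bad)}")
    if (table["estimate"] < 0).any():
        raise ValueError("negative estimates in behavioral table")
    return table


def write_behavior(table: pd.DataFrame, path: "str | Path") -> None:
    validate_behavior(table)
    table.to_csv(path, index=False, columns=_BEHAVIOR_COLUMNS, lineterminator="\n")


def read_behavior(path: "str | Path") -> pd.DataFrame:
    return validate_behavior(pd.read_csv(path))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_results(results: dict, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(_jsonify(results), indent=2, sort_keys=True) + "\n")


def read_results(path: "str | Path") -> dict:
    return json.loads(Path(path).read_text())
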