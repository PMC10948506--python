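"""Selective averaging: event-related potentials and condition averages.

ERPs are extracted over a deliberately short window (-100 to 200 ms,
baseline -100 to 0) restricted to numerosities 14-20: at numerosity 22 the
second flash of the test sequence arrives (~180 ms) before the window ends,
so it is excluded from the ERP average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochArray
from . import stats as _stats

__all__ = [
    "EvokedResponse",
    "selective_average",
    "compute_erp",
    "cluster_timecourse",
    "compare_erp",
    "ERP_NUMEROSITIES",
    "POSTERIOR_CLUSTER",
]

ERP_NUMEROSITIES = (14, 16, 18, 20)

#: posterior electrode cluster used for the ERP timecourse
POSTERIOR_CLUSTER = ("PO3", "PO4", "POz", "PO7", "PO8", "O1", "O2")


@dataclass
class EvokedResponse:
    """Trial average: channels x samples, with provenance."""

    data: np.ndarray
    sfreq: float
    t0: float  # ms of first sample relative to test onset
    condition: str
    numerosities: tuple[int, ...]
    n_trials: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("an evoked response needs at least one trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in evoked response")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def time_slice(self, start_ms: float, stop_ms: float) -> slice:
        i0 = int(round((start_ms - self.t0) / 1000.0 * self.sfreq))
        i1 = int(round((stop_ms - self.t0) / 1000.0 * self.sfreq))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"window [{start_ms}, {stop_ms}) ms not inside evoked span"
            )
        return slice(i0, i1)


def selective_average(
    epochs: EpochArray,
    condition: str,
    numerosities: "tuple[int, ...] | None" = None,
) -> EvokedResponse:
    """Average the trials of one condition (optionally one numerosity set)."""
    mask = (epochs.events["adaptation"] == condition).to_numpy()
    if numerosities is not None:
        mask &= epochs.events["numerosity"].isin(numerosities).to_numpy()
    if not mask.any():
        raise ValueError(
            f"no trials for condition {condition!r}, numerosities {numerosities}"
        )
    nums = (
        tuple(sorted(set(epochs.events.loc[mask, "numerosity"])))
        if numerosities is None
        else tuple(numerosities)
    )
    return EvokedResponse(
        data=epochs.data[mask].mean(axis=0),
        sfreq=epochs.sfreq,
        t0=epochs.t0,
        condition=condition,
        numerosities=nums,
        n_trials=int(mask.sum()),
        labels=epochs.montage.labels,
    )


def compute_erp(
    epochs: EpochArray,
    condition: str,
    numerosities: tuple[int, ...] = ERP_NUMEROSITIES,
    window: tuple[float, float] = (-100.0, 200.0),
    baseline: tuple[float, float] = (-100.0, 0.0),
) -> EvokedResponse:
    """Baseline-corrected ERP over the trimmed window for one condition."""
    ev = selective_average(epochs, condition, numerosities)
    sl = ev.time_slice(*window)
    bl = ev.time_slice(*baseline)
    data = ev.data[:, sl] - ev.data[:, bl].mean(axis=1, keepdims=True)
    return EvokedResponse(
        data=data,
        sfreq=ev.sfreq,
        t0=window[0],
        condition=condition,
        numerosities=tuple(numerosities),
        n_trials=ev.n_trials,
        labels=ev.labels,
    )


def cluster_timecourse(
    evoked: EvokedResponse, channels: tuple[str, ...] = POSTERIOR_CLUSTER
) -> np.ndarray:
    """Unweighted mean over a named channel set."""
    idx = []
    for ch in channels:
        if ch not in evoked.labels:
            raise KeyError(f"channel {ch!r} not in evoked response")
        idx.append(evoked.labels.index(ch))
    return evoked.data[idx].mean(axis=0)


def compare_erp(
    high: np.ndarray,
    low: np.ndarray,
    n_permutations: int = 15000,
    q: float = 0.05,
    seed: "int | np.random.Generator | None" = 0,
) -> dict:
    """Pointwise paired permutation test of per-participant ERP timecourses.

    ``high``/``low``: (n_participants, n_samples).  BH-FDR is applied across
    time samples.
    """
    high = np.atleast_2d(np.asarray(high, dtype=float))
    low = np.atleast_2d(np.asarray(low, dtype=float))
    if high.shape != low.shape:
        raise ValueError("high/low timecourses must be participant-paired")
    if high.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    t_obs, p_raw = _stats.paired_permutation_test(
        high, low, n_permutations=n_permutations, seed=seed
    )
    p_adj, mask = _stats.fdr_bh(p_raw, q)
    return {
        "statistic": t_obs,
        "p_raw": p_raw,
        "p_fdr": p_adj,
        "mask": mask,
        "n_permutations": n_permutations,
        "q": q,
    }
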