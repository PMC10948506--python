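"""Phase-based functional connectivity: surface Laplacian, narrowband
Hilbert phase, and inter-site phase clustering (ISPC).

ISPC between electrodes a and b is the length of the mean phasor of their
phase-angle differences over time,

    ISPC = | mean_t exp(i (phi_a(t) - phi_b(t))) |  in [0, 1],

computed here within condition-averaged (evoked) signals: per numerosity,
trials are averaged within condition, the average is spatially filtered
with the surface Laplacian, band-passed at that numerosity's tagging
frequency (second-order Butterworth, +/-0.5 Hz, forward-backward so the net
phase is zero) and Hilbert transformed; the five per-numerosity ISPC
matrices are then averaged, but the two adaptation conditions are kept
separate.  The first and last 500 ms of the 4000 ms test window are
excluded from the ISPC sum to suppress filter/Hilbert edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochArray, NUMEROSITIES
from .evoked import EvokedResponse, selective_average
from .montage import Montage
from .spectral import tagging_frequency
from . import splines
from . import stats as _stats

__all__ = [
    "AnalyticSignal",
    "surface_laplacian",
    "narrowband_phase",
    "ispc",
    "ispc_matrix",
    "compare_ispc",
    "pair_labels",
    "HALF_BANDWIDTH_HZ",
    "EDGE_EXCLUSION_MS",
]

HALF_BANDWIDTH_HZ = 0.5
EDGE_EXCLUSION_MS = 500.0


@dataclass
class AnalyticSignal:
    """Instantaneous phase/envelope per channel with a valid-sample mask."""

    phase: np.ndarray  # (n_channels, n_samples), wrapped to (-pi, pi]
    envelope: np.ndarray  # (n_channels, n_samples), >= 0
    f_tag: float
    valid: np.ndarray  # (n_samples,) bool
    sfreq: float
    labels: tuple[str, ...]


def surface_laplacian(obj, montage: "Montage | None" = None):
    """Perrin spherical-spline surface Laplacian (arbitrary units).

    Accepts an :class:`EpochArray` or :class:`EvokedResponse` (channel axis
    matching ``montage``) and returns the same type.  Linear in the input;
    a spatially constant potential maps to zero.
    """
    if isinstance(obj, EpochArray):
        montage = montage or obj.montage
        if len(montage) < 8:
            raise ValueError("surface Laplacian needs >= 8 channels")
        op = splines.laplacian_operator(montage)
        return obj.copy_with(np.einsum("dc,tcs->tds", op, obj.data))
    if isinstance(obj, EvokedResponse):
        if montage is None:
            raise ValueError("montage required for evoked input")
        if len(montage) < 8:
            raise ValueError("surface Laplacian needs >= 8 channels")
        op = splines.laplacian_operator(montage)
        out = EvokedResponse(
            data=op @ obj.data,
            sfreq=obj.sfreq,
            t0=obj.t0,
            condition=obj.condition,
            numerosities=obj.numerosities,
            n_trials=obj.n_trials,
            labels=obj.labels,
        )
        return out
    raise TypeError(f"cannot apply surface Laplacian to {type(obj).__name__}")


def narrowband_phase(
    evoked: EvokedResponse,
    f_tag: float,
    half_bandwidth: float = HALF_BANDWIDTH_HZ,
    edge_ms: float = EDGE_EXCLUSION_MS,
    window_ms: tuple[float, float] = (0.0, 4000.0),
) -> AnalyticSignal:
    """Zero-phase narrowband filtering + Hilbert transform at ``f_tag``.

    Second-order Butterworth band-pass at f_tag +/- half_bandwidth applied
    forward-backward (zero net phase, effectively fourth-order magnitude),
    then the analytic signal.  Valid samples are the test window with
    ``edge_ms`` trimmed from each end.
    """
    nyq = evoked.sfreq / 2.0
    lo, hi = f_tag - half_bandwidth, f_tag + half_bandwidth
    if lo <= 0 or hi >= nyq:
        raise ValueError(
            f"band [{lo}, {hi}] Hz outside (0, {nyq}) Hz at {evoked.sfreq} Hz"
        )
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=evoked.sfreq, output="sos")
    # the ~1 Hz band means seconds-long filter transients: pad generously
    # (odd-reflection) for the forward-backward pass, and keep the padding
    # through the (circular) Hilbert transform so edge artifacts stay out
    # of the analysis window
    pad = min(evoked.n_samples - 1, int(2 * evoked.sfreq))
    filtered = signal.sosfiltfilt(sos, evoked.data, axis=-1, padlen=pad)
    padded = np.pad(
        filtered,
        [(0, 0)] * (filtered.ndim - 1) + [(pad, pad)],
        mode="reflect",
        reflect_type="odd",
    )
    analytic = signal.hilbert(padded, axis=-1)[..., pad:-pad]
    valid = np.zeros(evoked.n_samples, dtype=bool)
    valid[evoked.time_slice(window_ms[0] + edge_ms, window_ms[1] - edge_ms)] = True
    return AnalyticSignal(
        phase=np.angle(analytic),
        envelope=np.abs(analytic),
        f_tag=f_tag,
        valid=valid,
        sfreq=evoked.sfreq,
        labels=evoked.labels,
    )


def ispc(phase_a: np.ndarray, phase_b: np.ndarray, valid: np.ndarray) -> float:
    """Inter-site phase clustering of two phase series over valid samples."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() == 0:
        raise ValueError("empty valid-sample mask")
    if valid.sum() < 100:
        raise ValueError("need >= 100 valid samples for a stable ISPC estimate")
    diff = phase_a[valid] - phase_b[valid]
    return float(np.abs(np.mean(np.exp(1j * diff))))


def _ispc_all_pairs(analytic: AnalyticSignal) -> np.ndarray:
    """Full channels x channels ISPC matrix from one analytic signal."""
    z = np.exp(1j * analytic.phase[:, analytic.valid])
    t = z.shape[1]
    m = np.abs(z @ z.conj().T) / t
    return np.clip(m, 0.0, 1.0)


def ispc_matrix(
    epochs: EpochArray,
    condition: str,
    montage: "Montage | None" = None,
    numerosities: tuple[int, ...] = NUMEROSITIES,
) -> np.ndarray:
    """Numerosity-averaged ISPC matrix for one condition.

    Pipeline per numerosity: condition x numerosity trial average ->
    surface Laplacian -> narrowband phase at that numerosity's tagging
    frequency -> ISPC for all channel pairs; the matrices are then averaged
    (unweighted) across numerosities.
    """
    montage = montage or epochs.montage
    present = set(
        map(tuple, epochs.events[["adaptation", "numerosity"]].drop_duplicates().values)
    )
    missing = [n for n in numerosities if (condition, n) not in present]
    if missing:
        raise ValueError(f"missing {condition} trials for numerosities {missing}")
    op = splines.laplacian_operator(montage)
    mats = []
    for num in numerosities:
        ev = selective_average(epochs, condition, (num,))
        ev.data = op @ ev.data
        analytic = narrowband_phase(ev, tagging_frequency(num))
        mats.append(_ispc_all_pairs(analytic))
    out = np.mean(mats, axis=0)
    np.fill_diagonal(out, 1.0)
    return out


def pair_labels(labels: tuple[str, ...]) -> list[tuple[str, str]]:
    """Unique off-diagonal channel pairs in (row-major) upper-triangle order."""
    n = len(labels)
    return [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]


def compare_ispc(
    matrices_high: np.ndarray,
    matrices_low: np.ndarray,
    labels: tuple[str, ...],
    n_permutations: int = 15000,
    q: float = 0.05,
    seed: "int | np.random.Generator | None" = 0,
) -> dict:
    """Paired permutation test of ISPC over all unique electrode pairs.

    ``matrices_high``/``matrices_low``: (n_participants, n_ch, n_ch)
    participant-paired ISPC matrices.  BH-FDR across pairs (435 for 30
    channels); returns the significant pair list.
    """
    mh = np.asarray(matrices_high, dtype=float)
    ml = np.asarray(matrices_low, dtype=float)
    if mh.shape != ml.shape or mh.ndim != 3 or mh.shape[1] != mh.shape[2]:
        raise ValueError("inputs must be participant-paired square matrices")
    if mh.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    n_ch = mh.shape[1]
    if n_ch != len(labels):
        raise ValueError("matrix size does not match labels")
    iu = np.triu_indices(n_ch, k=1)
    high = mh[:, iu[0], iu[1]]
    low = ml[:, iu[0], iu[1]]
    t_obs, p_raw = _stats.paired_permutation_test(
        high, low, n_permutations=n_permutations, seed=seed
    )
    p_adj, mask = _stats.fdr_bh(p_raw, q)
    pairs = pair_labels(tuple(labels))
    return {
        "pairs": pairs,
        "statistic": t_obs,
        "p_raw": p_raw,
        "p_fdr": p_adj,
        "mask": mask,
        "sig_pairs": [pairs[i] for i in np.flatnonzero(mask)],
        "n_permutations": n_permutations,
        "q": q,
    }
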