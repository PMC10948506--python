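"""ssVEP quantification: FFT amplitude spectra and tagging-bin extraction.

The spectrum is computed over exactly the 4000 ms test window (2000 samples
at 500 Hz), giving a bin width of 0.25 Hz that makes every tagging
frequency (numerosity / 4 = 3.5 ... 5.5 Hz) land on an exact bin - no
leakage, no windowing ambiguity.  "Power" is operationalized as the
single-sided amplitude spectrum in microvolt (2|X_k|/N for k >= 1, |X_0|/N
at DC), matching the magnitude output convention of frequency-tagging
toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evoked import EvokedResponse
from . import stats as _stats

__all__ = [
    "SpectrumSet",
    "fft_amplitude",
    "tagging_frequency",
    "tagging_power",
    "compare_ssvep",
    "SSVEP_WINDOW_MS",
]

SSVEP_WINDOW_MS = (0.0, 4000.0)


@dataclass
class SpectrumSet:
    """Single-sided amplitude spectra: channels x frequency bins (microvolt)."""

    amplitude: np.ndarray
    freqs: np.ndarray
    labels: tuple[str, ...]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def at_frequency(self, f: float, tol: float = 1e-9) -> np.ndarray:
        """Per-channel amplitude at an exact bin frequency."""
        k = f / self.df
        if abs(k - round(k)) > tol:
            raise ValueError(
                f"{f} Hz is not an exact bin (bin width {self.df} Hz): "
                "window/duration mismatch"
            )
        return self.amplitude[:, int(round(k))]


def tagging_frequency(numerosity: int, test_duration_ms: float = 4000.0) -> float:
    """Stimulation rate of the test sequence: numerosity / duration."""
    return numerosity / (test_duration_ms / 1000.0)


def fft_amplitude(
    evoked: EvokedResponse, window_ms: tuple[float, float] = SSVEP_WINDOW_MS
) -> SpectrumSet:
    """Single-sided amplitude spectrum of the test window of an average."""
    sl = evoked.time_slice(*window_ms)
    seg = evoked.data[:, sl]
    n = seg.shape[1]
    spec = np.fft.rfft(seg, axis=1)
    amp = np.abs(spec) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:  # unpaired Nyquist bin
        amp[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / evoked.sfreq)
    return SpectrumSet(amplitude=amp, freqs=freqs, labels=evoked.labels)


def tagging_power(
    spectra: "dict[int, SpectrumSet]",
    numerosities: "tuple[int, ...] | None" = None,
    test_duration_ms: float = 4000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tagging-bin amplitude per numerosity and its numerosity average.

    ``spectra`` maps numerosity -> SpectrumSet (one condition, one
    participant).  Returns ``(per_numerosity, average)`` with shapes
    (n_numerosities, n_channels) and (n_channels,).
    """
    if numerosities is None:
        numerosities = tuple(sorted(spectra))
    rows = []
    for num in numerosities:
        f_tag = tagging_frequency(num, test_duration_ms)
        rows.append(spectra[num].at_frequency(f_tag))
    per_num = np.array(rows)
    return per_num, per_num.mean(axis=0)


def compare_ssvep(
    power_high: np.ndarray,
    power_low: np.ndarray,
    labels: tuple[str, ...],
    n_permutations: int = 15000,
    q: float = 0.05,
    seed: "int | np.random.Generator | None" = 0,
) -> dict:
    """Paired permutation test of numerosity-averaged tagging amplitude.

    ``power_high``/``power_low``: (n_participants, n_channels).  BH-FDR is
    applied across channels; the returned ``sig_channels`` lists the labels
    whose adjusted p falls at or below ``q``.
    """
    power_high = np.asarray(power_high, dtype=float)
    power_low = np.asarray(power_low, dtype=float)
    if power_high.shape != power_low.shape:
        raise ValueError("condition arrays must be participant-paired")
    if power_high.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if power_high.shape[1] != len(labels):
        raise ValueError("channel axis does not match labels")
    t_obs, p_raw = _stats.paired_permutation_test(
        power_high, power_low, n_permutations=n_permutations, seed=seed
    )
    p_adj, mask = _stats.fdr_bh(p_raw, q)
    return {
        "labels": tuple(labels),
        "statistic": t_obs,
        "p_raw": p_raw,
        "p_fdr": p_adj,
        "mask": mask,
        "sig_channels": [labels[i] for i in np.flatnonzero(mask)],
        "n_permutations": n_permutations,
        "q": q,
    }
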