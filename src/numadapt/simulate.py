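"""Synthetic behavioral estimates and multichannel EEG epochs.

The generator produces data with the statistical structure the analysis
assumes, so every downstream stage can be validated against known ground
truth:

* Behavioral estimates are multiplicative: estimate = round(max(0,
  true * gain_condition * s_p + eps)) with a per-participant gain
  s_p ~ N(1, participant_gain_sd) and trial noise eps ~ N(0,
  response_noise_sd).  The default condition gains (High 0.925, Low 1.075)
  put the expected Low-High difference at 15% of the true numerosity.
* EEG epochs are 1/f background noise plus a steady-state response: a pure
  sinusoid at the trial's tagging frequency (numerosity / 4 Hz),
  phase-locked to test onset, active during the 4-s test window, with
  amplitude ssvep_amp_low (Low) or ssvep_amp_low * ssvep_amp_ratio_high
  (High) at the effect sensors and a Gaussian spatial falloff elsewhere.
  Condition-dependent phase coupling is injected over the channels of the
  coupling-pair graph: every involved channel carries a narrowband
  component at the tagging frequency (phase-locked across trials within a
  condition x numerosity cell).  The components of the involved channels
  are correlated Gaussian mixtures with a target correlation matrix that
  has (a) ``coupling_gain * coupling_strength[condition]`` (capped at
  0.95, then projected to the nearest correlation matrix) on directly
  coupled pairs and (b) a condition-INDEPENDENT ``coupling_background``
  correlation on all other node pairs of the graph.  The background term
  is forced by positive semi-definiteness - correlations near the ceiling
  on the spokes of a hub imply substantial spoke-spoke correlation - and
  making it identical in both conditions means only the directly coupled
  pairs carry a condition difference.  Component amplitude is also
  condition-independent: adaptation modulates synchronization, not power.
  Each channel's component enters the scalp with the topography of a
  focal current source under that electrode (the pseudoinverse column of
  the spherical-spline Laplacian operator): its raw scalp pattern is
  smooth, as volume conduction demands, and the Laplacian stage of the
  connectivity analysis recovers it focally at the member electrode, which
  is what makes pair-level recovery well-posed.

The background noise is synthesized by shaping white-noise FFT magnitude by
f**(-exponent/2) per source, with a shared low-rank spatial mixing (a few
smooth scalp patterns common to all channels) plus a channel-independent
remainder, mimicking the dominance of volume-conducted activity that the
surface Laplacian is meant to attenuate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import CONDITIONS, EpochArray, NUMEROSITIES
from .montage import Montage
from . import splines

__all__ = [
    "BehaviorParams",
    "EEGEffectSpec",
    "draw_participant_gains",
    "simulate_behavior",
    "simulate_eeg",
    "reduce_design",
]


@dataclass(frozen=True)
class BehaviorParams:
    gain_high: float = 0.925
    gain_low: float = 1.075
    participant_gain_sd: float = 0.05
    response_noise_sd: float = 1.2  # flashes

    def __post_init__(self) -> None:
        if self.gain_high <= 0 or self.gain_low <= 0:
            raise ValueError("condition gains must be positive")
        if self.participant_gain_sd < 0 or self.response_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def gain(self, condition: str) -> float:
        return self.gain_high if condition == "High" else self.gain_low


def draw_participant_gains(
    participants, params: BehaviorParams, rng: np.random.Generator
) -> dict[int, float]:
    """Fixed per-participant multiplicative gain s_p ~ N(1, sd), in order."""
    return {
        int(p): float(rng.normal(1.0, params.participant_gain_sd))
        for p in participants
    }


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # verbal integer reports; symmetric round-half-away-from-zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_behavior(
    design: pd.DataFrame,
    params: BehaviorParams,
    rng: np.random.Generator,
    gains: "dict[int, float] | None" = None,
) -> pd.DataFrame:
    """Per-trial verbal estimates for a generated design.

    ``gains`` may pre-specify the per-participant gain s_p (e.g. to couple
    the EEG effect size to behavior); otherwise gains are drawn here, one
    per participant in order of first appearance.
    """
    if gains is None:
        participants = pd.unique(design["participant"])
        gains = draw_participant_gains(participants, params, rng)
    true = design["numerosity"].to_numpy(dtype=float)
    cond_gain = np.array([params.gain(c) for c in design["adaptation"]])
    s_p = np.array([gains[int(p)] for p in design["participant"]])
    eps = rng.normal(0.0, params.response_noise_sd, size=len(design))
    raw = np.maximum(0.0, true * cond_gain * s_p + eps)
    out = design.copy()
    out = out.rename(columns={"numerosity": "true_numerosity"})
    out["estimate"] = _round_half_away(raw).astype(int)
    return out[
        ["participant", "block", "trial", "adaptation", "true_numerosity", "estimate"]
    ]


@dataclass(frozen=True)
class EEGEffectSpec:
    ssvep_amp_low: float = 1.0  # microvolt at effect sensors, Low condition
    ssvep_amp_ratio_high: float = 1.3
    effect_sensors: tuple[str, ...] = ("POz", "O2", "C3", "Cz")
    coupling_pairs: tuple[tuple[str, str], ...] = (
        ("C3", "CP5"), ("CP5", "CP6"), ("CP5", "POz"), ("C3", "PO7"),
    )
    coupling_strength_high: float = 0.6
    coupling_strength_low: float = 0.2
    coupling_amp_uv: float = 15.0  # focal-source strength of the coupling network
    coupling_gain: float = 1.55  # nominal strength -> injected band correlation
    coupling_background: float = 0.7  # condition-independent network correlation
    noise_exponent: float = 1.0  # 1/f spectral slope
    noise_rms_uv: float = 10.0
    topo_sigma_rad: float = 0.07  # Gaussian falloff of the ssVEP away from effect sensors
    shared_noise_frac: float = 0.92  # variance fraction of the low-rank shared noise
    n_shared_sources: int = 4

    def __post_init__(self) -> None:
        if self.ssvep_amp_low < 0 or self.ssvep_amp_ratio_high < 0:
            raise ValueError("ssVEP amplitudes must be non-negative")
        for w in (self.coupling_strength_high, self.coupling_strength_low):
            if not (0.0 <= w <= 1.0):
                raise ValueError("coupling strengths must be in [0, 1]")
        if self.coupling_amp_uv < 0 or self.noise_rms_uv < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (0.0 <= self.coupling_background < 1.0) or self.coupling_gain < 0:
            raise ValueError("invalid coupling network parameters")
        if not (0.0 <= self.shared_noise_frac <= 1.0):
            raise ValueError("shared_noise_frac must be in [0, 1]")

    def coupling_strength(self, condition: str) -> float:
        return (
            self.coupling_strength_high
            if condition == "High"
            else self.coupling_strength_low
        )


def reduce_design(design: pd.DataFrame, n_per_cell: int) -> pd.DataFrame:
    """First ``n_per_cell`` trials of every (condition, numerosity) cell."""
    return (
        design.groupby(["adaptation", "numerosity"], group_keys=False)
        .head(n_per_cell)
        .sort_values("trial")
        .reset_index(drop=True)
    )


def _pink_rows(
    rng: np.random.Generator, n_rows: int, n_samples: int, sfreq: float, exponent: float
) -> np.ndarray:
    """Unit-RMS rows of 1/f^exponent noise (power), shaped in the FFT domain.

    Synthesized directly in the frequency domain (complex Gaussian spectrum
    scaled by the target magnitude), which is equivalent to filtering white
    noise but needs only the inverse transform.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    # flatten below 1 Hz so the DC region does not dominate
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_rows, freqs.size))
        + 1j * rng.standard_normal((n_rows, freqs.size))
    ) * shape
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _narrowband_component(
    rng: np.random.Generator, n_samples: int, sfreq: float, f_center: float
) -> np.ndarray:
    """Unit-RMS narrowband noise in f_center +/- 0.5 Hz."""
    sos = signal.butter(
        2, [f_center - 0.5, f_center + 0.5], btype="bandpass", fs=sfreq, output="sos"
    )
    # generous padding so filter transients do not color the kept stretch
    pad = int(2 * sfreq)
    x = signal.sosfilt(sos, rng.standard_normal(n_samples + 2 * pad))[pad:-pad]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _noise_block(
    rng: np.random.Generator,
    n_trials: int,
    mixing: np.ndarray,
    n_samples: int,
    sfreq: float,
    spec: EEGEffectSpec,
) -> np.ndarray:
    """(n_trials, n_channels, n_samples) background noise, RMS = noise_rms_uv."""
    n_ch = mixing.shape[0]
    k = mixing.shape[1]
    sources = _pink_rows(
        rng, n_trials * k, n_samples, sfreq, spec.noise_exponent
    ).reshape(n_trials, k, n_samples)
    indep = _pink_rows(
        rng, n_trials * n_ch, n_samples, sfreq, spec.noise_exponent
    ).reshape(n_trials, n_ch, n_samples)
    shared = np.einsum("ck,tks->tcs", mixing, sources)
    w_shared = np.sqrt(spec.shared_noise_frac)
    w_indep = np.sqrt(1.0 - spec.shared_noise_frac)
    return spec.noise_rms_uv * (w_shared * shared + w_indep * indep)


def _shared_mixing(
    rng: np.random.Generator, montage: Montage, spec: EEGEffectSpec
) -> np.ndarray:
    """(n_channels, k) row-normalized smooth scalp patterns (volume conduction)."""
    k = spec.n_shared_sources
    # random source directions on the upper hemisphere
    v = rng.standard_normal((k, 3))
    v[:, 2] = np.abs(v[:, 2])
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    ang = np.arccos(np.clip(montage.positions @ v.T, -1.0, 1.0))
    mix = np.exp(-(ang**2) / (2 * 0.8**2))
    norms = np.linalg.norm(mix, axis=1, keepdims=True)
    return mix / norms


def _focal_source_profiles(montage: Montage, channels: list[int]) -> np.ndarray:
    """(n_requested, n_channels) smooth scalp patterns of focal sources.

    Column ``j`` of the Laplacian operator's pseudoinverse is the potential
    pattern whose surface Laplacian is exactly a unit delta at electrode
    ``j``, so a source of strength ``a`` appears with amplitude ``a`` at its
    member electrode (and nowhere else) after the Laplacian stage of the
    connectivity analysis, for every member alike.  On the raw scalp the
    pattern is smooth with a peak of roughly 0.13 a microvolt.
    """
    lap = splines.laplacian_operator(montage)
    pinv = np.linalg.pinv(lap, rcond=1e-8)
    return np.stack([pinv[:, j] for j in channels])


def _coupling_network(
    montage: Montage, pairs: tuple[tuple[str, str], ...]
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Involved channel indices, adjacency matrix, direct-pair index list."""
    members = sorted({montage.index(c) for pair in pairs for c in pair})
    pos = {ch: k for k, ch in enumerate(members)}
    adj = np.zeros((len(members), len(members)))
    direct = []
    for a, b in pairs:
        i, j = pos[montage.index(a)], pos[montage.index(b)]
        adj[i, j] = adj[j, i] = 1.0
        direct.append((i, j))
    return members, adj, direct


def _coupling_mixing(
    adj: np.ndarray, strength: float, background: float, gain: float
) -> np.ndarray:
    """Mixing matrix M with M M^T ~ the target correlation structure.

    Target: ``min(0.95, gain * strength)`` on directly coupled (adjacent)
    pairs, ``background`` on the remaining node pairs, unit diagonal.  The
    target is projected to the nearest correlation matrix (eigenvalue
    clipping + diagonal renormalization) before taking the symmetric
    square root, so near-ceiling direct correlations degrade gracefully
    instead of breaking positive semi-definiteness.
    """
    n = len(adj)
    rho_d = min(0.95, gain * strength)
    off = (1.0 - np.eye(n)) * (1.0 - adj)
    sigma = np.eye(n) + rho_d * adj + background * off
    w, v = np.linalg.eigh(sigma)
    sigma = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(sigma))
    sigma /= np.outer(d, d)
    w, v = np.linalg.eigh(sigma)
    return v @ np.diag(np.sqrt(w)) @ v.T


def _ssvep_topography(montage: Montage, spec: EEGEffectSpec) -> np.ndarray:
    idx = [montage.index(s) for s in spec.effect_sensors]
    ang = np.arccos(
        np.clip(montage.positions @ montage.positions[idx].T, -1.0, 1.0)
    )  # (n_ch, n_effect)
    return np.exp(-(ang.min(axis=1) ** 2) / (2 * spec.topo_sigma_rad**2))


def simulate_eeg(
    design: pd.DataFrame,
    montage: Montage,
    spec: EEGEffectSpec,
    rng: np.random.Generator,
    sfreq: float = 500.0,
    t0: float = -500.0,
    t1: float = 4500.0,
    test_duration_ms: float = 4000.0,
    amp_ratio_high: "float | None" = None,
) -> EpochArray:
    """Simulate one participant's epochs for every trial in ``design``.

    ``amp_ratio_high`` overrides the spec's High/Low amplitude ratio for
    this participant, which lets a caller couple the EEG effect size to the
    participant's behavioral adaptation strength.
    """
    for s in spec.effect_sensors:
        montage.index(s)
    for a, b in spec.coupling_pairs:
        montage.index(a), montage.index(b)
    n_samples = int(round((t1 - t0) / 1000.0 * sfreq))
    times = t0 + np.arange(n_samples) * 1000.0 / sfreq
    active = (times >= 0.0) & (times < test_duration_ms)
    ratio = spec.ssvep_amp_ratio_high if amp_ratio_high is None else amp_ratio_high
    topo = _ssvep_topography(montage, spec)
    mixing = _shared_mixing(rng, montage, spec)
    n_ch = len(montage)
    if spec.coupling_amp_uv > 0 and spec.coupling_pairs:
        members, adj, direct = _coupling_network(montage, spec.coupling_pairs)
        profiles = _focal_source_profiles(montage, members)  # (n_members, n_ch)
        mixings = {
            cond: _coupling_mixing(
                adj,
                spec.coupling_strength(cond),
                spec.coupling_background,
                spec.coupling_gain,
            )
            for cond in CONDITIONS
        }

    data = np.zeros((len(design), n_ch, n_samples), dtype=np.float64)
    design = design.reset_index(drop=True)
    for (condition, numerosity), cell in design.groupby(
        ["adaptation", "numerosity"], sort=True
    ):
        f_tag = numerosity / (test_duration_ms / 1000.0)
        if f_tag >= sfreq / 2.0:
            raise ValueError(
                f"tagging frequency {f_tag} Hz at or above Nyquist ({sfreq / 2} Hz)"
            )
        rows = cell.index.to_numpy()
        block = np.zeros((len(rows), n_ch, n_samples))
        if spec.noise_rms_uv > 0:
            block += _noise_block(rng, len(rows), mixing, n_samples, sfreq, spec)
        amp = spec.ssvep_amp_low * (ratio if condition == "High" else 1.0)
        if amp > 0:
            tone = np.sin(2 * np.pi * f_tag * times / 1000.0) * active
            block += amp * topo[None, :, None] * tone[None, None, :]
        if spec.coupling_amp_uv > 0 and spec.coupling_pairs:
            sources = np.stack(
                [
                    _narrowband_component(rng, n_samples, sfreq, f_tag)
                    for _ in range(len(members))
                ]
            )
            comps = (mixings[condition] @ sources) * active[None, :]
            # scalp contribution: sum over members of focal profile x component
            block += spec.coupling_amp_uv * np.einsum("mc,ms->cs", profiles, comps)[None, :, :]
        data[rows] = block

    return EpochArray(
        data=data, events=design.copy(), montage=montage, sfreq=sfreq, t0=t0
    )
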