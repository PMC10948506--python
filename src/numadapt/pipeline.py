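"""Study-level orchestration: multi-participant simulation and the
analysis chains (behavior, ERP, ssVEP, ISPC), plus the seeded
parameter-recovery studies used to validate the pipeline.

Memory notes: participants are simulated and analyzed one at a time
(epochs for one participant at the reduced 8-trials-per-cell profile are
~50 MB), so whole-study analyses never hold more than one participant's
raw trials.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignConfig, generate_design
from .io import CONDITIONS, EpochArray, NUMEROSITIES
from .montage import Montage, default_montage
from .simulate import (
    BehaviorParams,
    EEGEffectSpec,
    draw_participant_gains,
    reduce_design,
    simulate_behavior,
    simulate_eeg,
)
from .evoked import compute_erp, cluster_timecourse, compare_erp, selective_average
from .spectral import compare_ssvep, fft_amplitude, tagging_power
from .connectivity import compare_ispc, ispc_matrix
from . import stats as _stats

__all__ = [
    "StudyConfig",
    "simulate_study_behavior",
    "iter_participant_epochs",
    "simulate_study_epochs",
    "ssvep_amplitudes",
    "ispc_matrices_study",
    "erp_timecourses",
    "behavior_statistics",
    "brain_behavior_correlation",
    "ssvep_recovery_run",
    "ispc_recovery_run",
]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to simulate and analyze one synthetic study."""

    design: DesignConfig = field(default_factory=DesignConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    eeg: EEGEffectSpec = field(default_factory=EEGEffectSpec)
    n_trials_per_cell: int = 8  # reduced desk-scale profile; 35 = full design
    behavior_link: float = 0.5  # strength of the ssVEP-ratio/behavior coupling
    n_permutations: int = 15000
    q: float = 0.05
    ptp_threshold_uv: float = 150.0

    @staticmethod
    def from_dict(d: dict) -> "StudyConfig":
        d = dict(d)
        design = DesignConfig(**d.pop("design", {}))
        behavior = BehaviorParams(**d.pop("behavior", {}))
        eeg = d.pop("eeg", {})
        if "coupling_pairs" in eeg:
            eeg["coupling_pairs"] = tuple(tuple(p) for p in eeg["coupling_pairs"])
        if "effect_sensors" in eeg:
            eeg["effect_sensors"] = tuple(eeg["effect_sensors"])
        return StudyConfig(
            design=design, behavior=behavior, eeg=EEGEffectSpec(**eeg), **d
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _seed_tree(seed: int) -> tuple:
    root = np.random.SeedSequence(seed)
    gains_ss, behavior_ss, eeg_ss = root.spawn(3)
    return gains_ss, behavior_ss, eeg_ss


def _participant_gains(cfg: StudyConfig, seed: int) -> dict[int, float]:
    gains_ss, _, _ = _seed_tree(seed)
    rng = np.random.default_rng(gains_ss)
    return draw_participant_gains(
        range(cfg.design.n_participants), cfg.behavior, rng
    )


def simulate_study_behavior(
    cfg: StudyConfig, seed: int
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Full 350-trial behavioral tables for every participant.

    Returns the combined table and the per-participant gains s_p (shared
    with the EEG simulation so EEG effect size can track behavior).
    """
    gains = _participant_gains(cfg, seed)
    _, behavior_ss, _ = _seed_tree(seed)
    rng = np.random.default_rng(behavior_ss)
    tables = []
    for p in range(cfg.design.n_participants):
        design = generate_design(cfg.design, p, rng)
        tables.append(simulate_behavior(design, cfg.behavior, rng, gains=gains))
    return pd.concat(tables, ignore_index=True), gains


def _amp_ratio_for(cfg: StudyConfig, gain: float) -> float:
    """Participant ssVEP High/Low ratio, optionally coupled to behavior."""
    sd = cfg.behavior.participant_gain_sd
    z = 0.0 if sd == 0 or cfg.behavior_link == 0 else (gain - 1.0) / sd
    base = cfg.eeg.ssvep_amp_ratio_high - 1.0
    return 1.0 + base * (1.0 + cfg.behavior_link * z)


def iter_participant_epochs(
    cfg: StudyConfig,
    seed: int,
    montage: "Montage | None" = None,
    gains: "dict[int, float] | None" = None,
):
    """Yield (participant, EpochArray) one participant at a time."""
    montage = montage or default_montage()
    if gains is None:
        gains = _participant_gains(cfg, seed)
    _, _, eeg_ss = _seed_tree(seed)
    children = eeg_ss.spawn(cfg.design.n_participants)
    for p in range(cfg.design.n_participants):
        rng = np.random.default_rng(children[p])
        design = generate_design(cfg.design, p, rng)
        design = reduce_design(design, cfg.n_trials_per_cell)
        epochs = simulate_eeg(
            design,
            montage,
            cfg.eeg,
            rng,
            amp_ratio_high=_amp_ratio_for(cfg, gains[p]),
        )
        yield p, epochs


def simulate_study_epochs(
    cfg: StudyConfig, seed: int, montage: "Montage | None" = None
) -> EpochArray:
    """All participants' epochs concatenated (float32 to bound memory)."""
    montage = montage or default_montage()
    blocks, events = [], []
    for _, epochs in iter_participant_epochs(cfg, seed, montage):
        blocks.append(epochs.data.astype(np.float32))
        events.append(epochs.events)
    return EpochArray(
        data=np.concatenate(blocks, axis=0),
        events=pd.concat(events, ignore_index=True),
        montage=montage,
        sfreq=500.0,
        t0=-500.0,
    )


# ---------------------------------------------------------------------------
# analysis chains
# ---------------------------------------------------------------------------


def _split_participants(epochs: EpochArray):
    for p in sorted(epochs.events["participant"].unique()):
        yield int(p), epochs.select((epochs.events["participant"] == p).to_numpy())


def _as_participant_iter(source):
    """Accept an EpochArray holding many participants or an iterable of
    (participant, EpochArray)."""
    if isinstance(source, EpochArray):
        return _split_participants(source)
    return source


def ssvep_amplitudes(
    source, numerosities: tuple[int, ...] = NUMEROSITIES
) -> dict:
    """Numerosity-averaged tagging-bin amplitude per participant/condition.

    Returns dict with ``participants``, ``labels``, and per-condition
    (n_participants, n_channels) arrays plus per-numerosity tables.
    """
    participants, rows = [], {c: [] for c in CONDITIONS}
    per_num = {c: [] for c in CONDITIONS}
    labels = None
    for p, epochs in _as_participant_iter(source):
        participants.append(p)
        labels = epochs.montage.labels
        for cond in CONDITIONS:
            spectra = {
                num: fft_amplitude(selective_average(epochs, cond, (num,)))
                for num in numerosities
            }
            table, avg = tagging_power(spectra, numerosities)
            rows[cond].append(avg)
            per_num[cond].append(table)
    if labels is None:
        raise ValueError("no participants in input")
    return {
        "participants": participants,
        "labels": labels,
        "numerosities": tuple(numerosities),
        "high": np.array(rows["High"]),
        "low": np.array(rows["Low"]),
        "per_numerosity_high": np.array(per_num["High"]),
        "per_numerosity_low": np.array(per_num["Low"]),
    }


def ispc_matrices_study(source) -> dict:
    """Per-participant numerosity-averaged ISPC matrices for both conditions."""
    participants, mats = [], {c: [] for c in CONDITIONS}
    labels = None
    for p, epochs in _as_participant_iter(source):
        participants.append(p)
        labels = epochs.montage.labels
        for cond in CONDITIONS:
            mats[cond].append(ispc_matrix(epochs, cond))
    if labels is None:
        raise ValueError("no participants in input")
    return {
        "participants": participants,
        "labels": labels,
        "high": np.array(mats["High"]),
        "low": np.array(mats["Low"]),
    }


def erp_timecourses(source) -> dict:
    """Posterior-cluster ERP timecourses per participant and condition."""
    participants, courses = [], {c: [] for c in CONDITIONS}
    times = None
    for p, epochs in _as_participant_iter(source):
        participants.append(p)
        for cond in CONDITIONS:
            erp = compute_erp(epochs, cond)
            times = erp.times
            courses[cond].append(cluster_timecourse(erp))
    return {
        "participants": participants,
        "times": times,
        "high": np.array(courses["High"]),
        "low": np.array(courses["Low"]),
    }


def behavior_statistics(behavior: pd.DataFrame) -> dict:
    """Adaptation percentage, RM-ANOVA with GG correction, and post-hocs."""
    cells = _stats.cell_means(behavior)
    return {
        "adaptation": _stats.adaptation_percentage(behavior),
        "anova": _stats.rm_anova_gg(cells),
        "posthoc": _stats.bonferroni_posthoc(cells),
    }


def brain_behavior_correlation(
    adaptation_pct: np.ndarray,
    power_high: np.ndarray,
    power_low: np.ndarray,
    labels: tuple[str, ...],
    sensors: tuple[str, ...],
) -> dict:
    """Spearman correlation of adaptation percentage with the High-Low
    ssVEP difference averaged over ``sensors`` (normally the FDR-significant
    sensor set)."""
    idx = [labels.index(s) for s in sensors]
    diff = (power_high - power_low)[:, idx].mean(axis=1)
    rho, p = _stats.spearman_correlation(np.asarray(adaptation_pct), diff)
    return {"rho": rho, "p": p, "sensors": list(sensors), "ssvep_diff": diff}


# ---------------------------------------------------------------------------
# parameter-recovery studies
# ---------------------------------------------------------------------------


def _recovery_cfg(base: "StudyConfig | None") -> StudyConfig:
    return base if base is not None else StudyConfig()


def ssvep_recovery_run(
    seed: int, cfg: "StudyConfig | None" = None
) -> dict:
    """One seeded amplitude-recovery run: simulate EEG with the ssVEP
    amplitude effect only (no condition-dependent coupling), run the ssVEP
    comparison, and check the FDR-significant set against the injected
    sensors."""
    cfg = _recovery_cfg(cfg)
    eeg = replace(cfg.eeg, coupling_amp_uv=0.0)
    cfg = replace(cfg, eeg=eeg, behavior_link=0.0)
    amps = ssvep_amplitudes(iter_participant_epochs(cfg, seed))
    res = compare_ssvep(
        amps["high"], amps["low"], amps["labels"],
        n_permutations=cfg.n_permutations, q=cfg.q,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 1])),
    )
    injected = set(cfg.eeg.effect_sensors)
    found = set(res["sig_channels"])
    return {
        "sig_channels": sorted(found),
        "exact": found == injected,
        "n_sig": len(found),
    }


def ispc_recovery_run(
    seed: int, null: bool = False, cfg: "StudyConfig | None" = None
) -> dict:
    """One seeded coupling-recovery run: simulate EEG with the coupling
    effect only (amplitude ratio 1.0), run the ISPC comparison, and check
    the significant pair set against the injected pairs.

    With ``null=True`` the coupling strength is equalized across conditions
    (no effect anywhere); any significant pair is then a family error.
    """
    cfg = _recovery_cfg(cfg)
    if null:
        eeg = replace(
            cfg.eeg,
            ssvep_amp_low=0.0,
            ssvep_amp_ratio_high=1.0,
            coupling_strength_high=0.4,
            coupling_strength_low=0.4,
        )
    else:
        eeg = replace(cfg.eeg, ssvep_amp_low=0.0, ssvep_amp_ratio_high=1.0)
    cfg = replace(cfg, eeg=eeg, behavior_link=0.0)
    mats = ispc_matrices_study(iter_participant_epochs(cfg, seed))
    res = compare_ispc(
        mats["high"], mats["low"], mats["labels"],
        n_permutations=cfg.n_permutations, q=cfg.q,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 2])),
    )
    injected = {frozenset(p) for p in cfg.eeg.coupling_pairs}
    found = {frozenset(p) for p in res["sig_pairs"]}
    return {
        "sig_pairs": sorted(tuple(sorted(p)) for p in found),
        "exact": found == injected,
        "any_sig": bool(found),
        "n_sig": len(found),
    }
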