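"""Experimental design: blocked adaptation conditions, trial orders, and
quasi-periodic flash sequences.

The paradigm: each trial pairs an 8-s adaptor sequence (64 flashes ~8 Hz in
the High condition, 16 flashes ~2 Hz in the Low condition) with a 4-s test
sequence of 14, 16, 18, 20 or 22 flashes (~3.5-5.5 Hz).  350 trials are run
in 10 blocks of 35; the adaptation condition is constant within a block and
counterbalanced across participants (even participant indices start with
five High blocks, odd with five Low blocks).  Flash onsets are evenly
spaced with a random jitter bounded by +/-15% of the nominal inter-flash
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONDITIONS, NUMEROSITIES

__all__ = ["DesignConfig", "generate_flash_onsets", "generate_design"]


@dataclass(frozen=True)
class DesignConfig:
    n_participants: int = 16
    n_blocks: int = 10
    trials_per_block: int = 35
    adaptor_high_flashes: int = 64
    adaptor_low_flashes: int = 16
    adaptor_duration_ms: float = 8000.0
    test_numerosities: tuple[int, ...] = NUMEROSITIES
    test_duration_ms: float = 4000.0
    isi_ms: float = 1000.0
    flash_duration_ms: float = 40.0
    jitter_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_blocks < 2 or self.n_blocks % 2:
            raise ValueError("need >=1 participant and an even number of blocks")
        if self.trials_per_block % len(self.test_numerosities):
            raise ValueError(
                f"trials_per_block ({self.trials_per_block}) not divisible by the "
                f"number of numerosities ({len(self.test_numerosities)})"
            )
        if not (0.0 <= self.jitter_fraction < 0.5):
            raise ValueError("jitter_fraction must be in [0, 0.5)")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def tagging_frequency(self, numerosity: int) -> float:
        """Flashes per second of the test sequence (numerosity / 4 Hz)."""
        return numerosity / (self.test_duration_ms / 1000.0)


def generate_flash_onsets(
    n: int,
    duration_ms: float,
    jitter_fraction: float,
    rng: np.random.Generator,
    flash_duration_ms: float = 40.0,
) -> np.ndarray:
    """Onset times (ms) of ``n`` flashes quasi-evenly spread over ``duration_ms``.

    Flash k sits at k * nominal + delta_k with nominal = duration / n and
    delta_k uniform on +/- jitter_fraction * nominal / 2 (delta_0 = 0), so
    every inter-onset interval stays within nominal * (1 +/- jitter_fraction)
    and the whole train, including the final flash, fits in the period.
    """
    if n < 1:
        raise ValueError("need at least one flash")
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if not (0.0 <= jitter_fraction < 0.5):
        raise ValueError("jitter_fraction must be in [0, 0.5)")
    if n * flash_duration_ms > duration_ms:
        raise ValueError(
            f"{n} flashes of {flash_duration_ms} ms overlap within {duration_ms} ms"
        )
    nominal = duration_ms / n
    delta = rng.uniform(-0.5, 0.5, size=n) * jitter_fraction * nominal
    delta[0] = 0.0
    onsets = np.arange(n) * nominal + delta
    if onsets[-1] + flash_duration_ms > duration_ms:  # pragma: no cover - guarded above
        raise ValueError("flash train exceeds the stimulation period")
    return onsets


def generate_design(
    config: DesignConfig, participant: int, seed: "int | np.random.Generator"
) -> pd.DataFrame:
    """Ordered trial list for one participant.

    Returns a DataFrame with columns participant, block, trial, adaptation,
    numerosity: ``n_blocks * trials_per_block`` rows, every
    (condition, numerosity) cell filled equally, numerosity order shuffled
    within block, block condition following the counterbalancing rule.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first = CONDITIONS[0] if participant % 2 == 0 else CONDITIONS[1]
    second = CONDITIONS[1] if first == CONDITIONS[0] else CONDITIONS[0]
    half = config.n_blocks // 2
    block_conditions = [first] * half + [second] * half
    reps = config.trials_per_block // len(config.test_numerosities)
    rows = []
    trial = 0
    for block, condition in enumerate(block_conditions):
        numerosities = np.repeat(config.test_numerosities, reps)
        rng.shuffle(numerosities)
        for num in numerosities:
            rows.append((participant, block, trial, condition, int(num)))
            trial += 1
    return pd.DataFrame(
        rows, columns=["participant", "block", "trial", "adaptation", "numerosity"]
    )
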