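#!/usr/bin/env python
"""Brain-behavior link: Spearman correlation between each participant's
adaptation percentage and their High-Low ssVEP amplitude difference
averaged over the significant sensors.

The generator couples the ssVEP amplitude ratio to the behavioral gain
(behavior_link), so a positive correlation is the expected sign.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from numadapt.io import read_behavior
from numadapt.pipeline import brain_behavior_correlation
from numadapt.stats import adaptation_percentage

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    behavior = read_behavior(RESULTS / "behavior.csv")
    ssvep = json.loads((RESULTS / "ssvep_test.json").read_text())
    power = pd.read_csv(RESULTS / "ssvep_power.csv")
    sensors = tuple(ssvep["sig_channels"])
    wide = power.pivot_table(
        index="participant", columns=["adaptation", "channel"], values="amplitude_uv"
    )
    labels = tuple(sorted({c for (_, c) in wide.columns}))
    high = np.column_stack([wide[("High", c)] for c in labels])
    low = np.column_stack([wide[("Low", c)] for c in labels])
    adapt = adaptation_percentage(behavior)
    res = brain_behavior_correlation(
        adapt["per_participant"], high, low, labels, sensors
    )
    print(
        f"Spearman rho = {res['rho']:.3f}, p = {res['p']:.4f} "
        f"(sensors: {', '.join(sensors)})"
    )
    payload = {
        "rho": res["rho"],
        "p": res["p"],
        "sensors": list(sensors),
        "adaptation_pct": list(adapt["per_participant"]),
        "ssvep_diff": list(res["ssvep_diff"]),
    }
    (RESULTS / "brain_behavior.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
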