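#!/usr/bin/env python
"""Generate the four synthetic calorimetric scenarios.

The study's raw calorimeter exports are not deposited, so the analysis runs
on synthetic experiments whose parameters are pinned to the printed
observations: an unamended deep-borehole plateau (~100 nW), a formate burst
(~450 nW near 20 h), a slow acetate+nitrate rise (~175 nW), and the
0.371 mM amino-acid amendment (2.25 uW peak at 32.5 h, 0.0433 J total
biological heat).  Writes one thermogram file, a ground-truth sidecar, and
cell/chemistry series per scenario under results/simulated/.
"""

import json
from pathlib import Path

import pandas as pd

from nanocal import io as tio
from nanocal.simulate import list_presets, load_preset, simulate_thermogram

SEED = 1
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in list_presets():
        cfg = load_preset(name, seed=SEED)
        exp = simulate_thermogram(cfg)
        tio.write_thermogram(exp.thermogram, OUT / f"{name}.csv")
        truth = {
            "Q_true_J": exp.truth.Q_true_J,
            "peak_power_W": exp.truth.peak_power_W,
            "peak_time_h": exp.truth.peak_time_h,
        }
        (OUT / f"{name}_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        if exp.cells is not None:
            pd.DataFrame(exp.cells, columns=["time_h", "cells_per_mL"]).to_csv(
                OUT / f"{name}_cells.csv", index=False)
        if exp.chemistry is not None:
            exp.chemistry.to_csv(OUT / f"{name}_chemistry.csv", index=False)
        print(f"{name}: Q_true = {exp.truth.Q_true_J:.4g} J, "
              f"peak = {exp.truth.peak_power_W * 1e9:.3g} nW "
              f"at {exp.truth.peak_time_h:.1f} h")


if __name__ == "__main__":
    main()
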