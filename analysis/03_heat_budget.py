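#!/usr/bin/env python
"""Convert the amino-acid amendment's total heat into catabolic budgets.

Takes Q = 0.0433 J (the corrected total heat of the 0.371 mM amino-acid
amendment; script 02 recovers this value from the synthetic pipeline within
a few tenths of a percent) and asks, for each of seven candidate catabolic
reactions, how many moles of key reactants would have to turn over — and how
much CO2 would be produced — to release that heat.  Standard-state reaction
enthalpies come from the bundled 25 °C formation-enthalpy table with a small
heat-capacity correction to the 28 °C incubation temperature.

Writes results/budget_table.csv.
"""

from pathlib import Path

from nanocal import thermo
from nanocal.budget import budget_frame, build_budget_table

Q_TOTAL_J = 0.0433
OUT = Path("results")


def main() -> None:
    table = thermo.load_thermo_table()
    reactions = thermo.candidate_reactions(table)
    budgets = build_budget_table(Q_TOTAL_J, reactions)
    frame = budget_frame(budgets, focus=("CO2",))
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "budget_table.csv", index=False)
    print(f"heat-to-moles budget for Q = {Q_TOTAL_J} J "
          f"(dH at 28 C, kJ/mol as written):")
    with_units = frame.copy()
    print(with_units.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(f"wrote {OUT / 'budget_table.csv'}")


if __name__ == "__main__":
    main()
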