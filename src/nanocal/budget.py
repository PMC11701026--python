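"""Convert measured heat into reaction turnover and screen candidate catabolisms.

Given the total baseline-corrected heat Q released in an ampule and a
candidate catabolic reaction with standard-state enthalpy ΔH_r°, the moles of
any participating species consumed or produced are

    n_s = |ν_s| · Q / (|ΔH_r°| · 1000)

with Q in joules and ΔH in kJ per mole of reaction as written.  Candidates
are then screened against observed chemistry changes: a reaction whose
predicted consumption/production differs from the measured change by more
than a configurable factor (default one order of magnitude) is flagged
inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .thermo import Reaction

__all__ = [
    "HeatBudget",
    "ObservedChemistry",
    "ScreenRow",
    "ScreenResult",
    "heat_to_moles",
    "build_budget_table",
    "screen_reactions",
    "budget_frame",
]


def heat_to_moles(Q: float, reaction: Reaction, dH: float, species: str) -> float:
    """Moles of ``species`` turned over while the reaction releases heat Q.

    Q in J (>= 0), dH in kJ per mole of reaction as written (nonzero).
    """
    if Q < 0:
        raise ValueError(f"Q must be non-negative, got {Q}")
    if dH == 0:
        raise ZeroDivisionError("reaction enthalpy is zero; heat fixes no turnover")
    nu = reaction.coefficient(species)  # raises SpeciesLookupError if absent
    return abs(nu) * Q / (abs(dH) * 1000.0)


@dataclass
class HeatBudget:
    """A reaction, a total heat, and the implied moles of every participant."""

    reaction: Reaction
    Q: float
    dH: float
    moles: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.reaction.label

    @property
    def extent(self) -> float:
        """Moles of reaction (as written) implied by Q."""
        return self.Q / (abs(self.dH) * 1000.0)


def build_budget_table(
    Q: float,
    reactions: Sequence[tuple[Reaction, float]],
    focus: Iterable[str] = (),
) -> list[HeatBudget]:
    """One :class:`HeatBudget` per (reaction, ΔH) pair at total heat Q.

    ``focus`` species that do not participate in a given reaction are simply
    absent from that budget's moles (rendered NA in the exported table).
    """
    if not reactions:
        raise ValueError("no reactions supplied")
    budgets = []
    for rxn, dh in reactions:
        moles = {s: heat_to_moles(Q, rxn, dh, s) for s in rxn.coeffs}
        budgets.append(HeatBudget(reaction=rxn, Q=Q, dH=dh, moles=moles))
    # focus species are only an export concern; validate they are known names
    for s in focus:
        if not isinstance(s, str):
            raise TypeError("focus must be species keys")
    return budgets


def budget_frame(
    budgets: Sequence[HeatBudget],
    focus: Sequence[str] = ("CO2",),
) -> pd.DataFrame:
    """Delimited-text-ready summary: one row per candidate reaction.

    Columns: reaction label, ΔH (kJ/mol), heat (J), moles consumed of each
    reactant, and a produced-moles column per focus species (NA where the
    species does not participate).
    """
    rows = []
    for b in budgets:
        consumed = {
            f"consumed_{s}_mol": m
            for s, m in sorted(b.moles.items())
            if b.reaction.coeffs[s] < 0 and s not in ("H2O", "H+")
        }
        row: dict[str, object] = {
            "reaction": b.label,
            "dH_kJ_per_mol": b.dH,
            "Q_J": b.Q,
            **consumed,
        }
        for s in focus:
            row[f"produced_{s}_mol"] = (
                b.moles[s] if s in b.reaction.coeffs and b.reaction.coeffs[s] > 0
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ObservedChemistry:
    """Measured changes in species inventory over an experiment, in moles.

    ``changes`` are signed totals per ampule (negative = consumed); values
    measured per mL must be multiplied by the ampule volume upstream.
    ``detection_floor`` gives, per species, the moles below which a change is
    indistinguishable from zero (0 means the measurement is exact).
    """

    changes: Mapping[str, float]
    detection_floor: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, f in self.detection_floor.items():
            if f < 0:
                raise ValueError(f"detection floor for {s} must be >= 0")

    def floor(self, species: str) -> float:
        return self.detection_floor.get(species, 0.0)


@dataclass
class ScreenRow:
    reaction: str
    species: str
    predicted_mol: float
    observed_mol: float
    ratio: float | None
    verdict: str  # consistent | inconsistent | indeterminate
    flag: str = ""


@dataclass
class ScreenResult:
    rows: list[ScreenRow]
    factor: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def verdicts(self) -> dict[tuple[str, str], str]:
        return {(r.reaction, r.species): r.verdict for r in self.rows}


def screen_reactions(
    budgets: Sequence[HeatBudget],
    observed: ObservedChemistry,
    factor: float = 10.0,
) -> ScreenResult:
    """Screen each budget against observed chemistry changes.

    For every species that is both in a budget and in ``observed``:

    * ``indeterminate`` — the observed change is below its detection floor
      (no ratio can be formed; a prediction below the floor is equally
      unconstrained, which is how "only a very low quantity would be
      required" reasoning stays open);
    * ``consistent`` — predicted/|observed| strictly within (1/factor, factor);
    * ``inconsistent`` — the ratio reaches or exceeds the factor either way.

    An observed change of exactly zero with no declared floor and a nonzero
    prediction is verdict inconsistent with flag ``at_floor``.
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    rows: list[ScreenRow] = []
    for b in budgets:
        for species, change in observed.changes.items():
            if species not in b.reaction.coeffs:
                continue
            predicted = b.moles[species]
            obs = abs(change)
            floor = observed.floor(species)
            if floor > 0 and obs < floor:
                rows.append(
                    ScreenRow(
                        b.label, species, predicted, change, None, "indeterminate",
                        flag="" if predicted < floor else "prediction_above_floor",
                    )
                )
                continue
            if obs == 0:
                if predicted > 0:
                    rows.append(
                        ScreenRow(b.label, species, predicted, change, None,
                                  "inconsistent", flag="at_floor")
                    )
                else:
                    rows.append(
                        ScreenRow(b.label, species, predicted, change, None,
                                  "indeterminate")
                    )
                continue
            ratio = predicted / obs
            verdict = "consistent" if (1.0 / factor) < ratio < factor else "inconsistent"
            rows.append(ScreenRow(b.label, species, predicted, change, ratio, verdict))
    return ScreenResult(rows=rows, factor=factor)
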