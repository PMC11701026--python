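"""Thermodynamic species data, reaction algebra, and standard-state reaction enthalpies.

The catabolic bookkeeping throughout this package rests on standard-state
enthalpies of reaction, ΔH_r°, computed from a bundled table of standard
formation enthalpies of aqueous/liquid species at 25 °C and 1 bar
(convention: ΔH_f(H⁺, aq) = 0 and ΔH_f(e⁻) = 0).  An optional constant-heat-
capacity correction moves ΔH_r° to the incubation temperature (28 °C by
default); over a 3 K span this correction is far smaller than the spread
between thermodynamic data sources.

Redox reactions are assembled from half reactions carrying explicit
electrons: an oxidation half releasing the full carbon content of an organic
electron donor as CO₂ (nitrogen is released as NH₄⁺ and sulfur as HS⁻, i.e.
only carbon is fully oxidized), and a reduction half for the terminal
electron acceptor (O₂ → H₂O, SO₄²⁻ → HS⁻, or NO₃⁻ → ½N₂).  For amino-acid
mixtures of unknown makeup (casamino acids), a nominal "AA" species is used:
the mole-fraction-weighted mean of the 20 common amino acids in the
proportions found in E. coli protein.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ThermoSpecies",
    "ThermoTable",
    "Reaction",
    "HalfReaction",
    "AminoAcidComposition",
    "BalanceReport",
    "parse_formula",
    "delta_h_reaction",
    "combine_half_reactions",
    "oxidation_half",
    "reduction_half",
    "mean_amino_acid_reaction",
    "validate_reaction",
    "candidate_reactions",
    "load_thermo_table",
    "ecoli_composition",
    "AMINO_ACIDS",
    "ELECTRON",
]

#: canonical species key of the explicit electron in half reactions
ELECTRON = "e-"

#: the 20 common amino acids, by the species names used in the bundled table
AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
)

_BALANCE_TOL = 1e-9
_COEFF_TOL = 1e-12

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class SpeciesLookupError(KeyError):
    """A reaction references a species absent from the thermodynamic table."""


class ReactionBalanceError(ValueError):
    """A reaction fails element or charge balance beyond tolerance."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-style formula string (no parentheses) into element counts.

    ``"C3H7NO2S"`` -> ``{"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}``.
    An empty string (the electron) parses to an empty map.
    """
    out: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        out[el] = out.get(el, 0.0) + (float(n) if n else 1.0)
    if pos != len(formula.strip()):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


@dataclass(frozen=True)
class ThermoSpecies:
    """One thermodynamic species with its standard-state formation enthalpy.

    dHf25 is the standard formation enthalpy at 25 °C / 1 bar in kJ/mol;
    cp is an optional standard (partial molal) heat capacity in J/(mol K)
    used for the small correction to the experimental temperature.
    """

    name: str
    formula: Mapping[str, float]
    charge: int
    state: str  # aqueous | liquid | gas
    dHf25: float
    cp: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.state not in ("aqueous", "liquid", "gas"):
            raise ValueError(f"{self.name}: unknown state {self.state!r}")
        if not math.isfinite(self.dHf25):
            raise ValueError(f"{self.name}: dHf25 must be finite")
        if self.charge != int(self.charge):
            raise ValueError(f"{self.name}: charge must be an integer")
        if not self.formula and self.name != ELECTRON:
            raise ValueError(f"{self.name}: empty formula")


class ThermoTable:
    """A collection of :class:`ThermoSpecies`, keyed by species name.

    ``(name, state)`` pairs must be unique; in the bundled table names are
    themselves unique, so plain names serve as reaction keys.
    """

    def __init__(self, species: Iterable[ThermoSpecies]):
        self._species: dict[str, ThermoSpecies] = {}
        seen: set[tuple[str, str]] = set()
        for sp in species:
            if (sp.name, sp.state) in seen:
                raise ValueError(f"duplicate species ({sp.name}, {sp.state})")
            seen.add((sp.name, sp.state))
            if sp.name in self._species:
                raise ValueError(f"duplicate species key {sp.name!r}")
            self._species[sp.name] = sp

    def __contains__(self, key: str) -> bool:
        return key in self._species

    def __getitem__(self, key: str) -> ThermoSpecies:
        try:
            return self._species[key]
        except KeyError:
            raise SpeciesLookupError(
                f"species {key!r} not in thermodynamic table"
            ) from None

    def __iter__(self):
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    def add(self, sp: ThermoSpecies, replace_existing: bool = False) -> None:
        if sp.name in self._species and not replace_existing:
            raise ValueError(f"species {sp.name!r} already present")
        self._species[sp.name] = sp

    def names(self) -> list[str]:
        return list(self._species)


@dataclass(frozen=True)
class Reaction:
    """A chemical reaction as a signed stoichiometric map over species keys.

    Negative coefficients are consumed (reactants), positive are produced.
    """

    coeffs: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        clean = {k: float(v) for k, v in self.coeffs.items() if abs(v) > _COEFF_TOL}
        object.__setattr__(self, "coeffs", clean)

    @property
    def reactants(self) -> dict[str, float]:
        return {k: -v for k, v in self.coeffs.items() if v < 0}

    @property
    def products(self) -> dict[str, float]:
        return {k: v for k, v in self.coeffs.items() if v > 0}

    def coefficient(self, species: str) -> float:
        if species not in self.coeffs:
            raise SpeciesLookupError(f"species {species!r} not in reaction {self.label!r}")
        return self.coeffs[species]

    def reversed(self, label: str | None = None) -> "Reaction":
        return Reaction({k: -v for k, v in self.coeffs.items()},
                        label if label is not None else f"reverse({self.label})")

    def scaled(self, factor: float, label: str | None = None) -> "Reaction":
        return Reaction({k: v * factor for k, v in self.coeffs.items()},
                        label if label is not None else self.label)

    def __add__(self, other: "Reaction") -> "Reaction":
        coeffs = dict(self.coeffs)
        for k, v in other.coeffs.items():
            coeffs[k] = coeffs.get(k, 0.0) + v
        return Reaction(coeffs, f"{self.label}+{other.label}".strip("+"))


@dataclass(frozen=True)
class HalfReaction:
    """A redox half reaction with the electron as an explicit species.

    Convention: oxidation halves *produce* electrons (positive e⁻
    coefficient), reduction halves *consume* them (negative).
    """

    reaction: Reaction
    n_electrons: float

    def __post_init__(self) -> None:
        ecoeff = self.reaction.coeffs.get(ELECTRON, 0.0)
        if abs(ecoeff) <= _COEFF_TOL:
            raise ValueError("half reaction carries no electrons")
        if not math.isclose(abs(ecoeff), self.n_electrons, rel_tol=1e-12):
            raise ValueError(
                f"n_electrons={self.n_electrons} does not match electron "
                f"coefficient {ecoeff}"
            )

    @property
    def is_oxidation(self) -> bool:
        return self.reaction.coeffs[ELECTRON] > 0

    def per_electron(self) -> Reaction:
        return self.reaction.scaled(1.0 / self.n_electrons)


@dataclass(frozen=True)
class AminoAcidComposition:
    """Mole fractions over the 20 common amino acids (must sum to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.fractions) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.fractions)
            extra = set(self.fractions) - set(AMINO_ACIDS)
            raise ValueError(
                f"composition must cover exactly the 20 amino acids "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("mole fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _BALANCE_TOL:
            raise ValueError(f"mole fractions sum to {total}, not 1")


@dataclass
class BalanceReport:
    """Per-element and charge imbalance of a reaction (products - reactants)."""

    element_imbalance: dict[str, float]
    charge_imbalance: float
    tol: float = _BALANCE_TOL

    @property
    def max_abs_imbalance(self) -> float:
        vals = list(self.element_imbalance.values()) + [self.charge_imbalance]
        return max((abs(v) for v in vals), default=0.0)

    @property
    def balanced(self) -> bool:
        return self.max_abs_imbalance < self.tol


# ---------------------------------------------------------------------------
# bundled data
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("nanocal.data").joinpath(name)

_REQUIRED_ROSTER = (
    "H2O", "O2", "H2", "CO2", "N2", "SO4-2", "HS-", "NO3-", "NH4+", "H+",
    "acetate", ELECTRON,
) + AMINO_ACIDS


def load_thermo_table(path=None) -> ThermoTable:
    """Load the (bundled, by default) formation-enthalpy table.

    The delimited resource has columns name, state, formula, charge,
    dHf25_kJ_per_mol, cp_J_per_mol_K, source.  The loaded table is validated
    against the roster of species every bundled reaction needs.
    """
    src = path if path is not None else _data_path("formation_enthalpies.csv")
    ctx = resources.as_file(src) if path is None else _nullctx(src)
    with ctx as p:
        df = pd.read_csv(p, dtype={"formula": "string"})
    species = [
        ThermoSpecies(
            name=str(row["name"]),
            formula=parse_formula("" if pd.isna(row["formula"]) else str(row["formula"])),
            charge=int(row["charge"]),
            state=str(row["state"]),
            dHf25=float(row["dHf25_kJ_per_mol"]),
            cp=None if pd.isna(row["cp_J_per_mol_K"]) else float(row["cp_J_per_mol_K"]),
            source=str(row["source"]),
        )
        for _, row in df.iterrows()
    ]
    table = ThermoTable(species)
    missing = [k for k in _REQUIRED_ROSTER if k not in table]
    if missing:
        raise ValueError(f"thermodynamic table is missing required species: {missing}")
    return table


class _nullctx:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def ecoli_composition(path=None) -> AminoAcidComposition:
    """The bundled E. coli protein amino-acid composition, as mole fractions."""
    src = path if path is not None else _data_path("ecoli_aa_composition.csv")
    ctx = resources.as_file(src) if path is None else _nullctx(src)
    with ctx as p:
        df = pd.read_csv(p)
    total = df["mole_percent"].sum()
    return AminoAcidComposition(
        {str(r["name"]): float(r["mole_percent"]) / total for _, r in df.iterrows()}
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def validate_reaction(reaction: Reaction, table: ThermoTable) -> BalanceReport:
    """Report per-element and charge imbalance (products minus reactants)."""
    elements: dict[str, float] = {}
    charge = 0.0
    for key, coeff in reaction.coeffs.items():
        sp = table[key]
        for el, n in sp.formula.items():
            elements[el] = elements.get(el, 0.0) + coeff * n
        charge += coeff * sp.charge
    return BalanceReport(element_imbalance=elements, charge_imbalance=charge)


def delta_h_reaction(
    reaction: Reaction,
    table: ThermoTable,
    temperature_C: float = 28.0,
) -> float:
    """Standard-state enthalpy of reaction in kJ per mole of reaction as written.

    Computed as Σ ν_i ΔH_f,i(25 °C) plus a constant-cp correction
    Σ ν_i cp_i (T - 25 °C) over the species that carry heat-capacity data.
    Exothermic reactions return negative values.
    """
    if not (0.0 <= temperature_C <= 100.0):
        raise ValueError(f"temperature {temperature_C} °C outside 0-100 °C")
    has_reactant = any(v < 0 for v in reaction.coeffs.values())
    has_product = any(v > 0 for v in reaction.coeffs.values())
    if reaction.coeffs and not (has_reactant and has_product):
        raise ReactionBalanceError(
            f"reaction {reaction.label!r} needs at least one reactant and one product"
        )
    report = validate_reaction(reaction, table)
    if not report.balanced:
        raise ReactionBalanceError(
            f"reaction {reaction.label!r} unbalanced: "
            f"elements={report.element_imbalance}, charge={report.charge_imbalance}"
        )
    dh = sum(coeff * table[key].dHf25 for key, coeff in reaction.coeffs.items())
    dT = temperature_C - 25.0
    dcp = sum(
        coeff * table[key].cp
        for key, coeff in reaction.coeffs.items()
        if table[key].cp is not None
    )
    return dh + dcp * dT / 1000.0


def combine_half_reactions(
    oxidation: HalfReaction,
    reduction: HalfReaction,
    normalize: tuple[str, float] | None = None,
) -> Reaction:
    """Combine an oxidation and a reduction half into an electron-free reaction.

    Both halves are first normalized per electron and summed (the electron
    cancels exactly), then the result is rescaled.  By default the reduction
    half retains its as-given stoichiometry (so an acceptor written with
    coefficient 1 appears with coefficient 1); pass ``normalize=(species,
    coeff)`` to pin another species instead, e.g. ``("H2", -1.0)`` for the
    knallgas reaction written per mole of H₂.
    """
    if not oxidation.is_oxidation:
        raise ValueError("first argument must be an oxidation half (produces e-)")
    if reduction.is_oxidation:
        raise ValueError("second argument must be a reduction half (consumes e-)")
    per_e = oxidation.per_electron() + reduction.per_electron()
    if abs(per_e.coeffs.get(ELECTRON, 0.0)) > _COEFF_TOL:  # pragma: no cover
        raise AssertionError("electrons did not cancel")
    if normalize is None:
        scale = reduction.n_electrons
    else:
        species, target = normalize
        current = per_e.coefficient(species)
        scale = target / current
    combined = per_e.scaled(scale)
    return Reaction(combined.coeffs,
                    label=f"{oxidation.reaction.label} | {reduction.reaction.label}")


def oxidation_half(species: str, table: ThermoTable) -> HalfReaction:
    """Oxidation half reaction fully oxidizing a CHNOS donor's carbon to CO₂.

    Carbon goes to CO₂(aq); nitrogen is released as NH₄⁺ and sulfur as HS⁻
    (neither is oxidized); oxygen and hydrogen are balanced with H₂O and H⁺.
    Works for any species composed of C, H, N, O, S, including H₂ itself.
    """
    sp = table[species]
    f = sp.formula
    unknown = set(f) - {"C", "H", "N", "O", "S"}
    if unknown:
        raise ValueError(f"{species}: cannot build oxidation half with elements {unknown}")
    c = f.get("C", 0.0)
    h = f.get("H", 0.0)
    n = f.get("N", 0.0)
    o = f.get("O", 0.0)
    s = f.get("S", 0.0)
    water = 2.0 * c - o                    # H2O consumed to supply oxygen
    protons = h + 2.0 * water - 4.0 * n - s
    electrons = n - s + protons - sp.charge
    if electrons <= 0:
        raise ValueError(f"{species}: no electrons released by carbon oxidation")
    coeffs: dict[str, float] = {species: -1.0, "H2O": -water, "H+": protons,
                                ELECTRON: electrons}
    if c:
        coeffs["CO2"] = c
    if n:
        coeffs["NH4+"] = n
    if s:
        coeffs["HS-"] = s
    return HalfReaction(Reaction(coeffs, label=f"{species} oxidation"), electrons)


_REDUCTION_HALVES = {
    "O2": ({"O2": -1.0, "H+": -4.0, ELECTRON: -4.0, "H2O": 2.0}, 4.0),
    "SO4": ({"SO4-2": -1.0, "H+": -9.0, ELECTRON: -8.0, "HS-": 1.0, "H2O": 4.0}, 8.0),
    "NO3": ({"NO3-": -1.0, "H+": -6.0, ELECTRON: -5.0, "N2": 0.5, "H2O": 3.0}, 5.0),
}


def reduction_half(acceptor: str) -> HalfReaction:
    """Reduction half for a terminal electron acceptor: O2, SO4 or NO3."""
    try:
        coeffs, n_e = _REDUCTION_HALVES[acceptor]
    except KeyError:
        raise ValueError(
            f"unknown acceptor {acceptor!r}; choose from {sorted(_REDUCTION_HALVES)}"
        ) from None
    return HalfReaction(Reaction(dict(coeffs), label=f"{acceptor} reduction"), n_e)


def mean_amino_acid_reaction(
    composition: AminoAcidComposition,
    acceptor: str,
    table: ThermoTable,
    temperature_C: float = 28.0,
) -> tuple[Reaction, float]:
    """Oxidation of the nominal mean amino acid ("AA") by a terminal acceptor.

    Builds each amino acid's carbon-oxidation half, takes the mole-fraction-
    weighted mean half (per mole of mean amino acid), combines it with the
    acceptor's reduction half, and normalizes the full reaction per mole of
    electron acceptor.  A pseudo-species ``AA`` with the weighted mean
    formula and formation enthalpy is registered in ``table`` so the
    returned reaction balances and its ΔH can be recomputed from the table.

    Returns ``(reaction, ΔH)`` with ΔH in kJ per mole of acceptor.
    """
    halves = {aa: oxidation_half(aa, table) for aa in AMINO_ACIDS}
    # weighted mean oxidation half, per 1 mol of nominal amino acid
    mean_coeffs: dict[str, float] = {}
    mean_formula: dict[str, float] = {}
    mean_dhf = 0.0
    mean_cp_known = all(table[aa].cp is not None for aa in AMINO_ACIDS)
    mean_cp = 0.0
    for aa, x in composition.fractions.items():
        half = halves[aa]
        for key, coeff in half.reaction.coeffs.items():
            if key == aa:
                continue  # folded into the nominal AA species
            mean_coeffs[key] = mean_coeffs.get(key, 0.0) + x * coeff
        for el, cnt in table[aa].formula.items():
            mean_formula[el] = mean_formula.get(el, 0.0) + x * cnt
        mean_dhf += x * table[aa].dHf25
        if mean_cp_known:
            mean_cp += x * table[aa].cp  # type: ignore[operator]
    mean_coeffs["AA"] = -1.0
    n_e = mean_coeffs[ELECTRON]
    table.add(
        ThermoSpecies(
            name="AA",
            formula=mean_formula,
            charge=0,
            state="aqueous",
            dHf25=mean_dhf,
            cp=mean_cp if mean_cp_known else None,
            source="mole-fraction-weighted mean amino acid",
        ),
        replace_existing=True,
    )
    mean_half = HalfReaction(
        Reaction(mean_coeffs, label="AA oxidation (weighted mean)"), n_e
    )
    red = reduction_half(acceptor)
    reaction = combine_half_reactions(mean_half, red)
    acceptor_key = {"O2": "O2", "SO4": "SO4-2", "NO3": "NO3-"}[acceptor]
    reaction = Reaction(reaction.coeffs, label=f"AA oxidation by {acceptor}")
    # sanity: per-acceptor normalization
    assert math.isclose(reaction.coefficient(acceptor_key), -1.0, rel_tol=1e-9)
    dh = delta_h_reaction(reaction, table, temperature_C=temperature_C)
    return reaction, dh


# ---------------------------------------------------------------------------
# the seven candidate heat-source reactions
# ---------------------------------------------------------------------------

def stickland_reaction() -> Reaction:
    """Stickland fermentation of alanine with two glycines (all aqueous)."""
    return Reaction(
        {
            "alanine": -1.0,
            "glycine": -2.0,
            "H2O": -2.0,
            "CO2": 1.0,
            "acetate": 3.0,
            "NH4+": 3.0,
        },
        label="Stickland: alanine + 2 glycine",
    )


def knallgas_reaction() -> Reaction:
    """0.5 O2(aq) + H2(aq) -> H2O(l), written per mole of H2."""
    return Reaction({"O2": -0.5, "H2": -1.0, "H2O": 1.0}, label="knallgas: H2 + 0.5 O2")


def h2_sulfate_reaction() -> Reaction:
    """SO4^2- + 4 H2(aq) + H+ -> HS- + 4 H2O."""
    return Reaction(
        {"SO4-2": -1.0, "H2": -4.0, "H+": -1.0, "HS-": 1.0, "H2O": 4.0},
        label="sulfate reduction with H2",
    )


def h2_nitrate_reaction() -> Reaction:
    """NO3- + 2.5 H2(aq) + H+ -> 0.5 N2(aq) + 3 H2O."""
    return Reaction(
        {"NO3-": -1.0, "H2": -2.5, "H+": -1.0, "N2": 0.5, "H2O": 3.0},
        label="nitrate reduction with H2",
    )


def candidate_reactions(
    table: ThermoTable,
    composition: AminoAcidComposition | None = None,
    temperature_C: float = 28.0,
) -> list[tuple[Reaction, float]]:
    """The seven candidate catabolic reactions with their ΔH_r° (kJ/mol).

    Order: Stickland; AA + O2; AA + SO4; AA + NO3; knallgas; H2 + SO4;
    H2 + NO3.  Amino-acid reactions are per mole of electron acceptor and use
    the nominal mean amino acid; the others are as conventionally written.
    """
    comp = composition if composition is not None else ecoli_composition()
    out: list[tuple[Reaction, float]] = []
    for rxn in (stickland_reaction(),):
        out.append((rxn, delta_h_reaction(rxn, table, temperature_C)))
    for acceptor in ("O2", "SO4", "NO3"):
        out.append(mean_amino_acid_reaction(comp, acceptor, table, temperature_C))
    for rxn in (knallgas_reaction(), h2_sulfate_reaction(), h2_nitrate_reaction()):
        out.append((rxn, delta_h_reaction(rxn, table, temperature_C)))
    return out
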