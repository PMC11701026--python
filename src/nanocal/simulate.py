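"""Seeded synthetic thermograms, growth curves, and coupled chemistry series.

The study's raw calorimeter exports are not deposited, so every pipeline
stage is exercised against synthetic experiments with known ground truth.
A synthetic thermogram is the sum of

* an ampule-insertion artifact — a decaying power law a·t^b plus a constant
  instrument offset c (the same family the power-function correction fits;
  an exponential mode is included to test the fit under misspecification);
* a biological component — a sustained plateau plus one or more bursts
  (Gaussian or logistic-burst, i.e. sech², shapes: single-peaked tailed
  pulses like those seen after substrate amendment);
* white Gaussian instrument noise near the ~1.2 nW/mL detection limit.

The generator carries analytic (closed-form) integrals of the noise-free
biological component, so recovered peak powers and total heats can be judged
against exact truth, and the integrator (trapezoid) is checked against an
independent code path (erf/tanh closed forms).  Cell growth is logistic;
chemistry changes are tied to the cumulative biological heat through a
coupling reaction and its enthalpy, so synthetic substrate consumption obeys
the same heat-to-moles arithmetic the analysis applies.

Bundled presets (YAML) parameterize the scenarios the analysis targets:
``unamended_demmo6`` (a ~100 nW plateau), ``formate`` (oscillating burst),
``acetate_nitrate`` (slow ~175 nW rise), and ``aa_0371mM`` (the amino-acid
amendment: 2.25 µW peak near 32.5 h, 0.0433 J total biological heat,
20 nW noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.special import erf

from . import thermo
from .thermo import Reaction
from .thermogram import Thermogram

__all__ = [
    "Peak",
    "ArtifactSpec",
    "GrowthSpec",
    "CouplingSpec",
    "SimConfig",
    "SyntheticTruth",
    "SyntheticExperiment",
    "simulate_thermogram",
    "simulate_growth_and_chemistry",
    "load_preset",
    "list_presets",
    "coupling_reaction",
]

SECONDS_PER_HOUR = 3600.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """One biological heat burst: gaussian or logistic_burst (sech²)."""

    shape: str
    amplitude_W: float
    center_h: float
    width_h: float

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "logistic_burst"):
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if self.amplitude_W < 0 or self.width_h <= 0:
            raise ValueError("peak amplitude must be >= 0 and width > 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        u = (t - self.center_h) / self.width_h
        if self.shape == "gaussian":
            return self.amplitude_W * np.exp(-0.5 * u * u)
        return self.amplitude_W / np.cosh(u) ** 2

    def integral_h(self, lo: float, hi: float) -> float:
        """Exact integral in W·h over [lo, hi] (closed form)."""
        A, c, w = self.amplitude_W, self.center_h, self.width_h
        if self.shape == "gaussian":
            s = math.sqrt(2.0) * w
            return A * w * math.sqrt(math.pi / 2.0) * (
                erf((hi - c) / s) - erf((lo - c) / s)
            )
        return A * w * (math.tanh((hi - c) / w) - math.tanh((lo - c) / w))


@dataclass(frozen=True)
class ArtifactSpec:
    """Insertion transient: a·t^b + c (power) or a·e^{b·t} + c (exponential)."""

    a: float = 0.0
    b: float = -1.0
    c: float = 0.0
    shape: str = "power"

    def __post_init__(self) -> None:
        if self.shape not in ("power", "exponential"):
            raise ValueError(f"unknown artifact shape {self.shape!r}")
        if self.shape == "power" and self.b >= 0 and self.a != 0:
            raise ValueError("power-law artifact must decay (b < 0)")
        if self.shape == "exponential" and self.b >= 0 and self.a != 0:
            raise ValueError("exponential artifact must decay (b < 0)")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.shape == "power":
            return self.a * np.power(t, self.b) + self.c
        return self.a * np.exp(self.b * t) + self.c


@dataclass(frozen=True)
class GrowthSpec:
    """Logistic growth parameters: N(t) = K / (1 + ((K−N0)/N0)·e^{−r·t})."""

    N0: float
    K: float
    r: float

    def __post_init__(self) -> None:
        if self.N0 <= 0 or self.K <= 0:
            raise ValueError("N0 and K must be positive")
        if self.N0 > self.K:
            raise ValueError("N0 must not exceed the carrying capacity K")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.K / (1.0 + ((self.K - self.N0) / self.N0) * np.exp(-self.r * t))


@dataclass(frozen=True)
class CouplingSpec:
    """Ties biological heat to chemistry through one catabolic reaction.

    ``reaction`` is a registry label (see :func:`coupling_reaction`); ``dH``
    in kJ per mole of reaction as written (None: computed from the bundled
    thermodynamic table at 28 °C); ``substrate`` is the tracked reactant and
    ``S0_mol`` its initial inventory in the ampule.
    """

    reaction: str
    substrate: str
    S0_mol: float
    dH_kJ_per_mol: float | None = None

    def __post_init__(self) -> None:
        if self.S0_mol < 0:
            raise ValueError("S0_mol must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic calorimetric experiment."""

    duration_h: float
    dt_h: float
    artifact: ArtifactSpec = ArtifactSpec()
    peaks: tuple[Peak, ...] = ()
    plateau_W: float = 0.0
    noise_sd_W: float = 0.0
    growth: GrowthSpec | None = None
    coupling: CouplingSpec | None = None
    seed: int = 0
    volume_mL: float = 2.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if self.duration_h <= self.dt_h:
            raise ValueError("duration_h must exceed dt_h")
        if self.noise_sd_W < 0:
            raise ValueError("noise_sd_W must be >= 0")
        if self.plateau_W < 0:
            raise ValueError("plateau_W must be >= 0")

    @property
    def times_h(self) -> np.ndarray:
        """Sample grid: from one sampling interval to the duration."""
        n = int(round(self.duration_h / self.dt_h))
        return self.dt_h * np.arange(1, n + 1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        art = d.pop("artifact", None)
        peaks = d.pop("peaks", [])
        growth = d.pop("growth", None)
        coupling = d.pop("coupling", None)
        return cls(
            artifact=ArtifactSpec(**art) if art else ArtifactSpec(),
            peaks=tuple(Peak(**p) for p in peaks),
            growth=GrowthSpec(**growth) if growth else None,
            coupling=CouplingSpec(**coupling) if coupling else None,
            **d,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peaks"] = [asdict(p) for p in self.peaks]
        return d


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Noise-free ground truth of a synthetic experiment.

    Q_true_J is the analytic integral of the biological component (plateau +
    peaks, artifact excluded) over the record; peak values refer to the
    noise-free biological signal.
    """

    Q_true_J: float
    peak_power_W: float
    peak_time_h: float
    artifact: ArtifactSpec
    bio_cumulative_J: np.ndarray = field(repr=False, default=None)


@dataclass
class SyntheticExperiment:
    thermogram: Thermogram
    truth: SyntheticTruth
    cells: np.ndarray | None = None        # columns: time_h, cells_per_mL
    chemistry: "object | None" = None      # DataFrame: time_h, species, delta_mol
    coupling_reaction: Reaction | None = None
    coupling_dH: float | None = None


# ---------------------------------------------------------------------------
# coupling-reaction registry
# ---------------------------------------------------------------------------

def _formate_o2() -> Reaction:
    return Reaction(
        {"formate": -1.0, "O2": -0.5, "H+": -1.0, "CO2": 1.0, "H2O": 1.0},
        label="formate oxidation by O2",
    )


def _acetate_nitrate() -> Reaction:
    full = thermo.combine_half_reactions(
        thermo.oxidation_half("acetate", thermo.load_thermo_table()),
        thermo.reduction_half("NO3"),
    )
    return Reaction(full.coeffs, label="acetate oxidation by nitrate")


_REACTION_REGISTRY = {
    "knallgas": thermo.knallgas_reaction,
    "h2_sulfate": thermo.h2_sulfate_reaction,
    "h2_nitrate": thermo.h2_nitrate_reaction,
    "stickland": thermo.stickland_reaction,
    "formate_o2": _formate_o2,
    "acetate_nitrate": _acetate_nitrate,
}


def coupling_reaction(label: str) -> Reaction:
    """Resolve a coupling-registry label to its reaction."""
    try:
        return _REACTION_REGISTRY[label]()
    except KeyError:
        raise ValueError(
            f"unknown coupling reaction {label!r}; "
            f"choose from {sorted(_REACTION_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _bio_power(config: SimConfig, t: np.ndarray) -> np.ndarray:
    p = np.full(t.shape, config.plateau_W)
    for peak in config.peaks:
        p = p + peak.evaluate(t)
    return p


def _bio_cumulative_J(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form cumulative biological heat (J) at each sample time."""
    t0 = float(t[0])
    cum = config.plateau_W * (t - t0)
    for peak in config.peaks:
        cum = cum + np.array([peak.integral_h(t0, ti) for ti in t])
    return cum * SECONDS_PER_HOUR


def simulate_thermogram(config: SimConfig) -> SyntheticExperiment:
    """Generate one synthetic experiment: thermogram + analytic ground truth.

    The thermogram is artifact + plateau + peaks + white noise (seeded);
    truth carries the exact biological heat and peak location.  If the
    config includes growth/coupling parameters, the cell and chemistry
    series are attached as well.
    """
    t = config.times_h
    rng = np.random.default_rng(config.seed)
    bio = _bio_power(config, t)
    signal = config.artifact.evaluate(t) + bio
    noise = rng.normal(0.0, config.noise_sd_W, size=t.shape) if config.noise_sd_W else 0.0
    tg = Thermogram(
        t=t.copy(),
        p=signal + noise,
        volume_mL=config.volume_mL,
        label=config.label,
    )
    peak_idx = int(np.argmax(bio))
    truth = SyntheticTruth(
        Q_true_J=float(_bio_cumulative_J(config, t)[-1]),
        peak_power_W=float(bio[peak_idx]),
        peak_time_h=float(t[peak_idx]),
        artifact=config.artifact,
        bio_cumulative_J=_bio_cumulative_J(config, t),
    )
    exp = SyntheticExperiment(thermogram=tg, truth=truth)
    if config.growth is not None or config.coupling is not None:
        _attach_growth_and_chemistry(config, exp)
    return exp


def _attach_growth_and_chemistry(config: SimConfig, exp: SyntheticExperiment) -> None:
    import pandas as pd

    t = config.times_h
    if config.growth is not None:
        cells = config.growth.evaluate(t - t[0])
        exp.cells = np.column_stack([t, cells])
    if config.coupling is not None:
        rxn = coupling_reaction(config.coupling.reaction)
        dh = config.coupling.dH_kJ_per_mol
        if dh is None:
            dh = thermo.delta_h_reaction(rxn, thermo.load_thermo_table())
        q_cum = exp.truth.bio_cumulative_J
        extent = q_cum / (abs(dh) * 1000.0)  # mol of reaction at each time
        sub = config.coupling.substrate
        nu_sub = rxn.coefficient(sub)
        consumed_total = abs(nu_sub) * extent[-1]
        if consumed_total > config.coupling.S0_mol * (1 + 1e-9):
            raise ValueError(
                f"coupled heat would consume {consumed_total:.3e} mol of {sub}, "
                f"more than the initial inventory {config.coupling.S0_mol:.3e} mol"
            )
        frames = []
        for species, nu in rxn.coeffs.items():
            frames.append(pd.DataFrame({
                "time_h": t,
                "species": species,
                "delta_mol": nu * extent,
            }))
        exp.chemistry = pd.concat(frames, ignore_index=True)
        exp.coupling_reaction = rxn
        exp.coupling_dH = float(dh)


def simulate_growth_and_chemistry(config: SimConfig) -> SyntheticExperiment:
    """Growth + chemistry series only (thermogram included for the heat tie-in)."""
    if config.growth is None and config.coupling is None:
        raise ValueError("config has neither growth nor coupling parameters")
    return simulate_thermogram(config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def list_presets() -> list[str]:
    root = resources.files("nanocal.data").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, seed: int | None = None) -> SimConfig:
    """Load a bundled scenario preset; optionally override its seed."""
    root = resources.files("nanocal.data").joinpath("presets")
    path = root.joinpath(f"{name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ValueError(
            f"unknown preset {name!r}; available: {list_presets()}"
        ) from None
    d = yaml.safe_load(text)
    if seed is not None:
        d["seed"] = int(seed)
    d.setdefault("label", name)
    return SimConfig.from_dict(d)
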