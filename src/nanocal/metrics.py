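"""Scalar activity metrics: per-cell power, detectability, VPR, concentration units.

These are the small arithmetic conversions that turn corrected calorimetric
and microscopy observations into interpretable activity statements: the
metabolic power of a single cell, whether a site's predicted heat flow
clears the instrument's detection limit (~1.2 nW per mL of sample), the
virus-to-prokaryote ratio as a proxy for host activity, and the %-w/v to
molar conversion for casamino-acid amendments (mean molecular weight
539.583 g/mol).  Computation is in SI (watts, moles); report helpers render
the conventional nW/pW units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "CountObservation",
    "SitePrediction",
    "per_cell_power",
    "predict_site_power",
    "vpr",
    "vpr_summary",
    "casamino_to_molar",
    "molar_to_casamino",
    "CASAMINO_MEAN_MW",
    "DEFAULT_LOD_NW_PER_ML",
]

#: manufacturer mean molecular weight of casamino acids, g/mol
CASAMINO_MEAN_MW = 539.583

#: nanocalorimeter limit of detection, nW per mL of sample
DEFAULT_LOD_NW_PER_ML = 1.2


@dataclass(frozen=True)
class CountObservation:
    """Prokaryote and virus-like-particle densities at one site."""

    prokaryotes_per_mL: float
    viruses_per_mL: float
    site: str = ""
    depth_m: float = float("nan")

    def __post_init__(self) -> None:
        if self.prokaryotes_per_mL < 0 or self.viruses_per_mL < 0:
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class SitePrediction:
    """Predicted per-mL heat flow at a site and its detectability."""

    per_cell_power_W: float
    density_per_mL: float
    predicted_power_nW_per_mL: float
    lod_nW_per_mL: float = DEFAULT_LOD_NW_PER_ML

    @property
    def detectable(self) -> bool:
        return self.predicted_power_nW_per_mL >= self.lod_nW_per_mL

    def ampule_power_nW(self, volume_mL: float = 2.0) -> float:
        """Whole-ampule heat flow at the given sample volume."""
        return self.predicted_power_nW_per_mL * volume_mL


def per_cell_power(total_power_W: float, total_cells: float) -> float:
    """Metabolic power per cell, W/cell (e.g. 100 nW / 5.2e5 cells ≈ 0.19 pW)."""
    if total_cells <= 0:
        raise ZeroDivisionError("total_cells must be positive")
    if total_power_W < 0:
        raise ValueError("total power must be non-negative")
    return total_power_W / total_cells


def predict_site_power(
    per_cell_W: float,
    density_per_mL: float,
    lod_nW_per_mL: float = DEFAULT_LOD_NW_PER_ML,
) -> SitePrediction:
    """Per-mL heat-flow prediction from a per-cell power and a cell density."""
    if per_cell_W < 0 or density_per_mL < 0:
        raise ValueError("inputs must be non-negative")
    predicted_nw = per_cell_W * density_per_mL * 1e9
    return SitePrediction(
        per_cell_power_W=per_cell_W,
        density_per_mL=density_per_mL,
        predicted_power_nW_per_mL=predicted_nw,
        lod_nW_per_mL=lod_nW_per_mL,
    )


def vpr(observation: CountObservation) -> float:
    """Virus-to-prokaryote ratio for one observation."""
    if observation.prokaryotes_per_mL == 0:
        raise ZeroDivisionError(
            f"VPR undefined at {observation.site!r}: zero prokaryote density"
        )
    return observation.viruses_per_mL / observation.prokaryotes_per_mL


def vpr_summary(observations: Iterable[CountObservation]) -> pd.DataFrame:
    """Per-site VPR plus a summary row with the mean, min and max.

    The result is order-invariant in the summary statistics; per-site rows
    are sorted by site label.
    """
    obs = sorted(observations, key=lambda o: o.site)
    if not obs:
        raise ValueError("no observations")
    rows = [
        {
            "site": o.site,
            "depth_m": o.depth_m,
            "prokaryotes_per_mL": o.prokaryotes_per_mL,
            "viruses_per_mL": o.viruses_per_mL,
            "vpr": vpr(o),
        }
        for o in obs
    ]
    df = pd.DataFrame(rows)
    summary = {
        "site": "ALL (mean)",
        "depth_m": float("nan"),
        "prokaryotes_per_mL": float("nan"),
        "viruses_per_mL": float("nan"),
        "vpr": df["vpr"].mean(),
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def casamino_to_molar(percent_w_v: float) -> float:
    """Convert a casamino-acid % w/v to mM (0.02 % w/v ≈ 0.371 mM)."""
    if percent_w_v < 0:
        raise ValueError("percent w/v must be non-negative")
    grams_per_L = percent_w_v * 10.0  # 1 % w/v = 10 g/L
    return grams_per_L / CASAMINO_MEAN_MW * 1000.0


def molar_to_casamino(mM: float) -> float:
    """Inverse of :func:`casamino_to_molar`."""
    if mM < 0:
        raise ValueError("concentration must be non-negative")
    return mM * CASAMINO_MEAN_MW / 1000.0 / 10.0
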