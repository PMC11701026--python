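"""Heat-flow time series: baseline correction and feature extraction.

A thermogram is the heat flow (power) of one 2 mL ampule versus time.  Two
artifact-removal strategies are provided, mirroring practice with TAM-class
isothermal calorimeters:

* the *synchronization method* — align records on the ampule-insertion
  transient (the sharpest |dP/dt| early in the record), then discard
  everything before the transient has demonstrably settled; used when the
  biological signal is too small to separate from the artifact by fitting;
* the *power-function method* — fit f(t) = a·t^b + c to the initial and
  final segments of the record (where the signal is artifact + instrument
  offset only) and subtract it everywhere; used when a large biological
  peak sits on top of the decaying artifact.

All corrections act through the per-point mask and stored fits; raw samples
are never deleted, so any correction is reversible.  Time is kept in hours
(the plotting convention), power in watts; integration converts to seconds
internally and reports joules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .metrics import DEFAULT_LOD_NW_PER_ML

__all__ = [
    "Thermogram",
    "BaselineFit",
    "FeatureSet",
    "SyncConfig",
    "ThermogramError",
    "synchronize_group",
    "fit_power_baseline",
    "subtract_baseline",
    "cumulative_heat",
    "extract_features",
    "default_fit_windows",
]

SECONDS_PER_HOUR = 3600.0


class ThermogramError(ValueError):
    pass


@dataclass
class Thermogram:
    """One ampule's heat-flow record.

    t: sample times in hours, strictly increasing.
    p: heat flow in watts at each time.
    volume_mL: sample volume (2 mL ampules by default).
    mask: per-point inclusion flag; corrections exclude points, never delete.
    cut_time_h: accepted start of usable data (set by synchronization), in
        the record's own (shifted) time coordinates.
    """

    t: np.ndarray
    p: np.ndarray
    volume_mL: float = 2.0
    label: str = ""
    corrected: bool = False
    mask: np.ndarray | None = None
    cut_time_h: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.t.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.t) == len(self.p) == len(self.mask)):
            raise ThermogramError("t, p and mask must have equal length")
        if len(self.t) and not np.all(np.diff(self.t) > 0):
            raise ThermogramError("sample times must be strictly increasing")
        if self.volume_mL <= 0:
            raise ThermogramError("volume_mL must be positive")

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        """The included (time, power) samples."""
        return self.t[self.mask], self.p[self.mask]

    @property
    def lod_W(self) -> float:
        """Ampule-level detection floor: per-mL LOD times sample volume."""
        return DEFAULT_LOD_NW_PER_ML * 1e-9 * self.volume_mL


@dataclass
class BaselineFit:
    """Parameters of the insertion-artifact model f(t) = a·t^b + c.

    a is in W·h^−b, b dimensionless (negative: decay), c in W.  fit_windows
    are the time intervals (hours) whose points entered the fit; rmse is the
    root-mean-square residual over those points, in W.
    """

    a: float
    b: float
    c: float
    fit_windows: list[tuple[float, float]]
    rmse: float

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.power(t, self.b) + self.c


@dataclass
class FeatureSet:
    """Peak power / peak time / total heat / running cumulative heat."""

    peak_power_W: float
    peak_time_h: float
    total_heat_J: float
    cumulative_t_h: np.ndarray = field(repr=False, default=None)
    cumulative_J: np.ndarray = field(repr=False, default=None)


@dataclass
class SyncConfig:
    """Tunables of the synchronization method.

    The insertion event is the maximum |dP/dt| within the first
    ``search_window_h`` hours of the record.  The record is cut at the first
    time after the event where the smoothed signal varies by less than
    ``eps_mad_mult`` times the late-record noise MAD over a ``dwell_h``-hour
    window (i.e. the artifact has settled into the local trend).
    """

    search_window_h: float = 5.0
    dwell_h: float = 2.0
    eps_mad_mult: float = 3.0
    smooth_points: int = 5
    manual_cut_h: float | None = None


def _rolling_median(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or len(x) < k:
        return x.copy()
    pad = k // 2
    xp = np.pad(x, pad, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(xp, k)[: len(x)]
    return np.median(windows, axis=1)


def _noise_mad(p: np.ndarray) -> float:
    """Noise scale from the last 10 % of the record (median-detrended)."""
    tail = p[max(len(p) - max(len(p) // 10, 20), 0):]
    return float(np.median(np.abs(tail - np.median(tail))))


def _find_cut(t: np.ndarray, p: np.ndarray, event_t: float, cfg: SyncConfig) -> float:
    smooth = _rolling_median(p, cfg.smooth_points)
    eps = cfg.eps_mad_mult * _noise_mad(p)
    if eps == 0:
        eps = 1e-15
    start = int(np.searchsorted(t, event_t))
    ends = np.searchsorted(t, t + cfg.dwell_h)
    for i in range(start, len(t)):
        j = int(ends[i])
        if j >= len(t):
            break  # dwell window runs off the record
        window = smooth[i:j + 1]
        if window.max() - window.min() <= eps:
            return float(t[i])
    raise ThermogramError(
        "no settling point found after the insertion event; "
        "supply SyncConfig.manual_cut_h to cut manually"
    )


def synchronize_group(
    group: Sequence[Thermogram],
    config: SyncConfig | None = None,
) -> list[Thermogram]:
    """Align thermograms on their insertion transients and cut the artifact.

    Each record is time-shifted so its insertion event (maximum |dP/dt|
    within the configured search window) sits at t = 0, then mask-excluded
    before the first time the post-event signal stays within ε of its local
    trend for the configured dwell.  With ``manual_cut_h`` set, the cut is
    taken at that time (in the unshifted coordinates) with no event
    detection; records already synchronized are returned unchanged.  Raw
    samples are never deleted.
    """
    cfg = config or SyncConfig()
    if not group:
        raise ThermogramError("empty thermogram group")
    out: list[Thermogram] = []
    for tg in group:
        if tg.cut_time_h is not None:
            out.append(tg)  # already synchronized: no-op
            continue
        t, p = tg.t, tg.p
        if len(t) < 3:
            raise ThermogramError(f"{tg.label!r}: too few samples to synchronize")
        if cfg.manual_cut_h is not None:
            cut = float(cfg.manual_cut_h)
            shifted_t = t
        else:
            in_window = t <= t[0] + cfg.search_window_h
            if in_window.sum() < 3:
                raise ThermogramError(
                    f"{tg.label!r}: search window holds <3 points; "
                    "set SyncConfig.manual_cut_h"
                )
            dpdt = np.gradient(p, t)
            dpdt[~in_window] = 0.0
            event_idx = int(np.argmax(np.abs(dpdt)))
            event_t = float(t[event_idx])
            shifted_t = t - event_t
            cut = _find_cut(shifted_t, p, 0.0, cfg)
        mask = tg.mask & (shifted_t >= cut)
        if not mask.any():
            raise ThermogramError(f"{tg.label!r}: cut at {cut} h excludes all samples")
        out.append(replace(tg, t=shifted_t, mask=mask, cut_time_h=cut))
    return out


def default_fit_windows(tg: Thermogram, fraction: float = 0.10) -> list[tuple[float, float]]:
    """First and last ``fraction`` of the masked record, as time intervals."""
    tm, _ = tg.masked()
    if len(tm) < 2:
        raise ThermogramError("not enough masked-in samples for fit windows")
    span = tm[-1] - tm[0]
    return [
        (float(tm[0]), float(tm[0] + fraction * span)),
        (float(tm[-1] - fraction * span), float(tm[-1])),
    ]


def _window_mask(t: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(t.shape, dtype=bool)
    for lo, hi in windows:
        m |= (t >= lo) & (t <= hi)
    return m


def fit_power_baseline(
    tg: Thermogram,
    windows: Sequence[tuple[float, float]] | None = None,
    b_bounds: tuple[float, float] = (-10.0, 0.0),
    max_restarts: int = 5,
    seed: int = 0,
) -> BaselineFit:
    """Least-squares fit of f(t) = a·t^b + c to the window segments.

    The windows should cover record segments where only the insertion
    artifact and instrument offset are present (by default the first and
    last 10 % of the record).  Initialization: c₀ = median of the last
    window; (a₀, b₀) from a log-log regression of (p − c₀) against t.
    On non-convergence the fit restarts with jittered initial values.
    """
    if windows is None:
        windows = default_fit_windows(tg)
    t_all, p_all = tg.masked()
    sel = _window_mask(t_all, windows)
    t, p = t_all[sel], p_all[sel]
    if len(t) < 5:
        raise ThermogramError(f"fit windows hold {len(t)} points; need >= 5")
    if np.any(t <= 0):
        raise ThermogramError(
            "fit windows include t <= 0; shift the time origin past the cut"
        )
    last_lo, last_hi = windows[-1]
    tail = p[(t >= last_lo) & (t <= last_hi)]
    c0 = float(np.median(tail)) if len(tail) else float(np.median(p))
    resid = p - c0
    pos = resid > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[pos]), np.log(resid[pos]), 1)
        b0 = float(np.clip(slope, b_bounds[0] + 1e-6, b_bounds[1] - 1e-6))
        a0 = float(np.exp(intercept))
    else:
        b0, a0 = -1.0, max(float(np.std(p)), 1e-12)

    def model(tt, a, b, c):
        return a * np.power(tt, b) + c

    rng = np.random.default_rng(seed)
    lower = np.array([0.0, b_bounds[0], -np.inf])
    upper = np.array([np.inf, b_bounds[1], np.inf])
    p0 = np.array([a0, b0, c0])
    last_err: Exception | None = None
    for _attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(
                model, t, p, p0=np.clip(p0, lower, upper),
                bounds=(lower, upper), maxfev=20000,
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
            a, b, c = (float(v) for v in popt)
            rmse = float(np.sqrt(np.mean((model(t, a, b, c) - p) ** 2)))
            return BaselineFit(a=a, b=b, c=c,
                               fit_windows=[tuple(w) for w in windows], rmse=rmse)
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
            p0 = np.array([
                a0 * math.exp(rng.normal(0, 1)),
                float(np.clip(b0 + rng.normal(0, 0.5), b_bounds[0] + 1e-6,
                              b_bounds[1] - 1e-6)),
                c0 + rng.normal(0, abs(c0) * 0.5 + 1e-12),
            ])
    raise ThermogramError(
        f"power-function baseline fit failed after {max_restarts + 1} attempts "
        f"(windows={list(windows)}, n={len(t)}): {last_err}"
    )


def subtract_baseline(
    tg: Thermogram,
    fit: BaselineFit,
    exclusion: Sequence[tuple[float, float]] = (),
) -> Thermogram:
    """Subtract a fitted baseline; mask-exclude the given time intervals.

    Typical exclusions are the fit windows themselves (segments judged to be
    background only).  Applying to an already-corrected thermogram is an
    error; correction state is explicit, never silently stacked.
    """
    if tg.corrected:
        raise ThermogramError(f"{tg.label!r} is already baseline-corrected")
    p_corr = tg.p - np.asarray(fit(tg.t), dtype=float)
    mask = tg.mask & ~_window_mask(tg.t, exclusion)
    if not mask.any():
        raise ThermogramError("exclusion intervals mask out every sample")
    return replace(tg, p=p_corr, mask=mask, corrected=True)


def cumulative_heat(
    tg: Thermogram,
    time_range: tuple[float, float] | None = None,
    allow_uncorrected: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Running cumulative heat (J) by trapezoidal integration of power.

    Returns ``(times_h, cumulative_J)`` over the masked-in samples within
    ``time_range`` (the full mask by default).  Hours are converted to
    seconds inside the integral; a piecewise-linear power profile integrates
    exactly.
    """
    if not tg.corrected and not allow_uncorrected:
        raise ThermogramError(
            f"{tg.label!r} is not baseline-corrected; pass allow_uncorrected=True "
            "to integrate the raw signal"
        )
    t, p = tg.masked()
    if time_range is not None:
        lo, hi = time_range
        sel = (t >= lo) & (t <= hi)
        t, p = t[sel], p[sel]
    if len(t) < 2:
        raise ThermogramError("need at least 2 masked-in samples to integrate")
    cum = cumulative_trapezoid(p, t * SECONDS_PER_HOUR, initial=0.0)
    return t, cum


def extract_features(tg: Thermogram, allow_uncorrected: bool = False) -> FeatureSet:
    """Peak power, peak time (earliest at ties), and total heat of a record."""
    t, p = tg.masked()
    if len(t) == 0:
        raise ThermogramError("all samples are masked out")
    peak_idx = int(np.argmax(p))  # argmax returns the earliest maximum
    tt, cum = cumulative_heat(tg, allow_uncorrected=allow_uncorrected)
    return FeatureSet(
        peak_power_W=float(p[peak_idx]),
        peak_time_h=float(t[peak_idx]),
        total_heat_J=float(cum[-1]),
        cumulative_t_h=tt,
        cumulative_J=cum,
    )
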