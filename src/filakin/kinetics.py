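"""Elongation kinetics: velocities, pauses, rate constants, unit conversions.

Length-versus-time traces are converted to smoothed instantaneous
velocities; samples above the 1.5 subunits/s threshold form the
"kinetically active" phases and the remainder the paused state, whose
time fraction is the pausing probability P_p.  The pause-free elongation
velocity E measured at several actin concentrations c is fitted with the
single-filament rate law

    E = kon * c - koff,

so the slope estimates the association rate constant (subunits uM^-1
s^-1), the negative intercept the dissociation rate (subunits/s), and
their ratio koff/kon the critical concentration at which net growth
vanishes.  Confidence intervals are 95%, from the t distribution of the
(weighted) linear fit.

Unit conversions for the surface-tether experiments also live here:
adsorbed-protein concentration -> surface density (molecules/um^2) ->
tethers per micron of filament (0.006 um^2 footprint) -> fractional
lattice occupancy (370 subunits per micron).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .config import (
    AVOGADRO,
    FILAMENT_FOOTPRINT_UM2,
    PAUSE_THRESHOLD,
    SMOOTHING_WINDOW,
    SUBUNITS_PER_UM,
)
from .kymo import FilamentTrace

__all__ = [
    "PhaseSummary",
    "KineticRates",
    "PauseFreeVelocity",
    "smooth_velocity",
    "classify_phases",
    "pause_free_velocity",
    "fit_rate_constants",
    "critical_concentration",
    "surface_density_from_concentration",
    "tethers_per_micron",
    "fractional_occupancy",
]


@dataclass
class PhaseSummary:
    """Active/paused labels for a velocity series and the pause statistics."""

    labels: np.ndarray  # bool per sample, True = active
    threshold: float  # subunits/s
    pausing_probability: float  # fraction of samples paused
    active_mean_velocity: float  # subunits/s; NaN if fully paused


@dataclass
class KineticRates:
    """Rate constants from an elongation-versus-concentration fit."""

    kon: float  # subunits uM^-1 s^-1
    koff: float  # subunits/s (negative of the intercept; may be < 0)
    cc: float  # critical concentration koff/kon, uM
    ci95_kon: tuple[float, float]
    ci95_koff: tuple[float, float]
    n_points: int


@dataclass
class PauseFreeVelocity:
    velocity: float  # subunits/s, duration-weighted mean over active runs
    sem: float  # SEM of per-run slopes
    n_runs: int


def smooth_velocity(trace: FilamentTrace, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Instantaneous velocity (subunits/s): centred differences + running mean.

    The raw velocity is the centred finite difference of delta_length
    divided by dt (one-sided at the ends), then smoothed with a centred
    running mean of ``window`` samples whose window shrinks at the
    edges.  ``window=1`` returns the raw finite differences.  NaN gaps
    are ignored inside each smoothing window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    dt = trace.dt  # raises on non-uniform sampling
    y = trace.delta_length
    if y.size < window + 1:
        raise ValueError("trace shorter than the smoothing window")
    v = np.empty_like(y)
    v[1:-1] = (y[2:] - y[:-2]) / (2.0 * dt)
    v[0] = (y[1] - y[0]) / dt
    v[-1] = (y[-1] - y[-2]) / dt
    if window == 1:
        return v

    half_lo = window // 2
    half_hi = window - 1 - half_lo
    finite = np.isfinite(v)
    vs = np.where(finite, v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vs)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    n = v.size
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    counts = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (csum[hi] - csum[lo]) / counts
    out[counts == 0] = np.nan
    return out


def _runs(labels: np.ndarray):
    """Yield (start, stop, value) for each maximal constant run."""
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield start, i, labels[start]
            start = i


def classify_phases(
    velocities,
    threshold: float = PAUSE_THRESHOLD,
    min_run: int = 3,
) -> PhaseSummary:
    """Label each sample active (velocity > threshold) or paused.

    Runs shorter than ``min_run`` samples are merged into the
    surrounding phase (debouncing), shortest first, until no short run
    remains.  P_p is the paused fraction of (finite-velocity) samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(velocities, dtype=float)
    finite = np.isfinite(v)
    labels = np.where(finite, v > threshold, False)

    if min_run > 1:
        while True:
            runs = [(start, stop) for start, stop, _ in _runs(labels) if stop - start < min_run]
            if not runs or len(runs) == sum(1 for _ in _runs(labels)):
                break
            start, stop = min(runs, key=lambda r: r[1] - r[0])
            labels[start:stop] = ~labels[start]

    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("velocity series contains no finite samples")
    paused = np.sum(~labels[finite])
    p_p = float(paused / n_finite)
    active_v = v[labels & finite]
    return PhaseSummary(
        labels=labels,
        threshold=threshold,
        pausing_probability=p_p,
        active_mean_velocity=float(active_v.mean()) if active_v.size else float("nan"),
    )


def pause_free_velocity(
    trace: FilamentTrace,
    threshold: float = PAUSE_THRESHOLD,
    window: int = SMOOTHING_WINDOW,
    min_run: int = 3,
) -> PauseFreeVelocity:
    """Elongation velocity over the kinetically active phases only.

    The trace is smoothed, phases are classified, and a least-squares
    slope of delta_length versus time is fitted within every active run
    of at least 3 samples.  Slopes are combined as a duration-weighted
    mean; the SEM is taken across runs.
    """
    v = smooth_velocity(trace, window=window)
    summary = classify_phases(v, threshold=threshold, min_run=min_run)
    slopes = []
    weights = []
    for start, stop, val in _runs(summary.labels):
        if not val or stop - start < 3:
            continue
        t = trace.times[start:stop]
        y = trace.delta_length[start:stop]
        good = np.isfinite(y)
        if good.sum() < 3:
            continue
        slope = np.polyfit(t[good], y[good], 1)[0]
        slopes.append(slope)
        weights.append(t[-1] - t[0])
    if not slopes:
        raise ValueError("fully paused trace: no active run of >= 3 samples")
    slopes = np.asarray(slopes)
    weights = np.asarray(weights)
    mean = float(np.sum(slopes * weights) / np.sum(weights))
    sem = float(np.std(slopes, ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else 0.0
    return PauseFreeVelocity(velocity=mean, sem=sem, n_runs=len(slopes))


def fit_rate_constants(points) -> KineticRates:
    """Estimate kon, koff and the critical concentration from E(c) data.

    ``points`` is an iterable of ``(conc_uM, E, sem)`` or
    ``(conc_uM, E)`` tuples.  The fit is weighted least squares with
    weights 1/sem^2 when SEMs are supplied (unweighted otherwise);
    kon is the slope, koff the negative intercept (reported as-is even
    when negative) and cc = koff/kon.  95% confidence intervals use the
    t distribution with n - 2 degrees of freedom.
    """
    rows = [tuple(p) for p in points]
    conc = np.array([r[0] for r in rows], dtype=float)
    e = np.array([r[1] for r in rows], dtype=float)
    sems = np.array([r[2] if len(r) > 2 else np.nan for r in rows], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")

    x = sm.add_constant(conc)
    if np.all(np.isfinite(sems)) and np.all(sems > 0):
        res = sm.WLS(e, x, weights=1.0 / sems**2).fit()
    else:
        res = sm.OLS(e, x).fit()
    intercept, slope = res.params
    ci = res.conf_int(alpha=0.05)
    kon = float(slope)
    koff = float(-intercept)
    ci_kon = (float(ci[1][0]), float(ci[1][1]))
    ci_koff = tuple(sorted((-float(ci[0][1]), -float(ci[0][0]))))
    cc = koff / kon if kon != 0 else float("nan")
    return KineticRates(
        kon=kon,
        koff=koff,
        cc=float(cc),
        ci95_kon=ci_kon,
        ci95_koff=ci_koff,
        n_points=conc.size,
    )


def critical_concentration(kon: float, koff: float) -> float:
    """Critical concentration koff/kon (uM): net growth vanishes there."""
    if kon == 0:
        raise ValueError("critical concentration undefined for kon = 0")
    return koff / kon


def surface_density_from_concentration(
    conc_nM: float,
    volume_uL: float = 10.0,
    area_mm2: float = 100.0,
    both_surfaces: bool = True,
) -> float:
    """Adsorbed-molecule surface density (molecules/um^2).

    All protein in the applied volume is assumed to adsorb onto the flow
    cell glass; by default onto both the upper and lower surfaces, which
    doubles the available area.
    """
    if conc_nM < 0 or volume_uL <= 0 or area_mm2 <= 0:
        raise ValueError("concentration must be >= 0; volume and area positive")
    molecules = conc_nM * 1e-9 * volume_uL * 1e-6 * AVOGADRO
    area_um2 = area_mm2 * 1e6 * (2.0 if both_surfaces else 1.0)
    return molecules / area_um2


def tethers_per_micron(density_per_um2: float) -> float:
    """Surface density -> molecules per micron of filament (0.006 um^2 footprint)."""
    if density_per_um2 < 0:
        raise ValueError("density must be non-negative")
    return density_per_um2 * FILAMENT_FOOTPRINT_UM2


def fractional_occupancy(per_micron: float) -> float:
    """Tethers per micron -> per-lattice-site probability, capped at 1."""
    if per_micron < 0:
        raise ValueError("per_micron must be non-negative")
    return min(per_micron / SUBUNITS_PER_UM, 1.0)
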