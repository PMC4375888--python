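"""Persistence length of surface-adsorbed filaments from contour shapes.

For a filament contour parameterised by arc length s with tangent angle
theta(s), the apparent persistence length Lp of a two-dimensional
(surface-adsorbed) filament is defined through the tangent-angle
correlation

    <cos[theta(s) - theta(0)]> = exp(-s / (2 Lp)),

where the average runs over all admissible point pairs of all contours.
Contours are resampled to uniform arc-length spacing before tangents
are computed (the point spacing affects the estimate; 6-10 points per
micron is the recommended band) and Lp is obtained by nonlinear least
squares on the cosine values, which stays well-behaved when the
correlation approaches zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "Contour",
    "PersistenceFit",
    "resample_contour",
    "tangent_angles",
    "tangent_correlation",
    "fit_persistence_length",
]


@dataclass
class Contour:
    """Ordered planar polyline (microns) tracing one filament."""

    points: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise ValueError("contour needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive contour points must be distinct")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def spacing(self) -> float:
        return float(np.mean(self.segment_lengths))

    @property
    def contour_length(self) -> float:
        return float(np.sum(self.segment_lengths))


@dataclass
class PersistenceFit:
    lp: float  # microns; inf when capped
    s_max: float  # largest separation used, microns
    n_filaments: int
    capped: bool = False  # True for effectively straight inputs


def resample_contour(contour: Contour, spacing: float) -> Contour:
    """Resample a contour to uniform arc-length spacing (linear interpolation)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = contour.points
    s = np.concatenate([[0.0], np.cumsum(contour.segment_lengths)])
    total = s[-1]
    # tolerance keeps point counts stable when total is an exact multiple
    # of the spacing up to float rounding (e.g. rigidly moved contours)
    n = max(int(np.floor(total / spacing + 1e-9)), 1)
    grid = np.arange(n + 1) * spacing
    x = np.interp(grid, s, pts[:, 0])
    y = np.interp(grid, s, pts[:, 1])
    return Contour(np.stack([x, y], axis=1))


def tangent_angles(points: np.ndarray) -> np.ndarray:
    """Tangent angle at each point from central differences (one-sided at ends)."""
    p = np.asarray(points, dtype=float)
    d = np.empty_like(p)
    d[1:-1] = p[2:] - p[:-2]
    d[0] = p[1] - p[0]
    d[-1] = p[-1] - p[-2]
    return np.arctan2(d[:, 1], d[:, 0])


def tangent_correlation(
    contours,
    s_max: float | None = None,
    spacing: float | None = None,
):
    """Mean tangent-angle correlation versus separation, pooled over contours.

    For each separation s = k * spacing the mean of
    cos(theta(u + s) - theta(u)) is taken over all admissible pairs
    (u, u + s) of all contours (all-pairs pooling, not anchored at one
    end).  Returns ``(s, mean_cos, n_pairs)``.

    ``spacing`` defaults to the mean point spacing of the inputs; all
    contours are arc-length resampled to it first.
    """
    contours = list(contours)
    if not contours:
        raise ValueError("no contours given")
    if spacing is None:
        spacing = float(np.mean([c.spacing for c in contours]))
    angles = [tangent_angles(resample_contour(c, spacing).points) for c in contours]
    max_lag = max(len(a) - 1 for a in angles)
    if s_max is not None:
        if s_max < spacing:
            raise ValueError("s_max smaller than the point spacing")
        max_lag = min(max_lag, int(np.floor(s_max / spacing)))
    if max_lag < 1:
        raise ValueError("separation range beyond all contour lengths")

    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for a in angles:
        for k in range(0, min(max_lag, len(a) - 1) + 1):
            c = np.cos(a[k:] - a[: len(a) - k])
            sums[k] += c.sum()
            counts[k] += c.size
    s = np.arange(max_lag + 1) * spacing
    mean_cos = sums / counts
    return s, mean_cos, counts


def fit_persistence_length(
    s,
    mean_cos,
    s_max: float | None = None,
    n_filaments: int = 1,
) -> PersistenceFit:
    """Fit Lp in <cos dtheta>(s) = exp(-s / (2 Lp)) by least squares.

    Separations above ``s_max`` are ignored (estimates there are
    pair-starved); non-positive correlations inside the range shrink the
    range with a warning.  A correlation indistinguishable from 1
    (effectively straight filaments) returns ``capped=True`` with
    ``lp = inf``.
    """
    s = np.asarray(s, dtype=float)
    mean_cos = np.asarray(mean_cos, dtype=float)
    mask = s > 0
    if s_max is not None:
        mask &= s <= s_max
    s_fit = s[mask]
    c_fit = mean_cos[mask]
    if s_fit.size == 0:
        raise ValueError("no separations inside the fit range")

    nonpos = np.nonzero(c_fit <= 0)[0]
    if nonpos.size:
        warnings.warn(
            "non-positive correlations in the fit range; shrinking the range",
            stacklevel=2,
        )
        s_fit = s_fit[: nonpos[0]]
        c_fit = c_fit[: nonpos[0]]
        if s_fit.size == 0:
            raise ValueError("no usable separations: correlation non-positive throughout")

    used_smax = float(s_fit[-1])
    if np.all(c_fit > 1.0 - 1e-9):
        return PersistenceFit(np.inf, used_smax, n_filaments, capped=True)

    # log-linear slope as starting value, then NLS on the cosines
    slope = np.polyfit(s_fit, np.log(np.clip(c_fit, 1e-12, None)), 1)[0]
    lp0 = -1.0 / (2.0 * slope) if slope < 0 else used_smax
    lp0 = float(np.clip(lp0, 1e-3, 1e6))
    popt, _ = optimize.curve_fit(
        lambda ss, lp: np.exp(-ss / (2.0 * lp)),
        s_fit,
        c_fit,
        p0=[lp0],
        bounds=(1e-6, 1e9),
        maxfev=5000,
    )
    return PersistenceFit(float(popt[0]), used_smax, n_filaments, capped=False)


def estimate_lp(contours, s_max: float | None = None, spacing: float | None = None) -> PersistenceFit:
    """Convenience wrapper: pooled tangent correlation followed by the Lp fit.

    ``s_max`` defaults to half the mean contour length.
    """
    contours = list(contours)
    if s_max is None:
        s_max = 0.5 * float(np.mean([c.contour_length for c in contours]))
    s, mean_cos, _ = tangent_correlation(contours, s_max=s_max, spacing=spacing)
    fit = fit_persistence_length(s, mean_cos, s_max=s_max, n_filaments=len(contours))
    return fit
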