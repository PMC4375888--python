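"""Kymograph analysis: drift correction and subpixel filament-end tracking.

A kymograph is a time x position image of a single filament: one row per
movie frame, one column per pixel along the filament axis.  Because a
diffraction-limited filament end appears as an intensity step blurred by
the point-spread function, the end position in each row is located with
subpixel precision by least-squares fitting an error-function profile

    I(x) = B + (A / 2) * [1 + p * erf((x - mu) / (sqrt(2) * sigma))]

with p = +1 for a rising (left) edge and p = -1 for a falling (right)
edge.  Tracking both edges row by row yields length-versus-time traces
for the two filament ends, calibrated to microns via the pixel size and
to subunits via 370 subunits per micron.

Stage drift in raw movies is estimated by cross-correlation against the
first frame (subpixel peak localisation by locally upsampled DFT
cross-correlation) and removed by cubic-spline resampling before
kymographs are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.special import erf
from skimage.registration import phase_cross_correlation

from .config import SUBUNITS_PER_UM

__all__ = [
    "Kymograph",
    "EdgeFit",
    "FilamentTrace",
    "estimate_drift",
    "correct_drift",
    "fit_edge",
    "track_ends",
    "subtract_marker",
]


@dataclass
class Kymograph:
    """Time x position intensity grid with spatial/temporal calibration."""

    intensities: np.ndarray  # shape (rows=frames, cols=pixels)
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("kymograph intensities must be a 2D array")
        if self.intensities.shape[0] < 2 or self.intensities.shape[1] < 8:
            raise ValueError("kymograph needs at least 2 rows and 8 columns")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("kymograph intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("kymograph intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class EdgeFit:
    """Result of fitting one error-function edge to a 1D profile."""

    center: float  # subpixel edge position, pixel-center coordinates
    width: float  # blur sigma, pixels
    amplitude: float  # step height, counts
    background: float  # baseline, counts
    polarity: str  # "rising" | "falling"
    rss: float  # residual sum of squares
    ok: bool
    reason: str = ""


@dataclass
class FilamentTrace:
    """Length change of one filament end versus time.

    ``delta_length`` is stored in subunits, measured relative to the
    first successful observation; rows where the edge fit failed are
    carried as NaN gaps rather than silently interpolated.  Conversion
    between subunits and microns always uses 370 subunits per micron.
    """

    times: np.ndarray  # seconds, strictly increasing
    delta_length: np.ndarray  # subunits; NaN marks a gap
    end: str = "barbed"  # "barbed" | "pointed"
    initial_length_um: float | None = None
    phase: np.ndarray | None = None  # optional ground truth, True = active

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_length = np.asarray(self.delta_length, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.delta_length.shape:
            raise ValueError("times and delta_length must be matching 1D arrays")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.isinf(self.delta_length)):
            raise ValueError("delta_length must not contain infinities")
        if self.end not in ("barbed", "pointed"):
            raise ValueError("end must be 'barbed' or 'pointed'")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=bool)
            if self.phase.shape != self.times.shape:
                raise ValueError("phase must match times in length")

    @property
    def delta_length_um(self) -> np.ndarray:
        return self.delta_length / SUBUNITS_PER_UM

    @property
    def dt(self) -> float:
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise ValueError("trace is not uniformly sampled")
        return float(steps[0])

    @property
    def gap_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.delta_length)))


# ---------------------------------------------------------------------------
# drift estimation / correction


def estimate_drift(frames, upsample_factor: int = 100) -> np.ndarray:
    """Per-frame (row, col) offsets relative to the first frame.

    Offsets are the subpixel peak of the image cross-correlation with
    the first frame, localised by locally upsampled matrix-DFT
    cross-correlation.  A frame whose scene moved by ``(dy, dx)``
    relative to frame 0 yields offset ``(dy, dx)``.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to estimate drift")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must have identical shapes")

    offsets = np.zeros((len(frames), 2))
    for k, frame in enumerate(frames[1:], start=1):
        shift, _, _ = phase_cross_correlation(
            frames[0], frame, upsample_factor=upsample_factor, normalization=None
        )
        offsets[k] = -shift
    return offsets


def correct_drift(frames, offsets, order: int = 3):
    """Resample each frame at drift-shifted coordinates (cubic spline).

    Returns ``(corrected, valid)`` where ``valid`` is a boolean mask per
    frame marking pixels whose resampling coordinates fell inside the
    original image (border pixels without support are flagged False).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (len(frames), 2):
        raise ValueError("offsets must be an (n_frames, 2) array")
    corrected = []
    valid = []
    ny, nx = frames[0].shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for frame, (dy, dx) in zip(frames, offsets):
        if dy == 0 and dx == 0:
            corrected.append(frame.copy())
            valid.append(np.ones_like(frame, dtype=bool))
            continue
        out = ndimage.shift(frame, shift=(-dy, -dx), order=order, mode="nearest")
        corrected.append(out)
        sy = yy + dy
        sx = xx + dx
        valid.append((sy >= 0) & (sy <= ny - 1) & (sx >= 0) & (sx <= nx - 1))
    return corrected, valid


# ---------------------------------------------------------------------------
# error-function edge fitting


def _erf_model(x: np.ndarray, mu: float, sigma: float, amp: float, bg: float, sign: float) -> np.ndarray:
    return bg + 0.5 * amp * (1.0 + sign * erf((x - mu) / (np.sqrt(2.0) * sigma)))


def _robust_noise_sd(profile: np.ndarray) -> float:
    # successive-difference MAD estimator; insensitive to the edge itself
    d = np.diff(profile)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def fit_edge(profile, polarity: str = "rising") -> EdgeFit:
    """Fit one blurred step edge to a 1D intensity profile.

    The center is initialised at the maximum-magnitude gradient position
    and refined by bounded least squares.  The fit is flagged ``ok=False``
    when it fails to converge or when the fitted amplitude is not
    distinguishable from the profile noise (A < 3 x robust noise SD).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 8:
        raise ValueError("profile must be 1D with at least 8 samples")
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile must be finite")
    if polarity not in ("rising", "falling"):
        raise ValueError("polarity must be 'rising' or 'falling'")

    n = profile.size
    x = np.arange(n, dtype=float)
    sign = 1.0 if polarity == "rising" else -1.0

    failed = EdgeFit(np.nan, np.nan, np.nan, np.nan, polarity, np.nan, False)
    if np.ptp(profile) == 0:
        failed.reason = "no edge"
        return failed

    grad = np.gradient(profile)
    mu0 = float(np.argmax(sign * grad))
    bg0 = float(np.min(profile))
    amp0 = float(np.ptp(profile))
    p0 = [mu0, 1.5, amp0, bg0]
    lo = [0.0, 0.3, 0.0, bg0 - 2.0 * amp0 - 1.0]
    hi = [n - 1.0, 10.0, 4.0 * amp0 + 1.0, float(np.max(profile)) + 1.0]
    p0 = [min(max(v, a), b) for v, a, b in zip(p0, lo, hi)]
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, mu, s, a, b: _erf_model(xx, mu, s, a, b, sign),
            x,
            profile,
            p0=p0,
            bounds=(lo, hi),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        failed.reason = "did not converge"
        return failed

    mu, sig, amp, bg = (float(v) for v in popt)
    resid = profile - _erf_model(x, mu, sig, amp, bg, sign)
    rss = float(np.sum(resid**2))
    noise = _robust_noise_sd(profile)
    ok = amp >= 3.0 * noise and amp > 0
    reason = "" if ok else "amplitude indistinguishable from noise"
    return EdgeFit(mu, sig, amp, bg, polarity, rss, ok, reason)


# ---------------------------------------------------------------------------
# end tracking


def _fit_row_edges(row: np.ndarray) -> tuple[EdgeFit, EdgeFit]:
    """Fit the rising (left) and falling (right) edges of one plateau row."""
    grad = np.gradient(row)
    left0 = int(np.argmax(grad))
    right0 = int(np.argmin(grad))
    if right0 <= left0:  # degenerate row; fall back to whole-profile fits
        left0, right0 = 0, row.size - 1
    mid = (left0 + right0) // 2
    mid = int(np.clip(mid, 8, row.size - 8))
    left = fit_edge(row[: mid + 1], "rising")
    right = fit_edge(row[mid:], "falling")
    if right.ok:
        right.center += mid
    return left, right


def track_ends(
    kymo: Kymograph,
    polarity_barbed: str = "right",
) -> tuple[FilamentTrace, FilamentTrace]:
    """Track both filament ends through a kymograph.

    Each row must contain a single filament segment (one rising and one
    falling edge).  Both edges are fitted per row; positions are
    calibrated to microns (pixel size) and subunits (370 per micron);
    rows with failed fits become NaN gaps.  ``delta_length`` of each end
    is its outward displacement relative to the first successful row, so
    growth is positive for both ends.

    ``polarity_barbed`` names which image side ("left" or "right") is
    the barbed end.
    """
    if polarity_barbed not in ("left", "right"):
        raise ValueError("polarity_barbed must be 'left' or 'right'")
    lefts = np.full(kymo.n_frames, np.nan)
    rights = np.full(kymo.n_frames, np.nan)
    for i in range(kymo.n_frames):
        lf, rf = _fit_row_edges(kymo.intensities[i])
        if lf.ok:
            lefts[i] = lf.center
        if rf.ok:
            rights[i] = rf.center

    both = np.isfinite(lefts) & np.isfinite(rights)
    if both.sum() < 2:
        raise ValueError("fewer than 2 rows with successful edge fits")

    times = kymo.times
    px_to_sub = kymo.pixel_size_um * SUBUNITS_PER_UM
    first = int(np.argmax(both))
    # outward displacement: left end grows towards smaller x, right towards larger
    dl_left = -(lefts - lefts[first]) * px_to_sub
    dl_right = (rights - rights[first]) * px_to_sub

    if polarity_barbed == "right":
        barbed, pointed = dl_right, dl_left
    else:
        barbed, pointed = dl_left, dl_right
    return (
        FilamentTrace(times, barbed, end="barbed"),
        FilamentTrace(times, pointed, end="pointed"),
    )


def subtract_marker(trace: FilamentTrace, marker: FilamentTrace) -> FilamentTrace:
    """Remove filament sliding using a fiduciary-marker trace.

    The marker trace (apparent displacement of a fixed feature, in
    subunit units) is interpolated onto the end trace's time grid and
    subtracted, leaving only true elongation.
    """
    corr = np.interp(trace.times, marker.times, marker.delta_length)
    return FilamentTrace(
        trace.times,
        trace.delta_length - corr,
        end=trace.end,
        initial_length_um=trace.initial_length_um,
        phase=trace.phase,
    )
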