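"""Synthetic TIRF data with known ground truth.

Every input consumed by the analysis stages can be generated here:

* two-state (elongating / paused) length-versus-time traces at chosen
  association/dissociation rates and actin concentration;
* kymograph images with PSF-blurred filament edges plus camera noise;
* planar worm-like-chain contours at a chosen persistence length;
* elongation-versus-tether-density datasets produced by the forward
  allosteric Monte Carlo model.

Generators are bit-reproducible given the same seed, and each returns
(or embeds) the ground truth that downstream estimators are tested
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from . import allosteric
from .config import SUBUNITS_PER_UM, derive_seed
from .kymo import FilamentTrace, Kymograph
from .persistence import Contour

__all__ = [
    "GrowthParams",
    "RenderParams",
    "simulate_growth_trace",
    "render_kymograph",
    "simulate_wlc",
    "simulate_density_response",
]


@dataclass
class GrowthParams:
    """Parameters of the stochastic two-state elongation model.

    The filament alternates between an elongating state, where subunits
    associate at ``kon * conc`` and dissociate at ``koff`` per second,
    and a paused state where the length does not change.  Switching is a
    two-state continuous-time Markov chain with the given entry/exit
    rates, sampled on the ``dt`` grid.  The pause rates are fixture
    parameters: the underlying experiments report pause statistics but
    not the microscopic switching rates.
    """

    kon: float = 11.0  # subunits uM^-1 s^-1
    koff: float = 2.0  # subunits s^-1
    conc: float = 1.0  # uM
    pause_entry_rate: float = 0.0  # s^-1
    pause_exit_rate: float = 0.0  # s^-1
    duration: float = 100.0  # s
    dt: float = 1.0  # s
    seed: int = 0
    mode: str = "stochastic"  # "stochastic" | "deterministic"
    initial_paused: bool = False
    initial_length_um: float = 0.0

    def __post_init__(self) -> None:
        vals = [
            self.kon,
            self.koff,
            self.conc,
            self.pause_entry_rate,
            self.pause_exit_rate,
            self.duration,
            self.dt,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("growth parameters must be finite")
        if self.kon < 0 or self.koff < 0 or self.conc < 0:
            raise ValueError("rates and concentration must be non-negative")
        if self.pause_entry_rate < 0 or self.pause_exit_rate < 0:
            raise ValueError("pause rates must be non-negative")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError("mode must be 'stochastic' or 'deterministic'")


@dataclass
class RenderParams:
    """Imaging model for kymograph rendering.

    A filament row is a plateau of height ``amplitude`` above
    ``background`` between the two end positions, blurred by a Gaussian
    PSF of ``psf_sigma`` pixels.  Noise is optional: Poisson on the
    expected counts (shot noise), Gaussian read noise, or both.
    """

    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    psf_sigma: float = 2.0  # pixels
    amplitude: float = 100.0  # counts
    background: float = 10.0  # counts
    noise_model: str = "none"  # "none" | "gaussian" | "poisson"
    read_noise_sd: float = 0.0  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        if self.psf_sigma < 0 or self.amplitude < 0 or self.background < 0:
            raise ValueError("psf_sigma, amplitude, background must be non-negative")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none, gaussian or poisson")


def simulate_growth_trace(params: GrowthParams) -> FilamentTrace:
    """Simulate a two-state length-versus-time trace.

    In the elongating state the per-interval length increment is either
    the exact expected value ``(kon*conc - koff) * dt`` (deterministic
    mode) or the difference of independent Poisson counts of
    association and dissociation events (stochastic mode).  Paused
    intervals contribute zero increment.  Total length is truncated at
    zero.  The hidden phase sequence is returned as ground truth in
    ``trace.phase`` (True = elongating).
    """
    n = int(round(params.duration / params.dt))
    if n < 1:
        raise ValueError("duration must cover at least one dt interval")
    rng = np.random.default_rng(params.seed)
    dt = params.dt

    # phase chain sampled at dt; switching probability per interval
    p_enter = -np.expm1(-params.pause_entry_rate * dt)
    p_exit = -np.expm1(-params.pause_exit_rate * dt)
    active = np.empty(n + 1, dtype=bool)
    active[0] = not params.initial_paused
    u = rng.random(n)
    for k in range(n):
        if active[k]:
            active[k + 1] = u[k] >= p_enter
        else:
            active[k + 1] = u[k] < p_exit

    act = active[:-1]
    if params.mode == "deterministic":
        inc = np.where(act, (params.kon * params.conc - params.koff) * dt, 0.0)
    else:
        gains = rng.poisson(params.kon * params.conc * dt, size=n).astype(float)
        losses = rng.poisson(params.koff * dt, size=n).astype(float)
        inc = np.where(act, gains - losses, 0.0)

    # truncate total length at zero (Lindley recursion in closed form)
    l0 = params.initial_length_um * SUBUNITS_PER_UM
    s = l0 + np.concatenate([[0.0], np.cumsum(inc)])
    length = s - np.minimum.accumulate(np.minimum(s, 0.0))
    delta = length - length[0]

    times = np.arange(n + 1) * dt
    return FilamentTrace(
        times,
        delta,
        end="barbed",
        initial_length_um=params.initial_length_um,
        phase=active,
    )


def render_kymograph(
    trace: FilamentTrace,
    rp: RenderParams,
    n_pixels: int | None = None,
    fixed_end_um: float | None = None,
    moving_end: str = "right",
) -> Kymograph:
    """Render a kymograph image from a length trace.

    One image row per trace sample: a blurred plateau between a fixed
    end and a moving end whose separation follows the trace.  The
    blurred plateau is computed analytically as a difference of error
    functions (a top-hat convolved with a Gaussian), so the edge centers
    in the image are exactly the generating end positions.
    """
    if moving_end not in ("left", "right"):
        raise ValueError("moving_end must be 'left' or 'right'")
    dl = trace.delta_length
    if not np.all(np.isfinite(dl)):
        raise ValueError("cannot render a trace containing gaps")
    l0_um = trace.initial_length_um or 1.0
    length_um = l0_um + dl / SUBUNITS_PER_UM
    if np.any(length_um < 0):
        raise ValueError("trace implies negative filament length")

    px = rp.pixel_size_um
    margin_px = max(4.0 * rp.psf_sigma, 8.0)
    if fixed_end_um is None:
        fixed_end_um = margin_px * px if moving_end == "right" else (np.max(length_um) + margin_px * px)
    required = int(np.ceil((np.max(length_um) + (fixed_end_um if moving_end == "right" else 0)) / px + margin_px)) + 1
    if moving_end == "left":
        required = int(np.ceil(fixed_end_um / px + margin_px)) + 1
    if n_pixels is None:
        n_pixels = required
    elif n_pixels < required:
        raise ValueError(f"image too narrow for the trace: need at least {required} pixels, got {n_pixels}")

    if moving_end == "right":
        left_um = np.full_like(length_um, fixed_end_um)
        right_um = fixed_end_um + length_um
    else:
        right_um = np.full_like(length_um, fixed_end_um)
        left_um = fixed_end_um - length_um
        if np.any(left_um < 0):
            raise ValueError("trace exceeds the image on the left; increase fixed_end_um")

    x = np.arange(n_pixels, dtype=float)  # pixel-center coordinates
    left_px = left_um[:, None] / px
    right_px = right_um[:, None] / px
    if rp.psf_sigma > 0:
        s = np.sqrt(2.0) * rp.psf_sigma
        plateau = 0.5 * (erf((x - left_px) / s) - erf((x - right_px) / s))
    else:
        plateau = ((x >= left_px) & (x < right_px)).astype(float)
    image = rp.background + rp.amplitude * plateau

    rng = np.random.default_rng(rp.seed)
    if rp.noise_model == "poisson":
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
        if rp.read_noise_sd > 0:
            image = image + rng.normal(0.0, rp.read_noise_sd, image.shape)
    elif rp.noise_model == "gaussian":
        if rp.read_noise_sd > 0:
            image = image + rng.normal(0.0, rp.read_noise_sd, image.shape)
    image = np.clip(image, 0.0, None)

    # kymograph rows are trace samples; frame interval from the trace grid
    return Kymograph(image, rp.pixel_size_um, trace.dt)


def simulate_wlc(
    lp: float,
    contour_length: float,
    spacing: float = 8.0,
    seed: int = 0,
    initial_angle: float = 0.0,
) -> Contour:
    """Simulate a planar worm-like chain of persistence length ``lp``.

    The chain is built from segments of length ``1/spacing`` microns
    whose successive turning angles are drawn from a zero-mean Gaussian
    with variance ``ds / lp``, which realises the two-dimensional
    tangent-correlation law <cos[theta(s) - theta(0)]> = exp(-s / (2 lp)).

    Parameters
    ----------
    lp : persistence length, microns (may be ``np.inf`` for a rigid rod).
    contour_length : total arc length, microns.
    spacing : points per micron (6-10 recommended; coarser or finer
        spacing biases downstream tangent estimates).
    """
    if not lp > 0:
        raise ValueError("lp must be positive")
    if not contour_length > 0:
        raise ValueError("contour_length must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ds = 1.0 / spacing
    n_seg = max(int(round(contour_length * spacing)), 1)
    rng = np.random.default_rng(seed)
    if np.isinf(lp):
        turns = np.zeros(n_seg - 1)
    else:
        turns = rng.normal(0.0, np.sqrt(ds / lp), size=n_seg - 1)
    theta = initial_angle + np.concatenate([[0.0], np.cumsum(turns)])
    steps = ds * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    points = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return Contour(points)


def simulate_density_response(
    alpha: float,
    lc: float,
    mc_config: "allosteric.MCConfig | None" = None,
    densities=None,
    reps: int = 20,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> "allosteric.DensityResponse":
    """Forward-model an elongation-versus-tether-density dataset.

    For each surface density the occupancy is derived via the 0.006 um^2
    filament footprint and 370 subunits per micron, ``reps`` independent
    tether placements are simulated with the allosteric Monte Carlo
    model, and the mean and standard deviation of the elongation
    velocity over replicates are recorded.  Optional Gaussian
    measurement noise of SD ``noise_sd`` is added to each replicate.
    """
    from .kinetics import fractional_occupancy, tethers_per_micron

    cfg = mc_config if mc_config is not None else allosteric.MCConfig()
    if densities is None or len(densities) == 0:
        raise ValueError("at least one surface density is required")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    densities = np.asarray(densities, dtype=float)
    if np.any(densities < 0):
        raise ValueError("densities must be non-negative")
    base_seed = cfg.seed if seed is None else seed

    occ = np.array([fractional_occupancy(tethers_per_micron(d)) for d in densities])
    v_mean = np.empty_like(densities)
    v_std = np.empty_like(densities)
    for j, o in enumerate(occ):
        vs = np.empty(reps)
        for r in range(reps):
            sub = allosteric.MCConfig(
                kon0=cfg.kon0,
                koff=cfg.koff,
                conc=cfg.conc,
                lattice_size=cfg.lattice_size,
                mode=cfg.mode,
                seed=derive_seed(base_seed, f"density-response:{j}:{r}"),
            )
            vs[r] = allosteric.simulate_elongation(sub, alpha, lc, o)
        if noise_sd > 0:
            noise_rng = np.random.default_rng(derive_seed(base_seed, f"density-response-noise:{j}"))
            vs = vs + noise_rng.normal(0.0, noise_sd, size=reps)
        v_mean[j] = vs.mean()
        v_std[j] = vs.std(ddof=1) if reps > 1 else 0.0
    return allosteric.DensityResponse(
        density=densities,
        occupancy=occ,
        v=v_mean,
        std=v_std,
        n=np.full(densities.shape, reps, dtype=int),
    )
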