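"""Lattice Monte Carlo model of elongation under side-binding proteins.

The model: a filament is a lattice of N monomer sites.  Surface tethers
(side-binding proteins) occupy random sites, each site independently
with the fractional occupancy derived from the surface density.  A
tether at site j changes the monomer association rate at its own
position to ``alpha * kon0`` and the perturbation decays linearly back
to the basal ``kon0`` over a characteristic length L_C (in monomers)
ahead of the tether:

    kon_eff(i) = kon0 * [1 + (alpha - 1) * max(0, 1 - (i - j)/L_C)]

for the nearest tether j <= i (a tether influences only sites at or
beyond its own position, since it binds the already-polymerised lattice
behind the growing tip; overlapping perturbations take the maximum, so
the rate never exceeds ``alpha * kon0``).  The dissociation rate koff
is never modified.

Elongation velocity is either the lattice average of the instantaneous
net rate ``kon_eff(i) * conc - koff`` ("expected" mode, the default) or
the outcome of an event-driven stochastic polymerisation over the
lattice ("stochastic" mode).

The two free parameters (alpha, L_C) are fitted to measured
elongation-versus-density data by a two-stage chi-square grid search;
confidence intervals follow from delta-chi-square = 1 (68%) and = 4
(95%).

A rejected alternative is also provided: the local-concentration model,
in which each tether merely raises the local free-monomer concentration
(one tether carries up to 4 monomers), predicting the strictly linear
density response <E> = kon * c0 * (1 + 4 d) - koff that the measured
data do not show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import KOFF_BARBED, KON0_BARBED, LATTICE_SIZE, derive_seed

__all__ = [
    "MCConfig",
    "AllostericParams",
    "DensityResponse",
    "LocalConcModel",
    "place_tethers",
    "effective_kon",
    "enhancement_profile",
    "simulate_elongation",
    "chi_square",
    "grid_fit",
    "local_concentration_velocity",
]


@dataclass
class MCConfig:
    """Configuration of one Monte Carlo elongation run."""

    kon0: float = KON0_BARBED  # subunits uM^-1 s^-1
    koff: float = KOFF_BARBED  # subunits s^-1
    conc: float = 1.0  # uM
    lattice_size: int = LATTICE_SIZE  # monomers
    mode: str = "expected"  # "expected" | "stochastic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kon0 <= 0:
            raise ValueError("kon0 must be positive")
        if self.koff < 0 or self.conc < 0:
            raise ValueError("koff and conc must be non-negative")
        if self.lattice_size < 1000:
            raise ValueError("lattice_size must be >= 1000")
        if self.mode not in ("expected", "stochastic"):
            raise ValueError("mode must be 'expected' or 'stochastic'")


@dataclass
class AllostericParams:
    """Fitted allosteric parameters with delta-chi-square intervals."""

    alpha: float
    lc: float  # monomers
    chi2_min: float
    ci68_alpha: tuple[float, float]
    ci95_alpha: tuple[float, float]
    ci68_lc: tuple[float, float]
    ci95_lc: tuple[float, float]
    boundary: bool = False  # optimum on the grid boundary; intervals open


@dataclass
class DensityResponse:
    """Elongation velocity versus tether surface density."""

    density: np.ndarray  # molecules/um^2
    occupancy: np.ndarray  # per-site probability
    v: np.ndarray  # mean elongation velocity, subunits/s
    std: np.ndarray  # spread over replicates/filaments, subunits/s
    n: np.ndarray  # replicates per point

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        shapes = {a.shape for a in (self.density, self.occupancy, self.v, self.std, self.n)}
        if len(shapes) != 1:
            raise ValueError("all DensityResponse columns must have equal length")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancy must lie in [0, 1]")
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density_per_um2": self.density,
                "occupancy": self.occupancy,
                "v_mean": self.v,
                "v_std": self.std,
                "n": self.n,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DensityResponse":
        return cls(
            density=df["density_per_um2"].to_numpy(),
            occupancy=df["occupancy"].to_numpy(),
            v=df["v_mean"].to_numpy(),
            std=df["v_std"].to_numpy(),
            n=df["n"].to_numpy(),
        )


@dataclass
class LocalConcModel:
    """Parameters of the (rejected) local-concentration alternative model."""

    kon: float  # subunits uM^-1 s^-1
    koff: float  # subunits s^-1
    c0: float  # bulk actin concentration, uM
    d: float  # dimensionless tether surface-density term

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.d < 0:
            raise ValueError("c0 and d must be non-negative")


# ---------------------------------------------------------------------------
# forward model


def place_tethers(n_sites: int, occupancy: float, seed_or_rng=0) -> np.ndarray:
    """Occupy each lattice site independently with probability ``occupancy``.

    Returns ascending site indices; reproducible given the same seed.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    if occupancy == 0.0:
        return np.empty(0, dtype=np.int64)
    if occupancy == 1.0:
        return np.arange(n_sites, dtype=np.int64)
    return np.nonzero(rng.random(n_sites) < occupancy)[0]


def _distance_to_tether(n_sites: int, tethers: np.ndarray) -> np.ndarray:
    """For each site i: i minus the nearest tether index <= i (inf if none)."""
    last = np.full(n_sites, -np.inf)
    t = np.asarray(tethers, dtype=np.int64)
    if t.size:
        last[t] = t
    last = np.maximum.accumulate(last)
    return np.arange(n_sites) - last


def enhancement_profile(n_sites: int, tethers, alpha: float, lc: float) -> np.ndarray:
    """Per-site rate factor: 1 + (alpha - 1) * max(0, 1 - d/L_C).

    ``d`` is the distance to the nearest tether at or behind the site.
    Because the linear decay is monotone in distance, the maximum over
    all contributing tethers is attained by the nearest one, so the
    factor is bounded by alpha as required.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if lc < 1:
        raise ValueError("lc must be >= 1 monomer")
    d = _distance_to_tether(n_sites, np.asarray(tethers, dtype=np.int64))
    with np.errstate(invalid="ignore"):
        w = np.clip(1.0 - d / lc, 0.0, None)
    w[~np.isfinite(d)] = 0.0
    return 1.0 + (alpha - 1.0) * w


def effective_kon(i: int, tethers, alpha: float, lc: float, kon0: float = KON0_BARBED) -> float:
    """Effective association rate at tip site ``i`` (scalar reference form).

    Takes the maximum perturbation over all tethers j <= i within L_C:
    at a tether site the rate is exactly alpha * kon0; it decays
    linearly to kon0 over L_C monomers; sites with no qualifying tether
    keep the basal kon0.
    """
    t = np.asarray(tethers, dtype=np.int64)
    behind = t[(t <= i) & (i - t < lc)]
    if behind.size == 0:
        return kon0
    w = np.max(1.0 - (i - behind) / lc)
    return kon0 * (1.0 + (alpha - 1.0) * w)


def _gillespie_velocity(assoc_rates: np.ndarray, koff: float, rng: np.random.Generator) -> float:
    """Event-driven polymerisation over the lattice; returns subunits/s.

    The tip performs a birth-death walk (association at the site-local
    rate, dissociation at koff) until the full lattice is polymerised;
    velocity is lattice length over elapsed time.
    """
    n = assoc_rates.size
    i = 0
    t = 0.0
    # pre-draw random numbers in blocks to keep the event loop cheap
    block = 1 << 14
    exp_pool = rng.exponential(size=block)
    uni_pool = rng.random(size=block)
    k = 0
    while i < n:
        if k == block:
            exp_pool = rng.exponential(size=block)
            uni_pool = rng.random(size=block)
            k = 0
        a = assoc_rates[i]
        total = a + (koff if i > 0 else 0.0)
        t += exp_pool[k] / total
        if uni_pool[k] * total < a:
            i += 1
        else:
            i -= 1
        k += 1
    return n / t


def simulate_elongation(cfg: MCConfig, alpha: float, lc: float, occupancy: float) -> float:
    """Mean elongation velocity (subunits/s) for one random tether placement.

    Expected mode averages the instantaneous net rate over every lattice
    site; stochastic mode runs the event-driven polymerisation.  Both
    are reproducible from ``cfg.seed``.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    tethers = place_tethers(cfg.lattice_size, occupancy, rng)
    keff = cfg.kon0 * enhancement_profile(cfg.lattice_size, tethers, alpha, lc)
    if cfg.mode == "expected":
        return float(np.mean(keff) * cfg.conc - cfg.koff)
    rates = keff * cfg.conc
    if cfg.koff >= np.min(rates):
        raise ValueError("stochastic mode requires koff < association rate everywhere (net growth)")
    return float(_gillespie_velocity(rates, cfg.koff, rng))


# ---------------------------------------------------------------------------
# chi-square grid fitting


def chi_square(v_data, sim_v, std) -> float:
    """Sum of squared standardized residuals, sum_i ((v_i - vsim_i)/std_i)^2."""
    v_data = np.asarray(v_data, dtype=float)
    sim_v = np.asarray(sim_v, dtype=float)
    std = np.asarray(std, dtype=float)
    if not (v_data.shape == sim_v.shape == std.shape):
        raise ValueError("v_data, sim_v and std must have matching shapes")
    if np.any(std <= 0):
        raise ValueError("std must be positive for every point; set a floor on zero spreads")
    return float(np.sum(((v_data - sim_v) / std) ** 2))


def _mean_decay_weight(distances: np.ndarray, lc: float) -> float:
    """Lattice mean of max(0, 1 - d/L_C) given distances to nearest tether."""
    w = 1.0 - distances / lc
    return float(np.sum(w[w > 0]) / distances.size)


def grid_fit(
    data: DensityResponse,
    cfg: MCConfig | None = None,
    alpha_grid=None,
    lc_grid=None,
    refine_factor: int = 5,
    reps: int = 20,
    std_floor: float = 0.01,
    max_rounds: int = 10,
) -> AllostericParams:
    """Two-stage chi-square grid fit of (alpha, L_C) to density data.

    A coarse grid (by default alpha log-spaced over [0.1, 20], L_C
    linear over [1, 400], 30 x 30) roughly locates the optimum; a
    refined stage then zooms in with local grids at ``refine_factor`` x
    resolution.  Because the chi-square surface forms a narrow curved
    valley in (alpha, L_C) when the measured spreads are small, the
    refined stage is iterated: each round re-grids around the current
    minimum, keeping its span when the minimum sits on the local grid
    edge (walking along the valley) and shrinking otherwise, for at
    most ``max_rounds`` rounds.  Simulated velocities are the mean over
    ``reps`` independent tether placements per density (expected-rate
    mode, placements seeded from ``cfg.seed``).
    Per-parameter confidence intervals are the extreme evaluated grid
    values with chi2 <= chi2_min + 1 (68%) and + 4 (95%); an optimum on
    the coarse-grid boundary is flagged and its intervals are open.

    ``std_floor`` (subunits/s) replaces zero or tiny measured spreads so
    exactly reproduced points cannot produce infinite weights.
    """
    cfg = cfg if cfg is not None else MCConfig()
    if data.v.size < 3:
        raise ValueError("grid fit needs at least 3 density points")
    if alpha_grid is None:
        alpha_grid = np.geomspace(0.1, 20.0, 30)
    else:
        alpha_grid = np.asarray(alpha_grid, dtype=float)
    if lc_grid is None:
        lc_grid = np.linspace(1.0, 400.0, 30)
    else:
        lc_grid = np.asarray(lc_grid, dtype=float)

    std = np.maximum(data.std, std_floor)

    # one tether placement per (density, replicate); reused across the grid
    dist = [
        [
            _distance_to_tether(
                cfg.lattice_size,
                place_tethers(cfg.lattice_size, occ, derive_seed(cfg.seed, f"grid-fit:{j}:{r}")),
            )
            for r in range(reps)
        ]
        for j, occ in enumerate(data.occupancy)
    ]

    def chi2_map(a_grid: np.ndarray, l_grid: np.ndarray) -> np.ndarray:
        # mean decay weight depends only on (density point, L_C); velocity is
        # affine in alpha, so the chi-square map factorises cheaply
        wbar = np.empty((len(dist), l_grid.size))
        for j, placements in enumerate(dist):
            for li, lc in enumerate(l_grid):
                wbar[j, li] = np.mean([_mean_decay_weight(d, lc) for d in placements])
        # vsim[a, j, l]
        vsim = cfg.kon0 * cfg.conc * (1.0 + (a_grid[:, None, None] - 1.0) * wbar[None]) - cfg.koff
        resid = (data.v[None, :, None] - vsim) / std[None, :, None]
        return np.sum(resid**2, axis=1)  # (alpha, lc)

    chi2_coarse = chi2_map(alpha_grid, lc_grid)
    ia, il = np.unravel_index(np.argmin(chi2_coarse), chi2_coarse.shape)
    boundary = ia in (0, alpha_grid.size - 1) or il in (0, lc_grid.size - 1)

    # Polish the coarse optimum by a continuous simplex search before
    # regridding: when measured spreads are small, the chi-square surface
    # is a narrow valley running diagonally through (alpha, L_C), which a
    # purely axis-aligned local grid cannot descend.
    a_min, a_max = float(alpha_grid[0]), float(alpha_grid[-1])
    l_min, l_max = max(float(lc_grid[0]), 1.0), float(lc_grid[-1])

    def objective(p):
        a = float(np.clip(np.exp(p[0]), a_min, a_max))
        lc = float(np.clip(p[1], l_min, l_max))
        return chi2_map(np.array([a]), np.array([lc]))[0, 0]

    from scipy.optimize import minimize

    start = np.array([np.log(alpha_grid[ia]), lc_grid[il]])
    res = minimize(
        objective,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
    )
    opt_alpha = float(np.clip(np.exp(res.x[0]), a_min, a_max))
    opt_lc = float(np.clip(res.x[1], l_min, l_max))

    # refined grid at refine_factor x resolution, one coarse step on each side
    n_ref = 2 * refine_factor + 1
    ratio = (alpha_grid[-1] / alpha_grid[0]) ** (1.0 / (alpha_grid.size - 1))
    step_l = (lc_grid[-1] - lc_grid[0]) / (lc_grid.size - 1)
    alpha_ref = np.geomspace(opt_alpha / ratio, opt_alpha * ratio, n_ref)
    lc_ref = np.maximum(np.linspace(opt_lc - step_l, opt_lc + step_l, n_ref), 1.0)
    chi2_ref = chi2_map(alpha_ref, lc_ref)
    ja, jl = np.unravel_index(np.argmin(chi2_ref), chi2_ref.shape)
    best_alpha = float(alpha_ref[ja])
    best_lc = float(lc_ref[jl])
    chi2_min = float(chi2_ref[ja, jl])

    eval_alpha = [np.repeat(alpha_grid, lc_grid.size), np.repeat(alpha_ref, lc_ref.size)]
    eval_lc = [np.tile(lc_grid, alpha_grid.size), np.tile(lc_ref, alpha_ref.size)]
    eval_chi2 = [chi2_coarse.ravel(), chi2_ref.ravel()]

    # Resolve the delta-chi2 <= 4 region: its extent bears no relation to
    # the refined grid step (it shrinks with the measured stds), so adapt a
    # dedicated confidence grid until the region is neither clipped by the
    # grid edges nor unresolved between nodes.
    n_ci = 21
    half_a = 2.0 * np.log(alpha_ref[1] / alpha_ref[0])  # log-alpha half-span
    half_l = 2.0 * (lc_ref[1] - lc_ref[0])
    for _ in range(8):
        a_ci = best_alpha * np.exp(np.linspace(-half_a, half_a, n_ci))
        l_ci = np.maximum(np.linspace(best_lc - half_l, best_lc + half_l, n_ci), 1.0)
        chi2_ci = chi2_map(a_ci, l_ci)
        eval_alpha.append(np.repeat(a_ci, l_ci.size))
        eval_lc.append(np.tile(l_ci, a_ci.size))
        eval_chi2.append(chi2_ci.ravel())
        chi2_min = min(chi2_min, float(chi2_ci.min()))
        in95 = chi2_ci <= chi2_min + 4.0
        grow_a = in95[0, :].any() or in95[-1, :].any()
        grow_l = in95[:, 0].any() or in95[:, -1].any()
        rows = np.nonzero(in95.any(axis=1))[0]
        cols = np.nonzero(in95.any(axis=0))[0]
        shrink_a = not grow_a and rows.size < 5
        shrink_l = not grow_l and cols.size < 5
        if grow_a:
            half_a *= 2.0
        elif shrink_a:
            half_a /= 3.0
        if grow_l:
            half_l *= 2.0
        elif shrink_l:
            half_l /= 3.0
        if not (grow_a or grow_l or shrink_a or shrink_l):
            break

    all_alpha = np.concatenate(eval_alpha)
    all_lc = np.concatenate(eval_lc)
    all_chi2 = np.concatenate(eval_chi2)
    imin = int(np.argmin(all_chi2))
    if all_chi2[imin] < chi2_min:
        chi2_min = float(all_chi2[imin])
    best_alpha = float(all_alpha[imin])
    best_lc = float(all_lc[imin])

    def interval(delta: float, values: np.ndarray) -> tuple[float, float]:
        sel = values[all_chi2 <= chi2_min + delta]
        return (float(sel.min()), float(sel.max()))

    return AllostericParams(
        alpha=best_alpha,
        lc=best_lc,
        chi2_min=chi2_min,
        ci68_alpha=interval(1.0, all_alpha),
        ci95_alpha=interval(4.0, all_alpha),
        ci68_lc=interval(1.0, all_lc),
        ci95_lc=interval(4.0, all_lc),
        boundary=bool(boundary),
    )


def local_concentration_velocity(m: LocalConcModel) -> float:
    """Mean elongation under the local-concentration model.

    Each tether is assumed to raise the locally available monomer pool
    (one tether binds up to 4 monomers), giving a lattice-average
    concentration <c> = c0 (1 + 4 d) and hence the strictly linear
    density response <E> = kon * c0 * (1 + 4 d) - koff.  Kept as the
    documented alternative that the measured density dependence rules
    out.
    """
    return m.kon * m.c0 * (1.0 + 4.0 * m.d) - m.koff
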