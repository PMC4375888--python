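# Methods

`filakin` analyses the elongation kinetics and bending mechanics of
single actin filaments imaged by TIRF microscopy while tethered to a
glass surface through side-binding proteins (filamin, α-actinin,
NEM-inactivated myosin, VASP). This note describes the models the
package implements, the synthetic data it tests itself against, and the
numerical choices made where the underlying procedures were open.

## Unit conventions

Filament lengths are interconverted with **370 subunits per micron**;
tether surface densities (molecules/μm²) are converted to tethers per
micron of filament with the **0.006 μm²** area occupied by 1 μm of
adsorbed filament, and on to fractional lattice occupancy by dividing
by 370 (capped at 1). Adsorbed-protein surface density follows from the
applied concentration, a 10 μL sample volume, and a 100 mm² flow-cell
area counted on both glass surfaces. Velocities are in subunits/s,
concentrations in μM (μM⁻¹·s⁻¹ for association rates).

## End tracking in kymographs (`filakin.kymo`)

A filament end in one kymograph row is a step edge blurred by the PSF,
modelled as

    I(x) = B + (A/2) · [1 + p·erf((x − μ)/(√2·σ))],  p = ±1.

The four parameters are fitted per row by bounded least squares
(`scipy.optimize.curve_fit`), with μ initialised at the
maximum-magnitude gradient and bounds μ ∈ [0, n−1], σ ∈ (0.3, 10] px,
A ≥ 0. A fit is rejected when it does not converge or when
A < 3 × the robust noise SD of the profile (successive-difference MAD),
which catches the no-filament case. Pixel coordinates are 0-based pixel
centers; row k is time k·Δt. Both edges of the single filament segment
per row are fitted (profile split at the midpoint between the extreme
gradients); failed rows are carried as NaN gaps, never interpolated,
and ΔL is referenced to the first successful row. A user-supplied
fiduciary-marker trace can be subtracted to remove filament sliding.

Stage drift in movies is estimated against the first frame by
cross-correlation with subpixel peak localisation via locally upsampled
matrix-DFT cross-correlation, and removed by cubic-spline resampling
(`scipy.ndimage.shift`, order 3); border pixels without support are
flagged. Local parabolic peak interpolation was evaluated and rejected:
on smooth test scenes shifted by 0.5 px it mis-localised by up to
0.3 px, while the upsampled-DFT localisation is exact for integer
shifts and <0.01 px for subpixel ones.

## Elongation kinetics (`filakin.kinetics`)

Instantaneous velocity is the centred finite difference of ΔL(t)
smoothed by a centred running mean (default window 10 samples, shrunken
at the edges). Samples with smoothed velocity above **1.5 subunits/s**
are "kinetically active"; the paused fraction of samples is the pausing
probability P_p. Runs shorter than `min_run` (default 3 samples) are
merged into the surrounding phase — the threshold value is standard for
this assay, the debouncing is this package's choice to suppress
single-sample flicker.

The pause-free elongation velocity E is the duration-weighted mean of
per-run least-squares slopes over active runs of ≥3 samples (SEM across
runs). Fitting E against actin concentration c with weighted least
squares (statsmodels; weights 1/SEM² when given) yields
kon (slope), koff (negative intercept — reported as-is even when
negative, as happens within error for some conditions) and the critical
concentration cc = koff/kon. Confidence intervals are 95%, from the
t distribution with n−2 degrees of freedom.

## Allosteric lattice Monte Carlo (`filakin.allosteric`)

The model asks how surface tethers modify elongation. A filament is a
lattice of N monomers (default 10⁵); each site carries a tether
independently with the occupancy derived from the surface density. A
tether at site j sets the association rate at its own position to
α·kon⁰ and the perturbation decays linearly to the basal kon⁰ over L_C
monomers ahead of it:

    kon_eff(i) = kon⁰ · [1 + (α − 1) · max(0, 1 − (i − j)/L_C)]

for the nearest tether j ≤ i. Overlapping perturbations take the
maximum (never the sum), keeping the rate bounded by α·kon⁰; tethers
ahead of the tip exert no influence (they can only bind polymerised
lattice); koff is never modified; L_C = 1 means the effect exists only
at the tether site itself. Defaults kon⁰ = 11 μM⁻¹s⁻¹ and
koff = 2 s⁻¹ are the literature barbed-end values.

Velocity has two definitions:

* **expected** (default, used for fitting): the lattice average of the
  instantaneous net rate, mean_i[kon_eff(i)·c] − koff;
* **stochastic**: event-driven polymerisation (Gillespie birth–death
  walk of the tip), velocity = N / elapsed time.

These coincide for homogeneous rates (zero occupancy, or α = 1) but
*not* under strong rate heterogeneity: traversal time weights slow
stretches more heavily (a harmonic- vs arithmetic-mean effect), so the
stochastic traversal velocity falls measurably below the site-averaged
rate at, e.g., α ≈ 5 and 1% occupancy. The site-averaged definition is
the fitting model; the stochastic mode exists for realism checks in
the homogeneous regime and for generating event-level traces.

### χ² grid fit

(α, L_C) are fitted to elongation-versus-density data by minimising
χ² = Σᵢ ((v(xᵢ) − v_sim(xᵢ))/std(xᵢ))² with v_sim the mean over
`reps` (default 20) independent tether placements. Because the mean
decay weight depends only on (placement, L_C) and the velocity is
affine in α, the χ² map over an (α, L_C) grid is evaluated from one
set of per-placement distance arrays.

The search is staged: a coarse grid (α log-spaced over [0.1, 20],
L_C linear over [1, 400], 30 × 30 — spanning the physically plausible
regime with margin), then a refined grid at 5× resolution. Two
numerical refinements proved necessary on noiseless synthetic data,
where tiny replicate spreads make the χ² surface a narrow valley
running diagonally through (α, L_C):

1. a Nelder–Mead polish of χ²(log α, L_C) between the stages — an
   axis-aligned refined grid centred on the coarse argmin cannot
   descend the diagonal valley and misses the basin entirely;
2. an adaptive confidence-region grid after the refined stage — the
   Δχ² ≤ 4 region bears no relation to the refined step size, so a
   21 × 21 local grid doubles its span while the region is clipped by
   its edges and shrinks while under-resolved.

Confidence intervals are the extreme evaluated grid values with
χ² ≤ χ²_min + 1 (68%) and + 4 (95%); zero/tiny measured spreads are
floored (default 0.01 subunits/s) so exactly reproduced points cannot
carry infinite weight. An optimum on the coarse-grid boundary is
flagged and its intervals reported as open. Round-trip recovery on
noiseless forward data is within one refined-grid step across
α ∈ {0.4, 5.1, 9}, L_C ∈ {1, 11, 76, 160} at lattice 10⁴ and 20
replicate placements.

### Local-concentration alternative

The rejected alternative model — each tether merely raises the local
free-monomer pool (one tether carrying up to 4 monomers), giving
⟨E⟩ = kon·c₀·(1 + 4d) − koff — is implemented for comparison; it
predicts a strictly linear density response that measured data do not
show.

## Persistence length (`filakin.persistence`)

The apparent persistence length of surface-adsorbed (2D) filaments is
defined through the tangent-angle correlation
⟨cos[θ(s) − θ(0)]⟩ = e^(−s/(2·L_p)); no 3D conversion factor is
applied. Contours are arc-length resampled to uniform spacing (6–10
points per micron recommended), tangents come from central differences,
and the correlation is pooled over all admissible point pairs of all
contours (per-filament averaging is available but not the default).
L_p is obtained by nonlinear least squares on the cosine values —
robust when the correlation approaches zero, where a log-linear fit is
not. The default fit range caps separations at half the mean contour
length, where estimates stop being pair-starved; non-positive
correlations shrink the range with a warning, and correlations
indistinguishable from 1 return a `capped` flag instead of a finite
L_p. Known small biases of the estimator: the central-difference
tangent is effectively a half-step-offset chord direction, and contour
endpoints use one-sided differences — both negligible against the
sampling spread at the recommended spacing (mean recovery bias <10%
for L_p ∈ {2.2, 5, 18} μm at 200 chains of 10 μm).

## Synthetic data (`filakin.synthetic`)

The generators emulate the assay with known ground truth:

* **Growth traces** — a two-state (elongating/paused) continuous-time
  Markov chain sampled on the dt grid; elongating intervals add
  Poisson(kon·c·dt) − Poisson(koff·dt) subunits (or the exact expected
  increment in deterministic mode, for exact tests); paused intervals
  add none; total length is truncated at zero. The underlying
  experiments report pause statistics but not microscopic switching
  rates, so the pause entry/exit rates are *fixtures*, not biological
  estimates.
* **Kymographs** — per row, a plateau of `amplitude` over `background`
  between the two end positions, blurred analytically as a difference
  of error functions (so the generating end positions are exactly the
  edge centers), with optional Poisson shot noise and Gaussian read
  noise (the standard camera model). The barbed end is rendered as the
  right-hand edge by default.
* **Worm-like chains** — planar chains of segment length 1/spacing
  whose turning angles are N(0, Δs/L_p), realising exactly the 2D
  correlation law above.
* **Density responses** — the forward allosteric model evaluated at a
  density list with independent tether placements per replicate and
  optional Gaussian measurement noise.

All generators are bit-reproducible from their seeds; all pipeline
randomness derives from a single global seed through named, hashed
substreams.

What the generators do **not** emulate: filament bending in the image
(kymographs assume a straightened axis), fragmentation/annealing,
ATP-hydrolysis states, photobleaching, tether binding/unbinding
kinetics, and multi-filament scenes. Passing round-trip tests therefore
demonstrates the correctness of the estimators under the stated model,
not robustness to every artefact of real movies.

## Problem sizes

Default test and reproduction runs use lattices of 10⁴–10⁵ monomers,
8 densities × 20 placements for the density round trip, 200 chains for
persistence recovery, and 500 replicates for CI-coverage checks —
sizes at which every stochastic check sits comfortably inside its
tolerance while the full suite runs in well under a minute.

## Known limitations

* The erf edge fitter assumes one filament segment per row with both
  edges inside the image; crossing filaments and ends within ~4σ of
  the border are out of scope.
* The Δχ² intervals are grid-based extremes of the evaluated nodes, so
  their resolution is bounded by the adaptive confidence grid.
* The stochastic elongation mode requires net growth at every site
  (koff below the smallest association propensity); shrinking regimes
  are expected-mode only.
* P_p near phase boundaries depends on the smoothing window: a heavily
  smoothed velocity blurs the active/paused transition by ~window/2
  samples.
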