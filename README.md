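# filakin

Analysis of single actin-filament elongation from TIRF microscopy of
surface-tethered filaments: subpixel end tracking in kymographs,
elongation/pause kinetics and rate-constant estimation, a lattice
Monte Carlo model of how side-binding proteins (filamin, α-actinin,
NEM-myosin, VASP) modulate elongation, and worm-like-chain persistence
length estimation. Every stage ships with a synthetic-data generator
carrying known ground truth, so the whole pipeline is testable without
any microscope data.

## The science in brief

In the assay, single actin filaments grow while tethered to a glass
surface through a side-binding protein, and a kymograph (time × position
image) is built per filament. `filakin` implements the quantitative
chain:

* **End detection.** Each filament end in a kymograph row is a
  PSF-blurred intensity step, fitted with an error function
  `I(x) = B + (A/2)[1 + p·erf((x−μ)/(√2σ))]` to give the end position μ
  with subpixel precision; positions calibrate to microns (pixel size)
  and to subunits (370 subunits/μm).
* **Kinetics.** Velocities above 1.5 subunits/s define kinetically
  active phases; the paused time fraction is the pausing probability
  P_p. Pause-free velocity E versus actin concentration c follows
  `E = k_on·c − k_off`, so a weighted linear fit gives the association
  rate (slope), dissociation rate (−intercept) and critical
  concentration `c_c = k_off/k_on`, with 95% t-based confidence
  intervals.
* **Allosteric lattice model.** On a 10⁵-monomer lattice with randomly
  placed tethers, a tether multiplies the local association rate by α,
  decaying linearly back to k_on⁰ over L_C monomers. (α, L_C) are fitted
  to elongation-versus-tether-density data by a staged χ² grid search
  with Δχ² = 1 / 4 (68%/95%) confidence intervals. The rejected
  "local concentration" alternative, `⟨E⟩ = k_on·c₀(1+4d) − k_off`, is
  included for comparison.
* **Mechanics.** The apparent persistence length of surface-adsorbed
  filaments comes from the tangent-angle correlation
  `⟨cos[θ(s)−θ(0)]⟩ = e^(−s/2L_p)`.

See `docs/methods.md` for model assumptions, parameter defaults and
numerical choices.

## Worked example

Simulate a pausing filament at 1 μM actin (k_on = 11 μM⁻¹s⁻¹,
k_off = 2 s⁻¹), render it as a noisy kymograph, track the ends, and
recover the kinetics:

```python
import numpy as np
from filakin import synthetic, kymo, kinetics

gp = synthetic.GrowthParams(kon=11, koff=2, conc=1,
                            pause_entry_rate=0.01, pause_exit_rate=0.04,
                            duration=400, dt=1, seed=5)
trace = synthetic.simulate_growth_trace(gp)
kg = synthetic.render_kymograph(trace, synthetic.RenderParams(
    pixel_size_um=0.1, psf_sigma=2.0, noise_model="poisson",
    read_noise_sd=2.0, seed=5))
barbed, pointed = kymo.track_ends(kg)

pf = kinetics.pause_free_velocity(barbed)
phases = kinetics.classify_phases(kinetics.smooth_velocity(barbed))
print(f"pause-free E = {pf.velocity:.2f} +/- {pf.sem:.2f} subunits/s over {pf.n_runs} runs")
print(f"pausing probability P_p = {phases.pausing_probability:.3f}")
```

prints

```
pause-free E = 9.18 +/- 0.19 subunits/s over 4 runs
pausing probability P_p = 0.137
```

The pause-free velocity recovers the generating net rate
k_on·c − k_off = 9 subunits/s from the rendered image alone; the
ground-truth paused fraction of this trace is 0.202, of which the
10-sample smoothing window resolves the longer pauses (P_p = 0.137).
Fitting velocities measured at several concentrations then yields the
rate constants:

```python
pts = [(c, 11.0 * c - 1.6, 0.3) for c in (0.3, 0.5, 1.0, 2.0)]
r = kinetics.fit_rate_constants(pts)
print(f"kon = {r.kon:.1f} /uM/s, koff = {r.koff:.1f} /s, cc = {r.cc:.3f} uM")
# kon = 11.0 /uM/s, koff = 1.6 /s, cc = 0.145 uM
```

The same stages are available from the shell:

```sh
filakin simulate-trace --kon 11 --koff 2 --duration 400 --out trace.csv
filakin render-kymo --trace trace.csv --noise poisson --out kymo.tif
filakin detect-ends --kymo kymo.tif --out ends.csv
filakin kinetics --traces ends.csv --out summary.json
filakin fit-mc --data density_response.csv --out fit.json
filakin persistence --contours contours.csv --out lp.json
```

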