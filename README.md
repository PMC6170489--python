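# fetkin — compartment-model kinetic analysis of dynamic ¹⁸F-FET PET

Dynamic O-(2-[¹⁸F]fluoroethyl)-L-tyrosine (FET) PET of gliomas is usually
read through static uptake measures (SUV_max, tumor-to-background ratio).
Voxelwise tracer-kinetic modeling extracts more: transfer constants that
separate blood flow and transport across the blood–brain barrier from
cellular amino-acid uptake, plus the fractional blood volume of the tissue.
`fetkin` implements that full analysis chain for researchers working with
dynamic FET PET — model solvers, bound-constrained voxelwise fitting,
goodness-of-fit and model selection, the static-image tools around them, and
a Monte-Carlo framework that quantifies how reliable each parameter estimate
is at clinical data quality.

## Models

With C_a(t) the arterial plasma input and C_T(t) the measured voxel signal:

* **One-tissue model (1TCM)** — a single tissue compartment C_t exchanging
  with blood,

      dC_t/dt = K₁ C_a − k₂ C_t,
      C_T = (1 − V_B) C_t + V_B C_a,

  and its **simplified form (s1TCM)** with V_B ≡ 0.
* **Two-tissue model (2TCM)** — interstitial (C₁) and intracellular (C₂)
  compartments, the latter fed by the LAT transport system,

      dC₁/dt = K₁ C_a − (k₂ + k₃) C₁ + k₄ C₂,
      dC₂/dt = k₃ C₁ − k₄ C₂,
      C_T = (1 − V_B)(C₁ + C₂) + V_B C_a.

All rates are in min⁻¹ and constrained to 0 ≤ kᵢ ≤ 1 during fitting; V_B is
the dimensionless blood-volume fraction (reported clinically as ml/100 ml).
The solvers are closed-form: C_a is taken piecewise-linear between frame
midpoints, for which the exponential convolutions and their per-frame time
averages have exact per-segment expressions (PET frames integrate the
signal over their duration, so model curves are frame-averaged by default).

Fit quality uses reduced chi-square with a scalar squared measurement error
(χ²_red = SSR / ((n−p) Δy²); Δy ≈ √y for measured data, Δy = AIF_peak/SNR
for simulated data) and model comparison uses the small-sample-corrected
Akaike criterion, cAIC = n ln(SSR/n) + 2(p+1) + 2(p+1)(p+2)/(n−p−2), lowest
wins.

## Worked example

```python
import numpy as np
import fetkin as fk

schedule = fk.clinical_schedule()              # 6x20 s, 8x60 s, 6x300 s
aif = fk.make_aif("I", peak=100.0, schedule=schedule)
truth = fk.table3_combinations()[0]            # K1=0.10, k2=0.20, k3=0.025, k4=0.05, VB=0.05
tac = fk.simulate_tac(truth, aif, schedule, noise=fk.NoiseModel(snr=100), rng=0)
fit = fk.fit_voxel(tac, aif, model="2TCM", seed=0)
print({k: round(float(getattr(fit.params, k)), 4) for k in fit.params.free_names})
print("ssr", round(float(fit.ssr), 3), "at_bound", fit.at_bound)
```

prints

```
{'K1': 0.1116, 'k2': 0.2712, 'k3': 0.0255, 'k4': 0.0, 'VB': 0.0505}
ssr 7.806 at_bound {'K1': False, 'k2': False, 'k3': False, 'k4': True, 'VB': False}
```

i.e. this noisy replicate recovers K₁ within ~12% and V_B within ~1%, while
the small exchange rate k₄ collapses onto the box edge and is flagged
`at_bound` — exactly the stability ranking the Monte-Carlo study quantifies
(K₁ and V_B robust, k₂/k₃/k₄ progressively less so). The SSR of ≈7.8 over
n−p = 15 degrees of freedom at noise SD 1.0 gives χ²_red ≈ 0.52.

The numbered scripts under `analysis/` run the full analyses and write
tables to `results/`:

1. `01_simulate_inputs.py` — synthetic AIFs (type I: zero first frame;
   type II: bolus already under way at scan start) and example TAC banks.
2. `02_noiseless_recovery.py` — exact-curve recovery of all ten grid
   combinations (worst relative error ~1e-11).
3. `03_robustness_study.py` — 10 combinations × 2 AIF types × 1000 noisy
   replicates at SNR 100, 2TCM refits, error quantiles per parameter.
4. `04_model_selection.py` — s1TCM/1TCM/2TCM fits on noisy 2TCM banks,
   ranked by cAIC (pooled: 2TCM lowest cAIC in ~66% of fits, s1TCM worst in
   ~100%).
5. `05_phantom_pipeline.py` — dynamic phantom → endpoint static image →
   SUV → 70% isocontour → SUV_max/SUR → image-derived AIF → voxelwise
   parameter maps.

A thin CLI mirrors the common operations: `fetkin simulate`, `fetkin
segment`, `fetkin fit`, `fetkin study` (see `fetkin --help`).

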