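# Methods

## Models and conventions

The package implements the simplified one-tissue (s1TCM, parameters K₁, k₂),
standard one-tissue (1TCM, + V_B) and two-tissue (2TCM, + k₃, k₄)
compartment models for a reversibly bound, non-metabolized tracer. The
measured voxel signal mixes tissue activity with fractional blood volume,
C_T = (1 − V_B)·C_tissue + V_B·C_a. Internally V_B is a dimensionless
fraction in [0, 1); clinical ml/100 ml values are that fraction × 100.

**Units.** Rates are min⁻¹ everywhere; frame schedules are stored in seconds
(the natural unit of acquisition metadata) and converted once at the model
boundary. Activity units are arbitrary but must be consistent between AIF
and TAC; everything downstream of the fit is unit-free or scales linearly.

**Frame schedule.** The default clinical schedule is 20 frames over 40 min:
6 × 20 s, 8 × 60 s, 6 × 300 s. PET frames accumulate decays over their
whole duration, so model curves are *frame-averaged* by default; a midpoint
evaluation fallback (`frame_averaged=False`) exists for speed comparisons.

**Decay correction** is assumed already applied to all inputs (clinical SUV
images are decay-corrected), so no ¹⁸F half-life term appears in the models.

## Solvers

Both models have exponential impulse responses, so C_tissue is a sum of
convolutions C_a ⊛ e^(−αt). The 2TCM eigenrates are
α₁,₂ = ½[(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)]; the discriminant is
non-negative for any non-negative rates. C_a is represented piecewise-
linearly between frame midpoints with constant extension at both ends (an
AIF sampled on frames gives no information inside a frame; the linear
interpolant admits *exact* convolution and frame-integration formulas, so no
Riemann-sum error enters). Per segment of width Δ the update uses the stable
functions φ₁ = (1−e^(−x))/x, φ₂ = (1−φ₁)/x, φ₃ = (½−φ₂)/x with x = αΔ,
switching to Taylor forms below x = 10⁻³ so a zero rate (running integral)
flows through the same code path. Blood-volume mixing uses the AIF's frame
values directly: measured AIF frames are already frame-integrated data.

Near-degenerate eigenvalues (|α₂−α₁| < 10⁻⁹ min⁻¹, e.g. k₃ = 0 with
k₂ = k₄) switch to the confluent t·e^(−αt) kernel, evaluated as a symmetric
derivative of the exponential convolution with step 10⁻⁵ min⁻¹; in the
batched evaluator the fast eigenrate is instead nudged 10⁻⁹ apart, a
continuous ~10⁻⁶ relative perturbation that is negligible against
acquisition noise.

Verification: all three solvers agree with an adaptive stiff ODE integrator
(LSODA, rtol 10⁻¹⁰, frame averages via an auxiliary cumulative integral) to
better than 10⁻⁴ relative over random draws across the whole constraint box,
and the 2TCM with k₃ = k₄ = 0 equals the 1TCM to 10⁻¹⁰.

## Fitting

Ordinary (unweighted) least squares with all rates box-constrained to
[0, 1] min⁻¹ and V_B to [0, 0.999]; the open interval of the constraint is
implemented as a closed box with `at_bound` flags (tolerance 10⁻⁶) rather
than penalty terms. The 2TCM SSR surface is multimodal, so each fit is a
5-point multi-start: one data-driven start (K₁ from the early-curve slope
divided by the early AIF level; k₂ = 0.1, k₃ = k₄ = V_B = 0.05) plus four
log-uniform draws in [10⁻³, 1] from the fit's seed. Lowest SSR wins; ties
break by fewer iterations, then lexicographic parameters. Non-converged fits
return their least-SSR iterate flagged `converged=False` — they are data,
not errors, and are retained in all summaries.

Two optimizer backends share this policy and the same per-curve start
points:

* `fit_voxel` — SciPy trust-region reflective least squares (reference
  path);
* `fit_tac_batch` — a projected Levenberg–Marquardt vectorized over
  thousands of curves (forward-difference Jacobians evaluated in one batched
  model call; per-row Marquardt damping; steps clipped to the box; rows
  freeze as they converge and each row's trajectory depends only on its own
  data, so results are independent of batch composition and execution
  order). `fit_image` and the simulation study use this path; the test suite
  checks it lands on the same optima as the reference (median SSR agreement
  ~10⁻³ on noisy curves, identical noiseless recovery).

Determinism: every voxel/replicate derives its seed from
(master seed, cell indices) via hash-based seed sequences, so any single
cell is reproducible in isolation and results do not depend on iteration
order.

## Fit quality and model selection

χ²_red = SSR / ((n−p)·Δy²) with a single scalar Δy². For measured data the
per-frame counting error Δy ≈ √y is collapsed to Δy² = mean(y) (a single
global factor keeps the statistic's form; per-frame weighting would change
the fit itself). For simulated data Δy = σ = AIF_peak/SNR exactly. AIC uses
n·ln(SSR/n) + 2(p+1) with p+1 counting the variance as a fitted quantity;
cAIC adds 2(p+1)(p+2)/(n−p−2). SSR = 0 (noiseless synthetic fits) yields a
−∞ sentinel with a warning rather than an exception. Model selection takes
the lowest cAIC; ties go to fewer parameters.

## Synthetic data

No arterial curves are published with clinical FET studies, so the generator
emulates the arterial input with a gamma-variate bolus plus washout tail:
A·(u/αβ)^α·e^(α−u/β) + c·(1−e^(−u/τ_r))·e^(−λu), u = t − t₀, with α = 2,
β = 0.12 min (bolus peak 14.4 s after onset, inside the 20-s frames),
c = 0.18, τ_r = 0.5 min, λ = 0.01 min⁻¹ (tail ≈ 10–20 % of peak at 40 min —
the shape of measured image-derived FET inputs). Type I sets onset at 25 s
so the first frame is exactly zero; type II starts the bolus 3 s before the
scan so the first frame already carries near-peak activity. Curves are
frame-averaged (64-point Gauss–Legendre per frame) and normalized so the
maximum *frame* value equals the requested peak exactly.

Acquisition noise is additive i.i.d. Gaussian with SD = AIF_peak/SNR,
SNR = 100 by default (the level of clinical dynamic FET data). Noisy frames
may go negative and are kept (clipping is available but off by default); the
fitters tolerate them. Noise calibration is tested: realized SD within 2 %
of nominal over ≥10⁴ samples.

The simulation grid is the fixed set of ten 2TCM parameter combinations
spanning low/high flow, washout, exchange and the single high-k₄ row
(combination 9, k₄ = 0.2 min⁻¹); all rows carry V_B = 0.05. Replicates
default to 1000 per combination per AIF type (a documented knob; the source
material quotes both 1000 and 10000).

What the generator does *not* emulate: scanner PSF, attenuation, scatter,
reconstruction correlations, motion, partial-volume effects, or
patient-specific AIF variability. Passing tests therefore demonstrate the
estimator's statistical behaviour at matched SNR and sampling, not
performance on any individual patient's data; quantitative error levels
shift with the exact AIF shape, which is why study-level checks are
tolerance-banded rather than cell-by-cell.

## Robustness study

For each (combination, AIF type): simulate N noisy TACs, refit with the
2TCM using the same AIF, and summarize E_abs = P_fit − P_input and
E_rel = E_abs/P_input·100 % per parameter by median and 25th/75th
percentiles (linear interpolation between order statistics — the common
default; a zero true value marks E_rel undefined for that parameter).
Bound-hitting fits are *included* in the main summaries, with a filtered
variant emitted alongside for sensitivity. Findings at SNR 100 (seeded runs
reproduced by `analysis/03_robustness_study.py` and the acceptance script):
K₁ medians mostly below ~5 % with quartiles inside ±30 %; k₂ the widest
absolute-error band in most settings; k₃/k₄ pulled upward by noise (positive
mean absolute error in ~3/4 of settings) though medians can sit below zero;
errors shrink monotonically with SNR (tested at 50/100/400). χ²_red
concentrates near 1 with heavy upper outliers from failed fits.

## Image tools

SUV uses body-weight normalization, SUV = C·(weight)/(injected activity)
(units cancel for kBq/ml, kg, MBq at 1 g/ml density). The endpoint static
image is the duration-weighted mean of frames whose midpoint lies in the
last 10 min (the last two 300-s frames on the clinical schedule).
Isocontour segmentation thresholds at a fraction (default 0.70) of the
reference maximum — global, or within a seed region — and keeps the largest
26-connected component; note the largest-component step means masks at
different fractions are nested only when the threshold stage stays
connected. SUR = SUV_max(lesion)/mean SUV(background); the background
region is operator-defined and supplied as a mask. Image-derived AIFs
average the artery-mask voxels per frame (optionally only the k
highest-peak voxels, a partial-volume mitigation) and convert whole blood
to plasma by ×(1 + 0.10); the factor's direction (plasma above whole blood,
red-cell exclusion of the tracer) is configurable.

## Problem sizes and numerical choices

Defaults used by the analysis scripts and acceptance run: 1000 replicates ×
20 settings (20 000 fits, ~1.5 min on one CPU via the batched fitter);
model-selection banks of 100–200 replicates per combination; phantoms ≤ 32³
voxels. Optimizer tolerances: ftol = xtol = 10⁻¹⁰ (batched path freezes rows
on those), max 150 LM iterations / 400 function evaluations per start.
Quantiles: linear interpolation. Degenerate inputs: empty masks, mismatched
schedules, non-positive doses/weights, n ≤ p+2 and zero-variance error
models raise `ValueError` with a specific message; SSR = 0 warns and returns
−∞ criteria.

## Known limitations

* The AIF family is an emulation; absolute error magnitudes (especially for
  k₃ in low-exchange settings) depend on bolus sharpness and tail level.
* Ordinary least squares only; weighted fitting is out of scope by design.
* No irreversible (k₄ = 0-fixed) or reference-region model variants, no
  metabolite correction (the tracer is not metabolized over the scan).
* The projected-LM batch fitter can, like any local optimizer, stop at a
  different local optimum than the reference path on a small fraction of
  noisy curves; multi-start makes this rare and the flags expose it.
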