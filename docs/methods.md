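# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the known limitations of `dualkin`.

## Acquisition model

Two simultaneous dynamic series on a common, pre-registered 2 mm
isotropic grid:

- **PET**: 41 frames spanning one hour, histogrammed as 12 × 10 s,
  12 × 20 s, 4 × 60 s, 5 × 120 s, 8 × 300 s; activity in kBq/mL.
- **DCE-MRI**: 120 SPGR frames of 3.03 s each (the per-frame figures are
  taken as authoritative; note they total 363.6 s, slightly more than the
  nominal 6 min acquisition).

Frame timing is carried explicitly (`FrameSchedule`); kinetic models are
evaluated at frame midpoints, and for PET — whose frame lengths span
10–300 s — the continuous model is additionally averaged within each
frame window. Registration, segmentation and T10 estimation are out of
scope: masks and the T10 map are inputs, and grid equality is checked,
never corrected.

## PET kinetics

Irreversible two-tissue compartment model (free + phosphorylated FDG)
with a fractional blood-volume term; see the README for the equations.
The ODE system is linear; it is integrated with an explicit second-order
Runge-Kutta (Heun) scheme on a fixed 1 s internal grid (configurable),
with the input function linearly interpolated onto that grid. Accuracy
against the constant-input closed form is ~1e-6 relative at 1 s steps,
and ~2e-6 against a tolerance-1e-10 RK45 reference on a realistic input —
comfortably below fitting noise.

Voxel fits minimize unweighted squared residuals between the measured
TAC and the frame-averaged model using bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective; the classical
Levenberg-Marquardt update does not support bounds). Initialization
K1 = 0.1, k2 = 0.1, k3 = 0.05, v_b = 0.05; bounds: rates in [0, 5] min⁻¹,
v_b in [0, 1]. Frame-duration weighting is available behind a flag but
off by default. All-zero or non-finite TACs are flagged invalid, never
raised. Failed or invalid voxels appear as NaN in every parametric map.

The image-derived input function (IDIF) is the mean TAC of the aortic
VOI, used as both C_p and C_wb with no plasma or metabolite correction
(FDG equilibrates rapidly across the red-cell membrane; a
hematocrit-scaling flag exists for sensitivity analyses). Derived maps:
Ki = K1·k3/(k2+k3) (defined as 0 when k3 = 0) and
MRGlu = Ki·glycaemia/LC with LC = 1 by default.

### IDIF reconstruction

An IDIF sample is the *average* of the blood curve over its frame
window, not its midpoint value; for a first-pass bolus sampled by 10 s
frames the distinction matters (midpoint reading biases fitted
parameters by 1–3%). `aif_from_idif` therefore offers three modes:

1. `midpoint` — samples read as midpoint values (the naive reading);
2. `frame-consistent` — a nonparametric constrained deconvolution: the
   non-negative minimum-curvature piecewise-linear curve, anchored at
   zero at the scan start, whose frame averages reproduce every sample;
3. `model` (pipeline default) — a delayed Feng tri-exponential input
   model fitted by least squares to the frame-averaged samples, the
   standard model-based way to recover sub-frame structure; it also
   denoises the tail.

On phantom data the model-based mode recovers the continuous input to
< 1% of peak and leaves no measurable parameter bias; the nonparametric
mode is the fallback when no input-model family can be assumed.

## DCE kinetics

The SPGR conversion implements the exact algebraic inverse of the
steady-state signal equation; with B(t) = (S(t)/S0)·(1−E)/(1−cos α·E)
and E = e^(−TR/T10),

    C(t) = −1/(r·TR) · [ TR/T10 + ln( (B−1)/(B·cos α − 1) ) ],

multiplied by 1/(1−Hct) for the arterial curve only (tissue curves are
not hematocrit-corrected by default; a literal everywhere-corrected mode
exists, since conventions differ). S(t) = S0 maps to C = 0 exactly, and
the forward/inverse pair round-trips to ~1e-14 mM. Samples outside the
invertible signal range (non-positive log argument or non-positive
signal) are flagged and dropped from both the residual and the rRMSE; a
voxel is flagged missing when more than 20% of its samples drop.

Acquisition defaults: TR 3.46 ms, flip angle 15°, relaxivity
3.4 s⁻¹·mM⁻¹ (a macrocyclic gadolinium agent at 3 T), Hct 0.45 — all
configurable. S0 is estimated per voxel as the mean of the pre-bolus
frames; bolus arrival is detected on the arterial signal as the first
sample above baseline + max(5 SD, 2% of baseline), robust to noiseless
baselines.

The extended Tofts convolution uses the exact recursive scheme for a
piecewise-linear plasma curve on a uniform grid (with a series limit for
Kep·Δt → 0), so the only discretization error is the piecewise-linear
representation of C_p itself (~1e-7 relative on smooth inputs). Fits use
the same bounded least-squares machinery; initialization Ktrans = 0.1
min⁻¹, v_e = 0.2, v_p = 0.02; bounds Ktrans ∈ [0, 5] min⁻¹,
v_e ∈ [1e-3, 1] (the lower bound keeps Kep = Ktrans/v_e defined),
v_p ∈ [0, 1].

## Synthetic phantom

The generator (`dualkin.phantom`) defines the study conditions for every
validation in the package:

- 48 × 48 × 16 grid at 2 mm isotropic; an ellipsoidal tumor of ~520
  voxels, comparable to the smaller lesions the analysis targets.
- Two kinetic regions emulating the hypoxia-like decoupling pattern: a
  perfused rim (K1 0.15, k2 0.30, k3 0.05 min⁻¹, v_b 0.10; Ktrans 0.25
  min⁻¹, v_e 0.35, v_p 0.06) and a hypoperfused, metabolically active
  core (K1 0.08, k2 0.25, k3 0.15, v_b 0.03; Ktrans 0.06, v_e 0.25,
  v_p 0.015). k3 is thereby anticorrelated with Ktrans, v_p and v_b
  across the tumor.
- Within-region heterogeneity: seeded multiplicative log-normal jitter,
  5% relative SD per parameter, clipped to physiological bounds
  (v_e + v_p rescaled when the sum would exceed 0.95).
- Inputs: a dispersed Feng tri-exponential FDG curve (≈50 kBq/mL peak
  ~25 s after a 10 s arrival — an aortic image-derived shape, broader
  than arterial-sampling curves) and the Parker population gadolinium
  curve delayed by 30 s. An aorta-like cylinder (14 mm radius) carries
  the blood curves so IDIF extraction is exercised; tissue T10 1.4 s,
  blood 1.66 s, S0 500 (arbitrary units).
- Noise: PET frames receive zero-mean Gaussian noise with variance
  scale²·mean/duration (scale 1.5 by default) — a pseudo-Poisson
  surrogate for reconstructed count noise; DCE frames receive additive
  Gaussian noise with SD 2% of S0. Everything is deterministic given the
  spec seed.

What the phantom does **not** emulate: respiratory motion (the dominant
error source in real thoracic data), attenuation/scatter physics,
partial-volume spill between aorta and surrounding tissue, and
reconstruction-induced spatial noise correlation. Passing the recovery
tests therefore demonstrates numerical and statistical correctness of
the pipeline, not robustness to motion-corrupted clinical data — real
data show far larger fit errors than the phantom's 1–2% rRMSE.

## Statistics

- rRMSE is computed on exactly the samples used in the residual
  (dropped DCE samples excluded from both norms). Quartiles use the
  linear-interpolation (type-7) convention, which the binned tables
  inherit; bin boundaries at 20% and 45% are lower-inclusive.
- Outlier cleaning standardizes each parameter over tumor voxels and
  removes voxels with |z| > 3. The default is pairwise (per parameter
  pair), so records may use slightly different voxel subsets; a global
  mode cleaning all nine parameters at once is available.
- Spearman's r_s is the Pearson correlation of mid-ranks (average ranks
  on ties); it is cross-checked against an independent implementation in
  the test suite. Constant inputs leave it undefined and the pair is
  flagged not-computable.
- The bootstrap resamples voxel pairs with replacement (1000 draws,
  seeded; degenerate zero-rank-variance draws are redrawn) and takes
  percentile 2.5/97.5 bounds. Significance means the 95% CI excludes
  zero; no multiple-testing correction is applied. Empirical coverage at
  n = 500 voxels is ~93–95%, the expected mild undercoverage of the
  percentile bootstrap.
- Voxels are not independent samples (smoothing induces spatial
  correlation); the analysis deliberately reports per-tumor descriptive
  correlations without correcting for this.

## Pipeline

Stage order: PET Gaussian smoothing → IDIF extraction → PET map fitting
→ DCE conversion and map fitting → fit-quality tables → correlation
records, with stage-labelled failures and a provenance log (version,
seed, config hash). The 8-mm FWHM PET smoothing (reflect-padded,
frame-by-frame 3D, FWHM convention) is the clinical default and
intentionally trades resolution for noise regularization: it dilutes
edge-voxel parameters toward the background, so quantitative
ground-truth validation runs with `smoothing_fwhm_mm = 0`. DCE data are
never smoothed.

Problem sizes used by the validation suite and the acceptance script —
520-voxel tumor, 200-replicate noisy-recovery studies, 500-repetition
coverage simulation at n = 500 with 1000 bootstrap draws — are chosen to
give stable statistics at desk scale.

## Known limitations

- Single arterial input; dual-supply (bronchial + pulmonary) models are
  deliberately excluded.
- No Patlak/graphical PET analysis, no reversible (k4) model, no
  alternative DCE models (2CXM, Patlak), no B1/flip-angle correction.
- Whether tissue DCE curves should carry the hematocrit factor is
  convention-dependent; both behaviors are implemented, plasma-only by
  default.
- The per-voxel S0 estimate assumes enough pre-bolus frames; very early
  bolus arrival would starve it.
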