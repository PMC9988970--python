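# Methods

`ventfc` implements a bedside-monitoring analysis for preterm neonates with
germinal matrix–intraventricular hemorrhage (GMH-IVH): it relates lateral
ventricle volumes (VV, from segmented 3D cranial ultrasound) to spontaneous
functional connectivity (sFC) measured with multichannel fNIRS, longitudinally
across gestational age (GA), including before/after cerebrospinal-fluid (CSF)
diversion procedures. This note documents the models, the numerical choices,
and what the synthetic cohort does and does not emulate.

## Acquisition model

A continuous-wave fNIRS system samples 20 channels (10 per hemisphere, 22 mm
nominal source–detector separation, 8 sources + 8 detectors) at 10.17 Hz, each
source emitting at 760 and 850 nm. Channel separations scale linearly with the
cap size fitted to the infant's head (`cap_scale`). Four symmetric channel-pair
clusters (left/right × anterior/posterior), each a chain of 4 channel pairs
over a region's 5 channels, summarize connectivity at an intermediate
granularity between single pairs and hemispheres.

## Pipeline order

The per-session processing order is fixed and logged:

```
quality windows → best 2.5-min subsample → cardiac channel exclusion
→ optical density → spline motion correction → MBLL → nuisance regression
→ resample to 1 Hz → robust-correlation sFC
```

Quality metrics are computed on raw intensity; the spline operates on the
optical density of the selected subsample, where motion artifacts are additive
(they are multiplicative in intensity). Motion spikes degrade window quality
scores, so the subsample selection already steers away from the worst
segments; the spline cleans what remains. Within the cardiac-presence
detector, robustness to any remaining spikes comes from median-averaged
spectral estimation rather than from reordering the pipeline.

## Signal quality (SCI / PSP)

Both metrics are computed in 5-s windows with 50% overlap. Window and hop
lengths are `floor(window_s·fs)` and `floor(window_s·fs·(1−overlap))` samples
(50 and 25 at 10.17 Hz). Each window's two wavelength signals are band-passed
to the cardiac band — 90–210 bpm → 1.5–3.5 Hz, zero-phase forward–backward
3rd-order Butterworth — and z-scored:

* **SCI** = zero-lag Pearson correlation of the two filtered signals;
* **PSP** = peak, within the cardiac band, of the power spectrum of their
  normalized cross-correlation (Hamming-windowed, amplitude-normalized so a
  perfect shared sinusoid gives ≈ 0.25 and white noise ≈ 10⁻³).

Flat (zero-variance) windows get SCI = PSP = 0. Both metrics are invariant to
positive rescaling of the intensities.

**Subsample selection.** The contiguous `floor(150·fs)`-sample span (2.5 min)
maximizing the mean over covered windows and channels of rank-normalized SCI
plus rank-normalized PSP is selected; any span overlapping a dropout segment
(intensity < 1% of the channel median sustained > 0.5 s) is disqualified
unless no clean span exists, in which case the least-contaminated span is
returned with a warning. Ties break to the earliest start. The selected span's
score is tested against an exhaustive search over every candidate start.

**Cardiac-presence exclusion.** A channel is kept only if (a) at least 60% of
its windows have SCI ≥ 0.7 and PSP ≥ 0.1, and (b) its full-subsample power
spectrum has a local maximum inside the cardiac band exceeding twice the
band's median power. The spectrum is estimated per wavelength and averaged,
after a high-pass at 0.7× the band's lower edge (slow hemodynamic power is
orders of magnitude larger and otherwise leaks a 1/f floor across short welch
segments) with ~12.6-s welch segments and *median* averaging, which makes the
estimate insensitive to the broadband power of motion spikes. The exact
thresholds are reconstructions — the study describes the method but not its
parameters — and all are exposed in configuration.

## Motion correction

Detection flags samples where the 1-s moving SD exceeds 13.5× the series'
robust (MAD) SD or the 1-s peak-to-peak amplitude exceeds 5× the robust SD;
flags are dilated ±0.5 s and merged. Correction fits a cubic smoothing spline
to each artifact segment on the sample-index grid — penalty weight
λ = (1−p)/(6p) with p = 0.99, the csaps average-spacing normalization — and
keeps the residual, re-leveled by a linear offset ramp anchored to the nearest
sample on each side so the output is continuous at segment boundaries. Samples
outside the dilated segments are returned bit-identical. A segment covering
the whole series is handled by removing the best-fit line only (there is no
clean anchor), which leaves genuine oscillations essentially intact when a
clean series is flagged wholesale.

The sample-grid spline tracks the artifact trajectory including abrupt steps,
so a step-plus-transient artifact collapses to a small residual; the price is
that genuine signal variation *inside* a flagged segment is flattened toward
the boundary ramp. On the generator's injected artifacts this trade strictly
reduces the mean-squared error to the artifact-free ground truth in ≥ 95% of
sessions.

## Hemoglobin conversion (MBLL)

Optical density is ΔOD(t) = −ln(I(t)/Ī) with Ī the subsample mean, per channel
and wavelength; non-positive samples are replaced by the channel's smallest
positive value and logged. Concentration changes solve the 2×2 system

ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d(cm) · ppf(λ)

per sample, with the Gratzer/Cope extinction tabulation
(760 nm: 1486.59 / 3843.71; 850 nm: 2526.39 / 1798.64 cm⁻¹ M⁻¹; table id
`gratzer-cope-1999` recorded in provenance), channel distance d = nominal
separation × cap_scale, and age-appropriate partial pathlength factors
0.1063 (760 nm) and 0.0845 (850 nm). These factors are treated as opaque
multipliers: their absolute scale only rescales concentration units and
cancels exactly in correlation-based connectivity. ΔHbT = ΔHbO + ΔHbR holds
exactly by construction.

## Nuisance regression and resampling

Temporal filtering and global-signal removal are one OLS regression per
channel, HbO and HbR independently, with HbT recomputed from the cleaned pair.
The design contains:

* Fourier sine/cosine pairs at every frequency m/T with 0.09 Hz < m/T < fs/2
  (T = subsample length in seconds — session-length basis). On a 150-s
  subsample this is ~1500 columns: the regression deliberately acts like a
  0.004–0.09 Hz band-pass. Because these frequencies sit exactly on the DFT
  grid, the Fourier block is projected out by zeroing rfft bins — an exact
  fast path, verified against explicit least squares.
* Legendre polynomial drift terms of orders 0–4, QR-orthogonalized on the
  sample grid (discrete Gram polynomials; sampled continuous Legendre
  polynomials are not grid-orthogonal), spanning constant through quartic
  drift. The "first four-order" wording is read as orders 0–4 because the
  constant is required for a well-posed residual.
* The mean signal over valid channels (per chromophore), absorbing global
  physiology and residual motion.

No pre-whitening is applied anywhere. The cleaned series are resampled to
exactly 1 Hz with `scipy.signal.resample_poly` (polyphase, Kaiser-windowed
anti-aliasing; DC preserved, < 0.4 Hz flat to ~2%), trimmed to
`floor(n/fs)` samples — 149 samples for a 2.5-min subsample.

## Robust-correlation sFC

Session connectivity is a robust correlation per valid channel pair of the
1-Hz HbT series (HbO/HbR computable on demand). Both series are standardized
by median/MAD; an iteratively re-weighted line fit of y on x supplies
residuals; joint bisquare-style weights taper with both the residual and the
leverage (|x|) so gross outliers in either coordinate are rejected. Two weight
schedules are used: an aggressive taper (flat to 2 robust SDs, zero at 4.685)
during iteration, which reliably locks onto the uncontaminated fit even under
10% gross contamination, and a lenient final taper (flat to 5, zero at 8)
applied once from the converged fit, so clean Gaussian data is effectively
unweighted and the estimate agrees with the classical Pearson correlation to
well within 0.02. Convergence: Δr < 10⁻⁶ or 50 iterations; zero-MAD inputs
fall back to Pearson with a warning; results are clamped to [−1, 1]; matrices
are symmetric with unit diagonal, and entries touching excluded channels are
missing (NaN), never zero.

**Group maps.** Sessions are averaged within patient first (raw correlations,
no Fisher z — an option exists but is off by default), then each channel pair
gets a one-sample t-test of the patient means against zero (df = n−1). Pairs
contributed by fewer than the group's minimum patient count (defaults 10/23
no-diversion, 5/7 diversion) are flagged *low confidence* and excluded from
all downstream analyses.

## |sFC| versus ventricle volume: three slope estimators

Absolute sFC is used throughout: injury is expected to push correlations of
either sign toward zero, so |sFC| measures connectivity magnitude regardless
of polarity. Every channel pair is analyzed against the VV of its own
hemisphere; interhemispheric pairs use a configurable rule, defaulting to the
mean of left and right VV (the within-hemisphere convention does not define
them; `left`, `right`, and `total` are available).

1. **Per-patient OLS** — each patient's simple linear regression slope of
   |sFC| on VV (patients need ≥ 2 sessions with non-constant VV), then a
   one-sample t-test of patient slopes per pair.
2. **LME** — `|sFC| ~ 1 + VV` with per-patient random effects via statsmodels
   MixedLM (REML, L-BFGS). A random VV slope is attempted first; on
   non-convergence the fit falls back to a random intercept, and the structure
   used is recorded per pair. Reported: fixed-effect VV slope, SE, Wald t/p.
3. **LME + GA** — adds a GA fixed effect, separating the VV association from
   any shared maturation trend.

Hemisphere-level trends pool the group-level slopes of all within-hemisphere
pairs into a one-sample t-test per hemisphere and method (interhemispheric
pairs are not pooled; per-pair fixed effects, not BLUPs, enter the test).
α = 0.05 with no multiplicity correction, matching the single-hypothesis
stance; an FDR option exists but is off by default.

**GA post-hoc.** `VV ~ GA` and `mean |sFC| ~ GA` with patient random
intercepts; degenerate constant outcomes short-circuit to slope 0.

**Diversion paired comparisons.** For each CSF-diversion event (pre and post
sessions acquired the same day; matching window 0.05 weeks ≈ 8 h,
configurable), per-event deltas of VV (left/right/total) and of the four
cluster |sFC| summaries are tested against zero with paired t-tests. Events
without a same-day pre session are skipped with a log entry.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults encode the study
conditions the analysis assumes.

**Recording model.** intensity = baseline · exp(−attenuation) per wavelength,
with attenuation = wavelength-weighted (hemodynamic + cardiac) + drift +
motion, plus ~3·10⁻⁴ multiplicative measurement noise.

* *Hemodynamics*: white noise band-passed to 0.01–0.08 Hz, then **exactly**
  whitened in-sample and mixed with the Cholesky factor of the target
  correlation matrix, so the realized full-length correlation equals the
  target to machine precision at any duration (SD 0.02 attenuation units).
  This choice is deliberate: the 0.01–0.08 Hz band carries only ≈ 2·BW·T
  effective samples (~57 at 408 s), so a plain correlated draw fluctuates by
  ~0.13 per pair and could not satisfy a convergence check at realistic
  durations. Downstream estimates still carry natural sampling noise because
  the pipeline analyzes 2.5-min subsamples at 1 Hz.
* *Target structure*: a loading construction — channels load 0.6 on a factor
  per (hemisphere × region) block and ±0.45 on a global factor with opposite
  signs per hemisphere — yields clustered positive correlations (~0.56
  in-region), weaker within-hemisphere cross-region correlations (+0.20), and
  interhemispheric anti-correlations (−0.20), positive-definite by design.
* *Cardiac*: a shared quasi-periodic oscillation whose instantaneous frequency
  random-walks inside 1.5–3.5 Hz, amplitude 10% of the hemodynamic SD with
  ±30% per-channel variation; 15% of channels are cardiac-free (the exclusion
  target the quality module must find).
* *Motion*: Poisson events (0.5/min) of a sharp transient (τ ≈ 0.2–0.5 s) plus
  a decaying step (τ ≈ 2–5 s), amplitude 5–20× the hemodynamic SD, shared
  across channels and wavelengths. Artifacts are transient rather than
  persistent steps: the corrector only modifies flagged segments, and a
  persistent step cannot satisfy "outside segments unchanged" and "no boundary
  step" simultaneously.
* *Dropout*: per-channel Poisson (0.02/min, 1–5 s) intervals of near-zero
  intensity — occasional, as at the bedside.
* The artifact-free attenuation is stored as ground truth for
  motion-correction error tests; the same seed reproduces a session
  bit-for-bit.

**VV trajectories.** Linear growth per side (default 2 mL/week scale) with
Gaussian session noise (0.5 mL), optional per-event step decreases applied
between sessions, truncation at a 0.5 mL floor (warned), and
total = left + right exactly. Diversion events are preceded by a same-day pre
session (gap ≈ 30 min), so no growth accrues across an event.

**Two study arms.** No-diversion: 23 patients, 2–8 sessions, per-side baseline
4–15 mL. Diversion: 7 patients, 3–15 sessions, per-side baseline 18–40 mL
(severe posthemorrhagic dilatation — large enough that repeated ~10 mL/side
CSF removals never hit the volume floor, which would otherwise truncate the
configured step magnitudes), 1–3 diversion events with per-side steps
−9.74/−10.20 mL (SD 2 mL).

**Coupling.** Session-level targets attenuate the base correlation magnitudes
as |ρ| → max(0, |ρ₀| − β·VV) with signs preserved, using the pair's hemisphere
VV (interhemispheric pairs: configured rule). Default β = 0.002 per mL. If the
elementwise attenuation breaks positive semidefiniteness (possible only at
extreme β·VV), a minimal uniform shrinkage restores it. The recorded β is the
ground truth the slope estimators must recover with negative sign.

**Two fidelity levels.** `simulate_cohort` produces full raw recordings per
session and is used for end-to-end and determinism tests. For replicate-heavy
statistical studies (t-map structure, slope recovery, null calibration),
`simulate_session_records` draws 149 Gaussian samples per session from the
attenuated target — the length of a 2.5-min subsample at 1 Hz — and uses the
sample Pearson correlation as the session connectivity estimate; this
reproduces the estimation noise the optical pipeline hands to the slope stage
at a small fraction of the cost. Hundreds of full-pipeline replicates would
not change what these tests measure, only how long they take; the problem
sizes used (6-channel montage for slope replicates, 100 recovery / 200 null
replicates) were chosen as the smallest designs in which the hemisphere-level
tests are non-degenerate.

**What the generator does not emulate.** Real optode-scalp optics, spatially
varying pathlengths, vascular physiology (Mayer waves, respiration),
inter-subject montage registration error, serial correlation of clinical
noise, and manual segmentation variability in VV. Passing recovery tests
therefore demonstrates the estimators' correctness under the stated
statistical structure, not clinical validity on real recordings.

## Known limitations and behavior under dependence

The hemisphere-level test treats pair slopes as independent samples. When
channel pairs share channels and targets are strongly clustered, pair-slope
errors are positively correlated and the t-test is anti-conservative; this is
a property of the pooled test itself, faithfully reproduced. Null-calibration
checks therefore use near-independent (identity-target) cohorts, where the
test is calibrated (empirically ~3.5–6% rejection at α = 0.05). The per-pair
LME p-values are calibrated in either regime.

MixedLM fits with 7 patients occasionally fail to converge with a random
slope; the intercept-only fallback is used and recorded. Pairs whose fits fail
entirely are reported missing, never imputed.
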