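# Methods

## Forward model

Each synthetic voxel carries

```
y(t) = B + A_r · (s ∗ h_r)(t) + d(t) + ε(t)
```

where `B` is the baseline (1.0, so amplitudes are fractional signal
change), `s` the neural input — a train of 50 ms unit boxcars at the trial
onsets on a 0.05 s grid — `h_r` the region's unit-extremum HR kernel,
`A_r` the signed region amplitude, `d` a low-order Legendre polynomial
drift and `ε` stationary AR(1) noise. The convolution is evaluated on the
fine grid and sampled at volume times `t = k · TR` (volume-start
reference; slice timing is out of scope). The identical sampling routine
builds the GLM condition regressors, which is what makes matched-kernel
fits recover injected amplitudes to machine precision — an intentional
property used by the tests to separate estimator error from model error.

Amplitudes are uniform within a region block. That makes the region mean
of a noiseless dataset equal the analytic convolution exactly and keeps
the injected "truth" unambiguous; the cost is that the peak voxel within
a region is noise-selected rather than anatomically structured.

## HR kernel family

Generation uses a double gamma (peak delay 6 s, undershoot delay 16 s,
unit dispersions, undershoot ratio 1/6 — the conventional defaults, also
used verbatim as the canonical analysis kernel) whose time axis is
linearly stretched so the positive-lobe peak lands at a requested
time-to-peak. Stretching preserves the canonical morphology while making
latency a free parameter, which is the minimal deformation needed to
express latencies of 10–18 s. It does not model independent dispersion or
undershoot changes with age.

## Lifespan trajectories (generator defaults)

Anchored at the mean ages of the youngest (25.8 y) and oldest (82.6 y)
decile groups and interpolated linearly in age:

| region   | amplitude (young → old) | time-to-peak (young → old) |
|----------|-------------------------|----------------------------|
| iSM1     | −0.034 → −0.013         | 10 → 18 s                  |
| cSM1     | +0.040 (stable)         | 9.4 → 10.7 s               |
| V1       | +0.045 (stable)         | 5.6 s (stable)             |
| thalamus | +0.025 (stable)         | 8.2 → 10.1 s               |
| PCC      | −0.030 (stable)         | 12 s (stable)              |

The iSM1 amplitude/latency anchors and the cSM1/thalamus latency anchors
are the study conditions this package emulates; the stable-region
amplitudes are not published as numbers and were fixed once at realistic
fractional-signal-change values of the same order as the iSM1 response.

Between-subject scatter: amplitude SD 0.003, latency SD 1.5 s (clipped to
[5, 20] s), with signs clipped so every region keeps its response
polarity (|amplitude| ≥ 0.003). The amplitude SD is bounded above by a
calibration requirement on the generator itself — the sample correlation
between age and injected iSM1 amplitude across a default cohort must
exceed 0.9 — which pure between-subject scatter of the magnitude reported
for single-subject estimates (±0.023, inflated by estimation noise) could
not satisfy. With SD 0.003 the trajectory swing of 0.021 over 56.8 years
gives r ≈ 0.93.

Noise defaults: voxel sigma 0.01 (1 % of baseline, typical for 3 T EPI),
AR(1) ρ = 0.3, drift coefficients (0.01, −0.005) on Legendre degrees 1–2.
Voxels are spatially independent, so a 27-voxel region mean has sigma
≈ 0.0019; real data are spatially correlated and would average less
favourably — passing recovery tests here demonstrates estimator
correctness at this SNR, not field-strength-general performance.

Motion traces are smoothed Gaussian random walks rescaled so summed
framewise displacement matches a linear-in-age target (63.5 mm at 25.8 y →
135.5 mm at 82.6 y, lognormal subject jitter), emulating the empirical
increase of head motion with age. Motion is *not* coupled into the BOLD
signal; it exists so the nuisance-regression and FD machinery operate on
realistic inputs.

## Paradigm generator

Trials are packed on a 2 s slot grid with pseudo-random null gaps: one
inter-onset gap is pinned at the maximal SOA (26 s) and the remaining
slack slots are scattered one at a time, so observed SOAs span
[2 s, 26 s]. The published design used a 255-length m-sequence; a literal
m-sequence construction is not recoverable from its description (a binary
m-sequence alone does not produce 26 s gaps), so the grid scheduler is
used instead and an m-sequence option is left as future work. Condition
labels give equal numbers of the three audiovisual tone frequencies plus
audio-only/visual-only unimodal trials, pseudorandomly ordered. Practice
and incorrect-response trials (≈ 1 % of trials in the real task) are not
generated.

## First-level GLM

Ordinary least squares per voxel. Prewhitening (FILM) and mixed-effects
group variance modelling are deliberately not reproduced — the inference
engine is not the scientific content here — but an AR(1) Cochrane–Orcutt
correction is available (`fit(ar1_correction=True)`). Drift is handled by
Legendre nuisance regressors (degree 2 by default in the pipeline) rather
than high-pass filtering, whose settings are unknown. Degenerate voxels
(zero residual variance with a nonzero contrast) are flagged invalid
rather than given infinite Z. The t→Z map uses survival functions on each
tail separately, so it is odd and monotone and keeps precision at |t| ≫ 0.
Map summaries threshold voxelwise at |Z| > 3.1; cluster-level correction
is out of scope.

## FIR deconvolution

Unregularized least squares with one coefficient per lag bin of width TR
over a 24 s window — wide enough for 18 s latencies plus recovery; the
window used in the original analysis is unstated. All events are pooled
into one constant-amplitude train (unlike the five-condition GLM),
because the neural input per condition is not separable at this SNR and
the analysis targets the pooled evoked response. Polynomial drift
nuisance terms are included by default (their presence in the original is
unstated; they cost nothing on full-rank designs and protect against
drift leakage). A ridge option exists for pathological schedules;
rank-deficient lag designs raise an error naming the offending lag bins.

Because events sit on a 2 s grid and volumes on a 1.97 s grid, lags
within a bin vary across event–volume pairs, so the FIR estimate of a
smooth HR is a locally averaged version of it. The induced peak-magnitude
bias is ≈ 1–3 % for the latencies simulated here, and the exact-identity
property holds for signals generated through the FIR forward operator
(`fir_convolve`), which the identity tests use.

"Normalization by the maximum amplitude" of an HR is read as division by
the maximum *absolute* amplitude with sign preserved: a negative-going HR
normalizes to extremum −1 rather than being flipped and mis-scaled.
Consequently the data-driven GLM's NBR appears in the contrast aligned
with the kernel polarity, and downstream code reads maps from that
contrast. PBR maps fitted with an NBR-shaped kernel are emitted but
flagged non-interpretable.

## ROI and extent conventions

- Peak voxels are polarity-directed extrema within an anatomical mask,
  ties to the lowest linear index; the 3×3×3 cube is clipped at volume
  boundaries, not shifted, and only the peak (not the whole cube) must
  lie inside the mask.
- For cohort pipelines, subjects whose contrast map contains no voxel of
  the requested polarity anywhere in the mask use the polarity-directed
  extremum regardless of sign (`require_polarity=False`); the strict
  variant raises, as befits a single-subject analysis.
- Extent thresholds are per sign (5 % of the maximal positive beta for
  PBR, of the maximal |negative beta| for NBR), since the threshold is
  computed separately for positive and negative responses; a global-max
  option is provided.
- Tertile splits assign the remainder to the middle group first, then the
  lower group — the rule forced by the published 18/19/18 split of 55.
- Framewise displacement converts rotations on a 50 mm sphere (the
  standard convention for this FD definition); the radius is an argument.

## Group statistics

Post-hoc t-tests use the Welch (unequal-variance) form; the variant used
originally is unspecified and Welch is the safer default. Multiplicity:
uncorrected p-values are reported alongside a Bonferroni column; nothing
is corrected silently. The nested-regression F-test implements the
generic incremental-variance procedure (base predictors + one added
predictor) since the original models' exact predictor sets are not
enumerated.

## Data-driven re-analysis and circularity

Decile-mean HRs are estimated from the same subjects they are then
applied to, which is mildly circular; `compare_canonical_datadriven`
accepts `holdout=True` to estimate kernels on alternate subjects and
evaluate on the held-out half. The headline comparison — the
percent-of-Twenties mean |Z| profile declining more steeply under the
canonical kernel than under decile-matched kernels — is computed as the
mean over non-reference deciles because individual old-decile ratios are
noise-dominated at desk-scale cohort sizes.

## Problem sizes and numerical choices

Default simulations use a 12×12×6 voxel grid (five disjoint 27-voxel
region blocks), 261 volumes at TR 1.97 s and 128 trials, the acquisition
geometry scaled down spatially to keep cohort sweeps cheap: the
acceptance analyses use 10 subjects/decile for the kernel comparison and
200 replicate cohorts of 28 subjects for slope-coverage, sizes chosen so
the full run completes in about a minute on one core. Cohort sweeps that
only need one region's signal use `synthesize_region_timecourse`, which
is exactly the region-mean forward model with noise SD shrunk by
√n_voxels (verified against the 4-D path). Convolution uses a 0.05 s
internal grid (the event duration); volume sampling rounds to the nearest
fine-grid point (≤ 0.025 s error). Ties in HR peak finding go to the
earliest bin.

## Known limitations

- No physics: no k-space, distortion, slice timing or spin-history
  effects; motion does not corrupt the signal.
- The HR family confounds neural-input duration with HRF shape by design;
  the package estimates evoked HRs, not impulse-response functions.
- Spatially uniform region amplitudes make extent metrics cleaner than in
  real data, where activation borders are graded.
- AR(1) + polynomial drift understates low-frequency physiological
  structure; recovery results quantify estimator behaviour under the
  stated noise model only.
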