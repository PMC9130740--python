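# nbrlifespan

Event-related fMRI analysis of how the **negative BOLD response (NBR)**
changes across the adult lifespan, with a seeded synthetic-cohort simulator
for testing every stage without any data download.

## The scientific problem

During a simple audiovisual task with a right-hand button press, the
contralateral sensorimotor cortex (cSM1) shows a positive BOLD response
(PBR) while the ipsilateral sensorimotor cortex (iSM1) *deactivates* — an
NBR commonly read as cortical inhibition. Across the lifespan the iSM1 NBR
shrinks in magnitude and its evoked haemodynamic response (HR) peaks
progressively later (≈ 10 s in the twenties vs ≈ 18 s in the eighties).
This creates a methodological trap: the conventional GLM convolves event
timings with a canonical double-gamma HRF that peaks near 5 s, so a late,
shallow NBR is systematically under-fitted, and the apparent lifespan
decline conflates a true amplitude change with a pure shape mismatch.

The package implements the analysis chain that separates these effects:

1. **First-level GLM** — events modelled as 50 ms deltas per condition,
   convolved with a kernel (canonical or data-driven), fitted per voxel by
   OLS with motion and polynomial-drift nuisance regressors; contrast
   t statistics are mapped to Z. Under the model `y = Xβ + ε`,
   `t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c)`.
2. **FIR deconvolution** — the evoked response is recovered from an
   ROI-mean signal by inverting `signal = neural input ∗ HR`, one free
   coefficient per post-stimulus lag bin at TR resolution, with the event
   train treated as constant-amplitude deltas.
3. **Data-driven re-analysis** — decile-mean deconvolved HRs, normalized to
   unit extremum magnitude, replace the canonical kernel and the GLM is
   re-run ("all other parameters kept the same").
4. **ROI, extent and group statistics** — subject-specific 3×3×3 cube ROIs
   on peak voxels, PBR/NBR spatial-extent proportions with a 5 %-of-maximum
   beta threshold, tertile splits, framewise displacement, decile ANOVAs,
   Welch post-hoc t-tests, Pearson/partial correlations and the nested
   regression incremental-variance F-test.
5. **Synthetic cohorts** — a forward model (baseline + amplitude ×
   (delta train ∗ unit-extremum HR) + polynomial drift + AR(1) noise) on a
   toy block atlas, with per-region amplitude/latency lifespan trajectories
   and age-scaled head-motion traces.

## Worked example

```python
from nbrlifespan import generate_paradigm, subject_from_age, synthesize_subject
from nbrlifespan.deconvolution import FIRDeconvolution

schedule = generate_paradigm(seed=1)            # 128 trials, SOAs 2–26 s
spec = subject_from_age("sub-demo", age=72.0, seed=42)
data, motion = synthesize_subject(spec, schedule)  # 12×12×6 grid, 261 vols, TR 1.97 s
res = FIRDeconvolution(data.region_timecourse("iSM1"), schedule, tr=1.97).fit()
print(res.summary())
```

```
FIR deconvolution
  window: 23.64 s at dt 1.97 s, df: 245, residual SD: 0.00638
  peak magnitude: -0.01584 at 15.76 s
    lag_s       hr       se
  0.00000 -0.00003  0.00083
  1.97000  0.00067  0.00084
  ...
 15.76000 -0.01584  0.00082
 17.73000 -0.01578  0.00083
 ...
```

This 72-year-old synthetic subject was injected with an iSM1 amplitude of
−0.0147 (fractional signal change) peaking at 17.9 s; the FIR estimate
recovers a peak of −0.0158 at 15.8 s — the late, shallow NBR typical of
older age, with the latency uncertain by roughly one lag bin because the
aged response is nearly flat around its peak. Fitting the same subject with
the canonical kernel yields a beta several times smaller in magnitude than
the matched-kernel fit, which is the mechanism behind the apparent
"disappearance" of the NBR in conventional group maps.

A command-line interface mirrors the library
(`nbrlife simulate|first-level|deconvolve|reanalyze|group|pipeline`), e.g.:

```bash
nbrlife simulate --n-per-decile 2 --seed 1 --out cohort/
nbrlife reanalyze --cohort cohort/ --out reanalysis/
```

## Layout

- `src/nbrlifespan/events.py` — event schedules, paradigm generator
- `src/nbrlifespan/hrf.py` — HR timecourses, canonical/stretched kernels, metrics
- `src/nbrlifespan/glm.py` — design matrices, smoothing, `FirstLevelGLM`
- `src/nbrlifespan/deconvolution.py` — `FIRDeconvolution`
- `src/nbrlifespan/synthetic.py`, `atlas.py` — cohort simulator, toy atlas
- `src/nbrlifespan/roi.py` — cube ROIs, extent metrics, tertiles, FD
- `src/nbrlifespan/group.py` — second-level maps and cohort statistics
- `src/nbrlifespan/reanalysis.py` — data-driven kernel comparison
- `docs/methods.md` — model, assumptions, parameter choices, limitations
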