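# cordmap

Multiparametric quantitative MRI of the spinal cord, end to end: diffusion
tensor metrics, quantitative magnetization transfer, and CEST/rNOE
Z-spectrum decomposition, with the ROI-level group statistics of a
pre/post unilateral dorsal-nerve-root lesion study — runnable and
verifiable without scanner data via a synthetic phantom cohort generator.

It is written for researchers quantifying white/grey-matter and nerve-root
tissue changes at high field, who need the full chain from raw 4D stacks
to group-level statistics in one place, with forward models matched to
every fitter so each stage can be validated by round trip.

## What it computes

- **DTI** — log-linear (OLS or signal-weighted WLS) tensor fit of a
  1 b0 + 30 direction, b = 1000 s/mm² shell; FA = √(3/2)·‖λ−λ̄‖/‖λ‖,
  AD = λ₁, RD = (λ₂+λ₃)/2.
- **qMT (PSR)** — bound/free pool size ratio from the two-pool
  steady-state MT model with super-Lorentzian bound-pool lineshape and a
  CW power-equivalent mapping of the pulsed saturation (2 powers ×
  10 log-spaced offsets, 1–100 kHz); per-voxel bounded nonlinear least
  squares with multi-start.
- **CEST/rNOE** — Z-spectra (51 offsets, −5…+5 ppm, drift-corrected by
  bracketing 100 kHz references) inverted and anchored to zero at +5 ppm
  to cancel the flat semisolid-MT baseline, then decomposed into five
  Lorentzian pools: CEST(3.5), CEST(2.0), DS(0), rNOE(−1.6), rNOE(−3.5);
  reported metrics are the pool peak amplitudes.
- **Statistics** — per (ROI, metric): exact Wilcoxon rank-sum tests
  (lesion and contralateral vs pre-lesion, n = 8 injured segments, full
  permutation enumeration with mid-rank ties), percent changes, and the
  8×8 metric correlation matrix over 168 pooled entries (7 ROIs ×
  2 segments × 4 subjects × 3 groups).
- **Phantom** — schematic axial cord label maps (14 side-resolved ROIs:
  VH, DH, LP, VP, DP, DREZ, DNR × left/right), per-ROI ground-truth
  parameters with between-subject variation, lesion-effect multipliers,
  and noisy image stacks from the three forward models under Rician
  noise.

Model details, parameter defaults and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from cordmap import CohortDesign, run_pipeline

# 4 subjects x 2 lesioned segments x {pre, post}, left-side lesion
report = run_pipeline(CohortDesign(seed=1))

c = report.comparisons
for roi in ("DNR", "DREZ"):
    row = c[(c.roi == roi) & (c.metric == "PSR")].iloc[0]
    print(roi, round(row.percent_change_lesion, 1), row.p_lesion_vs_pre)
```

prints

```
DNR -35.9 0.0001554001554001554
DREZ -11.4 0.0029526029526029526
```

i.e. fitted PSR in the lesion-side dorsal nerve root dropped 35.9 %
relative to pre-lesion (the cohort was generated with a 35.4 % drop), the
adjacent dorsal root entry zone dropped 11.4 % (generated: 13.1 %), and
both survive the exact rank-sum test — 0.0001554 = 2/12870 is the
smallest two-sided p attainable with 8 vs 8 samples. The same report
carries the rNOE(−1.6) decreases (84.4 % and 71.4 % recovered for
generated 85.8 % / 72.5 %), the full region table, and the correlation
matrix, in which diffusion metrics correlate strongly with each other and
with PSR (r ≈ 0.9), as tissue-integrity measures should.

The same chain is available as numbered drivers under `analysis/`
(simulate → fit → statistics → null calibration) and as a CLI:

```sh
cordmap simulate --config cohort.yaml --out cohort/ --seed 1
cordmap roi-stats --manifest cohort/manifest.tsv --out stats/
cordmap run-all --out study/            # both steps, default config
```

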