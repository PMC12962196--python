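# Methods

`cordmap` quantifies multiparametric spinal-cord MRI — diffusion tensor
metrics, the bound-pool size ratio from quantitative magnetization
transfer (qMT), and CEST/rNOE amplitudes from Z-spectrum decomposition —
and runs the ROI-level group statistics of a pre/post unilateral
dorsal-root-lesion study. Because no scanner data ship with the package,
every stage is exercised against a synthetic phantom cohort whose forward
models are the same physics the fitters invert. This note records the
models, the defaults and why they were chosen, and what the synthetic
design can and cannot demonstrate.

## Diffusion tensor

The forward model is the mono-exponential single-tensor signal
S = S0·exp(−b gᵀDg), with diffusivities in μm²/ms and b in s/mm² (the
product is scaled by 10⁻³ so the exponent is dimensionless). Fitting is
log-linear least squares on the 1 b0 + 30 direction, b = 1000 s/mm²
shell; the default is one-step weighted least squares with weights equal
to the squared predicted signal from the ordinary pass, the standard
variance model for log-transformed magnitude data at moderate SNR.
Ordinary log-linear is kept as an option and as the oracle in round-trip
tests. Scalar maps follow the usual definitions: AD = λ₁,
RD = (λ₂+λ₃)/2, FA = √(3/2)·‖λ−λ̄‖/‖λ‖.

Numerical choices: voxels with any nonpositive sample are excluded and
reported in a mask rather than fitted; negative eigenvalues are flagged
in a QC mask, not clipped, and metrics are computed on the raw values;
the b-matrix is nominal single-shell (no gradient cross-terms, which the
protocol does not specify). The 30 directions are a fixed table generated
once by antipodally-symmetric electrostatic repulsion (minimum pairwise
separation 25.6°) and shipped as a constant, so fits are reproducible
without re-optimizing the sphere.

## Two-pool magnetization transfer (PSR)

The MT-weighted protocol is 2 saturation powers (flip 220° and 820°,
10 ms Gaussian pulses, TR 24 ms) × 10 offsets log-spaced over 1–100 kHz.
The pulsed saturation is mapped to a continuous-wave power equivalent by
average-power matching: the peak amplitude comes from the flip angle
(θ = ω₁p₁·pw) and ω₁cwpe = ω₁peak·√(p₂·pw/TR), where p₁, p₂ are the
normalized first and second moments of the unit-peak pulse shape
(Gaussian truncated at 1 % of peak), computed numerically on a dense
grid.

The signal is the steady state of the coupled two-pool longitudinal
equations,

    S = scale · [Rₐ(R_b + k_ba + R_rfb) + k_ba·R_b·PSR]
        / [(Rₐ + k_ba·PSR + R_rfa)(R_b + k_ba + R_rfb) − k_ba²·PSR]

with the bound-pool saturation rate R_rfb = π·ω₁²·g_SL(Δ, T2b) under the
super-Lorentzian lineshape and the free-pool direct-saturation term in
the Lorentzian-wing approximation R_rfa = (ω₁/2πΔ)²/T2a. The lineshape
integral is evaluated by fixed 256-point Gauss–Legendre quadrature split
at the orientation singularity u = 1/√3 (128 points per panel), which
agrees with adaptive quadrature to better than 10⁻⁴ relative over the
protocol's offset and T2b range; a fixed rule keeps every fit evaluation
bit-reproducible at constant cost.

Fitting is per-voxel bounded nonlinear least squares over
{PSR ∈ [0, 0.5], k_ba ∈ [1, 100] s⁻¹, T2b ∈ [5, 50] μs,
1/(RₐT2a) ∈ [1, 100], scale ∈ [0.3, 3]}, three fixed starting points,
lowest residual kept; non-converged voxels get PSR = NaN and a flag.
Each voxel's series is first normalized by its far-offset lowest-power
volume — the 100 kHz measurement is effectively unsaturated, and the
protocol lists no separate reference — and the free `scale` absorbs the
residual saturation of that reference, which makes the fit invariant to
global intensity scaling. Rₐ and R_b are fixed at 1 s⁻¹: with no
independent T1 observation in the protocol the longitudinal rates are
not identifiable, and fixing them is the standard constraint; both are
config-exposed.

## Five-pool Z-spectrum decomposition (CEST / rNOE)

Z-spectra are sampled at 51 offsets from −5 to +5 ppm in 0.2 ppm steps
(400 Hz/ppm), with two 100 kHz reference scans bracketing the
acquisition. Per voxel, S0 is linearly interpolated in acquisition order
between the two references (drift correction; a plain mean is available
and identical for drift-free data), Z = S/S0, and values above 1.05 are
reported, not clipped.

The model is a constant semisolid-MT floor plus five Lorentzians —
amide CEST at +3.5 ppm, amine CEST at +2.0 ppm, direct water saturation
(DS) at 0, and relayed NOE pools at −1.6 and −3.5 ppm:
Z(Δ) = 1 − c_mt − Σᵢ Aᵢ(wᵢ/2)²/((wᵢ/2)² + (Δ−Δ₀ᵢ)²). Processing inverts
the spectrum and subtracts its value at the +5 ppm endpoint, so
Y(+5 ppm) = 0 exactly and the flat MT floor cancels. The same anchoring
is applied to the model inside the fit: the rNOE(−3.5) tail at +5 ppm is
of order 0.01, and fitting an un-anchored pool sum to an anchored
spectrum would push that bias into the near-floor amplitudes. With the
anchored model the noiseless round trip is exact.

The decomposition is bounded least squares over five amplitudes in
[0, 1], five FWHMs (ppm bounds: DS [0.3, 3], CEST3.5 [0.5, 4], CEST2.0
[0.3, 3], NOE1.6 [0.3, 3], NOE3.5 [1, 8]) and a DS center shift within
±0.3 ppm that stands in for B0 correction; the other centers are fixed.
Initialisation is a fixed healthy-tissue-like pool table, the optimizer
is deterministic, and amplitudes are reported as peak heights, not
areas. Fitting the ROI-mean spectrum is the default for statistics
(regional spectra are what the group analysis consumes, and averaging
first raises the effective SNR ~√n_voxels); a voxelwise mode exists.

## Synthetic phantom cohort

The phantom reproduces the study design, not spinal-cord anatomy. The
default cohort is 4 subjects × 2 lesioned cervical segments ×
{pre, post}, one 48×48 axial slice per bundle, unilateral (left) lesion
— 16 bundles, 8 injured segments. The label map is schematic: an
elliptical cord with a butterfly grey-matter region (ventral/dorsal
horns), white matter split into ventral/lateral/dorsal pathways, DREZ
strips on the dorsolateral shell, and DNR blobs outside the cord; all
14 side-resolved ROIs hold ≥ 20 voxels at 48×48 (the minimum grid).

Per (subject, segment, side, ROI), tissue parameters are drawn once from
normal distributions centred on class means with a 5 % between-subject
CV, truncated to each parameter's valid range, with joint rejection of
pool tables that would drive Z below zero near the water resonance. Pre
and post share that base draw (a longitudinal design: the same animal is
imaged twice) and post-lesion lesion-side ROIs are multiplied by the
lesion-effect factors. An independent-draw mode (`shared_base=False`)
provides the cross-sectional null used for type-I calibration, where
shared draws would make pre and post identical.

Class means (config-overridable): WM λ = (1.7, 0.3, 0.3) μm²/ms, GM
(1.0, 0.7, 0.7), DNR (1.5, 0.35, 0.35); PSR 0.17 / 0.10 / 0.15 for
WM / GM / DNR; one shared pool table A_DS 0.85, A_CEST3.5 0.05,
A_CEST2.0 0.04, A_NOE1.6 0.04, A_NOE3.5 0.12, c_mt 0.08; S0 = 100.
These are plausible high-field values chosen once; the acceptance
surface is relative change, not absolute values, which no available
source pins down per ROI. Principal fiber direction is head–foot
(through-slice) for cord tissue and in-plane oblique for the nerve
roots, mirroring the DWI contrast behaviour of roots versus cord.

Lesion-effect defaults: PSR × 0.646 (DNR) and × 0.869 (DREZ);
rNOE(−1.6) × 0.142 (DNR) and × 0.275 (DREZ) — these four encode the
reported percent decreases and are the quantities the acceptance targets
recover. The remaining factors (CEST3.5 up, NOE3.5 down in DNR, radial
eigenvalues up / λ₁ down, i.e. FA down) are *directional only*: their
signs follow the described group differences, their magnitudes are
choices of this phantom.

Noise is Rician (v → √((v+n₁)² + n₂²)) with per-modality SDs set by SNR
relative to S0: 40 (DWI), 50 (qMT), 60 (Z-spectrum) — a high-field
surface-coil regime. The design seed determines parameter draws and
noise; identical seeds give bit-identical cohorts.

What the phantom does not emulate: anatomical geometry, CSF and fluid
accumulation, motion, B0/B1 inhomogeneity, partial-volume mixing at ROI
boundaries, registration error between modalities (stacks are generated
pre-aligned), or any biological coupling between metrics beyond the
shared parameter draws. Passing recovery tests therefore shows the
estimators invert their own forward physics at realistic SNR under the
study's n — not that the pipeline is robust to the confounds real
acquisitions add.

## Group statistics

ROI means are taken over finite voxels only, with missing counts
reported. Group comparison per (ROI, metric) is a two-sided Wilcoxon
rank-sum test of the 8 lesion-side (or contralateral) post-lesion
segment values against 8 pre-lesion values; pre-lesion values are
side-matched to the side under test by default (side-averaged mode is
config-exposed; the original design's choice is not recoverable).
For combined n ≤ 20 the null distribution is enumerated exactly over all
C(n+m, n) assignments of the pooled mid-ranks, so ties are handled by
tie-respecting permutation; larger samples fall back to the normal
approximation with tie and continuity corrections. Two-sided
p = min(1, 2·min(tail probabilities)); the exact size of the discrete
8-vs-8 test at α = 0.05 is 0.0499. Percent change is
100·(mean_lesion − mean_pre)/mean_pre. No multiple-testing correction is
applied by default (raw p at 0.05/0.01/0.001 is the reporting
convention); Benjamini–Hochberg is available in the config.

The correlation analysis pools, per metric, 7 ROIs × 2 segments ×
4 subjects × 3 groups = 168 entries: pre-lesion contributes one
side-averaged value per (subject, segment, ROI) while post-lesion
contributes the contralateral and lesion sides separately — the unique
bookkeeping consistent with n = 168 under this design. Correlation is
Pearson by default ("r values" without a named estimator; Spearman is a
config option), with per-pair two-sided p and a mask at p > 0.05.

## Problem sizes and runtime

The default cohort fits ~620 labeled voxels × 16 bundles voxelwise for
DTI and qMT (~10⁴ bounded nonlinear MT fits, the dominant cost, ≈3 min
single-core) plus 14 ROI-mean Z-spectrum fits per bundle. Type-I
calibration uses 200 null cohorts at the ground-truth level — the
Wilcoxon's calibration does not depend on the imaging stage, and
simulating and fitting 200 × 16 image bundles would add hours without
changing the statistic under test. The grid (48×48), slice count (one
lesion-level slice per segment) and replicate counts are the package's
own defaults; all are config-exposed.

## Known limitations

- The two-pool steady-state form and the CW power equivalent are one
  self-consistent choice among the family of pulsed-MT approximations;
  PSR values from other software will differ in absolute terms even
  though relative change is stable.
- R_a = R_b = 1 s⁻¹ fixed means fitted PSR absorbs any true T1
  variation; the phantom does not vary T1, so this is untested against
  T1 heterogeneity.
- The DS-center float (±0.3 ppm) is a proxy for B0 correction, adequate
  only for small, spatially smooth offsets.
- With 8 vs 8 samples the exact Wilcoxon's smallest attainable two-sided
  p is 1.554×10⁻⁴; significance stars below that level are unreachable
  at this design size.
- ROI statistics treat segments within a subject as independent, as the
  pooled n = 8 design does; no mixed-effects nesting is modelled.
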