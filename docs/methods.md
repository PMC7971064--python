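# Methods

## Scope and model of the data

The package treats a multiparametric small-animal liver MR exam at 9.4 T as
four acquisitions over a common subject: an inversion-recovery (IR) series
for T1, a multi-echo gradient-echo (MEGRE) series for T2\*, a two-point
Dixon pair for fat fraction, and a T1-weighted spoiled-gradient-echo (SPGR)
dynamic series bracketing injection of an allysine-targeted gadolinium
probe. Histology morphometry (collagen proportional area on Sirius red,
lipid vacuolization on H&E) provides the ex-vivo reference measures, and
cohort statistics compare diet groups across time on diet.

All images are magnitude images. Noise is modeled as Rician throughout:
a complex Gaussian perturbation of scale σ per channel followed by the
magnitude, so background voxels follow a Rayleigh distribution with mean
σ·√(π/2) and SD ≈ 0.655·σ. The quoted SNR of a simulation is the liver
proton-density amplitude divided by σ (SNR 50 ⇒ σ = 0.02 on a unit-signal
phantom).

## The disease trajectory and tissue states

`phantom.build_trajectory()` is a lookup table over the nine study groups
(normal chow and CDAHFD at weeks 2/6/10/14, plus withdrawal — 10 weeks of
diet then 4 of chow — at week 14) holding mean ± SEM for liver T1 (ms),
T2\* (ms), MRI fat (%), LV (%), and CPA (%), with the published group
sizes (n = 5–12, 70 animals total). Reported means are entered as printed;
the mid-diet T1/T2\*/%fat values, for which only endpoint values are
printed, are linear interpolations flagged `interpolated=True`. Tissue
allysine (μM) is a free model parameter (see below). Hydroxyproline and the
reported enhancement AUCs are carried as metadata only and never used as
simulation inputs.

A per-animal `TissueState` is a truncated-normal draw at the group mean
with SD = SEM·√n (the between-animal spread implied by the printed SEM).
Fat fraction and LV share one latent deviate, collagen and allysine share
another, and T1 is negatively coupled to the fat deviate (ρ = 0.6), so
cohort-level correlations emerge with the right signs: MRI fat vs LV
strongly positive, T1 moderately negative with steatosis, enhancement
tracking fibrogenesis. These couplings are structural choices, not fitted
quantities. `dispersion_scale=0` collapses a draw to the group means.

## Signal models

* IR: `S(TI) = |A − B·exp(−TI/T1)|` with B = 2A (ideal inversion) on the
  nine protocol TIs {0, 300, 550, 700, 850, 1500, 3000, 5000, 7000} ms.
* MEGRE: `S(TE) = S0·exp(−TE/T2*)` on the twelve protocol TEs
  2.62–30.68 ms.
* Dixon: per-voxel water W and fat F with `F/(W+F)` equal to the tissue
  fat signal fraction; in-phase = W+F, opposed-phase = |W−F|. The phantom
  enforces the water-dominant regime (fraction ≤ 0.5).
* DCE: voxel `R1(t) = 1/T1₀ + r1_free·C_free(t) + r1_bound·C_bound(t)`
  (R1 in s⁻¹, concentrations mM), converted to signal with the steady-state
  SPGR equation at TR 41 ms / flip 60°. Echo-time weighting is absorbed
  into the proton-density factor.

The phantom geometry is deliberately minimal: a liver ellipse, a muscle
slab (fixed reference values T1 1900 ms, T2\* 15 ms, fat 2 %), and air
background — enough to exercise ROI statistics, vessel exclusion, noise
estimation and liver/muscle ratios, with no anatomical realism claimed.

## Probe pharmacokinetics and binding

Blood concentration clears mono-exponentially from
C0 = dose / blood volume = 200 μmol/kg / 58.5 mL/kg ≈ 3.42 mM with
half-life 5 min. The tissue free pool is `v_d · C_blood` with distribution
volume fraction `v_d`; the bound pool follows quasi-equilibrium occupancy
`Bmax·free/(free + Kd)` (Kd = 650 μM) on the way up and is released no
faster than a first-order off-rate (0.02 min⁻¹ default) on the way down,
integrated on a 0.05 min grid. Free/bound relaxivities are 4.1 and
16.2 mM⁻¹s⁻¹.

Free parameters were calibrated once, before any validation runs, against
the published enhancement levels: `v_d = 0.08` and per-group allysine
(control 70 μM; CDAHFD 315/355/570/285 μM at weeks 2/6/10/14; withdrawal
150 μM) make the noiseless simulator reproduce the published %ΔSNR AUC
table (≈2030/2400/3750/2350/1530 %·min) with the control level at about
half the week-2 CDAHFD value. `bmax_per_allysine = 1` (one binding site
per allysine). These are phantom parameters: the DCE analysis module makes
no use of them.

## Estimators and numerical choices

**T1.** Three-parameter least squares on the magnitude model. Magnitude
data lose the sign of the recovering magnetization, so the fit is seeded
from signed linear solves under several polarity splits — flipping the
first k points negative for k ∈ {0, i_min, i_min+1, i_min+2}, where i_min
is the magnitude minimum (the zero crossing can only sit there) — and the
hypothesis with the lowest magnitude residual wins. T1 is initialized at
TI(min)/ln 2. Tolerances 1e-14 give noiseless recovery to solver precision;
at SNR 50 the mean recovered T1 over 100 single-voxel series is within
0.1 % of truth. Fit failure returns a flagged non-converged result, never
an exception, so voxelwise maps always complete.

**T2\*.** Initialized from the log-linear closed form. With σ known, the
fit minimizes `(S0·e^(−TE/T2*))² + 2σ² − M²` — the exact Rician second
moment — over all echoes. A hard 3σ echo-exclusion rule was evaluated
first and rejected: discarding sub-floor echoes truncates the information
in the tail and leaves a +2 to +5 % bias at single-voxel SNR 30–50 for
liver-range T2\* (and makes T2\* ≈ 3 ms unidentifiable on the protocol
echoes). The second-moment fit keeps the median bias within ±2 % over
T2\* ∈ [3, 10] ms at SNR ≥ 30. Echo counts above 3σ are still reported as
a diagnostic, and a series with essentially no supra-floor signal is
flagged non-converged.

**Dixon.** `FF = (IP − OP)/(2·IP)`, voxels with IP below 3σ masked,
negative FF (noise) clamped to 0 and counted rather than masked — masking
would bias low-fat ROI means upward; clamping leaves ≲1 % relative bias at
the 2.4 % control fat level. The two-point magnitude method cannot see
fat-dominant voxels (pool-swap ambiguity) and applies no T2\*/phase
correction; both are documented, inherent bias sources of the method
itself.

**DCE.** Vessel exclusion thresholds the seeded liver ROI at
median + 3·MAD of the pre-contrast frame (raw MAD, not
Gaussian-rescaled). Noise is the background-ROI SD divided by 0.655
(Rayleigh). Because exclusion is decided on the same noisy pre-frame used
as the %ΔSNR baseline, a zero-enhancement series shows a small positive
offset (≈ +1 % of baseline per frame at SNR 50); it is well inside the
Monte-Carlo spread of the AUC and negligible against the 50–130 %
enhancements of interest. AUCs are trapezoids over the acquired
{0, 5, 15, 25} min grid only — no extrapolation beyond the last frame.

**Morphometry.** Tissue vs slide: saturation > 0.15 followed by hole
filling, so unstained vacuoles inside the section count as tissue area.
Collagen gate: hue in the red band (≤ 0.06 or ≥ 0.90) with saturation
≥ 0.30; vacuole gate: saturation ≤ 0.15 with value ≥ 0.85. Gates are
recorded in every result. The renderer draws fibrous strands (jittered
dilated polylines) or round vacuoles in flat colors and then trims random
positive pixels so the truth count is exact; vacuole centers are kept
strictly interior to the section because a rim-touching vacuole is not a
topological hole and would otherwise be segmented as slide background. On
these renders the gates reproduce truth-mask pixel counts exactly; on real
slides, where stain colors vary and the study's ImageJ thresholds are
unreported, absolute agreement is not claimable — only recovery on renders
is.

**Statistics.** Welch t by default (printed group SEMs differ visibly;
pooled variance available by flag); zero-variance degeneracies resolve
deterministically (equal constants → t = 0, p = 1). ANOVA + Tukey HSD via
the standard library routines; Pearson r with Fisher-z 95 % CI. No
correction across metrics beyond Tukey within an ANOVA family.

## Determinism and seeds

Every simulator is a pure function of (inputs, seed). The cohort pipeline
threads one root seed through `numpy.random.SeedSequence`, spawning one
child per animal and one stream per series, so adding or reordering
acquisitions never perturbs another series' noise, and a full
simulate→fit→report run is bit-reproducible at the CSV level.

## Problem sizes

Recovery benchmarks use 100 noise realizations per condition at SNR 50:
single-liver-voxel signal vectors for T1/T2\* (the estimator's hardest
regime — no ROI averaging), 96×96 Dixon pairs with ROI averaging over the
liver ellipse, and 1024×1024 stain renders (~6.2×10⁵ tissue pixels).
Cohort runs default to 48×48 matrices and 256×256 renders; the phantom is
piecewise constant, so fitted values are independent of matrix size beyond
the number of voxels averaged, and the protocol-sized matrices remain
available through `AcquisitionParams` defaults.

## Known limitations

* Single-slice block anatomy; no B0/B1 inhomogeneity, motion, partial
  volume, or multi-peak fat spectrum — phantom recovery therefore bounds
  estimator error only, not acquisition-physics error on real data.
* The allysine trajectory and distribution volume are calibrated, not
  measured; DCE realism is limited to reproducing group-level enhancement
  magnitudes and their time course.
* Mid-diet T1/T2\*/%fat group means are interpolations between printed
  endpoints.
* Ordinal pathology beyond the numeric steatosis/inflammation thresholds
  (zone-based fibrosis staging, ballooning) is out of scope: it is not
  computable from these renders.
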