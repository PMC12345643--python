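# Methods

`habitatpipe` implements a multiparametric PET/MRI habitat analysis for
preclinical solid tumors: voxel-wise quantitative mapping, cross-modality
registration, pooled hierarchical clustering into physiological habitats,
spatial-interaction statistics, and validation against matched histology.
Because no public animal dataset accompanies the workflow, every stage is
exercised against a digital phantom with known ground truth; this note
records the models, defaults, and numerical choices, and what the phantom
does and does not emulate.

## Digital phantom

The phantom is an ellipsoidal flank tumor on a 64 x 64 x 10 grid at
0.53 x 0.53 x 1 mm (semi-axes 36% of the field of view per axis), plus a
rectangular skeletal-muscle slab used as the AIF reference region.  The
innermost fraction of tumor voxels (default 37%, matching the necrotic
volume typically seen in this model) is labelled necrotic; the remaining
viable shell is partitioned into `n_habitats` (default 5) spatially
contiguous Voronoi cells grown from random interior seed points.  A
`shuffled` flag permutes labels across viable voxels to produce a
non-contiguous control for spatial-interaction null testing.

Each habitat carries a parameter tuple (ADC mm^2/s, Ktrans min^-1, v_e,
v_p, FDG-SUV, FLT-SUV, T1 ms, S0 a.u.).  The five default archetypes encode
the phenotypes the analysis is designed to find — high vascularity (HV:
high Ktrans and v_e), hypoxic responding (HRSP: low Ktrans, high v_e, low
FDG), transitional zone (TZ: highest ADC), active tumor (ATMR: high FDG and
FLT, low Ktrans) and responding (RSP: low everything).  Necrotic tissue has
essentially no contrast exchange (Ktrans 0.002 min^-1, v_p 0.001), so its
simulated dynamic enhancement stays well under the 25% viability threshold;
all viable habitats enhance well above it at zero noise.

Forward models:

* DWI: `S(b) = S0 exp(-b ADC)` at b = 0/150/500/800 s/mm^2, Rician noise.
* Variable-TR saturation recovery: `S = S0 (1 - exp(-TR/T1))` at
  TR = 255...5500 ms, Gaussian noise.
* DCE: Extended Tofts concentration
  `C_t = v_p C_p + Ktrans \int C_p(\tau) e^{-(Ktrans/v_e)(t-\tau)} d\tau`
  computed by trapezoidal convolution on a 0.1 s grid, converted to signal
  with the same SPGR model the fitting stage inverts (TR 100 ms, flip 30°,
  r1 = 4.5 s^-1 mM^-1, appropriate at 9.4 T); 20 pure-baseline frames at
  6.4 s temporal resolution precede contrast arrival, Rician noise.
* PET: activity = SUV x injected dose / body weight on a grid twice as fine
  as the MRI per axis (and padded 4 mm beyond the MRI slab, since PET/CT
  covers more than the MRI imaging slab), blurred with a Gaussian PSF
  (default FWHM 1.5 mm), Gaussian noise.
* Histology: 2D sections of the central slice at several pixels per MRI
  voxel; per-stain counts are Poisson draws whose rates are monotone in the
  habitat's imaging parameters (nuclei ~ 1/ADC, CD31 vessels ~ Ktrans,
  Ki67 ~ FLT uptake, GLUT1 ~ FDG uptake, pimonidazole ~ FDG uptake damped
  exponentially by Ktrans so hypoxia concentrates where metabolism is high
  and perfusion poor).  Background and necrotic pixels are invalid.

The population AIF is a biexponential bolus
`C_p(t) = A (e^{-k_w (t-t0)} - e^{-k_u (t-t0)})` with A = 6 mM,
k_w = 1/120 s^-1, k_u = 0.05 s^-1 — a murine-scale bolus peaking ~3.5 mM
about 45 s after arrival.  Its two per-scan calibration handles are the
amplitude scale and the onset time.

What the phantom does *not* emulate: realistic anatomy, motion, coil
inhomogeneity, scanner reconstruction artifacts, arterial dispersion,
intra-habitat parameter gradients (each habitat is internally homogeneous
up to noise), and ex-vivo tissue deformation.  Passing tests therefore
demonstrate correctness of the numerics and the recoverability of planted
structure under acquisition-like noise and partial-volume blur — not
performance on animal data.

## Parametric mapping

* **ADC** — log-linear least squares of ln S(b) against b (standard for
  four b-values); voxels with non-positive signals are invalid.  Slices
  whose within-tumor mean ADC strictly exceeds the tumor median + 2 SD are
  excluded from ADC analysis (strict inequality; a slice exactly at the
  threshold is retained).
* **T1** — nonlinear least squares of the saturation-recovery curve via
  variable projection: S0 is profiled out analytically and the 1-D sum of
  squares is minimised over T1 in [1, 30000] ms by bounded scalar
  minimisation (tolerance 1e-3 ms).  Non-convergent, flat, or non-positive
  fits become NaN.
* **Signal-to-concentration** — SPGR steady-state inversion using the
  fitted pre-contrast T1 and the mean of the baseline frames (all 20 by
  default); concentrations are clipped at zero.  Relaxivity defaults to
  4.5 s^-1 mM^-1 and is configurable.
* **AIF calibration** — contrast arrival is the last sample before the
  muscle curve first exceeds baseline mean + 3 baseline SD, with the
  threshold floored at 5% of the curve's dynamic range.  The floor matters:
  a muscle curve averaged over thousands of voxels has an SD so small that
  pure-noise blips otherwise trigger arrivals minutes early.  The amplitude
  scale is the least-squares factor matching the Extended Tofts prediction
  for muscle (literature reference values Ktrans = 0.1 min^-1, v_e = 0.1,
  v_p = 0.02, configurable) to the observed muscle concentration curve.
* **Extended Tofts fitting** — bounded trust-region least squares with
  analytic Jacobian over Ktrans in [0, 5] min^-1, v_e in (0, 1],
  v_p in [0, 1); initial point (0.1, 0.2, 0.01), tolerances 1e-8, at most
  200 function evaluations.  The convolution is evaluated by discrete
  trapezoidal quadrature on the acquisition grid.  After convergence the
  fit is compared against the exact no-exchange solution (linear in v_p);
  if that fits at least as well, Ktrans is set to zero and v_e flagged
  unidentifiable.
* **Filtering** — voxels outside Ktrans 0-5 min^-1, v_e/v_p 0-1, or with
  peak enhancement under 25% of baseline are removed (idempotent).  The
  enhancement peak is taken on a 5-frame moving average of the
  post-contrast curve: a raw single-frame maximum is biased upward by
  noise and lets non-enhancing necrotic voxels leak through the filter.
* **SUV** — activity / (injected dose / body weight), voxel-wise.

## Coregistration

PET volumes are reframed to the MRI slice thickness by averaging adjacent
slices (exact mean conservation; integer thickness ratios only), then
down-sampled in-plane with a Gaussian prefilter (sigma = 0.42 x decimation
factor, suppressing content above the target Nyquist) and linear
interpolation onto the parametric-map grid (0.53 x 0.53 mm).  Affine
registration maximises Mattes mutual information (32 bins, random sampling
of 50% of voxels, fixed sampling seed) under regular-step gradient descent
capped at 100 iterations, in two stages: a 2-level multi-resolution global
stage, then a refinement whose metric samples are restricted to the tumor
ROI dilated by 3 voxels — this realises the "extra weight on the tumor"
idea with the machinery SimpleITK provides.  The refinement uses a 10x
smaller step so it cannot wander when the crop has little internal
contrast.  Accuracy is summarised by the Dice overlap of tumor masks
before/after; on random rigid misalignments up to 3 mm / 5° the
post-registration Dice exceeds 0.9 in at least 18 of 20 runs.  Translation
recovery is slice-thickness-limited along z (1 mm slices), so transform
errors up to ~1 mm there are expected even when Dice is high.

## Habitat clustering

Tumor voxels valid in all five maps (ADC, Ktrans, v_e, FDG-SUV, FLT-SUV)
and inside configurable physiological ranges (defaults: ADC 0.1e-3-3e-3
mm^2/s, Ktrans (0, 5] min^-1, v_e (0, 1], SUV (0, 20]) are pooled across
subjects and timepoints, z-scored per feature over the pooled matrix, and
clustered with Ward-linkage agglomerative clustering on Euclidean distance.
v_p is fitted and reported but not clustered.  Ward agglomeration is
O(n^2), so above 12,000 rows the tree is built on a fixed-seed subsample
and the remaining voxels join the nearest cluster centroid in z-space; the
silhouette used for selecting k (range 2-8, ties to the smaller k) is
evaluated on a fixed-seed subsample of at most 4,000 rows, with the Ward
tree built once and cut at every candidate k.  Cluster ids are ordered by
decreasing size.  Characterisation flags each feature high/low against the
median of the k cluster centroids (strictly above = high) and assigns names
from an ordered signature table (data, not code): RSP (all low), HRSP (low
Ktrans, high v_e, low FDG), HV (high Ktrans and v_e), ATMR (high FDG and
FLT, low Ktrans), TZ (high ADC); unmatched clusters get generic names.

## Spatial interaction (MSI)

Neighbouring voxel pairs among labelled voxels (face connectivity by
default; 26-neighbourhood available) are counted per unordered label pair
and normalised to fractions summing to 1.  The null preserves each
habitat's volume: labels are permuted uniformly over labelled positions
(default 1000 permutations, seeded), giving per-pair mean and SD, and
z = (observed - mean)/SD.  Under uniform shuffling each edge is a self-pair
of habitat h with probability n_h(n_h-1)/(N(N-1)) regardless of the edge
structure — the analytic check used in tests.  Contiguous planted habitats
produce diagonal z far above 5; shuffled controls are calibrated
(mean diagonal z near 0).

## Histology habitats

Stain density maps are box-smoothed (default kernel 10 px, zero padding —
the raw box filter conserves the global sum exactly) and bilinearly
resampled to an analysis resolution of ~0.1-0.3 mm/px.  Near the
living-tissue boundary densities are corrected by the valid footprint
fraction (normalized convolution), and pixels whose footprint is mostly
(>40%) outside living tissue are dropped.  The four clustering stains
(H&E nuclei, CD31, Ki67, GLUT1) feed the same Ward core used for imaging;
pimonidazole is withheld and used to validate hypoxia localisation as each
habitat's share of total pimonidazole-positive density (shares sum to 1).
In the integrated pipeline the histology cluster count mirrors the imaging
k so the bijective matching below is well-posed.

## Validation statistics

Histology clusters are matched to imaging habitats by exhaustive search
over all k! bijections (k <= 8), maximising the summed per-habitat Pearson
correlation between composition percentages across subjects; ties resolve
to the lexicographically smallest permutation.  Matching uses the mean
composition over the five-slice central window, then the central slice per
subject is the window slice whose matched habitat percentages correlate
best with histology (ties to the window center) — matching before slice
selection keeps the two steps well-defined.  Per-habitat Pearson r carries
a two-sided p from the t distribution with n-2 df.  Group comparisons use
a two-sided Mann-Whitney U test, computed by full enumeration over all
C(n1+n2, n1) assignments (midranks under ties) when both groups have at
most 8 observations — cohorts here are small — and a tie-corrected,
continuity-corrected normal approximation otherwise.  One-way ANOVA is
followed by Tukey HSD with adjusted p-values from the studentized range
distribution.  No further multiplicity adjustment is applied.

## Problem sizes and reproducibility

The test suite and the acceptance script run everything on phantom data at
fixed seeds: Tofts recovery on 500 voxels (SNR ~ 20 DCE noise), ADC/T1 on a
32 x 32 x 6 phantom (SNR 30), registration on 20 random misalignments of
the 64 x 64 x 10 phantom, habitat recovery on a 4-subject x 2-timepoint
feature cohort at 3-SD separation, MSI calibration on 50 shuffled
replicates (150 permutations each), and one full synthetic study with 8
subjects (64 x 64 x 10, ~5,000 fitted tumor voxels each) through
simulation, fitting, clustering, histology and matching.  These sizes keep
a complete run in the tens of minutes on one CPU while leaving each
recovery criterion comfortably away from its threshold.  Every random
component consumes an explicit seed recorded in the run report, and a
fixed-seed rerun reproduces the report byte-for-byte.

## Known limitations

* The fixed acquisition protocols carry limited information at moderate
  noise: with noise referenced to the equilibrium signal at SNR 30, the
  Cramér–Rao bound for the six-TR saturation-recovery protocol (tumor T1
  1700–2400 ms) and the efficient estimator for the four-b-value ADC
  protocol both sit near 6–8% median voxel-wise error, and the fits
  operate at that bound — tighter accuracy at this noise level is not
  achievable by any estimator, only by more or longer measurements.
* Habitat recovery through the full imaging chain degrades when habitat
  blobs approach the PET PSF scale (partial-volume mixing) — visible if the
  phantom grid is shrunk well below the default; the same effect is a
  documented limitation of the real acquisition.
* The reference-region AIF calibration assumes the literature muscle
  parameters; a mismatch biases Ktrans/v_e multiplicatively.
* The exact Mann-Whitney enumeration grows combinatorially; beyond 8 per
  group the normal approximation is used.
* Registration is affine only; no deformable step, and CT attenuation
  correction is assumed already applied to PET activity.
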