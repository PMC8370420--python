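# Methods

This note documents the models, conventions and numerical choices behind
`neorsn`, and what the synthetic-data experiments do and do not show.

## Data model and scope

All volumes are NIfTI-1 on a common voxel grid; cross-subject operations
assume voxel-grid alignment (in a real study every subject is registered
to an age-matched template first — registration is outside this package's
scope, as are acquisition, distortion correction and ICA-based denoising
of raw data). Covariates travel as a TSV with fixed columns
(`subject_id, ga_birth, pma_scan, sex, group, postnatal_days`); `group` is
derived from gestational age at birth when absent (term ⇔ GA ≥ 37 weeks),
and postmenstrual age (PMA) at scan must lie in the 37–44.5-week
term-equivalent window. An optional brain mask restricts all spatial
operations; with synthetic data the default is all voxels.

## Motion QC

DVARS for volume t is the RMS of the intensity difference to volume t−1
over in-mask voxels; it is undefined for the first volume, which is set to
0 and never flagged, and quartiles are computed over t ≥ 1 only. The
outlier threshold is Q3 + 1.5·IQR with the sorted-data linear-interpolation
quartile estimator (numpy's default, "type 7"); a constant series yields
that constant as threshold and zero outliers. The retained window is the
contiguous run of 1600 volumes (for a 2300-volume acquisition; other
lengths scale by the same ≈70% fraction, rounded) with the fewest flagged
volumes, ties broken toward the earliest start. A subject is excluded when
the retained window holds strictly more than ⌊10% of the window⌋ outliers
— 160 outliers keep the subject, 161 drop it. The retained count is stored
per subject and enters every subsequent regression as the motion covariate.

## Group ICA

Each subject's voxel time series are demeaned and scaled to unit variance,
then concatenated in time. The concatenated matrix is reduced by SVD (via
the Gram matrix on the smaller side) to K dimensions and whitened so the
K spatial rows have zero mean and identity covariance. Spatial independent
components are estimated with the fixed-point negentropy algorithm
(tanh/log-cosh contrast, parallel updates, max 1000 iterations, tolerance
1e-6, seeded); non-convergence raises with the advice to restart on a new
seed. Default dimensionality is 30 — deliberately above the expected
number of networks, which also gives the unmixing room to isolate
structured noise.

Raw component maps are converted to Z by a robust-σ normalisation:
(map − median) / (1.4826 · MAD). The background (non-network) voxels that
dominate the median/MAD act as the residual-noise reference, preserving
the Z > 3 (core template) and Z > 1 (parcellation) thresholding semantics
of mixture-model-calibrated maps without that model's machinery. Signs are
fixed so every map has positive skewness (networks are positive
activations); ordering is by explained variance, descending. On pure-noise
input the |Z| > 3 fraction stays below 1%.

Component labelling (RSN vs noise) is a manual decision supplied as a
labels file; `suggest_labels` offers an edge-concentration heuristic as a
starting point only. In synthetic experiments, labelling is replaced by
Hungarian matching of components to the generator's true maps — the
matched component per network is "signal", everything else "noise".

## Dual regression

Stage 1 regresses the full set of group maps — signal and noise components
alike, the latter kept purely to absorb confound variance — into each
volume (maps demeaned over in-mask voxels, each volume's voxel vector
demeaned), producing a T×K time-course matrix. Stage 2 regresses the
demeaned time courses into each voxel's demeaned time series, producing K
β maps. Variance-normalising the stage-1 time courses before stage 2 is a
flag (default off, matching the commonest reference formulation of the
two-stage procedure). The flag matters for amplitude questions: without
it, a subject's network amplitude scales the stage-1 time course and
cancels out of the stage-2 β, so βs carry shape but not strength; with it,
β is response per unit time-course standard deviation and scales with the
subject's network amplitude. All amplitude-based analyses in this package
(core network strength and its group/age tests) therefore run with the
flag on, and the recovery experiments pin it explicitly.

## Voxelwise inference

Designs follow the study's covariate plan — age model (term-born only):
intercept + PMA + sex + motion, contrast on PMA; sex model: + PMA, GA,
motion; term-vs-preterm and continuous-GA models: + PMA, sex, motion;
group-mean model (weekly bins): intercept + sex + motion, contrast on the
intercept. Continuous covariates are mean-centred; sex and group are coded
0/1 (male = 1, preterm = 1). Per voxel an OLS contrast t is computed with
n − p degrees of freedom.

Inference is nonparametric: TFCE with E = 0.5, H = 2, 100 integration
steps and 26-connectivity (the standard volumetric defaults), computed
separately for the positive map and its negation; the integration uses
dh = max/n_steps and thresholds at stat ≥ h. The implementation is an
incremental union-find over descending thresholds (exactly equivalent to
per-threshold connected-component labelling, verified against a flood-fill
oracle to 1e-6) and is JIT-compiled. The permutation scheme is
Freedman–Lane with all subjects exchangeable: data are residualised
against the nuisance columns, residual rows are permuted, the nuisance fit
is added back and the full model refit. Permutations are drawn without
replacement from distinct row permutations (seeded); when fewer distinct
permutations exist than requested the enumeration is exhaustive and
p-values are exact multiples of 1/n!. The identity permutation is always
counted, so p ≥ 1/(n_perm + 1). Significance masks use strict p < α with
α = 0.025 per direction (two-tailed convention), α/n with Bonferroni
across networks, and α = 0.05 for the weekly-bin group maps.

Known limitation: for the group-mean (intercept) contrast, row
permutations leave the mean essentially invariant, so the max-statistic
null is nearly degenerate and FWE p-values are extremely conservative; a
sign-flipping scheme would be the usual remedy and is deliberately out of
scope. The weekly-bin maps are therefore best read through their t-maps,
which is how the recovery tests evaluate them.

## Core network strength and its analyses

Core network strength is the arithmetic mean of a subject's β map over the
voxels where the same network's group template exceeds Z > 3 (strict). It
is linear in β and requires a non-empty core mask. Partial Spearman
correlation rank-transforms all variables (average ranks on ties),
residualises ranked strength and ranked PMA on the ranked covariates plus
intercept, and correlates the residuals; p comes from the t approximation
with n − c − 2 degrees of freedom. When a variable is fully explained by
the covariates the partial correlation is defined as 0. The group GLM
regresses strength on [intercept, group, PMA(centred), sex,
motion(centred)] per network; covariate-adjusted strengths (nuisance
effects removed, intercept and group retained) are emitted for plotting.
Percent reduction uses raw group means — 100·(term − preterm)/term — with
an unpaired t-test; a non-positive term mean is flagged, not fatal.

## Parcellation

Signal Z-maps are Gaussian-smoothed (FWHM in mm over the voxel size;
default 3 mm ≈ 1.5 voxels at 2.15 mm resolution — the kernel size is not
dictated by anything upstream and is config-exposed), and each voxel takes
the label of the network with the highest smoothed Z among those above
Z > 1, with ties broken deterministically to the lowest component index;
voxels with no suprathreshold candidate stay 0. Volume labels are the
deliverable; surface projection is out of scope.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **Networks** — K smooth, non-negative, midline-symmetric maps (mirrored
  Gaussian blob pairs, truncated to compact support, max-normalised);
  centres are placed with a minimum-separation rule and resampled until
  all pairwise spatial correlations are < 0.2.
* **Time courses** — white noise hard-limited in the frequency domain to
  < 0.1 Hz (the band where resting-state coherence lives), zero-mean, unit
  variance. At desk-scale T this leaves few temporal degrees of freedom,
  which is the main driver of estimation noise (see below).
* **Amplitude law** — a_k = base + slope_k·(PMA − 40), multiplied by
  (1 − attenuation) for preterm-born subjects; an optional additive delta
  on a subregion of one network for female subjects. The law is
  deterministic, so truth records reproduce it exactly.
* **Artifacts** — edge-localised rings with broadband time courses, giving
  component labelling genuine negatives and dual regression real confound
  regressors.
* **Noise and motion** — iid Gaussian sensor noise; motion spikes are
  whole volumes with an additive global jump of 3·(noise_sd + base
  amplitude), far above the DVARS threshold yet in a realistic intensity
  range. Spikes model only what downstream QC consumes (DVARS); rigid-body
  motion is not simulated.
* **Covariates** — GA at birth uniform on 37–42.3 weeks (term) or
  24.3–36.9 weeks (preterm), PMA at scan uniform on [max(37, GA), 43.5],
  sex Bernoulli(1/2), postnatal days implied.

Defaults mirror the study-scale acquisition (TR 0.392 s, 2300 volumes,
248 term + 65 preterm, 11 networks) on a desk-scale 24×24×14 grid. Effect
sizes have no published amplitude-unit values, so the defaults are chosen
once so that the recovery experiments at their stated sample sizes are
well powered: base amplitude 1, noise SD 1, age slope 0.07 per week,
attenuation 0.30 (the centre of the reduction range the method should
recover), sex delta 0.2, spike rate 0.03 (matching the observed outlier
fraction of roughly 50 of 1600 volumes).

## Recovery experiments and their scale

`neorsn.pipeline.effect_recovery_experiment` runs the full chain on a
seeded cohort: 84 term + 40 preterm subjects on a 16×16×10 grid with
T = 1000 volumes, 4 networks (age slope on two), 2 artifact components.
The last 24 term-born subjects are held out as the template group whose
group ICA defines the networks — mirroring the design in which an older
term subsample defines normative RSNs and is excluded from analysis —
leaving 60 term + 40 preterm for dual regression, the voxelwise age
contrast (500 permutations, FWE p < 0.025), percent reduction, the group
GLM and the partial Spearman age association.

Two desk-scale effects deserve note. First, band-limited time courses over
a cropped window have a random sample variance (~±15% at these lengths),
which acts as multiplicative per-subject amplitude noise; it shrinks with
longer acquisitions and is the reason T = 1000 rather than something
shorter. Second, stage-1 time-course estimation noise interacts with
variance normalisation to shrink measured amplitudes slightly more for
low-amplitude subjects; with networks covering a realistic fraction of the
grid the residual bias on the percent-reduction estimate is within ±2
points. Passing these tests demonstrates that the chain recovers known
effects under its own generative assumptions — stationary networks, linear
amplitude effects, Gaussian noise, global spikes. It does not certify
behaviour under real-data violations: subject-varying topography,
physiological noise spectra, registration error or spatially correlated
noise.

## Numerics and conventions

* Quartiles: linear interpolation; ranks: average on ties.
* OLS everywhere via `lstsq`/pinv; rank-deficient design or map matrices
  raise with the offending columns listed.
* TFCE: float64 throughout; the union-find path is exact, not approximate.
* Permutation p-values: (1 + #{null ≥ obs}) / (1 + n_perm); null maxima
  are per-direction spatial maxima of the TFCE map.
* Reproducibility: every stochastic stage takes an explicit seed; cohort
  generation derives per-subject seeds from the cohort seed, so a cohort
  is byte-reproducible; the CLI writes a JSON manifest with config, seed
  and file hashes per stage.
* Bin edges for weekly maps are half-open [lo, hi); subject selection
  within a bin sorts by (postnatal days, subject id).
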