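# Methods

This note documents the models and procedures implemented in `mvcs`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real data.

## The similarity analysis

### MVCS matrices

For one run and one region of interest (ROI) with $n$ voxels, the
multivoxel correlation structure (MVCS) is the $n \times n$ matrix of
pairwise Pearson correlations between the voxel time courses, Fisher
z-transformed entry-wise ($z = \operatorname{arctanh} r$) to make the
entries approximately normal. The diagonal is stored as zero and excluded
from all downstream use. Voxels with zero temporal variance are removed
(and logged) before the correlation; a degenerate off-diagonal pair
($|r| \ge 1 - 10^{-7}$, e.g. two identical voxel series) is clipped to
$\pm\operatorname{arctanh}(1 - 10^{-7})$ with a warning rather than
dropping the voxels — one tied pair should not discard two otherwise
informative voxels, and clipping keeps every downstream quantity finite.

### Similarity index

The similarity index (SI) between two runs is the Pearson correlation
between the vectorized **strict upper triangles** of their two MVCS
matrices, r-to-z transformed. The triangle, not the full matrix, is used:
the matrices are symmetric, so full-matrix correlation would double-count
every entry, and the diagonal carries no information. Using the triangle
or the full matrix changes nothing in expectation for symmetric matrices;
the triangle is the canonical choice. SI is symmetric in its arguments
and invariant to a voxel relabeling applied consistently to both
matrices. A perfect correlation between two matrices (e.g. a matrix with
itself) is reported as a degenerate-similarity error instead of an
infinite SI.

Three run pairings are assembled per subject, condition, and ROI:

* `early_late` — first vs. second half of task practice (blocks 1–8 vs.
  9–16, split at the boundary between block 8's rest period and block 9's
  onset), probing how much practice reshapes the local pattern;
* `rs_pre_post` — pre-task vs. post-task rest, probing intervention
  effects on resting structure;
* `task_rs_post` — the entire task run vs. post-task rest, the
  pattern-persistence ("replay") contrast.

For the task-run MVCS the interleaved rest blocks are included by default
(the run is analyzed as a continuous time series); a configuration switch
(`PreprocessSettings.include_task_rest_blocks`) restricts it to practice
frames for sensitivity analyses.

### Preprocessing

The cleaning chain, applied per run and per pairing, in a fixed order:

1. **Detrend + high-pass** (cutoff 1/128 Hz): voxel-wise least-squares
   projection onto [intercept | linear ramp | discrete-cosine modes with
   period > 128 s]. A DCT projection rather than a recursive filter: it
   is exactly linear, idempotent, and matches the convention of standard
   fMRI preprocessing environments. Runs shorter than the cutoff period
   have no drift mode; the projection then reduces to detrending.
2. **Down-sampling** (only when a pairing mixes TRs): the faster (rest,
   TR 1 s) run is linearly interpolated onto the slower (task, TR 2 s)
   grid. Resampling precedes censoring so that rows stay aligned by
   construction; motion tables and tissue pools are resampled with the
   same operator.
3. **Motion scrubbing**: framewise displacement
   $FD_t = \sum |\Delta \text{trans}| + 50\,\text{mm} \cdot \sum |\Delta \text{rot}|$
   (backward differences, rotations as arc length on a 50 mm sphere —
   the de-facto standard definition behind the 0.5 mm threshold).
   Volumes with $FD > 0.5$ mm are removed **together with the following
   volume**; $FD_0 = 0$.
4. **Gray-matter selection**: voxels with GM probability strictly
   greater than 0.10 are kept; voxel identifiers are preserved so the
   same voxels align across runs.
5. **Nuisance regression**: voxel-wise residuals against an intercept,
   the first 3 principal components of the white-matter pool and of the
   CSF pool (6 tissue regressors; unit-norm components with the
   largest-magnitude loading positive), and a 24-column motion expansion
   (parameters, squares, backward-difference derivatives with a zero
   first row, squared derivatives). Regressor rows are censored with the
   run's frame mask before fitting. Collinear columns are detected by a
   pivoted QR on unit-scaled columns and dropped with a log entry;
   residuals are numerically orthogonal to every retained regressor.
6. **Volume matching**: with $x$ the smaller retained-volume count of
   the pair, the longer run keeps the $x$ consecutive retained volumes
   starting at $\lfloor (N - x)/2 \rfloor$ — the window around its middle
   volume. Matching operates on the *post-censoring* sequence with
   floor rounding; whether the original analysis matched before or after
   censoring, and how it rounded, is not derivable from its description,
   so this is one defensible reading, fixed and documented here. Pairs
   with fewer than 30 matched volumes (configurable) are dropped with a
   logged reason.

All thresholds (0.5 mm, 1/128 Hz, 10 % GM, k = 3 components, 30-volume
minimum) are `PreprocessSettings` fields with these defaults.

Volume accounting is exact: per run and pairing,
`n_input = n_used + n_censored + n_trimmed`, and the per-pairing censored
fractions are reported in the pipeline provenance.

### ROI utilities

Spherical ROIs collect every voxel whose center lies within the radius
(inclusive) of a target coordinate; a 10 mm sphere on an isotropic 2 mm
grid centered on a voxel center contains 515 voxels. The
anterior/posterior split of a mask takes the middle slice of its coronal
extension, $m = \lfloor (y_{\min} + y_{\max})/2 \rfloor$, assigning
$y > m$ to the anterior half — an exhaustive, disjoint partition.
Coordinates are 0-based voxel indices; the second grid axis is
anterior-increasing.

## Mixed-model inference

SI values are compared with marginal (GLS) repeated-measures models:
subjects independent, observations within a subject jointly Gaussian
with a structured covariance over repeated cells.

* **SI model** (per ROI and pairing):
  `si ~ visit + stimulation + task + stimulation:task` with a fully
  **unstructured 4×4** covariance over the condition cells
  (cTBS/iTBS × SEQ/RND). Subjects with missing cells contribute their
  available cells; nothing is imputed.
* **Behavior model** (block-level speed or accuracy): fixed effects
  visit, stimulation, task, block, and the stimulation:task,
  stimulation:block, task:block, and stimulation:task:block
  interactions, with within-subject covariance
  **unstructured(4 conditions) ⊗ compound-symmetry(16 blocks)**. The
  compound-symmetry factor is a correlation matrix (unit diagonal), so
  all scale lives in the unstructured factor and the Kronecker product
  is identified.

Estimation is REML. Covariance parameters are unconstrained by
construction: log-Cholesky for the unstructured factor, $r = \tanh z$
for the compound-symmetry correlation (positive definiteness of the CS
block, $r > -1/(b-1)$, is enforced through the likelihood). The
optimizer is Fisher scoring with analytic score and expected
information and step halving; the REML log-likelihood is monitored and
never decreases across accepted iterations. Starting values are
moment-based (pooled OLS-residual covariances).

Fixed effects use sum-to-zero (effects) coding, so the block-of-
coefficients F test for each term is the Type-III test. Denominator
degrees of freedom use the Satterthwaite approximation

$$\nu = \frac{2\,(c' \hat\Phi c)^2}{g' A\, g},$$

with $\hat\Phi = (X' \hat\Sigma^{-1} X)^{-1}$ the fixed-effect
covariance, $g = \partial (c' \Phi c) / \partial \theta$ evaluated
analytically at $\hat\theta$, and $A$ the inverse **expected** REML
information. Multi-df effects (visit, block terms) decompose
$L \hat\Phi L'$ by eigencontrasts and combine the per-contrast $\nu_i$
by the standard harmonic rule $\nu = 2E/(E - q)$,
$E = \sum_{\nu_i > 2} \nu_i/(\nu_i - 2)$. In the balanced two-condition
paired sub-design this machinery reduces exactly to the paired t test:
$F = t^2$ and $\nu = n - 1$.

Follow-up contrasts are single-df F tests of condition-cell mean
differences (e.g. cSEQ − cRND) under the fitted covariance, with
Satterthwaite df. Multiple comparisons across ROIs are handled with the
Benjamini–Hochberg step-up procedure per pairing and effect (m = number
of ROIs, 4 in the emulated design).

Numerical notes: a constant response yields a flagged degenerate fit
with all F = 0 rather than a failure; a singular information matrix
falls back to a pseudo-inverse; a non-finite Satterthwaite denominator
falls back to residual df with a warning. The engine's REML criterion
was cross-checked against an independent dense-matrix evaluation and
against `nlme::gls` (corSymm + varIdent) on a frozen dataset; the
Kronecker path is checked in the test suite against a brute-force
dense-REML optimization.

## The synthetic-data generator

Real data of this kind (within-subject TBS × task fMRI) are not
publishable, so the package ships a generator whose ground truth is
known. It emulates the study design: 19 subjects by default; four
within-subject conditions {cTBS, iTBS} × {SEQ, RND} with visit order
counterbalanced by a cyclic Latin square (each condition once per visit
position when the subject count is a multiple of 4); per session a
300-volume pre-task rest run at TR 1 s, a task run at TR 2 s with 16
practice blocks of 48 key presses followed by 15 s rest blocks
(≈ 330 volumes at the default 0.55 s press interval), and a 300-volume
post-task rest run.

Each ROI run follows a low-rank factor model:
$y_v(t) = \sum_k W_{vk}\, s_k(t) + \text{drift}_v(t) + \gamma_v' \eta(t) + \varepsilon_v(t)$,
with:

* factor time courses $s_k$: moving-average-smoothed white noise
  (window ≈ 6 s), unit variance — MVCS operates on covariance
  structure, not evoked responses, so no hemodynamic model is needed;
* drift: a linear ramp and a random sinusoid with period 160–360 s
  (below the 1/128 Hz cutoff), per-voxel random amplitudes
  (`drift_amplitude`, default 2.0 in noise-SD units);
* nuisance: 3 smooth latent signals injected into voxels with random
  weights (`nuisance_gamma_sd = 0.5`) and exposed, mixed with noise, as
  20-signal WM and CSF pools — so tissue-PC regression has real shared
  structure to remove;
* white noise with `noise_sd = 1.5` against unit-scale loadings
  (columns of $W$ normalized to $\sqrt{n_{\text{voxels}}}$, 5 factors),
  i.e. roughly 70 % structured variance before drift/nuisance — chosen
  once as a moderate, realistic signal fraction for ROI-level BOLD.

**Pattern persistence** is loading mixing:
$W_B = \sqrt{\rho}\, W_A + \sqrt{1-\rho}\, W_{\text{new}}$ with columns
renormalized, so $\rho = 0$ gives independent correlation structure and
$\rho = 1$ identical structure. Within a session, late practice shares
`rho[early_late]` with early practice, and the post-rest loadings mix
the whole-task structure (`rho[task_rs_post]`) with the pre-rest
structure (`rho[rs_pre_post]`); the two shared fractions are jointly
rescaled if they exceed 1. Defaults (0.5 / 0.35 / 0.25) are moderate
values giving SI magnitudes in the range observed for within-session
vs. across-state comparisons; they are conditions, not fits. Condition
effects on persistence are additive on a product-coded scale
(task +½ for SEQ, stimulation +½ for cTBS), clipped to [0, 1], and
recorded per subject × condition × ROI × pairing in the ground-truth
table.

Motion is a slow 6-parameter random walk (0.01 mm / 2·10⁻⁴ rad steps)
plus sustained translation steps of `spike_mag` (default 1 mm) occurring
with probability `spike_prob` (default 0.02) per volume — each spike
produces exactly one FD exceedance, so the expected censored fraction
tracks `spike_prob`. Behavior is lognormal RTs around block means
$A + B e^{-\lambda (b-1)}$ for SEQ (defaults A = 350 ms, B = 150 ms,
λ = 0.35) and flat $A + B$ for RND, with Bernoulli accuracy 0.95; SEQ
target keys repeat a fixed 8-element sequence, RND keys permute all
eight keys per 8-press window.

What the generator does **not** emulate: hemodynamic response shapes and
task-evoked transients, spatial autocorrelation beyond the ROI factor
structure, physiological noise spectra, scanner artifacts, or
between-subject anatomical variability. Passing tests therefore
establish that the pipeline recovers known correlation-structure
persistence under realistic noise, motion, drift, and nuisance
contamination — not that any particular effect exists in real data.

## Simulation experiments and problem sizes

The statistical checks run the full chain (generation → preprocessing →
MVCS/SI → mixed model) at reduced problem sizes chosen so each
experiment completes in minutes while the inference problem (19
subjects, 4 cells, 10 covariance parameters) stays at study scale:
20-voxel ROIs and task runs with 12 presses/block and 5 s rest blocks
(≈ 90 task volumes). Type-I calibration uses 1000 null studies (the
acceptance script defaults to 400 to stay well inside its time budget;
`--type1-reps` overrides); the interaction-recovery experiment uses 200
studies.

The injected effect in the recovery experiment is calibrated, per the
experiment's definition, to one within-cell SD: null pilot batches
estimate the within-cell SI standard deviation and the local slope of
mean SI in ρ, and the interaction is set so each condition cell moves by
±½ SD (a standardized difference-in-differences of 1). The follow-up
contrast must then recover the injected (negative, cSEQ-lowering) sign.

## Known limitations

* The volume-matching and rounding conventions (step 6 above) are one
  reading of an under-specified procedure; results are insensitive to
  the choice for near-equal run lengths but the convention is fixed and
  logged rather than validated against the original.
* Satterthwaite df use the expected (not observed) information; the two
  agree asymptotically and exactly in the balanced paired case.
* The compound-symmetry correlation is shared across condition cells in
  the Kronecker model; heterogeneous block correlations are out of scope.
* The generator's task run keeps a fixed block schedule regardless of
  simulated RTs; block annotations are exact by construction rather than
  estimated from logs.
* NIfTI support is a thin extraction/storage hook (4D volume + mask →
  time-by-voxel table), not a full neuroimaging IO layer.
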