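# Methods

## The problem

Diffusion MRI of brain tumors is contaminated by freely diffusing water —
vasogenic edema, cystic and necrotic fluid, CSF partial volume. Free water
(FW) diffuses isotropically at about 3.0e-3 mm^2/s at body temperature,
much faster than water hindered by tissue (~0.8e-3 mm^2/s in normal brain),
so conventional single-tensor metrics such as fractional anisotropy (FA)
inside and around a lesion reflect a mixture of tissue and fluid. This
package implements the standard remedy — a two-compartment "free-water
elimination" fit on multi-shell data — together with everything needed to
exercise it end to end on synthetic tumors with known ground truth: a
phantom generator, the conventional single-shell tensor baseline, ROI
histogram summaries, and a group-level statistical battery.

## Signal model

Each voxel's signal is a weighted sum of two compartments,

    S_k = s0 * [ f * exp(-b_k * d_fw) + (1 - f) * exp(-b_k * g_k' D g_k) ]

where `f` is the fractional volume of the FW compartment, `d_fw = 3.0e-3
mm^2/s` is fixed (a physical constant, not a fitted parameter), and `D` is
the tissue diffusion tensor. "FAt" denotes the FA of `D` — the
tissue anisotropy after the fluid contribution is removed. The model is fit
to s0-normalized attenuations; with a single nonzero shell the (f, D)
decomposition is not identifiable, so at least two nonzero b-values are
required.

## Fitting

**Objective.** Sum of squared attenuation residuals over all volumes plus a
spatial regularizer: the squared Frobenius norm of forward finite
differences of the tensor field between neighboring in-mask voxels (the
Euclidean tensor metric; off-diagonal components count twice). One-sided
differences apply at mask boundaries; pairs leaving the mask contribute
nothing.

**Per-voxel scale (variable projection).** The data term profiles a
per-voxel scale gamma out in closed form,
`J_v = min_gamma sum_k (gamma * A_model,k - A_obs,k)^2`. The default
acquisition carries a single b=0 volume, so dividing all signals by it puts
a coherent ~1/SNR scale error on the whole attenuation profile; Monte Carlo
on single voxels at SNR 30 shows this alone floors the f error near 0.063
even when the tissue tensor is known exactly, while the profiled objective
floors near 0.031. By the envelope theorem the gradient taken at the
optimal gamma is the exact gradient of the profiled objective, so
monotonicity arguments are unaffected. Estimates are invariant to any
global rescaling of the signals.

**Initialization.** f starts from linear interpolation of the mean
top-shell attenuation between a tissue reference `exp(-b * md_init)` with
`md_init = 0.6e-3 mm^2/s` and the free-water reference `exp(-b * d_fw)`,
clamped to [0.01, 0.99]; tensors start from the single-shell DTI fit
rescaled to MD `md_init` (isotropic `md_init` where that fit is
unavailable).

**Optimization.** Monotone projected block-coordinate descent. Each voxel
takes a damped Gauss-Newton (Levenberg-Marquardt) step on its 7 parameters
(f and the 6 tensor components); the local Hessian of the regularizer with
neighbors fixed is diagonal and is added exactly. A step is accepted only
if it decreases the objective, accepted steps relax the voxel's damping and
rejected ones raise it. With `alpha = 0` the objective separates over
voxels and all voxels step together; with `alpha > 0` voxels are updated in
red-black (checkerboard) half-sweeps — every forward-difference pair joins
the two colors, so per-voxel acceptance provably decreases the coupled
objective. First-order gradient descent with backtracking was tried first
and needed thousands of sweeps without reaching the optimum on the coupled
objective; the damped-Newton scheme converges in tens of sweeps under the
same monotone contract. Convergence is declared after eight consecutive
sweeps with relative objective decrease below `rel_tol` (1e-6); `max_iter`
defaults to 400.

**Constraints.** After every step f is clamped to [0, 1] and tensors are
projected onto the eigenvalue box `[0.1e-3, 2.5e-3] mm^2/s` (keeping the
tissue compartment distinguishable from the d_fw pool; common practice for
this model family). Voxels whose f exceeds 0.98 keep their initialization
tensor and are flagged unidentifiable — essentially no tissue signal
remains to constrain them. Eigenvalue checks use a closed-form
(trigonometric) symmetric 3x3 eigensolver; only voxels violating the box
pay for a LAPACK decomposition.

**Regularization weight.** `alpha` multiplies raw tensor differences
(mm^2/s units), so meaningful weights are of order `1/d_fw^2`. The
noise-matched default is `0.0055 * K / d_fw^2` for K volumes, calibrated
once on phantom recovery: the voxel-wise f RMSE at SNR 30 across several
seeds has a flat optimum there (0.045, against 0.126 unregularized).
Stronger weights bleed tensor information across region borders and bias f;
weaker ones leave the f/tensor trade-off noise-dominated. Recovery
benchmarks against ground truth use `alpha = 0`.

MD of the tissue compartment is computed internally but exported only
behind a flag (`fit --export-md`): the initialization pins the tensor scale
at `md_init`, so tissue MD is not an independent readout of this fit.

## The phantom

A 48 x 48 x 12 voxel slab at 2 mm isotropic — large enough for stable ROI
histograms, small enough to fit in seconds. Three nested ellipsoids carve a
lesion out of an anisotropic background: a necrotic core (tissue FA 0.13,
MD 1.2e-3, f ~ N(0.50, 0.15)), an enhancing rim (FA 0.27, MD 1.0e-3,
f ~ N(0.30, 0.10)), and a non-enhancing margin (FA 0.30, MD 0.9e-3,
f ~ N(0.30, 0.10)); background is white-matter-like (FA 0.70, MD 0.8e-3,
f ~ N(0.05, 0.03)). All f draws are truncated to [0, 1]. Region means
follow the study conditions emulated (high FW with large spread in
necrosis, moderate FW elsewhere in the lesion, near-isotropic necrotic
tissue); the standard deviations are free choices of this package, set to
plausible within-region spreads. Tissue tensors are constant within each
region and built exactly from the target FA/MD (closed-form prolate
construction). Two controls are always present: a pure-tissue stripe
(f = 0) and a pure-water block (f = 1).

The acquisition mirrors a clinical multi-shell protocol: one b=0 plus 8
directions at each of b = 90, 150, 500 and 1000 s/mm^2 (33 volumes; the
low shells are the FW-sensitive ones). The 8 directions are an
antipodally-symmetric electrostatic-repulsion set, hard-coded; note that
sign-symmetric point sets such as cube vertices collapse to 4 projective
directions and cannot support a tensor fit. Noise is Rician (magnitude
MRI): `S' = sqrt((S + e1)^2 + e2^2)` with independent zero-mean Gaussians
of standard deviation `s0/SNR`; default SNR 30 on s0. Per-voxel f is
spatially independent within regions by default (`smooth_sigma_vox` adds
optional spatial correlation).

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: anatomy and crossing fibers, partial-volume ramps at
region borders, within-region tissue heterogeneity (tissue FA is exactly
constant per region), T2/TE-dependent compartment weighting, motion,
distortion, and registration error. One consequence is documented and
deliberate: in clinical data FW elimination *raises* histogram entropy of
FA in non-enhancing tumor regions, because removing spatially varying fluid
contamination reveals underlying tissue heterogeneity. This phantom has no
within-region tissue heterogeneity to reveal, so FW elimination *narrows*
the corrected-FA histogram (entropy drops by ~0.5 bits) — and the better
the fit, the lower the FAt entropy. The pipeline reports the entropy
contrast; on this phantom its sign is opposite to the clinical expectation,
by construction rather than by failure of the estimator.

## ROI summaries

Eight variables per (map, region): mean, unbiased variance, 25th/75th
quantile, median (linear interpolation between order statistics), moment
skewness `m3 / m2^1.5`, non-excess kurtosis `m4 / m2^2` (normal reference
3; both undefined for constant ROIs and reported as such), and Shannon
entropy in bits of the value histogram over a *fixed* range [0, 1] with 256
bins (ceiling 8 bits; empty bins contribute zero). The fixed range makes
entropies comparable across subjects and maps; bin count, range and log
base are estimator choices, not physical constants, and absolute entropy
values move with them while contrasts are robust. Non-finite voxels
(outside the fit mask) are excluded before all statistics. The non-enhancing
region is derived as total minus (enhancing plus necrotic); mask nesting is
validated, never silently clipped.

## Group statistics

Implemented from their defining formulas, with scipy supplying only the
reference distributions (Student t, F, studentized range):

- paired t-test on differences, two-sided, df = n-1;
- Bonferroni `p_adj = min(1, m p)`; the default family is the 8 summary
  variables tested per region (whether the family should also span regions
  is exposed as a knob);
- one-way ANOVA F with Tukey HSD post hoc; unbalanced groups use the
  Tukey-Kramer standard error, p-values from the studentized-range
  distribution;
- ROC by fitting a univariate logistic model (intercept + map value) with
  IRLS/Newton to 1e-8 on a standardized covariate, then sweeping its
  predicted probability. The logistic link is monotone in one covariate, so
  the AUC equals the Mann-Whitney statistic of the scores in the fitted
  direction; ties are credited one half. Under complete separation the IRLS
  diverges and the raw scores are swept directly (identical curve), with
  the event recorded on the result.

Study-level AUCs are per-subject curves averaged (a pooled-voxel mode
exists as an option); which of the two the emulated study design used is
not determinable, and the per-subject average is the more conservative
reading of "across all patients".

## Study orchestration

The default synthetic cohort is 10 high-grade subjects (full three-region
lesion) and 6 low-grade subjects (no necrotic core). Per-subject seeds
derive deterministically from the master seed, so a rerun reproduces every
table byte for byte. Each subject gets a single-shell (b=1000) OLS tensor
fit (the non-corrected baseline; S0 from the mean of b=0 volumes, voxels
with non-positive signal excluded) and the multi-shell FW fit with the
noise-matched alpha; FA, FAt and FW maps then feed the ROI summaries,
paired FA-vs-FAt tests per region, ANOVA + Tukey on region means of FW and
FAt, and per-subject ROC for necrotic-vs-enhancing (enhancing = positive
class) and enhancing-vs-non-enhancing (non-enhancing = positive class).
Registration to a structural space is the identity here: all phantom maps
share one grid by construction.

## Numerical and degenerate-input policy

- OLS (unweighted) log-linear tensor fit for the baseline: additive signal
  noise makes attenuation noise approximately homoscedastic, and OLS is the
  reproducible common denominator of routine tools; robust/weighted
  variants are out of scope.
- Eigen-decompositions keep negative eigenvalues; clipping happens only
  where a consumer requires it (FA is clipped to [0, 1] after evaluation).
- f is parameterized directly with clamping, not through a logit, so f = 1
  is attainable for the pure-water control.
- Degenerate inputs raise typed errors rather than returning numbers:
  single-shell schemes (degeneracy), fewer than 6 projective directions
  (rank deficiency), constant paired differences or zero within-group
  variance (degenerate statistics), non-nested ROI masks (validation).

## Problem sizes

Defaults were chosen so a full study (16 subjects, 33-volume fits on
~18,000 brain voxels each) completes in a few minutes on one CPU; the unit
test suite uses 24 x 24 x 8 phantoms with the same structure. The
acceptance script runs the full default sizes.

## Known limitations

- The regularization weight is phantom-calibrated, not theoretically
  optimal; real data with different noise or voxel size warrant
  recalibration.
- Rician bias is simulated but not corrected in the fit; at SNR 30 it
  biases necrotic-region f upward by a few hundredths (the reported
  necrotic FW mean runs ~0.58 against a planted 0.50).
- The baseline tensor fit is OLS; tools that use weighted fits will differ
  slightly in noisy voxels.
- Gradient directions are interpreted in the image frame; no reorientation
  or distortion handling.
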