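# Methods

`gliomamap` re-implements, as a tested library, the bespoke computations used
to relate multiregional glioma biopsies to multiparametric MRI: clonality
classification of somatic variants, genetic-versus-spatial distance analysis,
single-sample pathway subtyping, Boxerman leakage fitting of DSC-MRI,
a Monte-Carlo digital reference object (DRO), and random-intercept mixed
models. Because the real 313-biopsy cohort is not redistributable, every
stage is exercised against synthetic cohorts with a complete ground-truth
manifest. This note records the models, the defaults that matter, and the
choices made where a published description was silent.

## Synthetic cohorts

**Clone structure.** A patient's tumor is a rooted clone tree; the branch
into each clone carries the variants acquired by that lineage. Variants on
the root branch are truncal (carried by every clone), variants on internal
branches shared, and variants on leaf branches private — by construction.
`planted_composition_tree` builds a random binary merge tree over one leaf
clone per biopsy, so a requested truncal/shared/private split (default
60/22/18, the regime reported for multiregional IDH-mutant glioma) is
realized *exactly*, and non-enhancing (NE) biopsies receive a 3x weight when
private variants are distributed over leaves, planting the higher private
burden of invasive tumor.

**Sequencing.** A biopsy on the lineage root→leaf mixes its clones with
Dirichlet weights biased toward ancestral clones for contrast-enhancing (CE)
biopsies and toward leaves for NE (bias scalar 2.0). Expected VAF =
purity x lineage fraction x 0.5 (diploid heterozygous; CNV-driven VAF shifts
are out of scope). Alt reads are binomial(depth, expected VAF); a variant is
*called* only when alt reads reach `detect_min_alt` (default 3), which
creates the recoverable false negatives the rescue step exists for.
`depth=None` is the noiseless infinite-depth limit (counts at nominal depth
1e6 without sampling). Purity is uniform on (0.45, 0.85).

**Expression.** Log-scale expression = per-gene baseline N(5, 1) + an
`effect` (default 2) added to the sample's own subtype gene set + N(0,
`noise_sd`) noise. Gene sets must be disjoint so the planted truth is
unambiguous; optional purity scaling attenuates the effect by tumor purity.
Subtype labels are drawn region-dependently (PPR-weighted in CE,
NEU/GPM-weighted in NE) to reproduce the region-specific enrichment the
association tests look for.

**DSC time courses.** The whole-brain reference relaxation curve is a
gamma-variate A(t-t0)^a exp(-(t-t0)/b) (t0 = 30 s, a = 3, b = 1.5 s, peak
25 1/s at TR 1.5 s, TE 30 ms, 90 frames — the GE-EPI acquisition regime).
Each ROI follows dR2*_roi = K1 dR2*_ref - K2 cumint(dR2*_ref) and is
converted to signal S = S0 exp(-TE dR2*) with Rician noise at the stated SNR
(Gaussian optional). The reference curve is synthesized noise-free: it
stands for an average over thousands of voxels, and putting single-ROI noise
on it would inject an errors-in-variables attenuation bias into the fit that
real pipelines do not have. The NAWM curve has K2 = 0 and half blood volume.

What the generator does **not** emulate: spatial autocorrelation between
neighboring biopsies, CNV-driven VAF distortion, sequencing error (so rescue
has no false-positive channel), batch effects in expression, and bolus
recirculation. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to everything real
data does.

## Clonality

Labels follow carrier-set cardinality per patient: private = exactly one
carrier, truncal = all of the patient's biopsies, shared = otherwise.
Single-biopsy patients are excluded (the definitions collide at n = 1).
Rescue re-examines, for every (variant, non-carrier biopsy) cell, the pileup
at the mutant position and adds a flagged call when alt >= `min_alt` (2) and
alt/depth >= `min_vaf` (0.01); original calls are never removed, so rescue
can only move labels toward truncal. Region composition counts a variant
once in every region containing at least one carrier (private variants
follow their single carrier); the attribution rule is symmetric and stated
here because published per-region bars do not define one.

Mutual exclusivity reports the fraction of altered samples carrying exactly
one of the two genes, with a two-sided Fisher exact p computed by full
hypergeometric enumeration of the 2x2. The CE-vs-NE composition test
enumerates all 2x3 tables with the observed margins when the grand total is
<= 500 and falls back to chi-squared above that (the method used is always
reported).

## Distances

Genetic distance is 1 - Jaccard over post-rescue alteration keys (SNVs,
indels, and gene-level CNV states share one key space); two empty sets are
defined maximally similar (0) with a warning. Euclidean distance is the
plain 3-D norm in mm. All unordered within-patient pairs are formed, never
cross-patient ones, and stratified CE-CE / NE-NE / CE-NE. Pearson r comes
with the parametric p and an optional permutation p that shuffles genetic
distances *within patient* (pairs sharing a biopsy are dependent, so the
parametric p is optimistic); the permutation is exhaustive whenever the
number of distinct within-patient shuffles is below the requested count.

## Subtyping

For one sample and one gene set, U counts in-set/out-set gene pairs where
the in-set gene is expressed higher (ties 0.5); NES = U/(n_in n_out) is the
probability an in-set gene outranks an out-set gene, so NES is invariant
under any strictly increasing transform of expression. The p-value uses the
exact U distribution when n_in x n_out <= 1e4 with no ties, else the
tie-corrected normal approximation. A sample takes the subtype with the
highest score among those with logit(NES) > 0.40 and p < 0.05; exact logit
ties break to the lower p, then to the fixed order GPM < MTC < NEU < PPR.
The published method cites the mww-GST without restating formulas; the
common-language effect size above is this module's interpretation.

Variable-gene selection is top-n by variance with gene-id tie order.
Clustering is agglomerative on 1 - Pearson correlation between samples with
Ward linkage (standard for expression heatmaps; both are config-overridable
since the original analysis does not state its choices). The deconvolution
stand-in solves non-negative least squares per sample against a signature
matrix, renormalizes to 1, then fixes the tumor share to WES purity and
rescales non-tumor shares to (1 - purity).

## DSC-MRI

dR2*(t) = -(1/TE) ln(S(t)/S0) with S0 the mean over a pre-bolus baseline of
at least 5 frames. The leakage model regresses the measured tumor curve on
the reference curve and its running trapezoid integral; the coefficients are
(K1, -K2). The printed form of the model is self-referential (the same
symbol appears on both sides); this implementation uses the standard
Boxerman reading — measured tumor curve on the left, whole-brain
non-enhancing average on the right. Bolus arrival = first frame where the
reference exceeds baseline mean + 5 sd.

Derived metrics (definitions always emitted in metadata, since the vendor
pipeline's exact formulas are proprietary): corrected curve = measured +
K2 cumint(ref); rCBV = corrected area / NAWM corrected area from bolus
arrival; nK2 = K2_roi / K2_NAWM, an explicit null when K2_NAWM = 0; PSR =
100 (S_post - S_min)/(S0 - S_min) with S_post the mean of the last 20% of
frames; MTT = area/height of the corrected curve; RTTP = peak time minus
arrival; Tmax is a surrogate (peak offset vs reference peak — no AIF
deconvolution) and is labeled as such. ROI means use 8x8x1 voxel windows
with even dimensions anchored low (recorded voxel at in-window index
(4,4,0)); map normalization divides by the in-mask median.

## Digital reference object

Tissue is spherical cells (ellipsoids simplified to spheres; the
demagnetization tensor of a general ellipsoid is omitted) packed by random
sequential addition around randomly oriented cylindrical vessels in a
periodic 64 um box; monodisperse RSA jams near packing fraction 0.38, so the
default cell fraction is 0.30 with mean radius 5 um, vessel radius 2.5 um at
3% volume. Field offsets superpose the closed-form sphere (dipole) and
infinite-cylinder external fields, with standard interior constants; offsets
are linear in the susceptibility difference. Spins random-walk with
reflecting (rejection) boundaries at membranes by default, with free
diffusion as an option, and accumulate phase gradient-echo style (no
refocusing). `mode="fid"` integrates phase from t = 0 (single-shot decay,
used by the closed-form regime checks); `mode="dsc"` resets phase each TR
and accrues it over TE, which gives the S = S0 exp(-TE dR2*) semantics the
leakage fit expects. The remaining TR - TE diffusion is taken in 10 coarser
jumps with the same rejection rule.

Contrast: intravascular gamma-variate concentration c_v(t); optional EES
accumulation c_e = k_leak cumint(c_v) (unidirectional; T1 effects out of
scope). Field scaling is dchi_v (c_v - c_e) for vessels and -dchi_c c_e for
cells. Susceptibility-per-concentration defaults put peak tumor dR2* in the
clinical 10-30 1/s range, with the cell-interface offset several-fold below
the intravascular one (EES contrast is dilute), which also places cell-scale
dephasing in the intermediate/diffusion-narrowing regime where it responds
to cell size.

The heterogeneity experiment compares radius CV 0% vs 6.5% with *paired*
tissues: vessels and cell centers are shared (packing at the per-cell
maximum radius across variants) and radii are stratified lognormal
quantiles, so the conditions differ only via the radii draws. Even so, the
CV = 6.5% contrast is a second-order (CV^2 ~ 0.4%) perturbation of the
leakage dephasing: at 10^4 spins and 5 seeds the paired K2 difference
(~ -7e-4 on K2 ~ -0.08) is of the same order as its standard error, and the
package reports the difference in units of that standard error rather than
claiming a resolved direction. Cited DRO work varies ellipsoid aspect
ratios and diameters jointly and calibrates against patient signal-recovery
distributions; that calibration is not reproducible here and is replaced by
the invariant and regime checks in the test suite.

## Mixed models

y_ij = x_ij' beta + b_i + e_ij with one random intercept per patient.
Estimation is REML profiled over lambda = sigma_b^2/sigma_e^2: V = I +
lambda ZZ' is block diagonal and inverted per patient by a rank-one update,
beta is GLS, and the 1-D profile is minimized on a log grid refined by
bounded scalar search (tolerance 1e-10 on log10 lambda); the lambda = 0
boundary (OLS) always competes, so one-sample-per-patient data degrade
gracefully. Only a single random intercept is supported — no random slopes.

Percent variance is sequential (Type-I style): terms enter in model order at
the full-model lambda, and each term's share is the variance of the change
in GLS fitted values over the total response variance; patient and residual
shares are appended. The original analysis does not define its estimator;
this one is stated in the output. EMMs average model predictions over the
factor grid with equal cell weights (numerics at their means), contrasts use
the studentized-range (Tukey) adjustment, and degrees of freedom are
Satterthwaite via a numeric Hessian of the unprofiled REML surface with a
residual-df fallback. The signature screen z-scores both variables within
stratum and reports Pearson r/p next to the LMM slope, SE, slope p and
marginal R^2, plus a Benjamini-Hochberg column added as a convenience.
Median binning sends strictly-above-median to "high" and exact ties to
"low".

## Problem sizes and numerics

Synthetic-cohort tests use 2-6 patients x 6-8 biopsies x 50 variants/patient
at depth 500 — sizes at which every oracle (set enumeration, exhaustive
permutation, hypergeometric enumeration) is exact and the full suite runs in
minutes. The DRO experiment uses a 64 um box, 48^3 field grid, 10^4 spins,
60 frames, 1 ms substeps. Calibration runs use 500 null simulations
(type-I error) and 200 replicate fits (variance-component recovery).
Numerical choices: leakage fit via `lstsq` (rank-checked), REML convergence
1e-10 on log10 lambda, sigma_e^2 floored at 1e-30 for exact-fit data,
trilinear field interpolation with periodic wrap, Fisher/RxC enumeration in
log-gamma space with a 1e-9 relative tie tolerance.

## Known limitations

Single-nucleotide keys only (no haplotype phasing); no CNV segmentation; the
genetic distance treats all alteration classes equally; the DRO has no
k-space/EPI model, no spin-echo pathway, no T1 leakage term; Euclidean
distance underestimates along-tract separation; the LMM supports one
grouping factor. These mirror the scope of the original analyses or are
stated simplifications of them.
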