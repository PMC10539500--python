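# gliomamap

Tools for integrated molecular + multiparametric-MRI mapping of high-grade
glioma, built for studies that collect several stereotactic biopsies per
patient — from both the contrast-enhancing core (CE) and the non-enhancing,
invasive margin (NE) — and ask how regional genomics, transcriptional state,
and imaging physiology relate across space.

The package implements, as a reusable library with a synthetic-cohort
generator for validation:

- **Clonality** — somatic variants classified *truncal* (in all of a
  patient's biopsies), *shared* (some but not all) or *private* (exactly
  one), after a pileup-based rescue of calls missed at low VAF; per-region
  composition, gene-pair mutual exclusivity with an exact Fisher test, and
  an exact CE-vs-NE composition test.
- **Distances** — within-patient pair tables relating Euclidean distance
  `d(p,q) = sqrt(Σ (p_i - q_i)^2)` (mm, from stereotactic coordinates) to
  genetic distance `1 − |A∩B|/|A∪B|` over alteration patterns, with
  stratified correlations and within-patient permutation p-values.
- **Subtyping** — single-sample Mann–Whitney gene-set test:
  `NES = U/(n_in·n_out)`, the probability an in-set gene outranks an
  out-set gene; a sample takes the subtype (GPM/MTC/NEU/PPR) with the
  highest score passing `logit(NES) > 0.40` and `p < 0.05`. Plus
  variable-gene selection, correlation-distance Ward clustering,
  enrichment tests and a purity-scaled NNLS deconvolution.
- **DSC-MRI** — `ΔR2*(t) = −(1/TE)·ln(S(t)/S0)` and the Boxerman leakage
  fit `ΔR2*_tumor ≈ K1·ΔR2*_ref − K2·∫ΔR2*_ref dt'`, yielding K2, nK2
  (= K2 / K2 of contralateral normal-appearing white matter),
  leakage-corrected rCBV, PSR, MTT and timing surrogates; 8×8×1-voxel ROI
  means and whole-brain-median map normalization.
- **DRO** — a Monte-Carlo digital reference object: spherical cells packed
  around cylindrical vessels, analytic susceptibility fields, diffusing
  spins accumulating phase, gradient-echo signal; used to ask whether
  cell-size heterogeneity (radius CV 0% vs 6.5%) moves the fitted K2.
- **Association** — random-intercept linear mixed models
  `y_ij = x_ij'β + b_i + e_ij` (patient `i` as random effect, REML),
  percent-variance decomposition, estimated marginal means with
  Tukey-adjusted contrasts, imaging×signature screens and median
  high/low binning.

## Worked example

```bash
python examples/05_dsc_leakage.py
```

```
roi_id     K1      K2      nK2   rCBV      PSR    MTT  RTTP  Tmax_surrogate
  nawm 0.5094 -0.0007   1.0000 1.0000  98.3404 5.7248   3.0             0.0
 tumor 1.2180  0.0503 -76.9271 2.3793 151.4079 6.2460   3.0             0.0

K1 recovered 1.218 (true 1.2), K2 recovered 0.0503 1/s (true 0.05)
```

A tumor ROI was synthesized with K1 = 1.2 and K2 = 0.05 1/s at SNR 50
(TR 1.5 s, TE 30 ms); the fit recovers both to within a few percent. K2 > 0
means the post-bolus tail sits below the reference (T1-dominant leakage),
and rCBV ≈ 2.4 reflects the ROI's larger corrected ΔR2* area relative to
white matter. The other scripts in `examples/` walk through cohort
simulation, clonality with rescue, distance correlations, subtyping,
the DRO heterogeneity experiment, mixed models, and the end-to-end
pipeline (`gliomamap.pipeline.run_pipeline`).

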