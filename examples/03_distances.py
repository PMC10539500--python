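"""Relate genetic divergence (1 - Jaccard) to spatial separation in mm.

Builds all within-patient biopsy pairs, correlates the two distances with a
within-patient permutation p, and compares CE-to-NE genetic distance across
the NE member's transcriptional subtype.
"""

from gliomamap import clonality, distances, synthetic

variants, pileups, truth = synthetic.generate_planted_cohort(
    n_patients=6, samples_per_patient=6, seed=9, depth=500, detect_min_alt=3
)
rescued = clonality.rescue_calls(variants, pileups)
variant_sets = {s: set(g["variant_key"]) for s, g in rescued.groupby("sample_id")}
subtypes = dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))

pairs = distances.build_pair_table(truth.samples, variant_sets, subtypes)
print(f"pairs: {len(pairs)} "
      f"({pairs['pair_region'].value_counts().to_dict()})")

corr = distances.correlate_distances(pairs, n_permutations=2000, seed=9)
print(f"all pairs: r = {corr['pearson_r']:.3f}, "
      f"parametric p = {corr['p_param']:.3g}, permutation p = {corr['p_perm']:.3g}")

summary, tests = distances.ce_to_ne_subtype_distance(pairs, subtypes)
print(summary.round(3))
# The permutation p shuffles genetic distances within each patient, which
# respects the fact that pairs sharing a biopsy are not independent; in this
# synthetic cohort coordinates and variants are unlinked, so r is near zero.
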