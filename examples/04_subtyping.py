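"""Single-sample pathway classification with the Mann-Whitney gene-set test.

Scores every sample against the four subtype gene sets (GPM, MTC, NEU, PPR),
applies the logit(NES) > 0.40 & p < 0.05 rule, clusters samples on the most
variable genes, and tests subtype-by-region enrichment.
"""

import pandas as pd

from gliomamap import subtyping, synthetic

_, _, truth = synthetic.generate_planted_cohort(
    n_patients=5, samples_per_patient=8, seed=3, depth=None, detect_min_alt=1
)
gene_sets = synthetic.default_gene_sets(1000, 50)
expr = synthetic.generate_expression(
    truth, gene_sets, n_genes=1000, effect=2.0, noise_sd=1.0, seed=3
)

labels = subtyping.classify_all(expr, gene_sets)
truth_labels = pd.Series(dict(zip(truth.samples["sample_id"],
                                  truth.samples["subtype"])))
acc = (labels == truth_labels.reindex(labels.index)).mean()
print(f"label recovery: {100 * acc:.0f}% of 40 samples")

top = subtyping.select_variable_genes(expr, 300)
clusters = subtyping.cluster_samples(expr.loc[top], k=2)
regions = pd.Series(dict(zip(truth.samples["sample_id"],
                             truth.samples["region"])))
res = subtyping.pairwise_subtype_tests(labels, regions.reindex(labels.index))
print(res["table"])
print(f"subtype x region chi-squared p = {res['chi2_p']:.2e}")
# NEU is planted preferentially into NE biopsies and PPR into CE, so the
# omnibus chi-squared flags the region association, mirroring the
# region-specific enrichment of pathway subtypes in multiregional glioma.
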