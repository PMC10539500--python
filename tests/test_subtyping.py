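"""mww-GST scoring, subtype calls, clustering, enrichment, deconvolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliomamap import subtyping, synthetic
from gliomamap.subtyping import SubtypeScore


def brute_force_nes(values: pd.Series, gene_set) -> float:
    """Oracle: count in/out pairs directly (ties worth 0.5)."""
    inside = values[values.index.isin(set(gene_set))].to_numpy()
    outside = values[~values.index.isin(set(gene_set))].to_numpy()
    u = 0.0
    for vi in inside:
        for vo in outside:
            u += 1.0 if vi > vo else (0.5 if vi == vo else 0.0)
    return u / (len(inside) * len(outside))


class TestMwwGst:
    def test_maximal_separation(self):
        s = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"), name="s")
        assert subtyping.mww_gst(s, ["a", "b"]).nes == 1.0

    def test_worked_pair_count(self):
        s = pd.Series([5.0, 2.0, 4.0, 3.0, 1.0], index=list("abcde"), name="s")
        sc = subtyping.mww_gst(s, ["a", "b"])
        assert sc.nes == pytest.approx(4 / 6)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            vals = pd.Series(
                np.round(rng.normal(size=n), 1),  # rounding forces some ties
                index=[f"g{i}" for i in range(n)],
                name="s",
            )
            gs = list(rng.choice(vals.index, size=int(rng.integers(2, n - 2)), replace=False))
            assert subtyping.mww_gst(vals, gs).nes == pytest.approx(
                brute_force_nes(vals, gs)
            )

    def test_null_mean_nes_is_half(self, rng):
        vals = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)], name="s")
        nes = [
            subtyping.mww_gst(vals, rng.choice(vals.index, 10, replace=False)).nes
            for _ in range(1000)
        ]
        assert np.mean(nes) == pytest.approx(0.5, abs=0.01)

    def test_rank_invariance_under_monotone_transform(self, rng):
        vals = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)], name="s")
        gs = [f"g{i}" for i in range(7)]
        a = subtyping.mww_gst(vals, gs)
        b = subtyping.mww_gst(np.exp(vals), gs)
        assert a.nes == b.nes

    def test_antisymmetry_under_negation(self, rng):
        vals = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)], name="s")
        gs = [f"g{i}" for i in range(9)]
        assert subtyping.mww_gst(vals, gs).nes == pytest.approx(
            1.0 - subtyping.mww_gst(-vals, gs).nes
        )

    def test_p_value_matches_scipy(self, rng):
        vals = pd.Series(rng.normal(size=80), index=[f"g{i}" for i in range(80)], name="s")
        gs = [f"g{i}" for i in range(10)]
        sc = subtyping.mww_gst(vals, gs)
        ref = stats.mannwhitneyu(
            vals[gs], vals.drop(gs), alternative="two-sided", method="exact"
        ).pvalue
        assert sc.p_value == pytest.approx(ref)

    def test_degenerate_sets_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"), name="s")
        with pytest.raises(ValueError):
            subtyping.mww_gst(s, ["a"])
        with pytest.raises(ValueError):
            subtyping.mww_gst(s, ["a", "b", "c"])


class TestClassifySample:
    def _score(self, name, logit, p):
        nes = 1.0 / (1.0 + np.exp(-logit))
        return SubtypeScore("s", name, nes, logit, p)

    def test_highest_significant_score_wins(self):
        scores = [
            self._score("NEU", 0.9, 0.01),
            self._score("GPM", 0.5, 0.02),
            self._score("MTC", 0.2, 0.001),
            self._score("PPR", 1.5, 0.20),  # high but not significant
        ]
        assert subtyping.classify_sample(scores) == "NEU"

    def test_none_significant_is_unclassified(self):
        scores = [self._score(n, 0.3, 0.01) for n in subtyping.SUBTYPE_ORDER]
        assert subtyping.classify_sample(scores) == "unclassified"

    def test_threshold_is_strict(self):
        scores = [self._score("GPM", 0.40, 0.01)] + [
            self._score(n, 0.0, 0.5) for n in ("MTC", "NEU", "PPR")
        ]
        assert subtyping.classify_sample(scores) == "unclassified"

    def test_tie_breaks_lower_p_then_fixed_order(self):
        tie_p = [
            self._score("PPR", 0.8, 0.04),
            self._score("MTC", 0.8, 0.01),
        ]
        assert subtyping.classify_sample(tie_p) == "MTC"
        tie_all = [
            self._score("PPR", 0.8, 0.01),
            self._score("NEU", 0.8, 0.01),
        ]
        assert subtyping.classify_sample(tie_all) == "NEU"  # NEU < PPR in fixed order

    def test_planted_recovery_at_least_90_percent(self, planted_expression):
        expr, gene_sets, truth = planted_expression
        labels = subtyping.classify_all(expr, gene_sets)
        truth_labels = pd.Series(
            dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))
        )
        accuracy = (labels == truth_labels.reindex(labels.index)).mean()
        assert accuracy >= 0.90

    def test_null_effect_classifies_near_chance(self, noiseless_cohort):
        _, _, truth = noiseless_cohort
        gs = synthetic.default_gene_sets(400, 20)
        expr = synthetic.generate_expression(
            truth, gs, n_genes=400, effect=0.0, noise_sd=1.0, seed=8
        )
        labels = subtyping.classify_all(expr, gs)
        truth_labels = pd.Series(
            dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))
        )
        accuracy = (labels == truth_labels.reindex(labels.index)).mean()
        assert accuracy < 0.6  # chance is ~0.25 among 4 classes plus unclassified


class TestVariableGenesAndClustering:
    def test_constant_matrix_selects_first_by_id(self):
        expr = pd.DataFrame(
            np.ones((5, 4)), index=["g3", "g1", "g2", "g5", "g4"],
            columns=list("wxyz"),
        )
        assert subtyping.select_variable_genes(expr, 3) == ["g1", "g2", "g3"]

    def test_injected_variance_ranks_first(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 0.01, size=(20, 6)),
            index=[f"g{i}" for i in range(20)], columns=[f"s{i}" for i in range(6)],
        )
        expr.loc["g7"] = [0, 10, -10, 5, -5, 0]
        assert subtyping.select_variable_genes(expr, 1) == ["g7"]

    def test_matches_full_sort_oracle(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(50, 8)),
            index=[f"g{i:02d}" for i in range(50)],
            columns=[f"s{i}" for i in range(8)],
        )
        got = subtyping.select_variable_genes(expr, 10)
        var = expr.var(axis=1)
        expected = list(var.sort_values(ascending=False).index[:10])
        assert set(got) == set(expected)

    def test_invalid_n_rejected(self):
        expr = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError):
            subtyping.select_variable_genes(expr, 0)

    def test_separable_blobs_recovered(self, rng):
        a = rng.normal(0, 0.2, size=(30, 5))
        b = rng.normal(3, 0.2, size=(30, 5))
        expr = pd.DataFrame(
            np.hstack([a + rng.normal(0, 1, (30, 1)), b + rng.normal(0, 1, (30, 1))]),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(10)],
        )
        labels = subtyping.cluster_samples(expr, k=2)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_duplicate_sample_clusters_together(self, planted_expression):
        expr, _, _ = planted_expression
        dup = expr.copy()
        dup["dup_of_first"] = dup.iloc[:, 0]
        labels = subtyping.cluster_samples(dup, k=3)
        assert labels["dup_of_first"] == labels.iloc[0]

    def test_planted_subtypes_recovered_by_clustering(self, planted_expression):
        from sklearn.metrics import adjusted_rand_score

        expr, _, truth = planted_expression
        top = subtyping.select_variable_genes(expr, 300)
        labels = subtyping.cluster_samples(expr.loc[top], k=4)
        truth_labels = pd.Series(
            dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))
        ).reindex(labels.index)
        assert adjusted_rand_score(truth_labels, labels) >= 0.8

    def test_k_exceeding_samples_rejected(self, planted_expression):
        expr, _, _ = planted_expression
        with pytest.raises(ValueError):
            subtyping.cluster_samples(expr, k=expr.shape[1] + 1)


class TestEnrichment:
    def test_independent_margins_not_significant(self):
        table = pd.DataFrame([[20, 40], [10, 20]], index=["NEU", "other"],
                             columns=["NE", "CE"])
        res = subtyping.enrichment_test(table)
        assert res["chi2_p"] > 0.9

    def test_one_vs_rest_fisher_matches_enumeration(self):
        table = pd.DataFrame([[5, 0], [0, 5]], index=["a", "b"], columns=["x", "y"])
        res = subtyping.enrichment_test(table)
        # margins 5/5 over n=10: only X=5 and X=0 are as extreme; 2/C(10,5)
        assert res["fisher_p"][("a", "x")] == pytest.approx(2 / 252)
        ref = stats.fisher_exact([[5, 0], [0, 5]])[1]
        assert res["fisher_p"][("a", "x")] == pytest.approx(ref)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            subtyping.enrichment_test(pd.DataFrame([[0, 0], [0, 0]]))

    def test_planted_region_association_flagged(self, planted_expression):
        expr, gene_sets, truth = planted_expression
        labels = subtyping.classify_all(expr, gene_sets)
        regions = pd.Series(
            dict(zip(truth.samples["sample_id"], truth.samples["region"]))
        ).reindex(labels.index)
        res = subtyping.pairwise_subtype_tests(labels, regions)
        assert res["chi2_p"] < 0.05  # PPR planted into CE, NEU into NE


class TestDeconvolution:
    def _signatures(self, rng, n_genes=40):
        genes = [f"g{i}" for i in range(n_genes)]
        return pd.DataFrame(
            {
                "tumor": rng.uniform(1, 10, n_genes),
                "neuron": rng.uniform(1, 10, n_genes),
                "myeloid": rng.uniform(1, 10, n_genes),
            },
            index=genes,
        )

    def test_exact_mixture_recovered(self, rng):
        sig = self._signatures(rng)
        mix = 0.5 * sig["tumor"] + 0.5 * sig["neuron"]
        expr = pd.DataFrame({"s1": mix})
        out = subtyping.deconvolve_nnls(expr, sig, {"s1": 0.5})
        assert out.loc["s1", "raw_tumor"] == pytest.approx(0.5, abs=1e-8)
        assert out.loc["s1", "raw_neuron"] == pytest.approx(0.5, abs=1e-8)
        assert out.loc["s1", "raw_myeloid"] == pytest.approx(0.0, abs=1e-8)

    def test_purity_one_zeroes_non_tumor(self, rng):
        sig = self._signatures(rng)
        expr = pd.DataFrame({"s1": 0.7 * sig["tumor"] + 0.3 * sig["neuron"]})
        out = subtyping.deconvolve_nnls(expr, sig, {"s1": 1.0})
        assert out.loc["s1", "scaled_neuron"] == 0.0
        assert out.loc["s1", "scaled_myeloid"] == 0.0
        assert out.loc["s1", "scaled_tumor"] == pytest.approx(1.0)

    def test_noisy_mixture_rmse_below_5_percent(self):
        rng = np.random.default_rng(8)
        sig = self._signatures(rng, n_genes=60)
        true_fracs = rng.dirichlet([2, 2, 2], size=12)
        expr = pd.DataFrame(
            (sig.to_numpy() @ true_fracs.T) + rng.normal(0, 0.1, (60, 12)),
            index=sig.index,
            columns=[f"s{i}" for i in range(12)],
        )
        out = subtyping.deconvolve_nnls(
            expr, sig, {f"s{i}": 0.5 for i in range(12)}
        )
        got = out[["raw_tumor", "raw_neuron", "raw_myeloid"]].to_numpy()
        rmse = np.sqrt(np.mean((got - true_fracs) ** 2))
        assert rmse < 0.05

    def test_rank_deficient_signature_rejected(self, rng):
        sig = self._signatures(rng)
        sig["copy"] = sig["tumor"]
        with pytest.raises(ValueError, match="rank"):
            subtyping.deconvolve_nnls(pd.DataFrame({"s1": sig["tumor"]}), sig, {"s1": 0.5})


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("NEU\tdesc\tGAD2\tSYP\nGPM\tdesc\tHK2\tLDHA\tVEGFA\n")
    sets = subtyping.read_gmt(path)
    assert sets == {"NEU": ["GAD2", "SYP"], "GPM": ["HK2", "LDHA", "VEGFA"]}
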