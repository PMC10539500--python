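"""Single-sample pathway-based subtype classification of expression profiles.

The classifier scores one sample at a time against a gene set with the
Mann-Whitney U statistic: NES = U / (n_in * n_out) is the probability that a
random in-set gene outranks a random out-set gene in that sample's expression
ranking (0.5 = no enrichment). A sample is assigned the subtype (GPM, MTC,
NEU or PPR) with the highest significant score, requiring logit(NES) > 0.40
and p < 0.05; otherwise it is unclassified. Being rank-based, scores are
invariant to any strictly increasing transform of expression.

The module also provides top-variable-gene selection, hierarchical clustering
of samples on correlation distance, subtype-by-region enrichment tests, and a
simplified purity-scaled non-negative least squares deconvolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .clonality import _fisher_2x2_two_sided

SUBTYPE_ORDER = ("GPM", "MTC", "NEU", "PPR")
LOGIT_NES_CUTOFF = 0.40
P_CUTOFF = 0.05


@dataclass(frozen=True)
class SubtypeScore:
    sample_id: str
    gene_set: str
    nes: float
    logit_nes: float
    p_value: float


def mww_gst(
    expression: pd.Series,
    gene_set: list[str] | set[str],
    set_name: str = "",
    exact_max_pairs: int = 10_000,
) -> SubtypeScore:
    """Mann-Whitney gene-set test of one sample's expression column.

    U counts in-set/out-set gene pairs where the in-set gene is higher
    (ties count 0.5); NES = U/(n_in*n_out). The two-sided p uses the exact U
    distribution when n_in*n_out <= ``exact_max_pairs`` and there are no
    ties, and the tie-corrected normal approximation with continuity
    correction otherwise.
    """
    gene_set = set(gene_set)
    in_mask = expression.index.isin(gene_set)
    n_in = int(in_mask.sum())
    n_out = int(len(expression) - n_in)
    if n_in < 2 or n_out < 2:
        raise ValueError("need >= 2 genes inside and outside the set")
    values = expression.to_numpy(float)
    ranks = stats.rankdata(values)
    u = float(ranks[in_mask].sum() - n_in * (n_in + 1) / 2.0)
    nes = u / (n_in * n_out)
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (n_in * n_out <= exact_max_pairs and not has_ties) else "asymptotic"
    p = float(
        stats.mannwhitneyu(
            values[in_mask], values[~in_mask], alternative="two-sided", method=method
        ).pvalue
    )
    eps = 1e-12
    logit = math.log((nes + eps) / (1 - nes + eps))
    return SubtypeScore(str(expression.name), set_name, nes, logit, p)


def score_samples(
    expression: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """mww-GST scores for every sample x gene set (genes x samples input)."""
    rows = []
    for sid in expression.columns:
        col = expression[sid]
        for name, gs in gene_sets.items():
            s = mww_gst(col, gs, set_name=name)
            rows.append(
                {
                    "sample_id": sid,
                    "gene_set": name,
                    "nes": s.nes,
                    "logit_nes": s.logit_nes,
                    "p_value": s.p_value,
                }
            )
    return pd.DataFrame(rows)


def classify_sample(scores: list[SubtypeScore] | pd.DataFrame) -> str:
    """Highest significant score wins: logit(NES) > 0.40 and p < 0.05.

    Exact logit ties break toward the lower p, then toward the fixed subtype
    order GPM < MTC < NEU < PPR. Returns 'unclassified' when nothing passes.
    """
    if isinstance(scores, pd.DataFrame):
        recs = scores.to_dict(orient="records")
        cand = [
            (r["gene_set"], r["logit_nes"], r["p_value"])
            for r in recs
            if r["logit_nes"] > LOGIT_NES_CUTOFF and r["p_value"] < P_CUTOFF
        ]
    else:
        cand = [
            (s.gene_set, s.logit_nes, s.p_value)
            for s in scores
            if s.logit_nes > LOGIT_NES_CUTOFF and s.p_value < P_CUTOFF
        ]
    if not cand:
        return "unclassified"
    order = {name: i for i, name in enumerate(SUBTYPE_ORDER)}
    cand.sort(key=lambda c: (-c[1], c[2], order.get(c[0], len(order))))
    return cand[0][0]


def classify_all(
    expression: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> pd.Series:
    """Per-sample subtype labels from expression and the four gene sets."""
    scores = score_samples(expression, gene_sets)
    labels = {
        sid: classify_sample(grp) for sid, grp in scores.groupby("sample_id")
    }
    return pd.Series(labels, name="subtype").reindex(expression.columns)


def select_variable_genes(expression: pd.DataFrame, n: int) -> list[str]:
    """Top-n genes by variance of log expression; ties broken by gene id."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(expression):
        raise ValueError("n exceeds gene count")
    var = expression.var(axis=1, ddof=1)
    order = sorted(expression.index, key=lambda g: (-var[g], g))
    return order[:n]


def cluster_samples(
    expression: pd.DataFrame, k: int = 2, method: str = "ward"
) -> pd.Series:
    """Agglomerative clustering of samples on 1 - Pearson correlation.

    Operates on the (already gene-filtered) genes x samples matrix; Ward
    linkage by default, cut at ``k`` clusters. Labels are 1..k in linkage
    order; identity is meaningful only up to permutation.
    """
    n_samples = expression.shape[1]
    if k > n_samples:
        raise ValueError("k exceeds number of samples")
    corr = np.corrcoef(expression.to_numpy(float).T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=expression.columns, name="cluster")


def enrichment_test(contingency: pd.DataFrame) -> dict:
    """Association between two label sets (e.g. subtype x region).

    Omnibus chi-squared p on the full contingency table plus, per cell, a
    one-vs-rest 2x2 Fisher exact p (is this row label enriched in this
    column?).
    """
    table = contingency.to_numpy(int)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    chi2, chi2_p, dof, _ = stats.chi2_contingency(table[np.ix_(keep_r, keep_c)])
    fisher = {}
    n = table.sum()
    for i, row_lab in enumerate(contingency.index):
        for j, col_lab in enumerate(contingency.columns):
            a = table[i, j]
            b = table[i].sum() - a
            c = table[:, j].sum() - a
            d = n - a - b - c
            fisher[(row_lab, col_lab)] = _fisher_2x2_two_sided(
                np.array([[a, b], [c, d]])
            )
    return {
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "dof": int(dof),
        "fisher_p": fisher,
    }


def deconvolve_nnls(
    expression: pd.DataFrame,
    signatures: pd.DataFrame,
    purity: dict[str, float] | pd.Series,
    tumor_types: list[str] | None = None,
) -> pd.DataFrame:
    """Purity-scaled non-negative least squares cell-fraction estimates.

    Each sample's expression over the signature genes is decomposed as a
    non-negative combination of cell-type profiles, renormalized to sum to 1;
    then the tumor cell types' total share is fixed to the WES-derived purity
    and the non-tumor shares are rescaled to (1 - purity). ``tumor_types``
    defaults to signature columns whose name starts with 'tumor'.
    """
    missing = signatures.index.difference(expression.index)
    if len(missing):
        raise ValueError(f"signature genes absent from matrix: {list(missing)[:3]}")
    sig = signatures.to_numpy(float)
    if np.linalg.matrix_rank(sig) < sig.shape[1]:
        raise ValueError("signature matrix is rank deficient")
    if tumor_types is None:
        tumor_types = [c for c in signatures.columns if str(c).lower().startswith("tumor")]
    expr = expression.loc[signatures.index]
    out = {}
    for sid in expr.columns:
        f, _ = optimize.nnls(sig, expr[sid].to_numpy(float))
        total = f.sum()
        if total > 0:
            f = f / total
        frac = pd.Series(f, index=signatures.columns)
        pur = float(pd.Series(purity)[sid])
        is_tumor = frac.index.isin(tumor_types)
        t_share = frac[is_tumor].sum()
        nt_share = frac[~is_tumor].sum()
        scaled = frac.copy()
        scaled[is_tumor] = (
            frac[is_tumor] * (pur / t_share) if t_share > 0 else pur / max(is_tumor.sum(), 1)
        )
        scaled[~is_tumor] = (
            frac[~is_tumor] * ((1 - pur) / nt_share) if nt_share > 0 else 0.0
        )
        out[sid] = pd.concat([frac.add_prefix("raw_"), scaled.add_prefix("scaled_")])
    return pd.DataFrame(out).T


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def pairwise_subtype_tests(labels_a: pd.Series, labels_b: pd.Series) -> dict:
    """Convenience: cross-tabulate two label series and run enrichment_test."""
    table = pd.crosstab(labels_a, labels_b)
    return {"table": table, **enrichment_test(table)}


__all__ = [
    "SubtypeScore",
    "mww_gst",
    "score_samples",
    "classify_sample",
    "classify_all",
    "select_variable_genes",
    "cluster_samples",
    "enrichment_test",
    "deconvolve_nnls",
    "read_gmt",
    "pairwise_subtype_tests",
    "SUBTYPE_ORDER",
    "LOGIT_NES_CUTOFF",
    "P_CUTOFF",
]
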