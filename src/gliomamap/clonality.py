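"""Truncal/shared/private classification of multiregional somatic alterations.

A variant observed across a patient's spatially distinct biopsies is labeled
*truncal* when it occurs in every sample, *shared* when it occurs in two or
more but not all samples, and *private* when it occurs in exactly one.
Because single callers miss low-VAF variants, carrier sets are first augmented
by a pileup-based rescue step: at every mutant position, samples originally
called wild type are re-examined for mutant reads and rescued when the
evidence clears configurable thresholds. Region composition (percent
truncal/shared/private, cohort-, patient- or region-wise), gene-pair mutual
exclusivity with an exact Fisher test, and an exact/approximate test for
CE-vs-NE composition differences complete the module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LABELS = ("truncal", "shared", "private")


@dataclass(frozen=True)
class ClonalityAnnotation:
    patient_id: str
    variant_key: str
    label: str  # truncal | shared | private
    carrier_samples: frozenset[str]
    rescued_in: frozenset[str]


def rescue_calls(
    calls: pd.DataFrame,
    pileups: pd.DataFrame,
    min_alt: int = 2,
    min_vaf: float = 0.01,
) -> pd.DataFrame:
    """Recover false-negative calls from pileup evidence.

    For each patient and each variant key, every sample of that patient that
    lacks the call is re-examined in the pileup table; a rescued call is added
    iff alt reads >= ``min_alt`` and alt/depth >= ``min_vaf``. Original calls
    are never removed; rescued rows carry ``rescued=True``. Missing pileup
    rows are logged and skipped.
    """
    calls = calls.copy()
    if "rescued" not in calls.columns:
        calls["rescued"] = False
    pile = pileups.set_index(["patient_id", "sample_id", "variant_key"])
    patient_samples = (
        pd.concat([calls[["patient_id", "sample_id"]], pileups[["patient_id", "sample_id"]]])
        .drop_duplicates()
        .groupby("patient_id")["sample_id"]
        .apply(list)
    )
    new_rows = []
    for (pid, key), grp in calls.groupby(["patient_id", "variant_key"]):
        have = set(grp["sample_id"])
        template = grp.iloc[0]
        for sid in patient_samples.get(pid, []):
            if sid in have:
                continue
            try:
                row = pile.loc[(pid, sid, key)]
            except KeyError:
                logger.warning(
                    "no pileup for patient=%s sample=%s variant=%s; cannot rescue",
                    pid, sid, key,
                )
                continue
            alt, depth = int(row["alt_reads"]), int(row["depth"])
            if alt >= min_alt and depth > 0 and alt / depth >= min_vaf:
                new = template.to_dict()
                new.update(
                    sample_id=sid,
                    alt_reads=alt,
                    depth=depth,
                    vaf=alt / depth,
                    rescued=True,
                )
                new_rows.append(new)
    if new_rows:
        calls = pd.concat([calls, pd.DataFrame(new_rows)], ignore_index=True)
    return calls


def classify_sharing(calls: pd.DataFrame) -> list[ClonalityAnnotation]:
    """Label every variant of every multi-sample patient by carrier cardinality.

    Patients with a single sample are excluded (their variants are
    unclassifiable: the private and truncal definitions collide at n=1) and
    reported via a warning.
    """
    annotations = []
    for pid, grp in calls.groupby("patient_id"):
        samples = set(grp["sample_id"])
        if len(samples) < 2:
            logger.warning("patient %s has one sample; variants unclassifiable", pid)
            continue
        rescued_col = grp["rescued"] if "rescued" in grp.columns else pd.Series(
            False, index=grp.index
        )
        for key, vgrp in grp.groupby("variant_key"):
            carriers = frozenset(vgrp["sample_id"])
            rescued = frozenset(vgrp.loc[rescued_col.loc[vgrp.index], "sample_id"])
            if len(carriers) == 1:
                label = "private"
            elif carriers == frozenset(samples):
                label = "truncal"
            else:
                label = "shared"
            annotations.append(
                ClonalityAnnotation(pid, key, label, carriers, rescued)
            )
    return annotations


def composition(
    annotations: list[ClonalityAnnotation],
    sample_regions: dict[str, str] | None = None,
    scope: str = "cohort",
) -> pd.DataFrame:
    """Percent truncal/shared/private per cohort, patient, or region.

    Region scope counts each (variant, region) occurrence where at least one
    carrier sample lies in that region (a shared or truncal variant spanning
    both regions contributes once to each), with percentages relative to the
    region's occurrence total.
    """
    if not annotations:
        return pd.DataFrame(
            columns=["unit", "n", "percent_truncal", "percent_shared", "percent_private"]
        )

    def _row(unit: str, labels: list[str]) -> dict:
        n = len(labels)
        return {
            "unit": unit,
            "n": n,
            **{
                f"percent_{lab}": 100.0 * sum(l == lab for l in labels) / n
                for lab in LABELS
            },
        }

    if scope == "cohort":
        return pd.DataFrame([_row("cohort", [a.label for a in annotations])])
    if scope == "per-patient":
        rows = []
        for pid in sorted({a.patient_id for a in annotations}):
            rows.append(_row(pid, [a.label for a in annotations if a.patient_id == pid]))
        return pd.DataFrame(rows)
    if scope == "per-region":
        if sample_regions is None:
            raise ValueError("per-region composition needs sample region labels")
        rows = []
        for region in sorted(set(sample_regions.values())):
            labels = [
                a.label
                for a in annotations
                if any(sample_regions.get(s) == region for s in a.carrier_samples)
            ]
            if labels:
                rows.append(_row(region, labels))
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scope {scope!r}")


def _fisher_2x2_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of all 2x2 tables with the observed margins whose
    point probability does not exceed that of the observed table (within a
    small relative tolerance for float ties).
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def logp(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lp_obs = logp(a)
    p = sum(
        math.exp(lp) for x in range(lo, hi + 1) if (lp := logp(x)) <= lp_obs + 1e-9
    )
    return min(1.0, p)


def mutual_exclusivity(
    altered_a: pd.Series | np.ndarray | list,
    altered_b: pd.Series | np.ndarray | list,
) -> dict:
    """Mutual exclusivity of two genes' alterations across samples.

    ``n_altered`` counts samples with at least one of the genes altered;
    ``n_exclusive`` those with exactly one. The two-sided Fisher exact p is
    computed on the 2x2 (gene A altered x gene B altered over all samples) by
    hypergeometric enumeration. Returns fraction=None when nothing is altered.
    """
    a = np.asarray(altered_a, dtype=bool)
    b = np.asarray(altered_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must align")
    n_altered = int(np.sum(a | b))
    n_exclusive = int(np.sum(a ^ b))
    table = np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )
    if n_altered == 0:
        return {
            "n_exclusive": 0,
            "n_altered": 0,
            "fraction": None,
            "fisher_p_two_sided": 1.0,
        }
    return {
        "n_exclusive": n_exclusive,
        "n_altered": n_altered,
        "fraction": 100.0 * n_exclusive / n_altered,
        "fisher_p_two_sided": _fisher_2x2_two_sided(table),
    }


def _enumerate_rxc_exact(table: np.ndarray) -> float:
    """Exact conditional p for a 2x3 table by enumeration over fixed margins."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())

    def log_multinom(counts: np.ndarray) -> float:
        # log probability of a table under the hypergeometric (fixed margins)
        num = sum(math.lgamma(r + 1) for r in row) + sum(
            math.lgamma(c + 1) for c in col
        )
        den = math.lgamma(n + 1) + sum(
            math.lgamma(int(x) + 1) for x in counts.ravel()
        )
        return num - den

    lp_obs = log_multinom(table)
    p = 0.0
    r0 = int(row[0])
    for x in range(0, min(r0, int(col[0])) + 1):
        for y in range(0, min(r0 - x, int(col[1])) + 1):
            z = r0 - x - y
            if z > col[2]:
                continue
            cand = np.array(
                [[x, y, z], [col[0] - x, col[1] - y, col[2] - z]]
            )
            if (cand < 0).any():
                continue
            lp = log_multinom(cand)
            if lp <= lp_obs + 1e-9:
                p += math.exp(lp)
    return min(1.0, p)


def composition_test(
    ce_counts: tuple[int, int, int] | list[int],
    ne_counts: tuple[int, int, int] | list[int],
    exact_max_n: int = 500,
) -> dict:
    """CE vs NE difference in (truncal, shared, private) composition.

    Exact conditional test by full enumeration of 2x3 tables when the grand
    total is <= ``exact_max_n``; chi-squared approximation otherwise. The
    method used is reported in the result.
    """
    table = np.array([list(ce_counts), list(ne_counts)], dtype=int)
    if table.shape != (2, 3):
        raise ValueError("expected 2x3 counts (region x truncal/shared/private)")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or table.sum() == 0:
        raise ValueError("each region needs at least one classified variant")
    n = int(table.sum())
    if n <= exact_max_n:
        return {"p_value": _enumerate_rxc_exact(table), "method": "exact"}
    # drop empty columns so the chi-squared statistic is well defined
    keep = table.sum(axis=0) > 0
    chi2, p, _, _ = stats.chi2_contingency(table[:, keep])
    return {"p_value": float(p), "method": "chi2", "statistic": float(chi2)}


def annotations_frame(annotations: list[ClonalityAnnotation]) -> pd.DataFrame:
    """Tabular view (clonality.tsv dialect) of a set of annotations."""
    return pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in annotations],
            "variant_key": [a.variant_key for a in annotations],
            "label": [a.label for a in annotations],
            "carrier_samples": [",".join(sorted(a.carrier_samples)) for a in annotations],
            "rescued_in": [",".join(sorted(a.rescued_in)) for a in annotations],
        }
    )
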