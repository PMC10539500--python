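"""Within-patient genetic versus spatial distance analysis.

Each pair of biopsies from the same patient is related by (i) the Euclidean
distance between their stereotactic MRI coordinates,
d(p,q) = sqrt(sum_i (p_i - q_i)^2), in millimetres, and (ii) the genetic
distance 1 - Jaccard index over their somatic alteration patterns (SNVs,
indels and gene-level CNV states share one key space). Pairs are stratified
by region (CE-CE, NE-NE, CE-NE) and by subtype; correlations between the two
distances come with a parametric Pearson p and an optional within-patient
permutation p that respects the non-independence of pairs sharing a sample.
"""

from __future__ import annotations

import logging
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def euclidean_distance(p, q) -> float:
    """Straight-line distance in mm between two 3-D biopsy coordinates."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("coordinates must be 3-vectors")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def genetic_distance(a: set, b: set) -> float:
    """1 - Jaccard index of two alteration-key sets.

    Two empty sets are defined as maximally similar (distance 0, with a
    warning): the Jaccard index is 0/0 there and convention is required.
    """
    a, b = set(a), set(b)
    if not a and not b:
        logger.warning("both alteration sets empty; genetic distance defined as 0")
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def _pair_region(r1: str, r2: str) -> str:
    if "unlabeled" in (r1, r2):
        return "unlabeled"
    return "CE-CE" if r1 == r2 == "CE" else ("NE-NE" if r1 == r2 == "NE" else "CE-NE")


def build_pair_table(
    samples: pd.DataFrame,
    variant_sets: dict[str, set],
    subtypes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All unordered within-patient sample pairs with both distances.

    ``samples`` needs sample_id, patient_id, region, x_mm, y_mm, z_mm.
    Cross-patient pairs are never emitted; single-sample patients contribute
    none. ``pair_subtype`` is 'X-X' for like-labeled pairs and 'mixed'
    otherwise.
    """
    subtypes = subtypes or {}
    rows = []
    for pid, grp in samples.groupby("patient_id"):
        recs = grp.to_dict(orient="records")
        for s1, s2 in combinations(recs, 2):
            id1, id2 = sorted([s1["sample_id"], s2["sample_id"]])
            if s1["sample_id"] != id1:
                s1, s2 = s2, s1
            st1, st2 = subtypes.get(id1), subtypes.get(id2)
            if st1 and st2:
                pair_subtype = f"{st1}-{st2}" if st1 == st2 else "mixed"
            else:
                pair_subtype = "unknown"
            rows.append(
                {
                    "patient_id": pid,
                    "sample_1": id1,
                    "sample_2": id2,
                    "euclid_mm": euclidean_distance(
                        (s1["x_mm"], s1["y_mm"], s1["z_mm"]),
                        (s2["x_mm"], s2["y_mm"], s2["z_mm"]),
                    ),
                    "genetic_dist": genetic_distance(
                        variant_sets.get(id1, set()), variant_sets.get(id2, set())
                    ),
                    "region_1": s1.get("region", "unlabeled"),
                    "region_2": s2.get("region", "unlabeled"),
                    "pair_region": _pair_region(
                        s1.get("region", "unlabeled"), s2.get("region", "unlabeled")
                    ),
                    "pair_subtype": pair_subtype,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sample_1", "sample_2", "euclid_mm", "genetic_dist",
            "region_1", "region_2", "pair_region", "pair_subtype",
        ],
    )


def correlate_distances(
    pairs: pd.DataFrame,
    stratum: str | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Pearson correlation between Euclidean and genetic distance.

    ``stratum`` filters on pair_region (e.g. 'CE-CE'). The permutation p
    shuffles genetic distances among pairs *within each patient* (pairs
    sharing a sample are not independent, so the parametric p is optimistic);
    when the total number of distinct within-patient permutations is small
    the enumeration is exhaustive, otherwise ``n_permutations`` Monte-Carlo
    shuffles are drawn.
    """
    sub = pairs if stratum is None else pairs[pairs["pair_region"] == stratum]
    if len(sub) < 3:
        raise ValueError("need at least 3 pairs after stratification")
    x = sub["euclid_mm"].to_numpy(float)
    y = sub["genetic_dist"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance vector; correlation undefined")
    r, p_param = stats.pearsonr(x, y)
    out = {
        "stratum": stratum or "all",
        "n_pairs": int(len(sub)),
        "pearson_r": float(r),
        "p_param": float(p_param),
    }
    if n_permutations > 0:
        groups = [np.flatnonzero(sub["patient_id"].to_numpy() == pid)
                  for pid in sub["patient_id"].unique()]
        log_total = sum(np.sum(np.log(np.arange(1, len(g) + 1))) for g in groups)
        if log_total <= np.log(n_permutations):
            # exhaustive enumeration of within-patient shuffles
            perms_per_group = [list(permutations(range(len(g)))) for g in groups]
            count = total = 0
            idx = [0] * len(groups)
            while True:
                yp = y.copy()
                for g, pg, k in zip(groups, perms_per_group, idx):
                    yp[g] = y[g][list(pg[k])]
                rp, _ = stats.pearsonr(x, yp)
                count += abs(rp) >= abs(r) - 1e-12
                total += 1
                for d in range(len(idx) - 1, -1, -1):
                    idx[d] += 1
                    if idx[d] < len(perms_per_group[d]):
                        break
                    idx[d] = 0
                else:
                    break
            out["p_perm"] = count / total
            out["perm_method"] = "exhaustive"
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                yp = y.copy()
                for g in groups:
                    yp[g] = y[g][rng.permutation(len(g))]
                rp, _ = stats.pearsonr(x, yp)
                count += abs(rp) >= abs(r) - 1e-12
            out["p_perm"] = (count + 1) / (n_permutations + 1)
            out["perm_method"] = "monte-carlo"
    return out


def ce_to_ne_subtype_distance(
    pairs: pd.DataFrame,
    ne_subtypes: dict[str, str],
    metric: str = "genetic_dist",
    min_pairs: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance of CE samples to NE samples, grouped by the NE member's subtype.

    Restricted to CE-NE pairs whose NE member has a known subtype. Returns a
    per-subtype summary table and all pairwise two-sided Mann-Whitney tests
    between subtype groups (skipped for groups below ``min_pairs``, with a
    warning). ``metric`` may also be 'euclid_mm'.
    """
    sub = pairs[pairs["pair_region"] == "CE-NE"]
    groups: dict[str, list[float]] = {}
    for rec in sub.to_dict(orient="records"):
        ne_sample = rec["sample_1"] if rec["region_1"] == "NE" else rec["sample_2"]
        st = ne_subtypes.get(ne_sample)
        if st is not None:
            groups.setdefault(st, []).append(rec[metric])
    kept = {}
    for st, vals in sorted(groups.items()):
        if len(vals) < min_pairs:
            logger.warning("subtype %s has %d pair(s); excluded", st, len(vals))
            continue
        kept[st] = np.asarray(vals, float)
    summary = pd.DataFrame(
        {
            "ne_subtype": list(kept),
            "n_pairs": [len(v) for v in kept.values()],
            "mean": [float(v.mean()) for v in kept.values()],
            "median": [float(np.median(v)) for v in kept.values()],
        }
    )
    tests = []
    for s1, s2 in combinations(sorted(kept), 2):
        u, p = stats.mannwhitneyu(kept[s1], kept[s2], alternative="two-sided")
        tests.append({"group_1": s1, "group_2": s2, "U": float(u), "p_value": float(p)})
    return summary, pd.DataFrame(tests, columns=["group_1", "group_2", "U", "p_value"])
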