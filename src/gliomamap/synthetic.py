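"""Synthetic multiregional cohort generator with ground-truth manifests.

Emulates the data shapes of a multiregional high-grade glioma study: a clone
tree whose branches carry somatic variants (truncal pool on the root branch,
shared on internal branches, private on leaf branches), biopsy samples placed
on root-to-leaf lineages with region labels (CE = contrast-enhancing,
NE = non-enhancing), binomial read sampling with a detection threshold that
creates recoverable false-negative calls, subtype-signature-planted expression,
and gamma-variate DSC-MRI bolus curves with a Boxerman leakage term.

Every random draw is controlled by one master seed; each generator stage uses
its own stream spawned from it, so stages are individually reproducible.
Everything generated is recorded in a :class:`CohortTruth` manifest that
downstream recovery tests consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SUBTYPES = ("GPM", "MTC", "NEU", "PPR")
_BASES = "ACGT"

# stage offsets mixed into the master seed: one independent stream per stage
_STREAM_TREE = 1
_STREAM_VARIANTS = 2
_STREAM_EXPRESSION = 3
_STREAM_DSC = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------


@dataclass
class CloneTree:
    """Rooted clone tree; each node's incoming branch carries variant keys.

    ``parent[root] is None``. ``branch_mutations[node]`` lists the variant
    keys acquired on the branch from ``parent[node]`` to ``node``; the root's
    entry is the truncal pool carried by every clone.
    """

    parent: dict[int, int | None]
    branch_mutations: dict[int, list[str]]
    root: int = 0

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    def children(self, node: int) -> list[int]:
        return [c for c, p in self.parent.items() if p == node]

    def descendants(self, node: int) -> set[int]:
        """Node and everything below it (clones carrying this branch's variants)."""
        out, stack = set(), [node]
        while stack:
            v = stack.pop()
            if v not in out:
                out.add(v)
                stack.extend(self.children(v))
        return out

    def leaves(self) -> list[int]:
        return sorted(n for n in self.parent if not self.children(n))

    def path_to_root(self, node: int) -> list[int]:
        """Lineage from root down to ``node`` (inclusive)."""
        path = []
        v: int | None = node
        while v is not None:
            path.append(v)
            v = self.parent[v]
        return path[::-1]

    def all_variants(self) -> list[str]:
        out: list[str] = []
        for n in sorted(self.branch_mutations):
            out.extend(self.branch_mutations[n])
        return out

    def validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise ValueError("tree must have exactly one root")
        if self.descendants(self.root) != set(self.parent):
            raise ValueError("tree must be connected")
        seen: set[str] = set()
        for keys in self.branch_mutations.values():
            dup = seen.intersection(keys)
            if dup:
                raise ValueError(f"variant keys on multiple branches: {sorted(dup)[:3]}")
            seen.update(keys)
        if not self.branch_mutations.get(self.root):
            raise ValueError("root branch (truncal pool) must be non-empty")


def _make_variant_keys(n: int, prefix: str, rng: np.random.Generator) -> list[str]:
    keys = []
    for i in range(n):
        gene = f"{prefix}{i:04d}"
        chrom = int(rng.integers(1, 23))
        pos = int(rng.integers(1, 2_000_000))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        keys.append(f"{gene}:{chrom}:{pos}:{ref}:{alt}")
    return keys


def generate_clone_tree(
    n_clones: int,
    n_truncal: int,
    n_per_branch: int = 1,
    seed: int = 0,
) -> CloneTree:
    """Random clone-tree topology with variant keys on each branch.

    The root branch carries ``n_truncal`` keys (truncal pool); each of the
    ``n_clones - 1`` non-root branches carries ``n_per_branch`` keys.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_truncal < 0 or n_per_branch < 0:
        raise ValueError("variant counts must be >= 0")
    if n_truncal == 0:
        raise ValueError("root branch must carry at least one truncal variant")
    rng = _rng(seed, _STREAM_TREE)
    parent: dict[int, int | None] = {0: None}
    for i in range(1, n_clones):
        parent[i] = int(rng.integers(0, i))
    branch_mutations = {0: _make_variant_keys(n_truncal, "TRK", rng)}
    for i in range(1, n_clones):
        branch_mutations[i] = _make_variant_keys(n_per_branch, f"B{i:02d}G", rng)
    tree = CloneTree(parent=parent, branch_mutations=branch_mutations)
    tree.validate()
    return tree


def planted_composition_tree(
    n_samples: int,
    n_truncal: int,
    n_shared: int,
    n_private: int,
    regions: list[str],
    ne_private_weight: float = 3.0,
    seed: int = 0,
    key_prefix: str = "",
) -> tuple[CloneTree, dict[int, int]]:
    """Clone tree whose realized truncal/shared/private counts are exact.

    Builds a random binary merge tree over ``n_samples`` leaf clones, one
    biopsy per leaf. The root branch gets ``n_truncal`` keys, internal
    (non-root) branches share ``n_shared`` keys round-robin, and leaf branches
    receive ``n_private`` keys with NE leaves weighted ``ne_private_weight``-
    fold over CE leaves, so the planted private burden is higher in the NE.

    Returns the tree and a map sample index -> leaf clone id.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if n_shared > 0 and n_samples < 3:
        raise ValueError("shared branches need >= 3 samples")
    if len(regions) != n_samples:
        raise ValueError("one region label per sample")
    rng = _rng(seed, _STREAM_TREE)

    # random binary merges: leaves 1..n_samples, internal nodes appended after
    next_id = n_samples + 1
    parent: dict[int, int | None] = {i: None for i in range(1, n_samples + 1)}
    active = list(range(1, n_samples + 1))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_id
        parent[next_id] = None
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    top = active[0]
    # re-root: node 0 is the ancestral clone above the last merge
    parent[top] = 0
    parent[0] = None

    branch_mutations: dict[int, list[str]] = {n: [] for n in parent}
    branch_mutations[0] = _make_variant_keys(n_truncal, key_prefix + "TRK", rng)

    # the top merge node covers every leaf, so its branch would be truncal;
    # shared candidates are the internal nodes strictly below it
    internal = sorted(n for n in parent if n > n_samples and n != top)
    if n_shared > 0 and not internal:
        raise ValueError("no internal branch available for shared variants")
    shared_keys = _make_variant_keys(n_shared, key_prefix + "SHR", rng)
    for k, key in enumerate(shared_keys):
        branch_mutations[internal[k % len(internal)]].append(key)

    leaves = list(range(1, n_samples + 1))
    weights = np.array(
        [ne_private_weight if regions[i] == "NE" else 1.0 for i in range(n_samples)]
    )
    # largest-remainder allocation of private counts to leaves
    quota = n_private * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = n_private - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    private_keys = _make_variant_keys(n_private, key_prefix + "PRV", rng)
    pos = 0
    for i, leaf in enumerate(leaves):
        branch_mutations[leaf].extend(private_keys[pos : pos + counts[i]])
        pos += counts[i]

    tree = CloneTree(parent=parent, branch_mutations=branch_mutations)
    tree.validate()
    sample_leaf = {i: leaves[i] for i in range(n_samples)}
    return tree, sample_leaf


# ---------------------------------------------------------------------------
# cohort truth manifest
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Ground-truth manifest for one synthetic patient cohort.

    ``expected_vaf`` is samples x variants; a sample truly carries a variant
    iff its expected VAF is > 0. Expected VAF = purity x lineage fraction x
    0.5 (diploid heterozygous), hence always in [0, 0.5].
    """

    samples: pd.DataFrame  # sample_id, patient_id, region, x/y/z_mm, purity, subtype
    variant_keys: list[str]
    expected_vaf: pd.DataFrame  # index sample_id, columns variant_keys
    clone_fractions: pd.DataFrame  # index sample_id, columns clone ids (str)
    true_labels: dict[str, str]  # variant key -> truncal|shared|private (per patient space)
    roi_params: pd.DataFrame = field(default_factory=pd.DataFrame)  # K1, K2 per roi
    bolus: dict = field(default_factory=dict)
    seed: int = 0

    def carriers(self, key: str) -> set[str]:
        col = self.expected_vaf[key]
        return set(col.index[col > 0])

    def planted_composition(self) -> dict[str, float]:
        """Percent truncal/shared/private among all planted variants."""
        n = len(self.variant_keys)
        counts = {"truncal": 0, "shared": 0, "private": 0}
        for k in self.variant_keys:
            counts[self.true_labels[k]] += 1
        return {k: 100.0 * v / n for k, v in counts.items()}

    def private_fraction_by_region(self) -> dict[str, float]:
        """Planted percent-private among variants occurring in each region."""
        region_of = dict(zip(self.samples["sample_id"], self.samples["region"]))
        out = {}
        for region in ("CE", "NE"):
            tot = priv = 0
            for k in self.variant_keys:
                carr = self.carriers(k)
                if any(region_of[s] == region for s in carr):
                    tot += 1
                    priv += self.true_labels[k] == "private"
            out[region] = 100.0 * priv / tot if tot else float("nan")
        return out

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "samples": self.samples.to_dict(orient="records"),
            "variant_keys": self.variant_keys,
            "true_labels": self.true_labels,
            "expected_vaf": {
                s: self.expected_vaf.loc[s].to_dict() for s in self.expected_vaf.index
            },
            "clone_fractions": {
                s: self.clone_fractions.loc[s].to_dict() for s in self.clone_fractions.index
            },
            "roi_params": self.roi_params.to_dict(orient="records"),
            "bolus": self.bolus,
        }


# ---------------------------------------------------------------------------
# variants + pileups
# ---------------------------------------------------------------------------


def generate_variant_samples(
    tree: CloneTree,
    n_samples: int,
    region_fractions: dict[str, float] | None = None,
    depth: int | None = 500,
    detect_min_alt: int = 3,
    seed: int = 0,
    *,
    patient_id: str = "P01",
    sample_leaf: dict[int, int] | None = None,
    regions: list[str] | None = None,
    purity_range: tuple[float, float] = (0.45, 0.85),
    lineage_bias: float = 2.0,
    subtype_probs: dict[str, list[float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Draw biopsy samples from a clone tree and sequence them binomially.

    Each sample sits on a root-to-leaf lineage; its clone fractions are
    Dirichlet draws biased toward ancestral clones for CE samples and toward
    leaf clones for NE samples (strength ``lineage_bias``), reproducing the
    higher private burden of non-enhancing tumor. Alt reads are
    binomial(depth, expected VAF); a variant is CALLED only when alt reads
    >= ``detect_min_alt``, creating false negatives the pileup table can
    rescue. ``depth=None`` means noiseless sequencing at a nominal depth of
    1e6 (the infinite-depth limit).

    Returns (called-variants table, pileup table, truth manifest).
    """
    if not tree.parent:
        raise ValueError("empty clone tree")
    if depth is not None and depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed, _STREAM_VARIANTS)

    if regions is None:
        region_fractions = region_fractions or {"CE": 0.5, "NE": 0.5}
        if abs(sum(region_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("region_fractions must sum to 1")
        n_ce = int(round(n_samples * region_fractions.get("CE", 0.0)))
        regions = ["CE"] * n_ce + ["NE"] * (n_samples - n_ce)
    leaves = tree.leaves()
    if sample_leaf is None:
        sample_leaf = {i: leaves[i % len(leaves)] for i in range(n_samples)}

    sample_ids = [f"{patient_id}_S{i:02d}" for i in range(n_samples)]
    purity = rng.uniform(*purity_range, size=n_samples)
    keys = tree.all_variants()
    variants_rows, pileup_rows = [], []
    evaf = pd.DataFrame(0.0, index=sample_ids, columns=keys)
    all_clones = [str(c) for c in tree.nodes]
    cfrac = pd.DataFrame(0.0, index=sample_ids, columns=all_clones)

    nominal_depth = 1_000_000 if depth is None else depth
    for i, sid in enumerate(sample_ids):
        path = tree.path_to_root(sample_leaf[i])
        depth_rank = np.arange(len(path), dtype=float)
        if regions[i] == "CE":  # ancestral-biased
            alpha = lineage_bias ** (depth_rank[::-1])
        else:  # leaf-biased
            alpha = lineage_bias**depth_rank
        w = rng.dirichlet(alpha)
        for c, f in zip(path, w):
            cfrac.loc[sid, str(c)] = f
        # lineage fraction of branch at node v = total weight of clones at/below v
        for v in path:
            below = tree.descendants(v)
            lineage = sum(f for c, f in zip(path, w) if c in below)
            for key in tree.branch_mutations.get(v, []):
                evaf.loc[sid, key] = purity[i] * lineage * 0.5

    for i, sid in enumerate(sample_ids):
        p = evaf.loc[sid].to_numpy()
        if depth is None:
            alt = np.rint(p * nominal_depth).astype(int)
        else:
            alt = rng.binomial(nominal_depth, p)
        for j, key in enumerate(keys):
            gene, chrom, pos, ref, altb = key.split(":")
            pileup_rows.append(
                {
                    "patient_id": patient_id,
                    "sample_id": sid,
                    "variant_key": key,
                    "alt_reads": int(alt[j]),
                    "depth": int(nominal_depth),
                }
            )
            if alt[j] >= detect_min_alt:
                variants_rows.append(
                    {
                        "patient_id": patient_id,
                        "sample_id": sid,
                        "variant_key": key,
                        "gene": gene,
                        "chrom": chrom,
                        "pos": int(pos),
                        "ref": ref,
                        "alt": altb,
                        "vaf": alt[j] / nominal_depth,
                        "alt_reads": int(alt[j]),
                        "depth": int(nominal_depth),
                        "class": "SNV",
                    }
                )

    true_labels = {}
    all_samples = set(sample_ids)
    for key in keys:
        carr = set(evaf.index[evaf[key] > 0])
        if len(carr) == 1:
            true_labels[key] = "private"
        elif carr == all_samples:
            true_labels[key] = "truncal"
        else:
            true_labels[key] = "shared"

    subtype_probs = subtype_probs or {
        "CE": [0.30, 0.15, 0.05, 0.50],
        "NE": [0.35, 0.10, 0.45, 0.10],
    }
    subtype = [
        SUBTYPES[rng.choice(4, p=subtype_probs[regions[i]])] for i in range(n_samples)
    ]
    # CE biopsies cluster near the enhancing core, NE sit farther out
    radius = np.where(np.array(regions) == "CE", 10.0, 25.0) + rng.normal(
        0, 3.0, n_samples
    )
    direction = rng.normal(size=(n_samples, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    xyz = np.abs(radius)[:, None] * direction

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": patient_id,
            "region": regions,
            "x_mm": xyz[:, 0],
            "y_mm": xyz[:, 1],
            "z_mm": xyz[:, 2],
            "purity": purity,
            "subtype": subtype,
        }
    )
    truth = CohortTruth(
        samples=samples,
        variant_keys=keys,
        expected_vaf=evaf,
        clone_fractions=cfrac,
        true_labels=true_labels,
        seed=seed,
    )
    variants = pd.DataFrame(
        variants_rows,
        columns=[
            "patient_id", "sample_id", "variant_key", "gene", "chrom", "pos",
            "ref", "alt", "vaf", "alt_reads", "depth", "class",
        ],
    )
    pileups = pd.DataFrame(pileup_rows)
    return variants, pileups, truth


def generate_planted_cohort(
    n_patients: int = 4,
    samples_per_patient: int = 6,
    n_variants_per_patient: int = 50,
    composition: tuple[float, float, float] = (0.60, 0.22, 0.18),
    ne_fraction: float = 0.5,
    depth: int | None = 500,
    detect_min_alt: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Multi-patient cohort whose pooled truncal/shared/private split is exact.

    ``composition`` fractions are converted to integer counts per patient
    (they must divide ``n_variants_per_patient`` exactly for an exact plant).
    """
    counts = [f * n_variants_per_patient for f in composition]
    if any(abs(c - round(c)) > 1e-9 for c in counts):
        raise ValueError("composition x n_variants_per_patient must be integral")
    n_tr, n_sh, n_pr = (int(round(c)) for c in counts)
    all_v, all_p, truths = [], [], []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        n_ne = int(round(samples_per_patient * ne_fraction))
        regions = ["CE"] * (samples_per_patient - n_ne) + ["NE"] * n_ne
        tree, sample_leaf = planted_composition_tree(
            samples_per_patient, n_tr, n_sh, n_pr, regions,
            seed=seed + 101 * p, key_prefix=f"{pid}.",
        )
        v, pu, t = generate_variant_samples(
            tree,
            samples_per_patient,
            depth=depth,
            detect_min_alt=detect_min_alt,
            seed=seed + 101 * p,
            patient_id=pid,
            sample_leaf=sample_leaf,
            regions=regions,
        )
        all_v.append(v)
        all_p.append(pu)
        truths.append(t)
    variants = pd.concat(all_v, ignore_index=True)
    pileups = pd.concat(all_p, ignore_index=True)
    truth = merge_truths(truths, seed=seed)
    return variants, pileups, truth


def merge_truths(truths: list[CohortTruth], seed: int = 0) -> CohortTruth:
    samples = pd.concat([t.samples for t in truths], ignore_index=True)
    evaf = pd.concat([t.expected_vaf for t in truths]).fillna(0.0)
    cfrac = pd.concat([t.clone_fractions for t in truths]).fillna(0.0)
    keys: list[str] = sum((t.variant_keys for t in truths), [])
    labels: dict[str, str] = {}
    for t in truths:
        labels.update(t.true_labels)
    return CohortTruth(
        samples=samples,
        variant_keys=keys,
        expected_vaf=evaf,
        clone_fractions=cfrac,
        true_labels=labels,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def default_gene_sets(n_genes: int, set_size: int = 50) -> dict[str, list[str]]:
    """Four disjoint subtype gene sets over the universe G0000..G{n-1}."""
    if 4 * set_size > n_genes:
        raise ValueError("gene universe too small for 4 disjoint sets")
    genes = [f"G{i:04d}" for i in range(n_genes)]
    return {
        name: genes[k * set_size : (k + 1) * set_size] for k, name in enumerate(SUBTYPES)
    }


def generate_expression(
    truth: CohortTruth,
    gene_sets: dict[str, list[str]],
    n_genes: int = 1000,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    *,
    baseline_mean: float = 5.0,
    scale_by_purity: bool = False,
) -> pd.DataFrame:
    """Log-scale expression with the sample's own subtype gene set shifted up.

    expression[g, s] = baseline[g] + effect * 1[g in set(subtype_s)] + noise.
    With ``scale_by_purity`` the planted effect is attenuated by tumor purity
    (bulk signal diluted by non-tumor cells). Gene sets must be disjoint so
    the planted truth stays unambiguous.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    seen: set[str] = set()
    for name, gs in gene_sets.items():
        overlap = seen.intersection(gs)
        if overlap:
            raise ValueError(f"gene sets overlap at {sorted(overlap)[:3]}")
        seen.update(gs)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    missing = seen.difference(genes)
    if missing:
        raise ValueError(f"gene-set genes outside universe: {sorted(missing)[:3]}")
    rng = _rng(seed, _STREAM_EXPRESSION)
    sample_ids = list(truth.samples["sample_id"])
    subtype = dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))
    purity = dict(zip(truth.samples["sample_id"], truth.samples["purity"]))
    baseline = rng.normal(baseline_mean, 1.0, size=n_genes)
    mat = np.tile(baseline[:, None], (1, len(sample_ids)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, sid in enumerate(sample_ids):
        own = gene_sets.get(subtype[sid], [])
        eff = effect * (purity[sid] if scale_by_purity else 1.0)
        for g in own:
            mat[gene_index[g], j] += eff
    mat += rng.normal(0.0, noise_sd, size=mat.shape)
    return pd.DataFrame(mat, index=genes, columns=sample_ids)


# ---------------------------------------------------------------------------
# DSC-MRI time courses
# ---------------------------------------------------------------------------


def gamma_variate(
    t: np.ndarray, t0: float, alpha: float, beta: float, peak: float
) -> np.ndarray:
    """Gamma-variate bolus: A (t-t0)^alpha exp(-(t-t0)/beta), peak-normalized."""
    dt = np.clip(t - t0, 0.0, None)
    amp = peak / ((alpha * beta) ** alpha * np.exp(-alpha))
    out = amp * dt**alpha * np.exp(-dt / beta)
    out[t <= t0] = 0.0
    return out


def generate_dsc_timecourses(
    truth: CohortTruth | None,
    n_timepoints: int = 90,
    tr: float = 1.5,
    te: float = 0.030,
    snr: float | None = 50.0,
    seed: int = 0,
    *,
    roi_params: pd.DataFrame | None = None,
    bolus: dict | None = None,
    s0: float = 1000.0,
    noise_model: str = "rician",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize DSC signal time courses for tumor ROIs, reference, and NAWM.

    Reference relaxation-rate curve is a gamma-variate; each ROI follows the
    Boxerman leakage model dR2*_roi = K1 * dR2*_ref - K2 * cumint(dR2*_ref),
    converted to signal S = S0 exp(-TE * dR2*) with Rician (default) or
    Gaussian noise at the stated SNR (``snr=None`` for noiseless). The NAWM
    curve has no leakage (K2 = 0) and reduced blood volume. Updates
    ``truth.roi_params``/``truth.bolus`` in place when a manifest is given.

    Returns (long-format time-course table, ROI parameter table).
    """
    if te <= 0:
        raise ValueError("te must be > 0")
    if n_timepoints < 30:
        raise ValueError("need at least 30 timepoints")
    bolus = dict(bolus or {"t0": 30.0, "alpha": 3.0, "beta": 1.5, "peak": 25.0})
    t = np.arange(n_timepoints) * tr
    if int(bolus["t0"] / tr) < 5:
        raise ValueError("baseline window before bolus arrival must be >= 5 points")
    rng = _rng(seed, _STREAM_DSC)

    if roi_params is None:
        if truth is not None and len(truth.samples):
            sids = list(truth.samples["sample_id"])
            k1 = rng.uniform(0.8, 1.4, size=len(sids))
            k2 = rng.uniform(0.01, 0.08, size=len(sids))
            roi_params = pd.DataFrame({"roi_id": sids, "K1": k1, "K2": k2})
        else:
            roi_params = pd.DataFrame(
                {"roi_id": ["tumor"], "K1": [1.2], "K2": [0.05]}
            )
    roi_params = roi_params.copy()
    extra = pd.DataFrame(
        {"roi_id": ["reference", "nawm"], "K1": [1.0, 0.5], "K2": [0.0, 0.0]}
    )
    roi_params = pd.concat(
        [roi_params[~roi_params["roi_id"].isin(extra["roi_id"])], extra],
        ignore_index=True,
    )

    ref = gamma_variate(t, bolus["t0"], bolus["alpha"], bolus["beta"], bolus["peak"])
    cum = np.concatenate([[0.0], np.cumsum((ref[1:] + ref[:-1]) / 2.0 * tr)])

    rows = []
    for _, row in roi_params.iterrows():
        dr2 = row["K1"] * ref - row["K2"] * cum
        sig = s0 * np.exp(-te * dr2)
        # the reference is a whole-brain average over thousands of voxels,
        # so its thermal noise is negligible next to single-ROI curves
        if row["roi_id"] == "reference":
            pass
        elif snr is not None and np.isfinite(snr):
            sigma = s0 / snr
            if noise_model == "rician":
                sig = np.abs(
                    sig + rng.normal(0, sigma, n_timepoints)
                    + 1j * rng.normal(0, sigma, n_timepoints)
                )
            elif noise_model == "gaussian":
                sig = sig + rng.normal(0, sigma, n_timepoints)
            else:
                raise ValueError(f"unknown noise model {noise_model!r}")
        for k in range(n_timepoints):
            rows.append(
                {
                    "roi_id": row["roi_id"],
                    "t_index": k,
                    "t_s": t[k],
                    "signal": sig[k],
                }
            )
    courses = pd.DataFrame(rows)
    courses.attrs["tr"] = tr
    courses.attrs["te"] = te
    courses.attrs["s0"] = s0
    courses.attrs["baseline_n"] = int(bolus["t0"] / tr)
    if truth is not None:
        truth.roi_params = roi_params
        truth.bolus = bolus
    return courses, roi_params


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_cohort(
    outdir: str | Path,
    variants: pd.DataFrame,
    pileups: pd.DataFrame,
    truth: CohortTruth,
    expression: pd.DataFrame | None = None,
    timecourses: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the standard cohort file dialects plus the truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["variants"] = outdir / "variants.tsv"
    variants.to_csv(paths["variants"], sep="\t", index=False)
    paths["pileups"] = outdir / "pileups.tsv"
    pileups.to_csv(paths["pileups"], sep="\t", index=False)
    paths["samples"] = outdir / "samples.csv"
    truth.samples.to_csv(paths["samples"], index=False)
    if expression is not None:
        paths["expression"] = outdir / "expression.tsv"
        expression.to_csv(paths["expression"], sep="\t")
    if timecourses is not None:
        paths["timecourses"] = outdir / "timecourses.csv"
        timecourses.to_csv(paths["timecourses"], index=False)
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(truth.to_manifest(), fh, indent=1, default=float)
    return paths
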