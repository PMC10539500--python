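"""End-to-end orchestration: simulate -> clonality -> distances -> subtype
-> DSC -> association from one validated configuration.

Every stage writes its standard file dialect into the output directory and
the run report records provenance (config hash, master seed, package
version) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clonality, distances, dsc, subtyping, synthetic

_VERSION = "0.1.0"

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    # cohort
    n_patients: int = 4
    samples_per_patient: int = 6
    n_variants_per_patient: int = 50
    composition: tuple[float, float, float] = (0.60, 0.22, 0.18)
    depth: int | None = 500
    detect_min_alt: int = 3
    # clonality thresholds
    min_alt: int = 2
    min_vaf: float = 0.01
    # expression / subtyping
    n_genes: int = 1000
    gene_set_size: int = 50
    effect: float = 2.0
    noise_sd: float = 1.0
    top_n_genes: int = 2826
    n_clusters: int = 2
    # DSC
    n_timepoints: int = 90
    tr: float = 1.5
    te: float = 0.030
    snr: float | None = 50.0
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "clonality", "distances", "subtype", "dsc", "associate",
    )

    def validate(self) -> None:
        if not (0 < self.min_vaf < 1):
            raise ValueError("min_vaf must be in (0, 1)")
        if self.min_alt < 1 or self.detect_min_alt < 1:
            raise ValueError("read thresholds must be >= 1")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if self.top_n_genes <= 0 or self.n_genes <= 0:
            raise ValueError("gene counts must be positive")
        unknown = set(self.stages) - {
            "simulate", "clonality", "distances", "subtype", "dsc", "associate",
        }
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.composition, list):
            cfg.composition = tuple(cfg.composition)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


REGION_VOCAB = {"CE", "NE", "unlabeled"}

_SCHEMAS = {
    "variants": {
        "required": ["patient_id", "sample_id", "variant_key", "vaf", "alt_reads", "depth"],
    },
    "samples": {
        "required": ["sample_id", "patient_id", "region", "x_mm", "y_mm", "z_mm", "purity"],
    },
    "pileups": {
        "required": ["patient_id", "sample_id", "variant_key", "alt_reads", "depth"],
    },
    "timecourses": {
        "required": ["roi_id", "t_index", "t_s", "signal"],
    },
}


def validate_inputs(tables: dict[str, pd.DataFrame]) -> dict:
    """Schema and row-level checks; returns a report, never raises.

    Checks column presence, region vocabulary, VAF/purity ranges and
    alt <= depth; every failure is reported with its row number (malformed
    rows are reported, never silently dropped).
    """
    errors: list[dict] = []
    for name, df in tables.items():
        schema = _SCHEMAS.get(name)
        if schema is None:
            continue
        missing = [c for c in schema["required"] if c not in df.columns]
        if missing:
            errors.append({"table": name, "row": None, "error": f"missing columns {missing}"})
            continue
        if name == "samples":
            for i, region in enumerate(df["region"]):
                if region not in REGION_VOCAB:
                    errors.append(
                        {"table": name, "row": i, "error": f"region {region!r} not in {sorted(REGION_VOCAB)}"}
                    )
            for i, p in enumerate(df["purity"]):
                if not (0 <= p <= 1):
                    errors.append({"table": name, "row": i, "error": f"purity {p} out of [0,1]"})
        if name == "variants":
            for i, v in enumerate(df["vaf"]):
                if not (0 <= v <= 1):
                    errors.append({"table": name, "row": i, "error": f"vaf {v} out of [0,1]"})
            bad = df.index[df["alt_reads"] > df["depth"]]
            for i in bad:
                errors.append({"table": name, "row": int(i), "error": "alt_reads > depth"})
    return {"n_errors": len(errors), "errors": errors, "valid": not errors}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``run_report.json``); aborts on a
    stage failure with the stage name in the raised error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": _VERSION,
        "stages": {},
    }
    state: dict = {}
    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, out, state, report)
        except Exception as exc:
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_report(out, report)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    variants, pileups, truth = synthetic.generate_planted_cohort(
        n_patients=cfg.n_patients,
        samples_per_patient=cfg.samples_per_patient,
        n_variants_per_patient=cfg.n_variants_per_patient,
        composition=cfg.composition,
        depth=cfg.depth,
        detect_min_alt=cfg.detect_min_alt,
        seed=cfg.seed,
    )
    gene_sets = synthetic.default_gene_sets(cfg.n_genes, cfg.gene_set_size)
    expression = synthetic.generate_expression(
        truth, gene_sets, n_genes=cfg.n_genes, effect=cfg.effect,
        noise_sd=cfg.noise_sd, seed=cfg.seed,
    )
    courses, roi_params = synthetic.generate_dsc_timecourses(
        truth, n_timepoints=cfg.n_timepoints, tr=cfg.tr, te=cfg.te,
        snr=cfg.snr, seed=cfg.seed,
    )
    synthetic.write_cohort(out, variants, pileups, truth, expression, courses)
    state.update(
        variants=variants, pileups=pileups, truth=truth,
        expression=expression, courses=courses, gene_sets=gene_sets,
    )
    validation = validate_inputs(
        {"variants": variants, "samples": truth.samples, "pileups": pileups,
         "timecourses": courses}
    )
    report["stages"]["simulate"] = {
        "status": "ok",
        "n_variant_rows": len(variants),
        "validation_errors": validation["n_errors"],
    }


def _stage_clonality(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    rescued = clonality.rescue_calls(
        state["variants"], state["pileups"], min_alt=cfg.min_alt, min_vaf=cfg.min_vaf
    )
    annotations = clonality.classify_sharing(rescued)
    frame = clonality.annotations_frame(annotations)
    frame.to_csv(out / "clonality.tsv", sep="\t", index=False)
    regions = dict(zip(state["truth"].samples["sample_id"], state["truth"].samples["region"]))
    comp = pd.concat(
        [
            clonality.composition(annotations, scope="cohort"),
            clonality.composition(annotations, regions, scope="per-region"),
            clonality.composition(annotations, scope="per-patient"),
        ],
        ignore_index=True,
    )
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)
    state.update(annotations=annotations, rescued=rescued)
    report["stages"]["clonality"] = {
        "status": "ok",
        "n_variants": len(annotations),
        "cohort_composition": comp.iloc[0][
            ["percent_truncal", "percent_shared", "percent_private"]
        ].to_dict(),
    }


def _stage_distances(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    rescued = state["rescued"]
    variant_sets = {
        sid: set(grp["variant_key"]) for sid, grp in rescued.groupby("sample_id")
    }
    truth = state["truth"]
    subtype_map = dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))
    pairs = distances.build_pair_table(truth.samples, variant_sets, subtype_map)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    corr = distances.correlate_distances(pairs)
    with open(out / "correlations.json", "w") as fh:
        json.dump(corr, fh, indent=1)
    state["pairs"] = pairs
    report["stages"]["distances"] = {"status": "ok", **corr}


def _stage_subtype(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    expression = state["expression"]
    gene_sets = state["gene_sets"]
    scores = subtyping.score_samples(expression, gene_sets)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    labels = subtyping.classify_all(expression, gene_sets)
    labels.to_frame().to_csv(out / "labels.tsv", sep="\t")
    top = subtyping.select_variable_genes(
        expression, min(cfg.top_n_genes, len(expression))
    )
    clusters = subtyping.cluster_samples(expression.loc[top], k=cfg.n_clusters)
    clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    truth = state["truth"]
    truth_labels = pd.Series(
        dict(zip(truth.samples["sample_id"], truth.samples["subtype"]))
    )
    accuracy = float((labels == truth_labels.reindex(labels.index)).mean())
    state.update(subtype_labels=labels, clusters=clusters, scores=scores)
    report["stages"]["subtype"] = {"status": "ok", "label_recovery": accuracy}


def _stage_dsc(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    courses = state["courses"]
    metrics = dsc.analyze_timecourses(
        courses, te=cfg.te, baseline_n=courses.attrs.get("baseline_n", 20)
    )
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    with open(out / "metrics_definitions.json", "w") as fh:
        json.dump(dsc.DEFN, fh, indent=1)
    state["metrics"] = metrics
    truth = state["truth"]
    merged = metrics.merge(
        truth.roi_params, left_on="roi_id", right_on="roi_id", suffixes=("", "_true")
    )
    tumor = merged[~merged["roi_id"].isin(["nawm"])]
    k2_err = float(
        np.nanmedian(
            np.abs(tumor["K2"] - tumor["K2_true"])
            / np.where(tumor["K2_true"] != 0, tumor["K2_true"], np.nan)
        )
    )
    report["stages"]["dsc"] = {"status": "ok", "median_k2_rel_error": k2_err}


def _stage_associate(cfg: RunConfig, out: Path, state: dict, report: dict) -> None:
    truth = state["truth"]
    metrics = state["metrics"]
    table = truth.samples.merge(
        metrics, left_on="sample_id", right_on="roi_id", how="inner"
    )
    # continuous NEU signature score as the fixed effect, per-ROI nK2-style response
    scores = state["scores"]
    neu = scores[scores["gene_set"] == "NEU"][["sample_id", "nes"]].rename(
        columns={"nes": "NEU_score"}
    )
    table = table.merge(neu, on="sample_id", how="left")
    screen = association.signature_screen(
        table, ["K2", "rCBV", "PSR"], ["NEU_score"], stratum="all"
    )
    screen.to_csv(out / "screen.tsv", sep="\t", index=False)
    fit = association.fit_random_intercept_lmm(table, "K2", ["region"])
    vd = association.variance_decomposition(fit)
    vd.to_csv(out / "variance.tsv", sep="\t", index=False)
    emm = association.estimated_marginal_means(fit, "region")
    emm["emmeans"].to_csv(out / "emm.tsv", sep="\t", index=False)
    report["stages"]["associate"] = {
        "status": "ok",
        "n_screen_rows": len(screen),
        "region_percent_variance": float(
            vd.loc[vd["term"] == "region", "percent_variance"].iloc[0]
        ),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "clonality": _stage_clonality,
    "distances": _stage_distances,
    "subtype": _stage_subtype,
    "dsc": _stage_dsc,
    "associate": _stage_associate,
}
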