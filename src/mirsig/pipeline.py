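"""End-to-end orchestration: derivation profiling, validation, MP study.

Each entry point takes a :class:`RunConfig`, runs the stages in a fixed
order, writes a TSV report bundle plus a JSON manifest of parameters,
seed and per-stage counts, and returns the in-memory report.  Identical
config + seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexnet, evaluate, microparticle, preprocess, synthetic
from .io import CtMatrix, SampleAnnotation, read_ct_matrix, read_sample_annotation, validate_dataset
from .sam import SamConfig, sam_analysis, select_signature, write_sam_table
from .synthetic import CohortSpec, MpStudySpec

logger = logging.getLogger(__name__)

#: Covariates used by the adjusted logistic models.
ADJUSTMENT_COVARIATES = [
    "age", "sex", "hypertension", "dyslipidemia", "diabetes", "smoking", "statin", "antiplatelet",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either file inputs (ct_path + annotation_path) or a simulation spec
    must be provided.  Stage parameters default to the published
    analysis choices: detection in >=21 samples, U6 reference, fold
    change > 8 with q < 1e-6, network thresholds r >= 0.79 / p < 0.02,
    3 principal components.
    """

    ct_path: str | None = None
    annotation_path: str | None = None
    simulate: CohortSpec | None = None
    min_detected: int = 21
    reference_id: str = "U6"
    sam: SamConfig = field(default_factory=SamConfig)
    r_min: float = coexnet.DEFAULT_R_MIN
    p_max: float = coexnet.DEFAULT_P_MAX
    pca_k: int = 3
    seed: int = 0
    case_group: str = "UA"
    control_group: str = "CONTROL"
    roc_pool_non_ua: bool = True
    outdir: str | None = None


def _load(cfg: RunConfig):
    if cfg.simulate is not None:
        ct, ann, gt = synthetic.simulate_cohort(cfg.simulate, seed=cfg.seed)
        return validate_dataset(ct, ann), gt
    if not cfg.ct_path or not cfg.annotation_path:
        raise ValueError("need either a simulation spec or ct_path + annotation_path")
    ct = read_ct_matrix(cfg.ct_path)
    ann = read_sample_annotation(cfg.annotation_path)
    return validate_dataset(ct, ann), None


def _write_manifest(outdir: Path, manifest: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_derivation(cfg: RunConfig) -> dict:
    """Derivation profiling: filter, normalize, SAM, cluster/PCA, networks.

    Stage order is fixed: detection filter -> reference normalization ->
    SAM -> signature selection -> clustering + PCA -> per-group networks
    -> first-neighbor subnetworks -> network comparison.
    """
    stage = "load"
    manifest: dict = {"stages": [], "seed": cfg.seed, "parameters": {
        "min_detected": cfg.min_detected, "reference_id": cfg.reference_id,
        "fc_min": cfg.sam.fc_min, "q_max": cfg.sam.q_max,
        "n_permutations": cfg.sam.n_permutations,
        "r_min": cfg.r_min, "p_max": cfg.p_max, "pca_k": cfg.pca_k,
    }}
    try:
        ds, gt = _load(cfg)
        manifest["stages"].append({"stage": "load", "n_mirnas": len(ds.ct.mirna_ids),
                                   "n_samples": len(ds.ct.sample_ids),
                                   "group_sizes": ds.group_sizes})

        stage = "detection_filter"
        filtered = preprocess.detection_filter(ds.ct, cfg.min_detected)
        manifest["stages"].append({"stage": stage, "n_mirnas": len(filtered.mirna_ids)})

        stage = "normalize"
        em = preprocess.normalize_to_reference(filtered, cfg.reference_id)
        manifest["stages"].append({"stage": stage, "n_mirnas": len(em.mirna_ids)})
        # miRNAs entering SAM = survivors of the filter minus the reference row
        assert len(em.mirna_ids) == len(filtered.mirna_ids) - 1

        stage = "sam"
        case = (ds.ann.groups == cfg.case_group).to_numpy()
        cfg_sam = SamConfig(**{**asdict(cfg.sam), "seed": cfg.seed})
        sam_res = sam_analysis(em, case, cfg_sam)
        manifest["stages"].append({"stage": stage, "s0": sam_res.s0})

        stage = "select_signature"
        selected = select_signature(sam_res, cfg_sam)
        manifest["stages"].append({"stage": stage, "n_selected": len(selected)})

        stage = "cluster"
        clust = evaluate.hierarchical_cluster(em.log10_expr)
        manifest["stages"].append({"stage": stage})

        stage = "pca"
        pca = evaluate.pca_reduce(em.log10_expr, k=cfg.pca_k)
        pca_report = evaluate.pca_classify(pca, ds.ann.groups)
        manifest["stages"].append({"stage": stage,
                                   "variance_explained": [float(v) for v in pca.variance_explained],
                                   "loo_overall_rate": pca_report["overall_rate"]})

        stage = "networks"
        nets = {}
        for g in ds.group_sizes:
            ids = [s for s, lab in ds.ann.groups.items() if lab == g]
            nets[g] = coexnet.group_network(em.log10_expr, ids, r_min=cfg.r_min,
                                            p_max=cfg.p_max, group=g)
        seeds = selected.mirna_ids or em.mirna_ids[:1]
        subnets = {g: coexnet.first_neighbor_subnetwork(n, seeds) for g, n in nets.items()}
        manifest["stages"].append({"stage": stage, "networks": {
            g: {"nodes": n.number_of_nodes(), "edges": n.number_of_edges()} for g, n in nets.items()},
            "subnetworks": {
            g: {"nodes": n.number_of_nodes(), "edges": n.number_of_edges()} for g, n in subnets.items()}})

        stage = "compare_networks"
        glist = list(nets)
        comparison = coexnet.compare_networks(subnets[glist[0]], subnets[glist[1]]) \
            if len(glist) >= 2 else None
        if comparison is not None:
            manifest["stages"].append({"stage": stage, **comparison.summary()})
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"derivation pipeline failed at stage {stage!r}: {exc}") from exc

    report = {"dataset": ds, "ground_truth": gt, "filtered": filtered, "expression": em,
              "sam": sam_res, "selected": selected, "cluster": clust, "pca": pca,
              "pca_report": pca_report, "networks": nets, "subnetworks": subnets,
              "comparison": comparison, "manifest": manifest}

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        preprocess.write_expression_matrix(em, out / "expression_log10.tsv", log10=True)
        write_sam_table(sam_res, out / "sam_scores.tsv")
        selected.table.to_csv(out / "signature.tsv", sep="\t")
        for g, n in nets.items():
            coexnet.export_network(n, "tsv", out / f"network_{g}.tsv")
            coexnet.export_network(subnets[g], "sif", out / f"subnetwork_{g}.sif")
        _write_manifest(out, manifest)
    return report


def run_validation(cfg: RunConfig) -> dict:
    """Validation-cohort evaluation: per-miRNA ROC, adjusted logistic, PCA.

    ROC distinguishes UA from non-UA (stable angina + controls pooled by
    default); logistic contrasts are UA vs SA and UA vs control,
    adjusted for the risk-factor and drug covariates.  A missing
    covariate fails only the logistic stage; the ROC table is still
    produced (partial-failure contract).
    """
    ds, gt = _load(cfg)
    groups = ds.ann.groups
    for g in (cfg.case_group, "SA", cfg.control_group):
        if g not in set(groups):
            raise ValueError(f"validation cohort is missing group {g!r}")
    em = preprocess.normalize_to_reference(ds.ct, cfg.reference_id) \
        if cfg.reference_id in ds.ct.values.index else None
    if em is None:
        raise ValueError(f"reference {cfg.reference_id!r} absent from Ct matrix")

    case = (groups == cfg.case_group).to_numpy()
    roc_rows = {}
    for mid in em.mirna_ids:
        res = evaluate.roc_analysis(em.log10_expr.loc[mid], case)
        roc_rows[mid] = {"auc": res.auc, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                         "p": res.p_value, "cutoff": res.cutoff,
                         "sensitivity": res.sensitivity, "specificity": res.specificity}
    roc_table = pd.DataFrame.from_dict(roc_rows, orient="index")

    logit_tables = {}
    logit_error = None
    try:
        cov = ds.ann.covariates(ADJUSTMENT_COVARIATES)
        if cov.isna().any().any():
            bad = cov.columns[cov.isna().any()].tolist()
            raise ValueError(f"missing covariate value(s) in: {bad}")
        for other, label in ((("SA",), "UA_vs_SA"), ((cfg.control_group,), "UA_vs_Control")):
            mask = groups.isin([cfg.case_group, *other])
            y = (groups[mask] == cfg.case_group).astype(float)
            rows = {}
            for mid in em.mirna_ids:
                vals = em.log10_expr.loc[mid, mask.index[mask]]
                res = evaluate.logistic_adjusted(vals, y, cov.loc[mask.index[mask]])
                rows[mid] = {"odds_ratio": res.odds_ratio, "ci_low": res.ci95[0],
                             "ci_high": res.ci95[1], "p": res.p_value, "flagged": res.flagged}
            logit_tables[label] = pd.DataFrame.from_dict(rows, orient="index")
    except (ValueError, KeyError) as exc:
        logit_error = str(exc)
        logger.warning("logistic stage failed (%s); ROC table still emitted", exc)

    pca = evaluate.pca_reduce(em.log10_expr, k=min(cfg.pca_k, len(em.mirna_ids),
                                                   len(em.sample_ids) - 1))
    binary = groups.where(groups == cfg.case_group, "NON_UA")
    pca_report = evaluate.pca_classify(pca, binary)

    manifest = {"seed": cfg.seed, "n_mirnas": len(em.mirna_ids),
                "group_sizes": ds.group_sizes, "logit_error": logit_error,
                "pca_loo_rate": pca_report["overall_rate"]}
    report = {"dataset": ds, "ground_truth": gt, "expression": em, "roc": roc_table,
              "logistic": logit_tables, "logit_error": logit_error,
              "pca": pca, "pca_report": pca_report, "manifest": manifest}
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        roc_table.rename_axis("mirna_id").to_csv(out / "roc_table.tsv", sep="\t")
        for label, tab in logit_tables.items():
            tab.rename_axis("mirna_id").to_csv(out / f"logistic_{label}.tsv", sep="\t")
        _write_manifest(out, manifest)
    return report


def run_mp(cfg: RunConfig, mp_spec: MpStudySpec | None = None) -> dict:
    """MP study: subtype panel, count-adjusted miRNA levels, group tests."""
    spec = mp_spec or MpStudySpec()
    tables, groups, ct, gt = synthetic.simulate_mp_study(spec, seed=cfg.seed)
    panel = microparticle.subtype_panel(tables, groups)
    adjusted = microparticle.mp_mirna_expression(ct, panel.per_sample["annexinv+"])
    tests = {}
    for mid in adjusted.index:
        tests[mid] = evaluate.group_compare(adjusted.loc[mid].to_numpy(),
                                            groups.to_numpy(), kind="continuous")
    manifest = {"seed": cfg.seed,
                "subtype_tests": {k: v["p"] for k, v in panel.tests.items()},
                "mirna_tests": {k: v["p"] for k, v in tests.items()}}
    report = {"panel": panel, "adjusted": adjusted, "tests": tests,
              "ground_truth": gt, "manifest": manifest}
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        panel.per_sample.rename_axis("sample_id").to_csv(out / "mp_panel.tsv", sep="\t")
        panel.group_stats.to_csv(out / "mp_group_stats.tsv", sep="\t")
        adjusted.rename_axis("mirna_id").to_csv(out / "mp_adjusted_expression.tsv", sep="\t")
        _write_manifest(out, manifest)
    return report
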