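"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates qPCR low-density-array plasma profiling of two
small clinical groups: ~754 miRNA assays, a stable U6 reference, Ct
values around 28 +/- 3 cycles across assays with ~0.6-cycle
within-assay dispersion, miRNA-specific detection dropout that grows
with Ct, a planted upregulated signature (8- to 24-fold in cases, the
range printed for the published signature), and per-group latent-factor
correlation blocks that give the coexpression networks something to
find.  A companion generator emulates the microparticle (MP) study:
bead-calibrated flow-event tables at the published concentration scale
(n = 5 per group) and an MP Ct matrix with a 2-fold planted effect on
the count-adjusted scale.

Effects are planted on the Ct scale as -log2(FC) shifts, so
linear-scale fold changes are exact in expectation under the 2^-dCt
measurement model.  Everything is a deterministic function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleAnnotation
from .microparticle import MP_REFERENCE_ID, MpEventTable

#: The PCR-validated panel; used as planted ids in the validation preset.
VALIDATED_PANEL = [
    "hsa-miR-106b",
    "hsa-miR-25",
    "hsa-miR-92a",
    "hsa-miR-21",
    "hsa-miR-590-5p",
    "hsa-miR-126*",
    "hsa-miR-451",
]

#: Covariate marginals per group (frequencies / age moments from the
#: validation-cohort clinical table; sexes coded male=1).
COVARIATE_MODEL = {
    "CONTROL": {"age": (59, 6), "sex": 22 / 37, "hypertension": 0.568, "dyslipidemia": 0.459,
                "diabetes": 0.162, "smoking": 0.459, "statin": 0.486, "antiplatelet": 0.351},
    "SA": {"age": (62, 11), "sex": 18 / 31, "hypertension": 0.742, "dyslipidemia": 0.452,
           "diabetes": 0.290, "smoking": 0.387, "statin": 0.516, "antiplatelet": 0.516},
    "UA": {"age": (63, 12), "sex": 25 / 45, "hypertension": 0.756, "dyslipidemia": 0.667,
           "diabetes": 0.267, "smoking": 0.467, "statin": 0.422, "antiplatelet": 0.533},
}


@dataclass
class CohortSpec:
    """Parameters of the simulated profiling cohort.

    Defaults reproduce the derivation-cohort conditions: 754 assays,
    13 unstable-angina cases vs 13 controls, a 30-miRNA planted
    signature with fold changes spanning 8-24, and dropout calibrated
    so roughly 5-15% of assays fail the 21-of-26 detection rule.
    """

    n_mirnas: int = 754
    group_sizes: dict[str, int] = field(default_factory=lambda: {"UA": 13, "CONTROL": 13})
    case_group: str = "UA"
    baseline_mean: float = 28.0
    baseline_sd: float = 3.0
    within_sd: float = 0.6
    reference_id: str = "U6"
    reference_mean: float = 25.0
    reference_sd: float = 0.15
    ct_max: float = 40.0
    n_planted: int = 30
    fc_range: tuple[float, float] = (8.0, 24.0)
    planted_ids: list[str] | None = None
    dropout_center: float = 37.0
    dropout_scale: float = 3.0
    n_blocks: int = 4
    block_size: int = 10
    block_rho: float = 0.9  # target pairwise correlation within a block
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_range[0] <= 0:
            raise ValueError("fold changes must be positive")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.n_planted > self.n_mirnas:
            raise ValueError("more planted miRNAs than assays")

    @classmethod
    def validation_preset(cls, **overrides) -> "CohortSpec":
        """PCR-validation conditions: 45 UA / 31 SA / 37 controls, the
        7-miRNA validated panel planted at milder fold changes."""
        defaults = dict(
            n_mirnas=7,
            group_sizes={"UA": 45, "SA": 31, "CONTROL": 37},
            n_planted=7,
            planted_ids=list(VALIDATED_PANEL),
            fc_range=(2.0, 6.0),
            within_sd=1.6,  # wider biological spread -> realistic AUC ~0.7-0.8
            n_blocks=0,
            block_size=0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    planted_fc: dict[str, float]
    blocks: dict[str, list[list[str]]]  # group -> list of blocks (miRNA ids)
    covariate_model: dict
    mp_means: dict | None = None
    mp_planted_fc: dict[str, float] | None = None


def _mirna_names(n: int, planted_ids: list[str] | None) -> list[str]:
    names = [f"miR-{i:04d}" for i in range(1, n + 1)]
    if planted_ids:
        for k, pid in enumerate(planted_ids):
            names[k] = pid
    return names


def simulate_cohort(spec: CohortSpec, seed: int | None = None):
    """Generate (CtMatrix, SampleAnnotation, GroundTruth) for one cohort.

    Ct[i, s] = baseline_i - log2(FC_i)*[s is case] + block factor + noise,
    then censored at ct_max and thinned by a logistic dropout model in
    the true Ct.  The reference assay is emitted as a stable extra row.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    names = _mirna_names(spec.n_mirnas, spec.planted_ids)
    if spec.planted_ids:
        missing = [p for p in spec.planted_ids if p not in names]
        if missing:
            raise ValueError(f"planted id(s) not in miRNA universe: {missing}")

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_mirnas)

    # planted signature: prefer well-detected assays so the filter keeps them
    if spec.planted_ids:
        planted_idx = np.array([names.index(p) for p in spec.planted_ids])
    else:
        detectable = np.flatnonzero(baseline < spec.dropout_center - 4.0)
        planted_idx = rng.choice(detectable, size=spec.n_planted, replace=False)
    fcs = rng.uniform(spec.fc_range[0], spec.fc_range[1], size=len(planted_idx))
    planted_fc = {names[i]: float(f) for i, f in zip(planted_idx, fcs)}
    shift = np.zeros(spec.n_mirnas)
    shift[planted_idx] = np.log2(fcs)

    # per-group latent-factor correlation blocks (disjoint within a group)
    blocks: dict[str, list[list[str]]] = {}
    block_member: dict[str, np.ndarray] = {}
    for g in spec.group_sizes:
        member = np.full(spec.n_mirnas, -1)
        blocks[g] = []
        if spec.n_blocks and spec.block_size:
            detectable = np.flatnonzero(baseline < spec.dropout_center - 4.0)
            need = spec.n_blocks * spec.block_size
            if need > detectable.size:
                raise ValueError(
                    f"correlation blocks need {need} well-detected miRNAs, "
                    f"only {detectable.size} available"
                )
            chosen = rng.choice(detectable, size=need, replace=False)
            for b in range(spec.n_blocks):
                ids = chosen[b * spec.block_size : (b + 1) * spec.block_size]
                member[ids] = b
                blocks[g].append([names[i] for i in ids])
        block_member[g] = member

    samples, groups = [], []
    for g, n in spec.group_sizes.items():
        for j in range(n):
            samples.append(f"{g}_{j+1:02d}")
            groups.append(g)

    a = np.sqrt(spec.block_rho)
    b = np.sqrt(1.0 - spec.block_rho)
    ct = np.empty((spec.n_mirnas, len(samples)))
    for s_idx, g in enumerate(groups):
        is_case = g == spec.case_group
        member = block_member[g]
        factors = rng.normal(size=max(spec.n_blocks, 1))
        z = rng.normal(size=spec.n_mirnas)
        noise = np.where(
            member >= 0,
            spec.within_sd * (a * factors[np.clip(member, 0, None)] + b * z),
            spec.within_sd * z,
        )
        ct[:, s_idx] = baseline - (shift if is_case else 0.0) + noise

    # logistic detection dropout in the true Ct, then hard censoring
    p_detect = 1.0 / (1.0 + np.exp((ct - spec.dropout_center) / spec.dropout_scale))
    detected = rng.random(ct.shape) < p_detect
    ct = np.where(detected, ct, np.nan)
    ct = np.where(ct >= spec.ct_max, np.nan, ct)
    ct = np.clip(ct, 0.0, None)

    ref_row = rng.normal(spec.reference_mean, spec.reference_sd, size=len(samples))
    values = pd.DataFrame(ct, index=names, columns=samples)
    values.loc[spec.reference_id] = ref_row
    ct_matrix = CtMatrix(values, ct_max=spec.ct_max)

    ann_rows = {}
    for s, g in zip(samples, groups):
        model = COVARIATE_MODEL[g]
        row = {"group": g, "age": float(np.round(rng.normal(*model["age"]), 1))}
        for cov in ("sex", "hypertension", "dyslipidemia", "diabetes", "smoking", "statin", "antiplatelet"):
            row[cov] = int(rng.random() < model[cov])
        ann_rows[s] = row
    ann = SampleAnnotation(pd.DataFrame.from_dict(ann_rows, orient="index"))

    gt = GroundTruth(planted_fc=planted_fc, blocks=blocks, covariate_model=COVARIATE_MODEL)
    return ct_matrix, ann, gt


# ---------------------------------------------------------------------------
# microparticle study


@dataclass
class MpStudySpec:
    """Conditions of the simulated MP study (5 cases vs 5 controls).

    Group means are the published concentrations (per uL plasma); the
    per-subject SD is SEM * sqrt(n) with n = 5.  The MP Ct matrix
    carries the validated panel referenced to hsa-miR-24 with a planted
    fold change on the count-adjusted scale.
    """

    n_per_group: int = 5
    annexin_mean: dict[str, float] = field(default_factory=lambda: {"UA": 5213.0, "CONTROL": 2240.0})
    annexin_sem: dict[str, float] = field(default_factory=lambda: {"UA": 882.0, "CONTROL": 585.0})
    cd31_mean: dict[str, float] = field(default_factory=lambda: {"UA": 4318.0, "CONTROL": 1646.0})
    cd31_sem: dict[str, float] = field(default_factory=lambda: {"UA": 988.0, "CONTROL": 462.0})
    sem_n: int = 5
    bead_events: int = 500
    beads_per_tube: int = 25000
    test_volume_ul: float = 100.0
    panel: list[str] = field(default_factory=lambda: list(VALIDATED_PANEL))
    mp_fc: float = 2.0  # planted case/control ratio of count-adjusted levels
    mp_baseline_mean: float = 28.0
    mp_baseline_sd: float = 1.0
    mp_within_sd: float = 0.3
    reference_mean: float = 24.0
    reference_sd: float = 0.15
    ct_max: float = 40.0
    seed: int = 0


def simulate_mp_study(spec: MpStudySpec | None = None, seed: int | None = None):
    """Generate per-sample MP event tables, an MP Ct matrix, and the truth.

    Event counts are Poisson around per-subject true concentrations so
    that expected bead-calibrated concentrations match the group means;
    the Annexin V+ events partition exactly into CD31+ and CD31-.
    """
    spec = spec or MpStudySpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sd_scale = np.sqrt(spec.sem_n)
    # events per (unit concentration): conc = k/bead_events * beads/vol
    events_per_conc = spec.bead_events * spec.test_volume_ul / spec.beads_per_tube

    tables: dict[str, MpEventTable] = {}
    groups: dict[str, str] = {}
    annexin_conc: dict[str, float] = {}
    for g in ("UA", "CONTROL"):
        for j in range(spec.n_per_group):
            sample = f"{g}_MP{j+1}"
            # truncate below at 1% of the group mean: plasma always carries
            # some MPs, and downstream count adjustment divides by this
            total = max(0.01 * spec.annexin_mean[g],
                        rng.normal(spec.annexin_mean[g], spec.annexin_sem[g] * sd_scale))
            cd31p = max(0.0, rng.normal(spec.cd31_mean[g], spec.cd31_sem[g] * sd_scale))
            cd31p = min(cd31p, total)
            cd31n = total - cd31p
            k_pos = rng.poisson(cd31p * events_per_conc)
            k_neg = rng.poisson(cd31n * events_per_conc)
            k_debris = rng.poisson(0.05 * (k_pos + k_neg) + 1)
            frames = []
            if k_pos:
                frames.append(pd.DataFrame({"in_mp_gate": True, "annexin_v": True, "cd31": True},
                                           index=range(k_pos)))
            if k_neg:
                frames.append(pd.DataFrame({"in_mp_gate": True, "annexin_v": True, "cd31": False},
                                           index=range(k_neg)))
            frames.append(pd.DataFrame({"in_mp_gate": False, "annexin_v": False, "cd31": False},
                                       index=range(k_debris)))
            events = pd.concat(frames, ignore_index=True)
            tables[sample] = MpEventTable(
                events=events,
                bead_events=spec.bead_events,
                beads_per_tube=spec.beads_per_tube,
                test_volume_ul=spec.test_volume_ul,
            )
            groups[sample] = g
            # realized concentration used by the Ct model below
            annexin_conc[sample] = (
                (k_pos + k_neg) / spec.bead_events * (spec.beads_per_tube / spec.test_volume_ul)
            )

    # MP Ct matrix: planted effect on the count-adjusted scale.  Higher MP
    # concentration means proportionally more template, hence lower Ct.
    samples = list(tables)
    baseline = rng.normal(spec.mp_baseline_mean, spec.mp_baseline_sd, size=len(spec.panel))
    conc0 = spec.annexin_mean["CONTROL"]
    ct = np.empty((len(spec.panel), len(samples)))
    for s_idx, sample in enumerate(samples):
        is_case = groups[sample] == "UA"
        load = np.log2(max(annexin_conc[sample], 1.0) / conc0)
        noise = rng.normal(0.0, spec.mp_within_sd, size=len(spec.panel))
        ct[:, s_idx] = baseline - (np.log2(spec.mp_fc) if is_case else 0.0) - load + noise
    values = pd.DataFrame(ct, index=spec.panel, columns=samples)
    values.loc[MP_REFERENCE_ID] = rng.normal(spec.reference_mean, spec.reference_sd, size=len(samples))
    ct_matrix = CtMatrix(values, ct_max=spec.ct_max)

    gt = GroundTruth(
        planted_fc={},
        blocks={},
        covariate_model=COVARIATE_MODEL,
        mp_means={"annexinv+": spec.annexin_mean, "annexinv+cd31+": spec.cd31_mean},
        mp_planted_fc={m: spec.mp_fc for m in spec.panel},
    )
    return tables, pd.Series(groups), ct_matrix, gt


# ---------------------------------------------------------------------------
# recovery scoring


def ground_truth_report(
    gt: GroundTruth,
    selected_ids,
    fc_estimates: pd.Series | None = None,
    universe: list[str] | None = None,
) -> dict:
    """Score a selection against the planted signature.

    Returns sensitivity, the number of false selections, and (when fold
    change estimates are supplied) the mean absolute relative error of
    the estimated fold changes of recovered planted miRNAs.
    """
    planted = set(gt.planted_fc)
    selected = set(selected_ids)
    if universe is not None:
        unknown = selected - set(universe)
        if unknown:
            raise ValueError(f"selected id(s) outside the dataset: {sorted(unknown)[:5]}")
    tp = selected & planted
    report = {
        "sensitivity": len(tp) / len(planted) if planted else np.nan,
        "false_selections": len(selected - planted),
        "n_selected": len(selected),
        "n_planted": len(planted),
    }
    if fc_estimates is not None and tp:
        errs = [
            abs(fc_estimates[m] - gt.planted_fc[m]) / gt.planted_fc[m]
            for m in tp
            if m in fc_estimates and np.isfinite(fc_estimates[m])
        ]
        report["fc_mean_abs_rel_error"] = float(np.mean(errs)) if errs else np.nan
    return report


def block_edge_recall(blocks: list[list[str]], edges: set[tuple[str, str]]) -> dict:
    """Within-block edge recall and between-block edge rate by enumeration."""
    within_pairs = set()
    for blk in blocks:
        for i, u in enumerate(blk):
            for v in blk[i + 1 :]:
                within_pairs.add(tuple(sorted((u, v))))
    members = [m for blk in blocks for m in blk]
    between_pairs = set()
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            pair = tuple(sorted((u, v)))
            if pair not in within_pairs:
                between_pairs.add(pair)
    edges = {tuple(sorted(e)) for e in edges}
    recall = len(edges & within_pairs) / len(within_pairs) if within_pairs else np.nan
    between = len(edges & between_pairs) / len(between_pairs) if between_pairs else np.nan
    return {"within_block_recall": recall, "between_block_rate": between,
            "n_within_pairs": len(within_pairs), "n_between_pairs": len(between_pairs)}
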