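"""Flow-cytometry microparticle (MP) quantification and MP-adjusted miRNA levels.

Plasma MPs are the 0.1-1 um events in the size gate; a known quantity
of counting beads per tube converts event ratios into absolute
concentrations:

    concentration = (matching gated events / bead events)
                    * (beads per tube / test volume)

Annexin V marks phosphatidylserine-exposing MPs; CD31 splits them into
endothelial/platelet-derived (CD31+) and other (CD31-) subtypes, an
exact event-level partition.  MP miRNA expression is referenced to
hsa-miR-24 and divided by the sample's MP concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import group_compare
from .io import CtMatrix

#: Named subtype predicates on the event table.
SUBTYPES = {
    "annexinv+": lambda ev: ev["annexin_v"],
    "annexinv+cd31+": lambda ev: ev["annexin_v"] & ev["cd31"],
    "annexinv+cd31-": lambda ev: ev["annexin_v"] & ~ev["cd31"],
}

MP_REFERENCE_ID = "hsa-miR-24"


@dataclass
class MpEventTable:
    """Per-event flags plus the bead calibration for one sample.

    ``events`` columns: in_mp_gate, annexin_v, cd31 (booleans).
    """

    events: pd.DataFrame
    bead_events: int
    beads_per_tube: int
    test_volume_ul: float

    def __post_init__(self) -> None:
        for col in ("in_mp_gate", "annexin_v", "cd31"):
            if col not in self.events.columns:
                raise ValueError(f"event table missing column {col!r}")
        self.events = self.events.astype({c: bool for c in ("in_mp_gate", "annexin_v", "cd31")})
        if self.bead_events < 1:
            raise ValueError("no calibration beads acquired")
        if self.test_volume_ul <= 0:
            raise ValueError("test volume must be positive")


@dataclass
class MpPanel:
    """Bead-calibrated subtype concentrations per sample and per group."""

    per_sample: pd.DataFrame  # samples x subtypes, per-uL plasma
    groups: pd.Series
    group_stats: pd.DataFrame  # (group, subtype) mean and sem
    tests: dict  # subtype -> group_compare result


def mp_concentration(table: MpEventTable, subtype: str = "annexinv+") -> float:
    """Absolute concentration (events per uL plasma) of one MP subtype."""
    try:
        predicate = SUBTYPES[subtype]
    except KeyError:
        raise ValueError(f"unknown subtype {subtype!r}; known: {sorted(SUBTYPES)}") from None
    matching = int((predicate(table.events) & table.events["in_mp_gate"]).sum())
    return (matching / table.bead_events) * (table.beads_per_tube / table.test_volume_ul)


def subtype_panel(tables: dict[str, MpEventTable], groups: pd.Series | dict) -> MpPanel:
    """Three-subtype concentrations per sample with group mean +/- SEM and tests.

    The event-level partition guarantees
    AnnexinV+CD31+ + AnnexinV+CD31- = AnnexinV+ for every sample.
    """
    groups = pd.Series(groups)
    missing = [s for s in tables if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    rows = {
        sample: {name: mp_concentration(tab, name) for name in SUBTYPES}
        for sample, tab in tables.items()
    }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    groups = groups.loc[per_sample.index]
    stats_rows = []
    for g, chunk in per_sample.groupby(groups):
        for name in SUBTYPES:
            vals = chunk[name]
            stats_rows.append(
                {
                    "group": g,
                    "subtype": name,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sem": vals.sem() if len(vals) > 1 else np.nan,
                }
            )
    tests = {}
    if groups.nunique() == 2 and groups.value_counts().min() >= 2:
        for name in SUBTYPES:
            tests[name] = group_compare(per_sample[name].to_numpy(), groups.to_numpy(), kind="continuous")
    return MpPanel(
        per_sample=per_sample,
        groups=groups,
        group_stats=pd.DataFrame(stats_rows).set_index(["group", "subtype"]),
        tests=tests,
    )


def mp_mirna_expression(
    ct: CtMatrix, mp_counts: pd.Series, reference_id: str = MP_REFERENCE_ID
) -> pd.DataFrame:
    """MP miRNA levels: 2^-(Ct[miRNA]-Ct[miR-24]) divided by MP concentration.

    The reference must be detected in every sample and every MP count
    must be positive; the reference row is dropped from the output.
    """
    if reference_id not in ct.values.index:
        raise ValueError(f"reference assay {reference_id!r} missing from MP Ct matrix")
    ref = ct.values.loc[reference_id]
    und = ref[ref.isna()].index.tolist()
    if und:
        raise ValueError(f"reference {reference_id!r} undetected in sample(s): {und}")
    counts = mp_counts.reindex(ct.values.columns)
    if counts.isna().any():
        raise ValueError(f"missing MP count for sample(s): {counts[counts.isna()].index.tolist()}")
    if (counts <= 0).any():
        raise ValueError("MP counts must be positive")
    expr = np.power(2.0, -(ct.values.sub(ref, axis=1))).drop(index=reference_id)
    return expr.div(counts, axis=1)
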