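"""Reading, writing and validation of Ct matrices and sample annotations.

The central data model is the cycle-threshold (Ct) matrix produced by
qPCR low-density arrays: one row per miRNA assay, one column per plasma
sample.  A well that never crossed the fluorescence threshold is
"undetected"; we store it as NaN.  Following the strict detection
criterion Ct < ct_max, a value at or above the ceiling (default 40
cycles) is also treated as undetected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed clinical group labels (unstable angina, stable angina, non-cardiac
#: chest-pain controls).
GROUPS = ("UA", "SA", "CONTROL")

DEFAULT_UNDETECTED_TOKEN = "Undetermined"


@dataclass
class CtMatrix:
    """Cycle-threshold values per (miRNA, sample); NaN marks undetected wells.

    Parameters
    ----------
    values
        DataFrame of Ct values (cycles); index = miRNA ids, columns =
        sample ids.  NaN means the well is undetected.
    ct_max
        Detection ceiling in cycles.  Values >= ct_max are coerced to NaN
        on construction (the detection rule is strict: Ct < ct_max).
    """

    values: pd.DataFrame
    ct_max: float = 40.0

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.values.astype(float)
        # strict detection: Ct == ceiling is not a detection
        vals = vals.mask(vals >= self.ct_max)
        if (vals < 0).any().any():
            bad = vals.stack()[vals.stack() < 0]
            raise ValueError(f"negative Ct values: {bad.index.tolist()[:5]}")
        self.values = vals

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected wells (defined Ct strictly below ct_max)."""
        return self.values.notna()

    def detection_counts(self) -> pd.Series:
        """Number of samples in which each miRNA is detected."""
        return self.detected().sum(axis=1)


@dataclass
class SampleAnnotation:
    """Per-sample group labels and clinical covariates.

    ``table`` is indexed by sample_id with a mandatory ``group`` column
    (one of UA / SA / CONTROL) plus arbitrary covariate columns
    (age, sex, hypertension, ..., coded numerically; binary as 0/1).
    Missing covariate values are permitted at load time and only
    rejected by operations that need them.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in annotation: {dups}")
        if "group" not in self.table.columns:
            raise ValueError("annotation must have a 'group' column")
        groups = self.table["group"].astype(str).str.upper()
        bad = sorted(set(groups) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group label(s) {bad}; allowed: {list(GROUPS)}")
        self.table = self.table.copy()
        self.table["group"] = groups

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def covariates(self, names: list[str]) -> pd.DataFrame:
        missing_cols = [n for n in names if n not in self.table.columns]
        if missing_cols:
            raise KeyError(f"missing covariate column(s): {missing_cols}")
        return self.table[names]


@dataclass
class ValidatedDataset:
    """A Ct matrix and annotation restricted to their common samples."""

    ct: CtMatrix
    ann: SampleAnnotation
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_sizes:
            self.group_sizes = self.ann.group_sizes


def read_ct_matrix(
    path,
    undetected_token: str = DEFAULT_UNDETECTED_TOKEN,
    ct_max: float = 40.0,
) -> CtMatrix:
    """Read a delimited Ct matrix (rows = miRNAs, header row = sample ids).

    Delimiter (tab or comma) is auto-detected.  Cells equal to
    ``undetected_token`` (case-insensitive) or >= ``ct_max`` become
    undetected.  Parsing is locale-independent (dot decimal separator).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    delim = "\t" if "\t" in header else ","
    sample_ids = header.split(delim)[1:]
    dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dups:
        raise ValueError(f"duplicate sample ids in header: {dups}")
    raw = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ValueError(f"no miRNAs in {path}")
    if raw.shape[1] == 0:
        raise ValueError(f"no samples in {path}")
    token = undetected_token.strip().lower()

    def _parse(cell: str, mirna: str, sample: str) -> float:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        s = str(cell).strip()
        if s == "" or s.lower() in (token, "nan", "na"):
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValueError(
                f"non-numeric Ct value {s!r} at miRNA {mirna!r}, sample {sample!r}"
            ) from None

    parsed = pd.DataFrame(
        [
            [_parse(raw.iat[i, j], raw.index[i], raw.columns[j]) for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index.astype(str),
        columns=raw.columns.astype(str),
        dtype=float,
    )
    return CtMatrix(parsed, ct_max=ct_max)


def write_ct_matrix(
    ct: CtMatrix,
    path,
    undetected_token: str = DEFAULT_UNDETECTED_TOKEN,
    sep: str = "\t",
) -> None:
    """Write a Ct matrix as TSV; undetected wells become the sentinel token.

    Float cells are written with repr-round-trip precision so that
    write→read is the identity on valid matrices.
    """
    out = ct.values.map(lambda v: undetected_token if pd.isna(v) else repr(float(v)))
    out.index.name = "mirna_id"
    out.to_csv(path, sep=sep)


def read_sample_annotation(path) -> SampleAnnotation:
    """Read a delimited annotation table with columns sample_id and group.

    Group tokens are case-insensitive; any additional columns are kept
    as covariates (missing entries stay missing).
    """
    tab = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in tab.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise ValueError("annotation needs 'sample_id' and 'group' columns")
    tab = tab.rename(columns={cols["sample_id"]: "sample_id", cols["group"]: "group"})
    tab["sample_id"] = tab["sample_id"].astype(str)
    tab = tab.set_index("sample_id")
    return SampleAnnotation(tab)


def write_sample_annotation(ann: SampleAnnotation, path, sep: str = "\t") -> None:
    out = ann.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


def validate_dataset(ct: CtMatrix, ann: SampleAnnotation) -> ValidatedDataset:
    """Intersect sample sets and align the annotation to the matrix order.

    Samples present in only one input are dropped with a log message;
    an empty intersection is a hard error.  Idempotent.
    """
    common = [s for s in ct.sample_ids if s in set(ann.sample_ids)]
    if not common:
        raise ValueError("no samples shared between Ct matrix and annotation")
    dropped_ct = sorted(set(ct.sample_ids) - set(common))
    dropped_ann = sorted(set(ann.sample_ids) - set(common))
    for s in dropped_ct:
        logger.info("dropping sample %s (in Ct matrix but not annotated)", s)
    for s in dropped_ann:
        logger.info("dropping sample %s (annotated but absent from Ct matrix)", s)
    ct2 = CtMatrix(ct.values[common], ct_max=ct.ct_max)
    ann2 = SampleAnnotation(ann.table.loc[common])
    return ValidatedDataset(ct=ct2, ann=ann2)
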