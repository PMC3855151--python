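"""Detection filtering and reference-gene normalization.

Relative expression follows the standard comparative-Ct model: for
miRNA i in sample s with reference assay r (U6 for plasma,
hsa-miR-24 for microparticle RNA),

    expr[i, s] = 2 ** -(Ct[i, s] - Ct[r, s])

which is dimensionless and positive wherever the target is detected.
Downstream statistics operate on log10(expr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Relative expression (2^-dCt) with an optional log10 view.

    ``expr`` is strictly positive where defined; undetected wells
    propagate as NaN and are never imputed here.
    """

    expr: pd.DataFrame
    reference_id: str
    log10_expr: pd.DataFrame | None = None

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)


def detection_filter(ct: CtMatrix, min_detected: int, ct_max: float | None = None) -> CtMatrix:
    """Keep miRNAs detected (Ct < ct_max) in at least ``min_detected`` samples.

    The derivation-cohort rule is 21 of 26 samples.  Sample order is
    preserved; the result may be empty (logged, not an error).
    """
    n = len(ct.sample_ids)
    if not 1 <= min_detected <= n:
        raise ValueError(f"min_detected must be in [1, {n}], got {min_detected}")
    if ct_max is not None and ct_max < ct.ct_max:
        mask = (ct.values < ct_max).sum(axis=1)
    else:
        mask = ct.detection_counts()
    keep = mask >= min_detected
    if not keep.any():
        logger.warning("detection filter removed every miRNA")
    return CtMatrix(ct.values.loc[keep], ct_max=ct.ct_max)


def normalize_to_reference(
    ct: CtMatrix, reference_id: str, drop_reference: bool = True
) -> ExpressionMatrix:
    """Comparative-Ct normalization: expr = 2^-(Ct[miRNA] - Ct[reference]).

    The reference assay must be detected in every sample; wells that are
    undetected for the target stay missing in the output.  The reference
    row (identically 1 after normalization) is dropped by default.
    """
    if reference_id not in ct.values.index:
        raise ValueError(f"reference assay {reference_id!r} not present in Ct matrix")
    ref = ct.values.loc[reference_id]
    bad = ref[ref.isna()].index.tolist()
    if bad:
        raise ValueError(f"reference {reference_id!r} undetected in sample(s): {bad}")
    expr = np.power(2.0, -(ct.values.sub(ref, axis=1)))
    if drop_reference:
        expr = expr.drop(index=reference_id)
    em = ExpressionMatrix(expr=expr, reference_id=reference_id)
    return log_transform(em)


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Fill the log10 view of relative expression; missing stays missing."""
    vals = em.expr
    if ((vals <= 0) & vals.notna()).any().any():
        raise ValueError("expression values must be positive for log transform")
    em.log10_expr = np.log10(vals)
    return em


def write_expression_matrix(em: ExpressionMatrix, path, log10: bool = False, sep: str = "\t") -> None:
    df = em.log10_expr if log10 else em.expr
    out = df.copy()
    out.index.name = "mirna_id"
    out.to_csv(path, sep=sep, na_rep="NA")
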