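import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from mirsig.io import CtMatrix, SampleAnnotation
from mirsig.preprocess import ExpressionMatrix, log_transform


@pytest.fixture
def tiny_ct() -> CtMatrix:
    """3 miRNAs x 4 samples with one undetected well and a stable reference."""
    vals = pd.DataFrame(
        {
            "S1": [30.0, 28.0, 25.0],
            "S2": [31.0, np.nan, 25.1],
            "S3": [29.5, 27.5, 24.9],
            "S4": [30.5, 28.5, 25.0],
        },
        index=["miR-a", "miR-b", "U6"],
    )
    return CtMatrix(vals)


@pytest.fixture
def two_group_ann() -> SampleAnnotation:
    tab = pd.DataFrame(
        {
            "group": ["UA", "UA", "CONTROL", "CONTROL"],
            "age": [60, 62, 55, 58],
            "sex": [1, 0, 1, 0],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return SampleAnnotation(tab)


def make_expression(case: np.ndarray, control: np.ndarray, n_samples_case=None) -> ExpressionMatrix:
    """One-miRNA expression matrix from explicit log10 group values."""
    vals = np.concatenate([case, control])
    cols = [f"C{i}" for i in range(len(case))] + [f"K{i}" for i in range(len(control))]
    log10 = pd.DataFrame([vals], index=["m1"], columns=cols)
    em = ExpressionMatrix(expr=10.0**log10, reference_id="U6")
    return log_transform(em)


@pytest.fixture
def expr_from_log10():
    return make_expression
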