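import numpy as np
import pytest
from hypothesis import settings

from degrerank import ExpressionMatrix, PhenotypeLabels

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with easily hand-checked group means."""
    values = np.array(
        [
            [1.0, 1.0, 3.0, 3.0],   # log_fc = +2 (pos = s3, s4)
            [5.0, 5.0, 5.0, 5.0],   # constant
            [4.0, 2.0, 1.0, 1.0],   # log_fc = -2
        ]
    )
    return ExpressionMatrix(("gA", "gB", "gC"), ("s1", "s2", "s3", "s4"), values)


@pytest.fixture
def tiny_labels() -> PhenotypeLabels:
    return PhenotypeLabels(
        ("s1", "s2", "s3", "s4"), ("ctrl", "ctrl", "case", "case"), "case"
    )


def balanced_labels(n: int, n_pos: int, seed: int = 0) -> PhenotypeLabels:
    rng = np.random.default_rng(seed)
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, n_pos, replace=False)] = True
    return PhenotypeLabels(
        tuple(f"s{i}" for i in range(n)),
        tuple("case" if f else "ctrl" for f in flags),
        "case",
    )
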