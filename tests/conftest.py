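import numpy as np
import pytest

from anninfer import ExpressionMatrix, PhenotypeLabels, generate_truth, simulate_expression


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples with hand-set values."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [0.5, 0.5, 1.5, 1.5],
        [-1.0, 0.0, 1.0, 2.0],
    ])
    return ExpressionMatrix(["PA", "PB", "PC"], ["S1", "S2", "S3", "S4"], values)


@pytest.fixture
def tiny_labels():
    return PhenotypeLabels(["S1", "S2", "S3", "S4"], [0, 0, 1, 1])


@pytest.fixture
def small_cohort():
    """20 probes x 120 samples with 5 associated probes and 4 planted edges."""
    truth = generate_truth(20, 5, 4, seed=11)
    matrix, labels = simulate_expression(truth, 120, seed=12)
    return truth, matrix, labels
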