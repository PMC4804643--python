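import numpy as np
import pytest

from crtpredict import (
    BinaryContrast,
    CohortDataset,
    DworakLabels,
    ExpressionMatrix,
    SyntheticSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with a strongly planted signal (delta = 2 * sd)."""
    spec = SyntheticSpec(
        seed=42, n_genes=400, delta_to=2.0, delta_mi=2.0,
        n_planted_to=40, n_planted_mi=40,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def to_contrast():
    return BinaryContrast("TO")


@pytest.fixture(scope="session")
def mi_contrast():
    return BinaryContrast("MI")


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples, deterministic values."""
    return ExpressionMatrix(
        gene_ids=("GA", "GB", "GC"),
        sample_ids=("S1", "S2", "S3", "S4"),
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 6.0, 7.0, 8.0],
                [2.5, 2.5, 2.5, 2.5],
            ]
        ),
    )


def make_labeled_toy(
    n_per_class=(6, 6), noise_sd=0.01, seed=0, target="TO", other_grade="MO"
):
    """Cohort whose first gene encodes the class label almost perfectly."""
    rng = np.random.default_rng(seed)
    n_pos, n_neg = n_per_class
    n = n_pos + n_neg
    samples = tuple(f"T{i}" for i in range(n))
    grades = (target,) * n_pos + (other_grade,) * n_neg
    flag = np.array([1.0] * n_pos + [0.0] * n_neg)
    values = np.vstack(
        [
            flag + rng.normal(0, noise_sd, n),
            rng.normal(5, 1, n),
            rng.normal(8, 1, n),
        ]
    )
    expr = ExpressionMatrix(("FLAG", "NOISE1", "NOISE2"), samples, values)
    return CohortDataset(expr, DworakLabels(samples, grades))
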