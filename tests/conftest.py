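import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from unbalanced_anova import DesignCounts, SampleData, balanced_design, study_designs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: canonical base seed of every seeded test
SEED = 0


@pytest.fixture(scope="session")
def balanced10() -> DesignCounts:
    return balanced_design(10)


@pytest.fixture(scope="session")
def designs34() -> list[DesignCounts]:
    return study_designs(10)


def random_small_sample(rng: np.random.Generator, max_per_cell: int = 6) -> SampleData:
    """A random unbalanced 2x2 sample with 2..max_per_cell subjects per cell."""
    counts = rng.integers(2, max_per_cell + 1, size=4)
    cell_effects = rng.normal(0.0, 3.0, size=4)
    a = np.repeat([0, 0, 1, 1], counts)
    b = np.repeat([0, 1, 0, 1], counts)
    y = np.repeat(cell_effects, counts) + rng.normal(0.0, 1.0, counts.sum())
    return SampleData.from_arrays(a, b, y)


def projection_regression_ss(columns: list[np.ndarray], y: np.ndarray) -> float:
    """Brute-force model SS about the grand mean via an explicit projection matrix.

    Independent of the engine: builds the subject-level design matrix
    with an intercept, projects y onto its column space with a
    pseudoinverse hat matrix, and measures the fitted scatter.
    """
    design = np.column_stack([np.ones_like(y)] + columns)
    hat = design @ np.linalg.pinv(design)
    fitted = hat @ y
    return float(((fitted - y.mean()) ** 2).sum())
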