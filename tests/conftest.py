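import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import biopriority as bp
from biopriority.registry import VariableRegistry, VariableSpec

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return bp.default_registry()


@pytest.fixture(scope="session")
def panel_weights():
    return bp.panel_weights()


@pytest.fixture(scope="session")
def toy_registry():
    """Three mixed-kind variables with hand-checkable impact shares."""
    return VariableRegistry(
        (
            VariableSpec(
                id="Sev3",
                kind="ordinal",
                levels=("low", "medium", "high"),
                impact_scores=(2, 5, 9),
            ),
            VariableSpec(
                id="Wait",
                kind="continuous",
                intervals=((0.0, 6.0), (6.0, 12.0), (12.0, 24.0)),
                impact_scores=(1, 3, 6),
            ),
            VariableSpec(id="Flag", kind="binary", binary_scores=(9, 1)),
        )
    )


@pytest.fixture(scope="session")
def synthetic_cohort(registry):
    """One seeded default-condition cohort with its ground truth and alpha."""
    config = bp.SynthesisConfig(seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truth = bp.generate_cohort(config, registry)
    alpha = bp.build_alpha_matrix(cohort, registry)
    return cohort, truth, alpha


@pytest.fixture(scope="session")
def scored_cohort(synthetic_cohort, panel_weights):
    cohort, truth, alpha = synthetic_cohort
    scores = bp.priority_score(panel_weights, alpha)
    return cohort, truth, alpha, scores


def make_blobs_3(seed: int = 0, n_per: int = 15, spread: float = 0.02):
    """Three tight, well-separated point clouds in 4-D."""
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[0.1, 0.1, 0.1, 0.1], [0.5, 0.9, 0.5, 0.9], [0.9, 0.2, 0.9, 0.2]]
    )
    X = np.vstack(
        [c + rng.normal(0, spread, size=(n_per, 4)) for c in centers]
    )
    labels = np.repeat(np.arange(3), n_per)
    return X, labels
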