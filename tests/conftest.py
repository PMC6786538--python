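import numpy as np
import pytest

from hmmselect import (
    ConditionTensor,
    ExperimentDesign,
    HMMParameters,
)


@pytest.fixture
def two_condition_design() -> ExperimentDesign:
    return ExperimentDesign(
        time_points=(0.0, 2.0, 6.0, 12.0),
        conditions=("control", "case"),
        replicates=2,
        control="control",
    )


@pytest.fixture
def small_tensors(two_condition_design) -> list[ConditionTensor]:
    """Deterministic 4-feature, 2-replicate, 4-time-point pair of tensors."""
    rng = np.random.default_rng(42)
    ids = ("gA", "gB", "gC", "gD")
    return [
        ConditionTensor(cond, rng.normal(5.0, 1.0, size=(4, 2, 4)), ids)
        for cond in two_condition_design.conditions
    ]


def random_parameters(rng: np.random.Generator, r: int) -> HMMParameters:
    """Random but valid two-state parameters for oracle comparisons."""
    initial = rng.dirichlet([1.0, 1.0])
    transition = np.vstack([rng.dirichlet([2.0, 1.0]), rng.dirichlet([1.0, 2.0])])
    means = rng.normal(0.0, 0.5, size=(2, r))
    covs = []
    for _ in range(2):
        a = rng.normal(0.0, 1.0, size=(r, r))
        covs.append(a @ a.T + np.eye(r) * 0.5)
    return HMMParameters(initial, transition, means, np.stack(covs))
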