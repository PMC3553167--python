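import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sexalloc import (
    AllocationCurve,
    LifeHistoryModel,
    OffspringSurvivalCurve,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def power_model(delta: float, c0: float = 0.5, E0: float = 0.8, k: float = 0.5,
                P: float = 0.5, M: float = 10.0,
                family: str = "exponential") -> LifeHistoryModel:
    """Constant-elasticity model with the package's default life history."""
    return LifeHistoryModel(
        P=P,
        M=M,
        allocation=AllocationCurve(family=family, E0=E0, k=k),
        survival=OffspringSurvivalCurve(family="power", c0=c0, delta=delta),
    )


@pytest.fixture
def default_model() -> LifeHistoryModel:
    """Exponential allocation (E0=0.8, k=0.5), power survival (c0=0.5, delta=1)."""
    return power_model(delta=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
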