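import numpy as np
import pytest

from fbnoise.kinetics import RegulatoryFunction


def make_linear_activation_positive(a: float, b: float, s: float, r: float) -> RegulatoryFunction:
    """Increasing regulatory form c(x) = (a x s + b r) / (a x + b)."""

    def c_fn(x):
        x = np.asarray(x, dtype=float)
        return (a * x * s + b * r) / (a * x + b)

    return RegulatoryFunction(
        c_fn=c_fn, declared_topology="positive", lo=min(r, s), hi=max(r, s)
    )


def make_linear_inactivation_negative(a: float, b: float, s: float, r: float) -> RegulatoryFunction:
    """Decreasing regulatory form c(x) = (a s + b x r) / (a + b x)."""

    def c_fn(x):
        x = np.asarray(x, dtype=float)
        return (a * s + b * x * r) / (a + b * x)

    return RegulatoryFunction(
        c_fn=c_fn, declared_topology="negative", lo=min(r, s), hi=max(r, s)
    )


@pytest.fixture(scope="session")
def hill_negative():
    from fbnoise.kinetics import hill_regulatory_function

    return hill_regulatory_function(a=50.0, s=100.0, r=5.0, h=2.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170913)
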