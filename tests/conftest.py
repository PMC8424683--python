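import numpy as np
import pytest

from pharmglass.components import PureComponent


@pytest.fixture
def simple_pair() -> tuple[PureComponent, PureComponent]:
    """A generic binary pair with well-separated melting points."""
    return (
        PureComponent("A", 100.0, 400.0, 25000.0, glass_tg=320.0),
        PureComponent("B", 120.0, 350.0, 20000.0, glass_tg=280.0),
    )


@pytest.fixture
def simple_triple(simple_pair) -> tuple[PureComponent, ...]:
    a, b = simple_pair
    return a, b, PureComponent("C", 150.0, 380.0, 30000.0, glass_tg=300.0)


def random_component(rng: np.random.Generator, name: str = "X") -> PureComponent:
    """Random but physically plausible component constants."""
    return PureComponent(
        name,
        molar_mass=float(rng.uniform(100.0, 600.0)),
        melt_temperature=float(rng.uniform(300.0, 500.0)),
        fusion_enthalpy=float(rng.uniform(10000.0, 60000.0)),
    )
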