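import numpy as np
import pytest

from gait2dft import (
    SpectralParams,
    default_session_spec,
    generate_session,
    magnitude,
)


@pytest.fixture(scope="session")
def params() -> SpectralParams:
    return SpectralParams()


@pytest.fixture(scope="session")
def separated_session():
    """Seeded session with well-separated cadences (1.4/1.9/2.4 steps/s)."""
    spec = default_session_spec(seed=1, cadences=(1.4, 1.9, 2.4))
    rec, selections = generate_session(spec)
    return magnitude(rec), selections


@pytest.fixture(scope="session")
def training_database(separated_session, params):
    """High-density 300-row 2DFT training database of the seeded session."""
    from gait2dft import build_high_density_matrix

    series, selections = separated_session
    return build_high_density_matrix(series, selections, params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
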