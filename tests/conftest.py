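import pytest

from antnest import CohesionParams, ModelParams


@pytest.fixture
def baseline() -> ModelParams:
    """Baseline two-site setting: N=100, quorum 0.5N, alpha=alpha_s=0.1,
    alpha_leak=0.05, H=0.2, z=0.3."""
    return ModelParams()


@pytest.fixture
def cohesion_baseline() -> CohesionParams:
    return CohesionParams()
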