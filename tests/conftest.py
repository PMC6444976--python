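import pytest

import gelstream as gs

#: Zero-field thermal diffusivity used in Monte-Carlo consistency runs,
#: cm^2/s — realistic for sub-10-kbp dsDNA in 1.2% agarose.
DIFFUSION_CM2_S = 2e-8


@pytest.fixture(scope="session")
def fixture_model() -> gs.MobilityModel:
    return gs.synthetic_mobility_model()


@pytest.fixture(scope="session")
def chamber() -> gs.ChamberSpec:
    return gs.ChamberSpec()


@pytest.fixture(scope="session")
def paper_protocol() -> gs.FieldProtocol:
    """Highest-resolution operating point: 59.5/22.4 V/cm, ~90 deg apart, 2 Hz."""
    return gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 2.0)


@pytest.fixture(scope="session")
def fragments5() -> list[gs.FragmentSpec]:
    return [gs.FragmentSpec(L) for L in (500, 1000, 2000, 5000, 10000)]
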