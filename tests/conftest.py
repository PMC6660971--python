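import numpy as np
import pytest

from radrep.synthetic import NoduleSpec, generate_case


@pytest.fixture(scope="session")
def sphere_case():
    """Clean 10 mm sphere on an anisotropic grid (no texture, light noise)."""
    spec = NoduleSpec(center=(16.8, 16.8, 16.0), equivalent_diameter=10.0,
                      texture_amplitude=0.0, margin_width=0.5)
    return generate_case(spec, (0.7, 0.7, 2.0), (49, 49, 17), noise_sd=5.0,
                         rng=np.random.default_rng(1), case_id="sphere10"), spec


@pytest.fixture(scope="session")
def textured_case():
    """Large textured isotropic nodule: every feature family computable."""
    spec = NoduleSpec(center=(24.0, 24.0, 24.0), equivalent_diameter=19.0,
                      texture_amplitude=50.0, margin_width=1.0)
    return generate_case(spec, (0.6, 0.6, 0.6), (81, 81, 81), noise_sd=10.0,
                         rng=np.random.default_rng(3), case_id="big19")


@pytest.fixture(scope="session")
def tiny_case():
    """4 mm nodule whose neighbourhood texture features must fail."""
    spec = NoduleSpec(center=(14.2, 14.2, 14.0), equivalent_diameter=4.0,
                      texture_amplitude=20.0, margin_width=0.5)
    return generate_case(spec, (0.7, 0.7, 2.0), (41, 41, 15), noise_sd=10.0,
                         rng=np.random.default_rng(4), case_id="tiny4")
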