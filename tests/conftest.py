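import numpy as np
import pytest

from glycurate.synth import GlycositeSpec, make_glycosite, make_link_cases


def ideal_chair(z0: float = 0.25) -> np.ndarray:
    """Regular hexagon with alternating +-z0 displacements (ideal 4C1)."""
    k = np.arange(6)
    return np.stack([np.cos(np.radians(60.0 * k)),
                     np.sin(np.radians(60.0 * k)),
                     z0 * (-1.0) ** k], axis=1)


@pytest.fixture(scope="session")
def glycosite_bundle():
    """A clean core-5 glycosite: (truth model, observed map, working model)."""
    return make_glycosite(GlycositeSpec(seed=11, noise_sd=0.1))


@pytest.fixture(scope="session")
def cropped_glycosite():
    """Same site with the whole tree cropped from the working model."""
    return make_glycosite(GlycositeSpec(seed=11, noise_sd=0.1, crop="all"))


@pytest.fixture(scope="session")
def link_battery():
    return make_link_cases(seed=0)
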