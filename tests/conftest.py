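import numpy as np
import pytest

from mutscale.synthetic_data import gen_strain_panel, preset


@pytest.fixture(scope="session")
def m63_panel():
    """One default M63 strain panel (10 strains, 96 cultures, Nt=1e9)."""
    return gen_strain_panel(preset("M63"), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
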