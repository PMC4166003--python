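import numpy as np
import pytest

from snarefold.presets import make_preset


@pytest.fixture(scope="session")
def neuronal():
    return make_preset("neuronal")


@pytest.fixture(scope="session")
def glut4():
    return make_preset("glut4")


@pytest.fixture(scope="session")
def all_presets():
    return {name: make_preset(name) for name in ("neuronal", "glut4", "endosomal", "yeast")}


@pytest.fixture(scope="session")
def neuronal_ctd_scan(neuronal):
    """Simulated constant-separation scan of the neuronal CTD transition:
    7 separations spanning p = 0.1-0.9, 10 s each at 10 kHz, analysed with
    the two-state HMM.  Shared by the round-trip tests."""
    from snarefold.hmm import analyze_separation_scan
    from snarefold.simulate import simulate_constant_separation

    seps = neuronal.ctd.suggested_separations(7)
    trajs = [
        simulate_constant_separation(neuronal.ctd, d, 10.0, seed=20140 + i)
        for i, d in enumerate(seps)
    ]
    return analyze_separation_scan(trajs)
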