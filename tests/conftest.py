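import numpy as np
import pytest

from odontomech import synthetic as syn


@pytest.fixture(scope="session")
def cone_mesh():
    """Reference cone: height 4, radius 1, 512 segments, apex on +z."""
    return syn.make_cone(4.0, 1.0, 512)


@pytest.fixture(scope="session")
def cone_exact_area():
    """Closed-form area of the reference cone: lateral + base disk."""
    return np.pi * 1.0 * np.sqrt(17.0) + np.pi * 1.0 ** 2


@pytest.fixture()
def jaw_spec():
    return syn.JawSpec()


@pytest.fixture()
def jaw(jaw_spec):
    """Default 10-cone jaw: (meshes, landmarks, ground-truth table)."""
    return syn.make_jaw(jaw_spec)
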