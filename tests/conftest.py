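import numpy as np
import pytest

import propriodemix as pdx

# Published spindle gain-matrix entries and scalar force gains used
# throughout the suite as the generating ("true") encoder parameters.
K_TRUE = dict(k11=337.8, k12=33.6, k21=182.8, k22=4.9)
KF_II = 182.8
KF_IB = 128.8


@pytest.fixture(scope="session")
def protocol():
    return pdx.StretchProtocol()


@pytest.fixture(scope="session")
def trials(protocol):
    return pdx.generate_protocol(protocol)


@pytest.fixture(scope="session")
def trial15(trials):
    """First repetition of the 15 mm/s ramp–hold–release."""
    tr = next(t for t in trials if t.velocity_label == 15.0 and t.rep_index == 0)
    return tr


@pytest.fixture(scope="session")
def forces15(trial15):
    return pdx.simulate_forces(trial15, pdx.MuscleParams())


@pytest.fixture(scope="session")
def rates15(forces15):
    """Noiseless Ia/II/Ib rates for the 15 mm/s trial, published default gains."""
    return {cls: pdx.encode_afferent(forces15, params, velocity_label=15.0)
            for cls, params in (("Ia", pdx.IA_DEFAULT),
                                ("II", pdx.II_DEFAULT),
                                ("Ib", pdx.IB_DEFAULT))}


def constant_rate(value, duration=1.0, dt=1e-3, afferent_class=None):
    t = np.arange(int(duration / dt) + 1) * dt
    return pdx.RateTrace(t, np.full(t.size, float(value)), afferent_class)
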