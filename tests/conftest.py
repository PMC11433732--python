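import numpy as np
import pytest

from ehrpk.engine import simulate_group
from ehrpk.parameters import load_parameter_set


@pytest.fixture(scope="session")
def healthy_params():
    return load_parameter_set("healthy")


@pytest.fixture(scope="session")
def group_sims():
    """120-h production-resolution simulations for all three groups."""
    return {
        g: simulate_group(g, rtol=1e-7, atol=1e-10)
        for g in ("healthy", "moderate", "severe")
    }


@pytest.fixture(scope="session")
def healthy_sim(group_sims):
    return group_sims["healthy"]


def auc(result, analyte, t0=0.0, t1=None):
    t, c = result.t, result.conc[analyte]
    t1 = t[-1] if t1 is None else t1
    m = (t >= t0) & (t <= t1)
    return float(np.trapezoid(c[m], t[m]))
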