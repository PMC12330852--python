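import numpy as np
import pytest

from loresd.estimator import FitConfig
from loresd.response import assemble_response, build_dictionary
from loresd.scheme import ShellSignal
from loresd.simulate import (
    DEFAULT_KERNEL,
    default_scheme,
    ground_truth_odf,
    ground_truth_response,
    simulate_signal,
)


@pytest.fixture(scope="session")
def scheme():
    """The 3-shell acquisition used throughout: b = 0/1/2 ms/um^2, 5/128/128."""
    return default_scheme()


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture(scope="session")
def dictionary(scheme, fit_config):
    return build_dictionary(fit_config.grid, scheme, fit_config.lmax)


@pytest.fixture(scope="session")
def table1_phantom(scheme):
    """Noise-free single-fibre voxel built from the default three-compartment kernel."""
    H = ground_truth_response(DEFAULT_KERNEL, scheme)
    p = ground_truth_odf(0.0)
    s = simulate_signal(H, p, scheme)
    return {"H": H, "p": p, "signal": s}


@pytest.fixture(scope="session")
def ongrid_phantom(scheme, fit_config, dictionary):
    """Noise-free phantom whose ground truth lies exactly on grid nodes.

    Mimics the default composition with each compartment snapped to its
    nearest grid node, so the mixture model can represent the signal exactly.
    """
    nodes = fit_config.grid.nodes

    def nearest(lpar, lperp):
        return int(np.argmin(np.abs(nodes[:, 0] - lpar) + np.abs(nodes[:, 1] - lperp)))

    f = np.zeros(len(nodes))
    f[nearest(2.2, 0.0)] += 0.45
    f[nearest(2.0, 0.7)] += 0.45
    f[nearest(3.0, 3.0)] += 0.10
    H = assemble_response(f, dictionary, 1.0)
    out = {}
    for angle in (0.0, 60.0):
        p = ground_truth_odf(angle)
        s = simulate_signal(H, p, scheme)
        out[angle] = {"f": f, "H": H, "p": p, "signal": s,
                      "sig": ShellSignal.from_amplitudes(s, scheme, 8)}
    return out
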