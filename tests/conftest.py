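import numpy as np
import pytest

from netinfer import netsim
from netinfer.deconv import build_linear_system


@pytest.fixture(scope="session")
def small_instance():
    """A 20-node weighted scale-free network with its exact closure."""
    A = netsim.sample_scale_free(20, 2.2, 40, seed=1)
    S0 = netsim.assign_weights(A, seed=2)
    G0 = netsim.total_influence_closure(S0)
    return S0, G0


@pytest.fixture(scope="session")
def noisy_instance(small_instance):
    S0, G0 = small_instance
    G, dG = netsim.add_noise(G0, netsim.NoiseSpec("proportional", 0.3, seed=3))
    return S0, G0, G, dG


@pytest.fixture(scope="session")
def mm_ensemble():
    """A 7-node Michaelis-Menten perturbation ensemble (node 1 unregulated)."""
    rng = np.random.default_rng(0)
    A = netsim.sample_scale_free(7, 2.2, 10, seed=3)
    A[0, :] = 0  # node 1 has no incoming arcs
    S0 = netsim.assign_weights(A, (0.5, 1.0), "positive", False, seed=4)
    system = netsim.MMSystem(S0=S0, degradation=np.ones(7), x0=rng.uniform(0.8, 1.2, 7))
    times = np.arange(0.0, 4.001, 0.1)
    ens = netsim.perturb_and_simulate(system, times, 0.1, 1e-4, seed=5)
    return system, ens
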