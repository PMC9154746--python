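import numpy as np
import pytest

import golgicode as gc


@pytest.fixture(scope="session")
def target3():
    """Wide-peaked 3-component mixture target on Ns=100."""
    return gc.make_gmm_target(gc.random_mixture_spec(3, Ns=100, seed=5))


@pytest.fixture(scope="session")
def target20():
    """Narrow-peaked 20-component mixture target on Ns=200."""
    return gc.make_gmm_target(gc.random_mixture_spec(20, Ns=200, seed=7))


@pytest.fixture(scope="session")
def system33():
    return gc.GolgiSystem(NC=3, NE=3, Ns=100)


@pytest.fixture(scope="session")
def opt33(system33, target3):
    """Sigma scan + optimum at (NE, NC) = (3, 3) on the 3-component target,
    shared by the landscape and swap analyses."""
    scan = gc.scan_sigma(system33, target3, [0.1, 0.25, 0.5, 1.0],
                         n_starts=6, seed=3, maxiter=150)
    best = scan.results[int(np.nanargmin(scan.Dbar))]
    return scan, best


def random_params(system: gc.GolgiSystem, sigma: float, seed: int) -> gc.ParameterSet:
    """In-bounds random parameter draw (log-uniform rates)."""
    rng = np.random.default_rng(seed)
    return gc.ParameterSet(
        mu=np.exp(rng.uniform(*np.log(system.mu_bounds), system.NC)),
        R=np.exp(rng.uniform(*np.log(system.R_bounds), (system.NE, system.NC))),
        L=rng.uniform(1.0, system.Ns, (system.NE, system.NC)),
        sigma=sigma,
    )
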