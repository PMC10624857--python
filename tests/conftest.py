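import numpy as np
import pytest

from selindex import RCBDTrial, SimulationSpec, simulate_rcbd_trial, worked_fixture


@pytest.fixture(scope="session")
def fixture2():
    """(panel, P, G, a) two-trait worked example with hand-checked values."""
    return worked_fixture()


@pytest.fixture
def tiny_trial():
    """2 genotypes x 2 reps, one trait; hand ANOVA: MS_g=16, MS_e=0."""
    return RCBDTrial(["A", "B", "A", "B"], ["r1", "r1", "r2", "r2"],
                     np.array([[10.0], [14.0], [12.0], [16.0]]), ["t"])


def random_spd(rng, m, scale=1.0):
    """Random symmetric positive-definite matrix with bounded conditioning."""
    A = rng.standard_normal((m, m))
    return scale * (A @ A.T + m * np.eye(m))


@pytest.fixture
def spd_factory():
    return random_spd


@pytest.fixture(scope="session")
def sim4():
    """Simulated 4-trait RCBD trial (n=120, r=3) with its ground truth."""
    rng = np.random.default_rng(7)
    G = random_spd(rng, 4, scale=2.0)
    E = random_spd(rng, 4, scale=1.0)
    spec = SimulationSpec(G_true=G, E_true=E, mu=np.array([50.0, 20.0, 10.0, 5.0]),
                          n_genotypes=120, n_reps=3, seed=99)
    trial, truth = simulate_rcbd_trial(spec)
    return spec, trial, truth
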