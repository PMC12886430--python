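import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sameness as sn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# -- independent brute-force oracles (direct double summation) -----------


def oracle_entropy(probs) -> float:
    return -sum(p * np.log2(p) for p in np.ravel(probs) if p > 0)


def oracle_conditional(mat: np.ndarray, direction: str) -> float:
    """H(X|Y) by explicit summation over joint cells."""
    mat = np.asarray(mat, float)
    h = 0.0
    if direction == "R_given_M":
        py = mat.sum(axis=0)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                if mat[i, j] > 0:
                    h -= mat[i, j] * np.log2(mat[i, j] / py[j])
    else:
        px = mat.sum(axis=1)
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                if mat[i, j] > 0:
                    h -= mat[i, j] * np.log2(mat[i, j] / px[i])
    return h


def random_joint(rng: np.random.Generator, nr: int = 3, nm: int = 3) -> sn.JointDistribution:
    mat = rng.dirichlet(np.ones(nr * nm)).reshape(nr, nm)
    return sn.JointDistribution(range(nr), [f"m{j}" for j in range(nm)], mat)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def chain_env():
    return sn.generate_environment(sn.preset_spec("chain"))


@pytest.fixture(scope="session")
def branching_env():
    return sn.generate_environment(sn.preset_spec("branching"))


@pytest.fixture(scope="session")
def nonstationary_env():
    return sn.generate_environment(sn.preset_spec("nonstationary"))


@pytest.fixture(scope="session")
def chain_memory(chain_env):
    """Memory of a learn-policy agent after fully memorizing the chain."""
    cfg = sn.AgentConfig(policy="learn")
    return sn.run_episode(cfg, chain_env, 40, seed=6).memory


@pytest.fixture(scope="session")
def nonstat_memory():
    """Memory trained on the nonstationary preset's base structure (no novelty)."""
    spec = sn.preset_spec("nonstationary").model_copy(update={"novelty_rate": 0.0})
    env = sn.generate_environment(spec)
    cfg = sn.AgentConfig(policy="learn")
    return sn.run_episode(cfg, env, 200, seed=5).memory
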