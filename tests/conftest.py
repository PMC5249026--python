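import numpy as np
import pytest

from snoscout.config import PipelineConfig
from snoscout.folding import MaxPairEngine, ViennaEngine
from snoscout.synthetic import GeneratorConfig, default_pwms, gen_cd, gen_haca

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(list(RNA), size=length, p=p))


@pytest.fixture(scope="session")
def maxpair():
    return MaxPairEngine()


@pytest.fixture(scope="session")
def vienna():
    return ViennaEngine()


@pytest.fixture(scope="session")
def pwms():
    return default_pwms(seed=1)


@pytest.fixture()
def config():
    return PipelineConfig(n_shuffles=20)


@pytest.fixture(scope="session")
def small_haca():
    """30 canonical H/ACA records with ground truth."""
    return gen_haca(GeneratorConfig(seed=11, n=30))


@pytest.fixture(scope="session")
def small_cd():
    """30 canonical C/D records with ground truth."""
    return gen_cd(GeneratorConfig(seed=11, n=30))
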