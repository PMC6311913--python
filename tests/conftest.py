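import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stemloop as sl
from stemloop.pipeline import RunConfig, extract

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def property_table():
    return sl.load_property_table()


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 12+12 synthetic corpus on disk for IO / CLI tests."""
    out = tmp_path_factory.mktemp("corpus_small")
    cfg = sl.SynthConfig(n_pos=12, n_neg=12, seed=3)
    paths = sl.make_benchmark(cfg, out)
    return cfg, paths


@pytest.fixture(scope="session")
def benchmark_table(tmp_path_factory):
    """Extracted 591-column feature table of the default 50+50 corpus."""
    out = tmp_path_factory.mktemp("corpus_e2e")
    cfg = sl.SynthConfig(seed=0)
    paths = sl.make_benchmark(cfg, out)
    run = RunConfig(
        fasta=paths["fasta"],
        structures=paths["structures"],
        pssm_dir=paths["pssm_dir"],
        labels=paths["labels"],
    )
    return extract(run)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
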