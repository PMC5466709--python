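import numpy as np
import pytest
from hypothesis import settings

from otuflow import MockSpec, default_references, emit_paired_reads

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def refs10():
    return default_references(10)


@pytest.fixture(scope="session")
def refs21():
    return default_references(21)


@pytest.fixture(scope="session")
def clean_run(refs10):
    """Error-free, chimera-free simulated run: 300 pairs from 10 species."""
    spec = MockSpec(
        refs=refs10, n_fragments=300, sub_rate=0.0, ins_rate=0.0,
        del_rate=0.0, chimera_rate=0.0, seed=11,
    )
    pairs, truth = emit_paired_reads(spec)
    return spec, pairs, truth


@pytest.fixture(scope="session")
def noisy_run(refs10):
    """Realistic small run: substitutions at 1e-3, 5% chimeras."""
    spec = MockSpec(
        refs=refs10, n_fragments=1500, sub_rate=0.001, chimera_rate=0.05,
        seed=23,
    )
    pairs, truth = emit_paired_reads(spec)
    return spec, pairs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(987)
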