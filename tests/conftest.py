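import pytest
from hypothesis import HealthCheck, settings

from notepheno.corpus_io import NoteRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")
from notepheno.context_library import starter_library
from notepheno.search import find_instances
from notepheno.synthgen import SimConfig, generate
from notepheno.textnorm import compile_pattern


@pytest.fixture
def pneumonia_pattern():
    return compile_pattern("pneumonia", ["pneumonia", "pna"])


@pytest.fixture
def small_corpus():
    """Hand-built three-patient corpus covering several context categories."""
    texts = {
        ("p1", "n1"): "Admitted with pneumonia. Vital signs stable overnight.",
        ("p1", "n2"): "pna resolving. pna on cxr",
        ("p2", "n3"): "There is no evidence of pneumonia today.",
        ("p3", "n4"): "History of pneumonia as a child. Labs reviewed.",
    }
    return [
        NoteRecord.build(pid, nid, text)
        for (pid, nid), text in texts.items()
    ]


@pytest.fixture
def starter_lib():
    return starter_library()


@pytest.fixture(scope="session")
def sim_default():
    """One 200-patient simulated study shared by read-only tests."""
    return generate(SimConfig(n_patients=200, seed=11))


@pytest.fixture
def small_db(small_corpus, pneumonia_pattern):
    return find_instances(small_corpus, pneumonia_pattern)
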