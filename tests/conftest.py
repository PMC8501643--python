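import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from manna import open_store
from manna.fixtures import make_synthetic_phage, make_terminase_db


FIXED_CLOCK = "2000-01-01T00:00:00Z"


@pytest.fixture
def store(tmp_path):
    with open_store(tmp_path / "store.sqlite", clock=lambda: FIXED_CLOCK) as s:
        yield s


@pytest.fixture
def phage(tmp_path):
    """A canonical synthetic phage genome on disk plus its ground truth."""
    fasta, truth = make_synthetic_phage(seed=42, n_genes=8, with_terminase="large")
    path = tmp_path / "phage.fasta"
    path.write_text(fasta)
    return path, truth


@pytest.fixture
def terminase_db():
    _, truth = make_synthetic_phage(seed=42, n_genes=8, with_terminase="large")
    return make_terminase_db(truth, seed=43)
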