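import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One full synthetic study at the standing conditions, shared across
    tests (the generator is deterministic for a fixed seed)."""
    from paleovar.synthetic import SimConfig, simulate_all

    out = tmp_path_factory.mktemp("sim")
    return simulate_all(SimConfig(), out, seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced configuration for tests that re-run the generator."""
    from paleovar.synthetic import SimConfig

    return SimConfig(length=800, n_pv=15, n_bv=25, n_vus=3, n_multibp=2,
                     n_indels=2, n_samples=6, coverage=6.0)


@pytest.fixture(scope="session")
def maf_index(sim_bundle):
    from paleovar.maf import MafIndex, read_maf

    blocks = read_maf(sim_bundle["paths"]["maf"])
    return MafIndex(blocks, "human")


@pytest.fixture
def single_exon_tm():
    """Plus-strand single-exon toy transcript: exon [1000,1200), CDS starting
    at transcript offset 10."""
    from paleovar.catalog import TranscriptModel

    return TranscriptModel("toy+", "chr1", "+", ((1000, 1200),), 10, 200)


@pytest.fixture
def two_exon_tm():
    """Plus-strand two-exon transcript whose CDS position 211 is the last
    base of exon 1 (c.211+1 is the first intronic base)."""
    from paleovar.catalog import TranscriptModel

    return TranscriptModel("toy2+", "chr1", "+", ((0, 221), (321, 600)), 10, 500)
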