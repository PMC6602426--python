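import pytest
from hypothesis import HealthCheck, settings

from casdesign.enumeration import builtin_effectors

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")
from casdesign.fixtures import FixtureSpec, PlantedSite, build_fixture


@pytest.fixture(scope="session")
def effectors():
    return builtin_effectors()


@pytest.fixture(scope="session")
def cas9(effectors):
    return effectors["cas9"]


@pytest.fixture(scope="session")
def cas13a(effectors):
    return effectors["cas13a"]


@pytest.fixture(scope="session")
def standard_fixture():
    """Two two-isoform genes on a 12 kb contig, seeded."""
    return build_fixture(
        FixtureSpec(seed=3, contig_len=12_000, n_genes=2, isoforms_per_gene=2)
    )


@pytest.fixture(scope="session")
def spiked_fixture():
    """Genome with a Cas9 site planted twice exactly and once with 1 mismatch."""
    spacer = "ACGTTGCAGATCCGGATTCA"
    spec = FixtureSpec(
        seed=11,
        contig_len=20_000,
        planted_sites=(
            PlantedSite(spacer, n_copies=2, mismatches=0, motif="AGG"),
            PlantedSite(spacer, n_copies=1, mismatches=1, motif="TGG"),
        ),
    )
    return spacer, build_fixture(spec)
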