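import pytest
from hypothesis import HealthCheck, settings

import circprobe as cp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Standard synthetic study pair: 3 kb host, 600 nt target, three 16-mers
# copied from host into the target at recorded positions.
FIXTURE_SPEC = cp.FixtureSpec(
    host_length=3_000, target_length=600, n_planted_shared=3, seed=11
)


@pytest.fixture(scope="session")
def fixture_pair():
    return cp.generate_pair(FIXTURE_SPEC)


@pytest.fixture(scope="session")
def set_index(fixture_pair):
    host, _, _ = fixture_pair
    return cp.build_host_index([host], backend="set")


@pytest.fixture(scope="session")
def bitmap_index(fixture_pair):
    host, _, _ = fixture_pair
    return cp.build_host_index([host], backend="bitmap")


@pytest.fixture(scope="session")
def host_kmer_strings(fixture_pair):
    """Naive oracle: the set of all 16-mer windows of the host, as strings."""
    host, _, _ = fixture_pair
    res = host.residues
    return {res[i : i + 16] for i in range(len(res) - 15)}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk FASTA pair for CLI tests."""
    out = tmp_path_factory.mktemp("fixture")
    cp.write_fixture(FIXTURE_SPEC, out)
    return out


@pytest.fixture(scope="session")
def index_file(fixture_dir, tmp_path_factory):
    """Bitmap index file produced through the CLI, shared across tests."""
    from click.testing import CliRunner

    from circprobe.cli import main

    out = tmp_path_factory.mktemp("index") / "host.roaidx"
    result = CliRunner().invoke(
        main,
        ["build-index", "--host", str(fixture_dir / "host.fa"), "--out", str(out)],
    )
    assert result.exit_code == 0, result.output
    return out
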