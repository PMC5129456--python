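import pytest

from orthocoal.synth import SyntheticScenario, simulate_fixture


@pytest.fixture(scope="session")
def fixture_scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def fixture_manifest(fixture_scenario, tmp_path_factory):
    """A complete synthetic input set (FASTA/VCF/clusters) plus ground truth."""
    outdir = tmp_path_factory.mktemp("fixture")
    return simulate_fixture(fixture_scenario, outdir)
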