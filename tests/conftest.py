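import pytest

from dgrscout import synthetic_data as sd


@pytest.fixture(scope="session")
def panel():
    return sd.reference_panel()


@pytest.fixture(scope="session")
def flagship():
    """The synthetic worked-example genome and its truth."""
    return sd.generate_flagship()


@pytest.fixture(scope="session")
def complete_genome():
    """One planted complete-cassette genome at generator defaults."""
    return sd.generate_genome_with_cassette(sd.CassetteSpec(seed=5))


@pytest.fixture(scope="session")
def anchor_refs(panel):
    return {label: panel["protein"][label] for label in ("TNP", "IHF", "T-CFP", "RT")}
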