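import pytest

from globinevo.synthetic import canonical_globin_fixture


@pytest.fixture(scope="session")
def globin_fixture():
    """(template, helix annotation) of the frozen 150-codon globin gene."""
    return canonical_globin_fixture()


@pytest.fixture(scope="session")
def vertebrate_gene(globin_fixture):
    """Fixture gene with the vertebrate neuroglobin intron pattern
    (B12.2 + E11.0 + G7.0: CDS junctions after nt 95, 204, 318)."""
    template, _ = globin_fixture
    return template.with_introns([95, 204, 318])
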