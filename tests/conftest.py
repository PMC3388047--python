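import pytest

from nesprintx.synthetic import SimConfig, make_gene, mini_nesprin_fixture


@pytest.fixture(scope="session")
def nesp1():
    return mini_nesprin_fixture("nesp1")


@pytest.fixture(scope="session")
def nesp2():
    return mini_nesprin_fixture("nesp2")


@pytest.fixture(scope="session")
def sim3():
    config = SimConfig(seed=3)
    model, truth, fasta_text, gff_text = make_gene(config)
    return config, model, truth, fasta_text, gff_text
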