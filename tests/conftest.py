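import pytest
from hypothesis import settings

from lditrends.corpus_model import Corpus, Publication
from lditrends.synthetic_corpus import GeneratorConfig, generate_corpus

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def hand_corpus() -> Corpus:
    """Small handcrafted corpus exercising fields and phrase boundaries."""
    pubs = [
        Publication(
            pub_id="P1",
            title="matrix optimization study",
            abstract="we analyzed small molecules with a new matrix",
            methods_text="samples were measured by MALDI-TOF mass spectrometry",
            pub_year=2015,
            cited_by_count=10,
        ),
        Publication(
            pub_id="P2",
            title="a proteomics workflow",
            abstract="MALDI imaging of peptides and proteins",
            methods_text="electrospray ionization was used for MS analysis",
            first_pub_date="2012-03-01",
            first_index_date="2013-01-01",
        ),
        Publication(
            pub_id="P3",
            title="polymer characterization",
            abstract="oligomers and polymers were studied",
            methods_text="laser desorption/ionization mass spectrometry",
        ),
    ]
    return Corpus(publications=pubs)


@pytest.fixture(scope="session")
def generated():
    """Medium synthetic corpus shared across unit-test modules."""
    config = GeneratorConfig(n_publications=2000, seed=11)
    corpus, truth = generate_corpus(config)
    return config, corpus, truth
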