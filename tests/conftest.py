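import pytest

from trialtax.synthetic_data import (
    SynthConfig,
    generate_annotations,
    generate_cohort,
    generate_specialty_tags,
    generate_thesaurus,
)


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=7, n_studies=300)


@pytest.fixture(scope="session")
def thesaurus(config):
    return generate_thesaurus(config)


@pytest.fixture(scope="session")
def specialty_tags(config, thesaurus):
    return generate_specialty_tags(config, thesaurus)


@pytest.fixture(scope="session")
def cohort(config, thesaurus, specialty_tags):
    return generate_cohort(config, thesaurus, specialty_tags)


@pytest.fixture(scope="session")
def annotations(config, thesaurus, specialty_tags):
    return generate_annotations(config, thesaurus, specialty_tags)
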