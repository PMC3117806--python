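import pytest

from chemphrase import parse_document
from chemphrase.samples import PREPARATION, SAMPLE_SENTENCE


@pytest.fixture(scope="session")
def prep_doc():
    """The benzazepine preparation, fully parsed."""
    return parse_document(PREPARATION, source_id="prep82")


@pytest.fixture(scope="session")
def sample_doc():
    """The single worked add-sentence, fully parsed."""
    return parse_document(SAMPLE_SENTENCE, source_id="sample")
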