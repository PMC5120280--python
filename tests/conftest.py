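import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_text():
    from dnastore.message import DEMO_MESSAGE

    return DEMO_MESSAGE


@pytest.fixture(scope="session")
def demo_key(demo_text):
    from dnastore.codec import build_huffman, count_symbols

    return build_huffman(count_symbols(demo_text))


@pytest.fixture(scope="session")
def demo_archive(demo_text):
    """Encoded demo message: (archive key, per-segment tiles, oligos)."""
    from dnastore.pipeline import encode_message

    return encode_message(demo_text)
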