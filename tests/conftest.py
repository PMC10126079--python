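import pytest

from nonwordeval import default_inventory
from nonwordeval.phoneme_core import Pronunciation


@pytest.fixture(scope="session")
def inv():
    return default_inventory()


@pytest.fixture(scope="session")
def entry():
    """Factory: one (speaker, pronunciation) response per DISC string given."""

    def make(*discs):
        return [(f"s{i:02d}", Pronunciation(d)) for i, d in enumerate(discs)]

    return make
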