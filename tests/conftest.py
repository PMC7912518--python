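import pytest
from hypothesis import settings

from citeshare import AnnotationStore, build_graph

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_store(records, name="test"):
    return AnnotationStore(name, {k: frozenset(v) for k, v in records.items()})


@pytest.fixture
def chain_graph():
    """A -> B -> C citation chain."""
    return build_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def make_tsv(tmp_path):
    counter = [0]

    def _write(text, name=None):
        counter[0] += 1
        p = tmp_path / (name or f"in{counter[0]}.tsv")
        p.write_text(text)
        return p

    return _write
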