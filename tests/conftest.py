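import pytest
from hypothesis import settings

from tagdge import GeneCount, LibraryPair

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


def make_pair(rows, label_a="A", label_b="B"):
    """Build a LibraryPair from (gene_id, length_bp, count_a, count_b) tuples."""
    return LibraryPair(label_a, label_b, tuple(GeneCount(*r) for r in rows))


@pytest.fixture
def small_pair():
    return make_pair(
        [
            ("g1", 1000, 100, 200),
            ("g2", 500, 50, 50),
            ("g3", 2000, 0, 30),
        ]
    )


@pytest.fixture
def count_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene_id\tlength_bp\tcount_a\tcount_b\n"
        "g1\t1000\t100\t200\n"
        "g2\t500\t50\t50\n"
        "g3\t2000\t0\t30\n"
    )
    return path
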