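import numpy as np
import pytest

from resintrap.data_model import PieceCollection, ResinPiece, TaxonCountMatrix


def make_collection(mass_count_pairs, label="test"):
    pieces = [
        ResinPiece(f"p{i}", float(m), int(c)) for i, (m, c) in enumerate(mass_count_pairs)
    ]
    return PieceCollection(label=label, tree_group="other", resin_class="defaunation", pieces=pieces)


@pytest.fixture
def small_collection():
    """The worked five-piece example: P(empty|1)=1/2, P(empty|2)=2/3."""
    return make_collection([(1.00, 0), (1.00, 1), (2.00, 0), (2.00, 0), (2.00, 3)])


@pytest.fixture
def tiny_matrix():
    return TaxonCountMatrix(
        sample_ids=["s1", "s2"],
        taxon_ids=["Diptera", "Acari", "Collembola"],
        counts=np.array([[3, 1, 0], [0, 2, 4]]),
    )
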