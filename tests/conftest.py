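import numpy as np
import pytest

from nitkit import io as nio
from nitkit import synthetic


@pytest.fixture
def small_alignment():
    """Five-sequence, six-column grouped alignment with a hand-known best column."""
    records = [
        nio.SequenceRecord("a1", "ARKDEF"),
        nio.SequenceRecord("a2", "ARKDEF"),
        nio.SequenceRecord("b1", "AHKDEW"),
        nio.SequenceRecord("b2", "AHKDEW"),
        nio.SequenceRecord("c1", "ATKD-W"),
    ]
    rows = [
        nio.GroupRow("a1", "G1", "s1"),
        nio.GroupRow("a2", "G1", "s1"),
        nio.GroupRow("b1", "G2", "s2"),
        nio.GroupRow("b2", "G2", "s2"),
        nio.GroupRow("c1", "G3", "s3"),
    ]
    return nio.AlignedSeqSet(records).with_groups(nio.GroupTable(rows))


@pytest.fixture
def planted_scenario():
    """Zero-noise planted-determinant scenario: 4 groups x 3 sequences."""
    return synthetic.ScanScenario(
        n_groups=4,
        seqs_per_group=3,
        width=40,
        planted_columns=(5, 17, 29),
        background="conserved",
        seed=11,
    )


@pytest.fixture
def random_asu():
    return synthetic.make_helical_asu(n_atoms=20, seed=7)
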