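import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from popgenkit.seqdata import Alignment, SequenceEntry

TOY4_SEQS = ["AAAA", "AAAT", "AATT", "ATTT"]


@pytest.fixture
def toy4():
    """Four-sequence toy alignment with polymorphic columns {1, 2, 3}."""
    return Alignment(
        SequenceEntry(f"s{i + 1}", s) for i, s in enumerate(TOY4_SEQS)
    )


@pytest.fixture
def toy4_outgroup():
    """TOY4 plus an all-ancestral outgroup row (AAAA)."""
    entries = [SequenceEntry(f"s{i + 1}", s) for i, s in enumerate(TOY4_SEQS)]
    entries.append(SequenceEntry("out", "AAAA", is_outgroup=True))
    return Alignment(entries)


def random_alignment(rng, n=None, length=None, groups=None, missing=0.0):
    """Random nucleotide alignment for property tests."""
    n = n or int(rng.integers(4, 9))
    length = length or int(rng.integers(2, 31))
    mat = rng.choice(list("ACGT"), size=(n, length))
    # make columns mostly low-diversity so polymorphism patterns vary
    for j in range(length):
        if rng.random() < 0.6:
            mat[:, j] = rng.choice(list("ACGT"))
        elif rng.random() < 0.5:
            base, alt = rng.choice(list("ACGT"), size=2, replace=False)
            mat[:, j] = np.where(rng.random(n) < 0.3, alt, base)
    if missing > 0:
        mask = rng.random(mat.shape) < missing
        mat[mask] = "N"
    if groups is None:
        groups = [0] * n
    return Alignment(
        SequenceEntry(f"s{i + 1}", "".join(row), group=groups[i])
        for i, row in enumerate(mat)
    )
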