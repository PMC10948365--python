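import numpy as np
import pandas as pd
import pytest

from remodel3d import matrix as mx


@pytest.fixture
def toy_fragments():
    """Fragment lengths [300, 800, 200, 400, 500] on one 2200 bp chromosome."""
    from remodel3d.digest import FragmentMap

    lengths = [300, 800, 200, 400, 500]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    frags = np.column_stack([bounds[:-1], bounds[1:]])
    return FragmentMap(chrom_lengths={"chr1": int(bounds[-1])}, fragments={"chr1": frags})


@pytest.fixture
def small_symmetric_matrix():
    m = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 2.0], [8.0, 2.0, 0.0]])
    return mx.ContactMatrix(chrom="chr1", bin_size=10_000, matrix=m, mask=np.ones(3, bool))


def _make_ibed(rows):
    """rows: (bait_name, oe_start, score[, oe_name]) on a fixed 5 kb grid."""
    recs = []
    for row in rows:
        bait, oe_start, score = row[:3]
        oe_name = row[3] if len(row) > 3 else "."
        bait_idx = int(bait.replace("b", ""))
        recs.append(
            {
                "bait_chr": "chr1",
                "bait_start": bait_idx * 5000,
                "bait_end": (bait_idx + 1) * 5000,
                "bait_name": bait,
                "oe_chr": "chr1",
                "oe_start": oe_start,
                "oe_end": oe_start + 5000,
                "oe_name": oe_name,
                "N_reads": 10,
                "score": score,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def make_ibed():
    return _make_ibed
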