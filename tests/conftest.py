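import numpy as np
import pytest

from punctapol import (
    MoleculeMap,
    PunctaSimParams,
    binarize_molecule_map,
    make_puncta_map,
    measure_puncta,
    segment_clusters,
)


@pytest.fixture
def wt_map():
    """A seeded wild-type-profile molecule map with its ground truth."""
    return make_puncta_map(PunctaSimParams(seed=11), "wt")


@pytest.fixture
def small_table():
    """Puncta table from a tiny hand-checkable molecule map.

    Two well-separated clusters: a 2x2 block of 5s (20 molecules) and a
    single pixel of 7 (below the 10-molecule threshold).
    """
    counts = np.zeros((40, 120), dtype=int)
    counts[10:12, 10:12] = 5
    counts[30, 100] = 7
    mmap = MoleculeMap(counts=counts, pixel_size_nm=3.0)
    labels = segment_clusters(binarize_molecule_map(mmap), closing_radius_px=5)
    return measure_puncta(labels, mmap), mmap
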