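import numpy as np
import pandas as pd
import pytest

from vdrcohort.genome import GenomeLayout, SegmentTrack


@pytest.fixture
def tiny_layout():
    return GenomeLayout({"chr1": 1000, "chr2": 800})


def make_track(layout, triples):
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    return SegmentTrack(layout, df)


def random_track(layout, rng, n_segments=10, max_len=50):
    """Random (possibly overlapping) segments, for oracle comparisons."""
    rows = []
    chroms = layout.chroms
    for _ in range(n_segments):
        chrom = chroms[rng.integers(len(chroms))]
        L = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, layout.lengths[chrom] - L + 1))
        rows.append((chrom, start, start + L))
    return make_track(layout, rows)


def bitmap(track):
    """Per-base boolean coverage masks — the brute-force oracle for all
    interval arithmetic."""
    masks = {c: np.zeros(track.layout.lengths[c], dtype=bool) for c in track.layout.chroms}
    for seg in track:
        masks[seg.chrom][seg.start:seg.end] = True
    return masks
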