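"""Overlap-enrichment similarity between samples and hierarchical clustering.

Similarity between two peak tracks is the fold enrichment of one in the
other under the length-preserving randomization null, symmetrized by the
arithmetic mean of the two directions.  Sample distance is the inverse of
this similarity; samples with highly co-located binding have enrichment
far above 1 and hence small distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import mc_segment_segment
from .genome import SegmentTrack

__all__ = ["EnrichmentMatrix", "pairwise_enrichment_matrix", "cluster_by_enrichment", "to_newick"]


@dataclass
class EnrichmentMatrix:
    sample_ids: list[str]
    values: np.ndarray  # square, symmetric after symmetrization
    symmetrization: str = "mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def pairwise_enrichment_matrix(
    tracks: list[SegmentTrack],
    sample_ids: list[str] | None = None,
    n: int = 1000,
    rng=None,
) -> EnrichmentMatrix:
    """Pairwise fold-enrichment among sample tracks.

    Entry (i, j) is the mean of fold(i in j) and fold(j in i); the diagonal
    is set to each row's maximum so a sample is never closer to another
    sample than to itself.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    ids = sample_ids or [f"sample{i+1}" for i in range(len(tracks))]
    if len(ids) != len(tracks):
        raise ValueError("sample_ids length mismatch")
    for t in tracks:
        if t.covered_bp == 0:
            raise ValueError("a track has zero coverage")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = len(tracks)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f_ij = mc_segment_segment(tracks[i], tracks[j], n=n, rng=rng).fold
            f_ji = mc_segment_segment(tracks[j], tracks[i], n=n, rng=rng).fold
            vals = [v for v in (f_ij, f_ji) if v is not None]
            m[i, j] = m[j, i] = float(np.mean(vals)) if vals else 0.0
    for i in range(k):
        off = np.delete(m[i], i)
        m[i, i] = off.max() if len(off) else 1.0
    return EnrichmentMatrix(ids, m)


def cluster_by_enrichment(
    matrix: EnrichmentMatrix,
    method: str = "average",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Agglomerative clustering on distance = 1 / enrichment.

    Zero or undefined enrichment entries are floored at a small epsilon so
    the distance stays finite (such pairs simply end up maximally distant).
    Returns the scipy linkage matrix and the distance matrix as a frame.
    """
    vals = matrix.values.copy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite enrichment entries")
    floor = 1e-6
    vals[vals <= 0] = floor
    dist = 1.0 / vals
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard against floating asymmetry
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    dist_df = pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)
    return linkage, dist_df


def first_bipartition(linkage: np.ndarray, sample_ids: list[str]) -> tuple[set[str], set[str]]:
    """The two sample sets split by the root of the dendrogram."""
    tree = hierarchy.to_tree(linkage)
    left = {sample_ids[i] for i in tree.left.pre_order()}
    right = {sample_ids[i] for i in tree.right.pre_order()}
    return left, right


def to_newick(linkage: np.ndarray, sample_ids: list[str]) -> str:
    """Newick string with branch lengths from the linkage heights."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height) -> str:
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{sample_ids[node.id]}:{length:.6g}"
        children = ",".join(rec(c, node.dist) for c in (node.left, node.right))
        return f"({children}):{length:.6g}"

    def rec_root(node) -> str:
        if node.is_leaf():
            return f"{sample_ids[node.id]}:0"
        children = ",".join(rec(c, node.dist) for c in (node.left, node.right))
        return f"({children});"

    return rec_root(tree)
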