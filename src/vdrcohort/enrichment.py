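"""Monte-Carlo overlap-enrichment tests for genomic tracks.

Three null models, all empirical:

* **segment-segment** — the query track is randomized while preserving, per
  chromosome, the exact multisets of segment lengths and inter-segment gap
  lengths (terminal gaps included); positions are shuffled by independently
  permuting the two multisets.  The statistic is overlapping base pairs.
* **point-segment** — points (peak midpoints) are resampled from an
  intensity track, i.e. per-bin sampling weights built to match a
  confounder such as proximity to genes.  The statistic is the number of
  points falling inside the reference segments.
* **case-control** — segment positions of both tracks stay fixed while the
  binary case/control labels of the query are permuted; the statistic is
  the difference in per-bp overlap rates between the two label classes.

P-values use the add-one convention p = (b + 1) / (n + 1), so 0 is never
reported and the smallest attainable p is 1/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneModel
from .genome import (
    GenomeLayout,
    PointTrack,
    SegmentTrack,
    _coverage_breakpoints,
    _merge_arrays,
    _points_in_intervals,
    from_arrays,
)

__all__ = [
    "EnrichmentResult",
    "CaseControlTrack",
    "CaseControlResult",
    "IntensityTrack",
    "randomize_preserving_lengths",
    "mc_segment_segment",
    "build_gene_proximity_intensity",
    "mc_point_segment",
    "mc_case_control",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic vs. a randomization null.

    ``fold`` is observed/expected (None when the null expectation is zero);
    ``p_value`` is the empirical add-one p for the requested tail.
    """

    observed: float
    expected: float
    fold: float | None
    p_value: float
    n_randomizations: int
    tail: str = "greater"
    seed: int | None = None

    def __str__(self) -> str:
        fold = f"{self.fold:.3g}" if self.fold is not None else "NA"
        return (f"observed={self.observed:g} expected={self.expected:.4g} "
                f"O/E={fold} p={self.p_value:.4g} (n={self.n_randomizations}, {self.tail})")


def _empirical_p(null: np.ndarray, observed: float, tail: str) -> float:
    n = len(null)
    p_greater = (np.count_nonzero(null >= observed) + 1) / (n + 1)
    p_less = (np.count_nonzero(null <= observed) + 1) / (n + 1)
    if tail == "greater":
        return p_greater
    if tail == "less":
        return p_less
    if tail == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown tail {tail!r}")


# ---------------------------------------------------------------------------
# length/gap-preserving segment randomization
# ---------------------------------------------------------------------------

def _chrom_lengths_gaps(starts: np.ndarray, ends: np.ndarray, chrom_len: int):
    lengths = ends - starts
    gaps = np.empty(len(starts) + 1, dtype=np.int64)
    gaps[0] = starts[0]
    gaps[1:-1] = starts[1:] - ends[:-1]
    gaps[-1] = chrom_len - ends[-1]
    return lengths, gaps


def _randomize_chrom(lengths: np.ndarray, gaps: np.ndarray, rng: np.random.Generator):
    """New (starts, ends) from independently permuted length and gap multisets."""
    lp = rng.permutation(lengths)
    gp = rng.permutation(gaps)
    # layout: gap0 seg0 gap1 seg1 ... segk-1 gapk
    starts = np.cumsum(gp[:-1]) + np.concatenate(([0], np.cumsum(lp[:-1])))
    return starts, starts + lp


def randomize_preserving_lengths(
    track: SegmentTrack,
    layout: GenomeLayout | None = None,
    rng: np.random.Generator | int | None = None,
) -> SegmentTrack:
    """Randomize segment positions chromosome by chromosome, preserving the
    empirical distributions of segment and inter-segment lengths exactly.

    The track is merged first, so the null applies to disjoint segments.
    """
    layout = layout or track.layout
    rng = _as_rng(rng)
    arrays = {}
    for chrom, (s, e) in track.merged_by_chrom().items():
        if len(s) == 0:
            continue
        lengths, gaps = _chrom_lengths_gaps(s, e, layout.lengths[chrom])
        arrays[chrom] = _randomize_chrom(lengths, gaps, rng)
    return from_arrays(layout, arrays)


# ---------------------------------------------------------------------------
# segment-segment test
# ---------------------------------------------------------------------------

def _null_overlap_draws(
    query: SegmentTrack,
    ref_cov: Mapping[str, tuple[np.ndarray, np.ndarray]],
    layout: GenomeLayout,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    per_chrom = []
    for chrom, (s, e) in query.merged_by_chrom().items():
        if len(s) == 0 or chrom not in ref_cov:
            continue
        lengths, gaps = _chrom_lengths_gaps(s, e, layout.lengths[chrom])
        xp, fp = ref_cov[chrom]
        draws = np.empty(n)
        for i in range(n):
            rs, re = _randomize_chrom(lengths, gaps, rng)
            draws[i] = (np.interp(re, xp, fp) - np.interp(rs, xp, fp)).sum()
        per_chrom.append(draws)
    if not per_chrom:
        return np.zeros(n)
    return np.sum(per_chrom, axis=0)


def mc_segment_segment(
    query: SegmentTrack,
    reference: SegmentTrack,
    n: int = 1000,
    rng: np.random.Generator | int | None = None,
    tail: str = "greater",
    seed: int | None = None,
) -> EnrichmentResult:
    """Overlap-bp enrichment of ``query`` in ``reference`` under the
    length/gap-preserving randomization null."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if query.layout.lengths != reference.layout.lengths:
        raise ValueError("query and reference use different genome layouts")
    if seed is not None and rng is None:
        rng = seed
    rng = _as_rng(rng)
    layout = query.layout
    ref_cov = {c: _coverage_breakpoints(s, e)
               for c, (s, e) in reference.merged_by_chrom().items() if len(s)}
    qm = query.merged_by_chrom()
    observed = 0
    for chrom, (s, e) in qm.items():
        if chrom in ref_cov:
            xp, fp = ref_cov[chrom]
            observed += int(round((np.interp(e, xp, fp) - np.interp(s, xp, fp)).sum()))
    null = _null_overlap_draws(query, ref_cov, layout, n, rng)
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else None
    p = _empirical_p(null, observed, tail)
    return EnrichmentResult(float(observed), expected, fold, p, n, tail, seed)


# ---------------------------------------------------------------------------
# intensity track + point-segment test
# ---------------------------------------------------------------------------

@dataclass
class IntensityTrack:
    """Per-bin point-sampling weights over the genome (weights sum to 1)."""

    layout: GenomeLayout
    bin_size: int
    weights: dict[str, np.ndarray]

    def __post_init__(self):
        total = sum(float(w.sum()) for w in self.weights.values())
        if total <= 0:
            raise ValueError("intensity track has no positive weight")
        if abs(total - 1.0) > 1e-9:
            for w in self.weights.values():
                w /= total

    def restrict(self, layout: GenomeLayout) -> "IntensityTrack":
        """Drop excluded chromosomes and renormalize."""
        w = {c: arr.copy() for c, arr in self.weights.items() if c in layout}
        return IntensityTrack(layout, self.bin_size, w)

    def _flat(self):
        chroms = [c for c in self.weights if len(self.weights[c])]
        w = np.concatenate([self.weights[c] for c in chroms])
        bin_chrom = np.concatenate([np.full(len(self.weights[c]), i) for i, c in enumerate(chroms)])
        bin_idx = np.concatenate([np.arange(len(self.weights[c])) for c in chroms])
        return chroms, w, bin_chrom, bin_idx

    def sample_points(self, m: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Draw m points: bin by weight, position uniform within the bin."""
        chroms, w, bin_chrom, bin_idx = self._flat()
        w = w / w.sum()
        flat = rng.choice(len(w), size=m, p=w)
        out: dict[str, list[np.ndarray]] = {}
        for i, chrom in enumerate(chroms):
            sel = bin_chrom[flat] == i
            if not sel.any():
                continue
            bidx = bin_idx[flat[sel]]
            lo = bidx * self.bin_size
            hi = np.minimum(lo + self.bin_size, self.layout.lengths[chrom])
            pos = lo + rng.integers(0, hi - lo)
            out[chrom] = pos
        return {c: np.asarray(v) for c, v in out.items()}


def _nearest_distance(pos: np.ndarray, gs: np.ndarray, ge: np.ndarray) -> np.ndarray:
    """Distance from each position to the nearest merged interval (0 inside)."""
    if len(gs) == 0:
        return np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.searchsorted(gs, pos, side="right")
    d_prev = np.where(idx > 0, pos - ge[np.clip(idx - 1, 0, None)] + 1, np.iinfo(np.int64).max)
    d_next = np.where(idx < len(gs), gs[np.clip(idx, None, len(gs) - 1)] - pos, np.iinfo(np.int64).max)
    inside = _points_in_intervals(pos, gs, ge)
    d = np.minimum(np.maximum(d_prev, 0), np.maximum(d_next, 0))
    d[inside] = 0
    return d


def _distance_class(d: np.ndarray) -> np.ndarray:
    """0 for distance 0, else 1 + floor(log2(d)): log2-spaced distance bands."""
    cls = np.zeros(len(d), dtype=np.int64)
    pos = d > 0
    cls[pos] = 1 + np.floor(np.log2(d[pos])).astype(np.int64)
    return cls


def build_gene_proximity_intensity(
    points: PointTrack,
    genes: GeneModel,
    layout: GenomeLayout | None = None,
    bin_size: int = 10_000,
    use_tss: bool = False,
) -> IntensityTrack:
    """Sampling weights matching the observed distribution of point-to-
    nearest-gene distances.

    Observed distances are histogrammed into log2-spaced classes ({0},
    [1,2), [2,4), ...); each genomic bin is assigned the class of its own
    midpoint-to-gene distance, and receives weight (class point fraction) /
    (number of bins in the class).  Bins in classes beyond the largest
    observed distance get zero weight.  ``use_tss`` measures distance to
    transcription start sites instead of gene bodies.
    """
    layout = layout or points.layout
    if len(genes) == 0:
        raise ValueError("gene model is empty")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    gene_iv: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in genes:
        if g.chrom not in layout:
            continue
        if use_tss:
            tss = g.start if g.strand == "+" else g.end - 1
            gene_iv.setdefault(g.chrom, ([], []))[0].append(tss)
            gene_iv[g.chrom][1].append(tss + 1)
        else:
            gene_iv.setdefault(g.chrom, ([], []))[0].append(g.start)
            gene_iv[g.chrom][1].append(g.end)
    gene_iv = {c: _merge_arrays(np.array(s, np.int64), np.array(e, np.int64))
               for c, (s, e) in gene_iv.items()}
    if not gene_iv:
        raise ValueError("no genes on included chromosomes")

    # observed distance classes
    point_classes = []
    for chrom, pos in points.by_chrom().items():
        gs, ge = gene_iv.get(chrom, (np.empty(0, np.int64),) * 2)
        if len(gs) == 0:
            continue
        point_classes.append(_distance_class(_nearest_distance(pos, gs, ge)))
    if not point_classes:
        raise ValueError("no points on chromosomes carrying genes")
    point_classes = np.concatenate(point_classes)
    n_classes = int(point_classes.max()) + 1
    class_frac = np.bincount(point_classes, minlength=n_classes) / len(point_classes)

    # per-bin classes
    bin_classes: dict[str, np.ndarray] = {}
    for chrom in layout.chroms:
        L = layout.lengths[chrom]
        n_bins = (L + bin_size - 1) // bin_size
        centers = np.minimum(np.arange(n_bins, dtype=np.int64) * bin_size + bin_size // 2, L - 1)
        gs, ge = gene_iv.get(chrom, (np.empty(0, np.int64),) * 2)
        d = _nearest_distance(centers, gs, ge)
        cls = _distance_class(np.minimum(d, np.int64(2) ** 62))
        bin_classes[chrom] = cls
    all_cls = np.concatenate(list(bin_classes.values()))
    bins_per_class = np.bincount(np.clip(all_cls, 0, n_classes), minlength=n_classes + 1)

    weights = {}
    for chrom, cls in bin_classes.items():
        w = np.zeros(len(cls))
        in_range = cls < n_classes
        denom = bins_per_class[cls[in_range]]
        w[in_range] = class_frac[cls[in_range]] / np.maximum(denom, 1)
        weights[chrom] = w
    return IntensityTrack(layout, bin_size, weights)


def mc_point_segment(
    points: PointTrack,
    segments: SegmentTrack,
    intensity: IntensityTrack,
    n: int = 1000,
    rng: np.random.Generator | int | None = None,
    exclude_chroms: Sequence[str] = (),
    tail: str = "greater",
    seed: int | None = None,
) -> EnrichmentResult:
    """Point-in-segment enrichment with nulls drawn from the intensity track."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is not None and rng is None:
        rng = seed
    rng = _as_rng(rng)
    layout = points.layout
    if exclude_chroms:
        layout = layout.exclude(exclude_chroms)
        points = points.restrict(layout)
        segments = segments.restrict(layout)
        intensity = intensity.restrict(layout)
    seg_iv = segments.merged_by_chrom()
    m = len(points)
    observed = sum(
        int(_points_in_intervals(pos, *seg_iv.get(chrom, (np.empty(0, np.int64),) * 2)).sum())
        for chrom, pos in points.by_chrom().items()
    )
    null = np.empty(n)
    for i in range(n):
        sampled = intensity.sample_points(m, rng)
        null[i] = sum(
            int(_points_in_intervals(pos, *seg_iv.get(chrom, (np.empty(0, np.int64),) * 2)).sum())
            for chrom, pos in sampled.items()
        )
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else None
    p = _empirical_p(null, observed, tail)
    return EnrichmentResult(float(observed), expected, fold, p, n, tail, seed)


# ---------------------------------------------------------------------------
# case-control preferential overlap
# ---------------------------------------------------------------------------

@dataclass
class CaseControlTrack:
    """Segments with fixed positions and a binary case/control label each.

    Segments must be non-overlapping within the track (pool per-group merged
    tracks before labelling) so per-label covered bp is the sum of lengths.
    """

    track: SegmentTrack
    is_case: np.ndarray  # bool, aligned with track.df rows

    def __post_init__(self):
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if len(self.is_case) != len(self.track):
            raise ValueError("label array length does not match track")
        if not self.is_case.any() or self.is_case.all():
            raise ValueError("both case and control labels must be present")


@dataclass(frozen=True)
class CaseControlResult:
    statistic: float          # case rate - control rate, observed
    case_rate: float          # overlap bp per covered bp, case segments
    control_rate: float
    case_fold: float | None   # case rate / its permutation-null mean
    control_fold: float | None
    p_value: float            # two-sided on |statistic|
    n_randomizations: int
    seed: int | None = None


def mc_case_control(
    cc: CaseControlTrack,
    reference: SegmentTrack,
    n: int = 10_000,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
) -> CaseControlResult:
    """Differential enrichment of case vs. control segments in a reference.

    Segment positions (both tracks) stay fixed; case/control labels are
    permuted over segments, preserving label counts.  The statistic is the
    difference of per-bp overlap rates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is not None and rng is None:
        rng = seed
    rng = _as_rng(rng)
    track = cc.track
    ref_cov = {c: _coverage_breakpoints(s, e)
               for c, (s, e) in reference.merged_by_chrom().items() if len(s)}
    # per-segment overlap bp with the reference, in track row order
    seg_ov = np.zeros(len(track))
    seg_len = (track.df["end"] - track.df["start"]).to_numpy(np.float64)
    chroms = track.df["chrom"].to_numpy()
    starts = track.df["start"].to_numpy(np.float64)
    ends = track.df["end"].to_numpy(np.float64)
    for chrom in np.unique(chroms):
        if chrom not in ref_cov:
            continue
        xp, fp = ref_cov[chrom]
        sel = chroms == chrom
        seg_ov[sel] = np.interp(ends[sel], xp, fp) - np.interp(starts[sel], xp, fp)

    labels = cc.is_case

    def rates(lab: np.ndarray) -> tuple[float, float]:
        cov_case = seg_len[lab].sum()
        cov_ctrl = seg_len[~lab].sum()
        if cov_case == 0 or cov_ctrl == 0:
            raise ValueError("a label class covers zero bp")
        return seg_ov[lab].sum() / cov_case, seg_ov[~lab].sum() / cov_ctrl

    case_rate, ctrl_rate = rates(labels)
    t_obs = case_rate - ctrl_rate
    null_t = np.empty(n)
    null_case = np.empty(n)
    null_ctrl = np.empty(n)
    for i in range(n):
        perm = rng.permutation(labels)
        cr, xr = rates(perm)
        null_t[i] = cr - xr
        null_case[i] = cr
        null_ctrl[i] = xr
    p = (np.count_nonzero(np.abs(null_t) >= abs(t_obs)) + 1) / (n + 1)
    mean_case = float(null_case.mean())
    mean_ctrl = float(null_ctrl.mean())
    return CaseControlResult(
        statistic=float(t_obs),
        case_rate=float(case_rate),
        control_rate=float(ctrl_rate),
        case_fold=case_rate / mean_case if mean_case > 0 else None,
        control_fold=ctrl_rate / mean_ctrl if mean_ctrl > 0 else None,
        p_value=float(p),
        n_randomizations=n,
        seed=seed,
    )
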