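"""Cohort-level statistics tying VDR binding to serum 25-hydroxyvitamin D.

Samples are split at the clinical sufficiency cutoff of 75 nmol/L serum
25(OH)D.  The module provides Pearson correlation with a t-based p-value,
an exact two-sided rank-sum test for small two-group comparisons, group
summaries, and the fraction of pooled binding sites unique to one sample.

A published reference table of nine CD4+ VDR ChIP-seq samples (per-sample
25(OH)D, binding-site count and genomic-category percentages) ships with
the package for worked examples and regression checks; see
:func:`load_reference_cohort_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, SegmentTrack, merge_union, read_segment_track
from .util import round_half_up

__all__ = [
    "CohortSample",
    "CorrelationResult",
    "GroupSummary",
    "pearson_with_p",
    "exact_rank_sum",
    "group_summary",
    "unique_site_fraction",
    "read_sample_sheet",
    "load_reference_cohort_table",
]

SUFFICIENCY_CUTOFF_NMOL = 75.0


@dataclass
class CohortSample:
    sample_id: str
    vitd_nmol: float
    track: SegmentTrack

    def __post_init__(self):
        if self.vitd_nmol <= 0:
            raise ValueError(f"{self.sample_id}: 25(OH)D level must be positive")

    def group(self, cutoff: float = SUFFICIENCY_CUTOFF_NMOL) -> str:
        return "high" if self.vitd_nmol >= cutoff else "low"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __str__(self) -> str:
        return f"r = {self.r:.2f}, P = {self.p:.4g} (n = {self.n})"


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p from the t distribution
    (t = r * sqrt(n-2) / sqrt(1-r^2), df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def exact_rank_sum(a, b, max_exact: int = 20) -> float:
    """Exact two-sided rank-sum p-value by full enumeration.

    All C(n_a + n_b, n_a) assignments of the pooled values to the two
    groups are enumerated (ties carry mid-ranks); p is twice the smaller
    tail probability of the group-a rank sum, capped at 1.  Refuses
    n > ``max_exact``; use scipy's normal-approximation ranksums there.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if n > max_exact:
        raise ValueError(f"exact mode refused for n = {n} > {max_exact}")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    t_obs = ranks[:n_a].sum()
    total = comb(n, n_a)
    le = ge = 0
    for idx in combinations(range(n), n_a):
        t = ranks[list(idx)].sum()
        if t <= t_obs + 1e-9:
            le += 1
        if t >= t_obs - 1e-9:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(1.0, p)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_level: float       # nmol/L, 1 decimal
    level_range: tuple[float, float]
    mean_count: int         # binding sites, nearest integer
    count_range: tuple[int, int]


def group_summary(samples: list[CohortSample], cutoff: float = SUFFICIENCY_CUTOFF_NMOL) -> dict[str, GroupSummary]:
    """Per-group sample count, 25(OH)D mean/range and peak-count mean/range.

    A level exactly at the cutoff belongs to the sufficient (">=75") group.
    Empty groups are simply absent from the result.
    """
    out: dict[str, GroupSummary] = {}
    for gname in ("high", "low"):
        members = [s for s in samples if s.group(cutoff) == gname]
        if not members:
            continue
        levels = np.array([s.vitd_nmol for s in members], dtype=float)
        counts = np.array([len(s.track) for s in members], dtype=float)
        out[gname] = GroupSummary(
            group=gname,
            n=len(members),
            mean_level=round_half_up(float(levels.mean()), 1),
            level_range=(float(levels.min()), float(levels.max())),
            mean_count=int(round_half_up(float(counts.mean()))),
            count_range=(int(counts.min()), int(counts.max())),
        )
    return out


def unique_site_fraction(tracks: list[SegmentTrack]) -> float:
    """Percentage of pooled merged binding sites intersected by peaks from
    exactly one sample."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    pooled = merge_union(tracks)
    if len(pooled) == 0:
        return 0.0
    hits = np.zeros(len(pooled), dtype=np.int64)
    offset = 0
    for chrom, sub in pooled.df.groupby("chrom", sort=False, observed=True):
        ps = sub["start"].to_numpy(np.int64)
        pe = sub["end"].to_numpy(np.int64)
        for t in tracks:
            ts, te = t.merged_by_chrom().get(chrom, (np.empty(0, np.int64),) * 2)
            if len(ts) == 0:
                continue
            idx = np.searchsorted(ts, pe, side="left")
            h = idx > 0
            h[h] = te[idx[h] - 1] > ps[h]
            hits[offset:offset + len(ps)] += h.astype(np.int64)
        offset += len(ps)
    return round_half_up(100.0 * float((hits == 1).sum()) / len(pooled), 1)


def read_sample_sheet(path: str | Path, layout: GenomeLayout) -> list[CohortSample]:
    """TSV with header (sample_id, vitd_nmol, peaks_path); peak paths are
    resolved relative to the sheet's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "peaks_path": str})
    required = {"sample_id", "vitd_nmol", "peaks_path"}
    if required - set(df.columns):
        raise ValueError(f"{path}: sample sheet missing columns {sorted(required - set(df.columns))}")
    samples = []
    for r in df.itertuples(index=False):
        peaks = Path(r.peaks_path)
        if not peaks.is_absolute():
            peaks = path.parent / peaks
        track = read_segment_track(peaks, layout)
        samples.append(CohortSample(r.sample_id, float(r.vitd_nmol), track))
    return samples


def load_reference_cohort_table() -> pd.DataFrame:
    """The bundled nine-sample CD4+ VDR ChIP-seq cohort summary: per sample,
    serum 25(OH)D (nmol/L), total binding-site count, and the percentage of
    sites per genomic category."""
    with resources.files("vdrcohort.data").joinpath("cd4_cohort_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
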