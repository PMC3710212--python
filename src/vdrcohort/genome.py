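"""Genome layout and segment/point track primitives.

Every analysis stage works on one of two containers: a :class:`SegmentTrack`
(ordered genomic intervals, used for ChIP-seq peaks, blacklists, disease
regions and gene windows) or a :class:`PointTrack` (single-base positions,
used for peak midpoints).  Coordinates are 0-based half-open throughout,
matching BED; real hg19-style coordinates pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Segment",
    "SegmentTrack",
    "PointTrack",
    "read_chrom_sizes",
    "read_segment_track",
    "write_segment_track",
    "merge_union",
    "subtract_blacklist",
    "overlap_bp",
    "overlap_count",
    "midpoints",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length (bp), with an optional excluded set.

    Chromosome order is the insertion order of ``lengths`` and is used to
    canonically sort tracks.
    """

    lengths: Mapping[str, int]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for name, length in self.lengths.items():
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ValueError(f"chromosome {name!r} has invalid length {length!r}")
        object.__setattr__(self, "excluded", frozenset(self.excluded))

    @property
    def chroms(self) -> list[str]:
        return [c for c in self.lengths if c not in self.excluded]

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths[c] for c in self.chroms)

    def exclude(self, chroms: Iterable[str]) -> "GenomeLayout":
        """A copy with additional chromosomes excluded."""
        return GenomeLayout(dict(self.lengths), self.excluded | set(chroms))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths and chrom not in self.excluded


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    name: str | None = None
    value: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_COLUMNS = ["chrom", "start", "end", "name", "value"]


class SegmentTrack:
    """A sorted collection of genomic intervals on a fixed layout.

    Segments within one track may overlap (raw peak calls often do); use
    :meth:`merged` for a disjoint union.  Iterating yields :class:`Segment`.
    """

    def __init__(self, layout: GenomeLayout, segments: pd.DataFrame | Iterable[Segment], *, validate: bool = True):
        self.layout = layout
        if isinstance(segments, pd.DataFrame):
            df = segments.copy()
        else:
            rows = [(s.chrom, s.start, s.end, s.name, s.value) for s in segments]
            df = pd.DataFrame(rows, columns=_COLUMNS)
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                               zip(_COLUMNS, [str, np.int64, np.int64, object, float])})
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = None
        df = df[_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if validate:
            self._validate(df)
        order = {c: i for i, c in enumerate(layout.lengths)}
        df = df.sort_values(["chrom", "start", "end"],
                            key=lambda s: s.map(order) if s.name == "chrom" else s,
                            kind="mergesort").reset_index(drop=True)
        self.df = df
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._merged_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def _validate(self, df: pd.DataFrame) -> None:
        for chrom in df["chrom"].unique():
            if chrom not in self.layout.lengths:
                raise ValueError(f"unknown chromosome {chrom!r}")
        bad = df[df["start"] >= df["end"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(f"segment start >= end at {r.chrom}:{r.start}-{r.end}")
        neg = df[df["start"] < 0]
        if len(neg):
            r = neg.iloc[0]
            raise ValueError(f"negative start at {r.chrom}:{r.start}")
        lens = df["chrom"].map(self.layout.lengths)
        oob = df[df["end"] > lens]
        if len(oob):
            r = oob.iloc[0]
            raise ValueError(
                f"segment {r.chrom}:{r.start}-{r.end} exceeds chromosome length "
                f"{self.layout.lengths[r.chrom]}"
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for r in self.df.itertuples(index=False):
            yield Segment(r.chrom, int(r.start), int(r.end), r.name,
                          None if r.value is None or (isinstance(r.value, float) and np.isnan(r.value)) else r.value)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentTrack):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    # -- array access -------------------------------------------------------
    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Raw (starts, ends) int64 arrays per chromosome (excluded chroms dropped)."""
        if self._by_chrom is None:
            out = {}
            for chrom, sub in self.df.groupby("chrom", sort=False, observed=True):
                if chrom in self.layout:
                    out[chrom] = (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
            self._by_chrom = out
        return self._by_chrom

    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Disjoint merged (starts, ends) per chromosome."""
        if self._merged_by_chrom is None:
            self._merged_by_chrom = {
                chrom: _merge_arrays(s, e) for chrom, (s, e) in self.by_chrom().items()
            }
        return self._merged_by_chrom

    @property
    def covered_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self.merged_by_chrom().values()))

    def merged(self) -> "SegmentTrack":
        """Disjoint union of this track's segments (names/values dropped)."""
        return from_arrays(self.layout, self.merged_by_chrom())

    def restrict(self, layout: GenomeLayout) -> "SegmentTrack":
        """The same segments on a (possibly more excluded) layout."""
        keep = self.df["chrom"].map(lambda c: c in layout)
        return SegmentTrack(layout, self.df[keep], validate=False)


def from_arrays(layout: GenomeLayout, arrays: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> SegmentTrack:
    frames = []
    for chrom, (s, e) in arrays.items():
        if len(s):
            frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return SegmentTrack(layout, df, validate=False)


class PointTrack:
    """Single-base positions (e.g. peak midpoints) on a fixed layout."""

    def __init__(self, layout: GenomeLayout, points: pd.DataFrame | Sequence[tuple[str, int]], *, validate: bool = True):
        self.layout = layout
        if isinstance(points, pd.DataFrame):
            df = points[["chrom", "pos"]].copy()
        else:
            df = pd.DataFrame(points, columns=["chrom", "pos"])
        if df.empty:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
        df["pos"] = df["pos"].astype(np.int64)
        if validate:
            for chrom in df["chrom"].unique():
                if chrom not in layout.lengths:
                    raise ValueError(f"unknown chromosome {chrom!r}")
            lens = df["chrom"].map(layout.lengths)
            if ((df["pos"] < 0) | (df["pos"] >= lens)).any():
                raise ValueError("point position outside chromosome bounds")
        order = {c: i for i, c in enumerate(layout.lengths)}
        df = df.sort_values(["chrom", "pos"],
                            key=lambda s: s.map(order) if s.name == "chrom" else s,
                            kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> dict[str, np.ndarray]:
        return {chrom: sub["pos"].to_numpy(np.int64)
                for chrom, sub in self.df.groupby("chrom", sort=False, observed=True)
                if chrom in self.layout}

    def restrict(self, layout: GenomeLayout) -> "PointTrack":
        keep = self.df["chrom"].map(lambda c: c in layout)
        return PointTrack(layout, self.df[keep], validate=False)


# ---------------------------------------------------------------------------
# low-level interval arithmetic
# ---------------------------------------------------------------------------

def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted intervals into disjoint ones.

    Book-ended intervals ([a,b) + [b,c)) are coalesced.
    """
    if len(starts) == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    # running max of ends; a new block begins where start > max(previous ends)
    run_end = np.maximum.accumulate(e)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_end[:-1]
    idx = np.flatnonzero(new_block)
    out_s = s[idx]
    out_e = np.empty(len(idx), dtype=np.int64)
    out_e[:-1] = run_end[idx[1:] - 1]
    out_e[-1] = run_end[-1]
    return out_s, out_e


def _coverage_breakpoints(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear cumulative coverage of disjoint intervals.

    Returns (xp, fp) such that ``np.interp(x, xp, fp)`` gives the number of
    covered bases strictly below coordinate x.
    """
    n = len(starts)
    xp = np.empty(2 * n, dtype=np.float64)
    fp = np.empty(2 * n, dtype=np.float64)
    xp[0::2], xp[1::2] = starts, ends
    cum = np.cumsum(ends - starts)
    fp[1::2] = cum
    fp[0::2] = cum - (ends - starts)
    return xp, fp


def _overlap_bp_arrays(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]) -> int:
    """Intersection bp between two *merged* interval sets."""
    sa, ea = a
    sb, eb = b
    if len(sa) == 0 or len(sb) == 0:
        return 0
    xp, fp = _coverage_breakpoints(sb, eb)
    return int(round((np.interp(ea, xp, fp) - np.interp(sa, xp, fp)).sum()))


def _points_in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the merged intervals."""
    if len(starts) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right")
    inside = idx > 0
    inside[inside] = pos[inside] < ends[idx[inside] - 1]
    return inside


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column ``name<TAB>length`` file -> GenomeLayout."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split("\t")[:2]
            lengths[name] = int(size)
    return GenomeLayout(lengths)


def read_segment_track(path: str | Path, layout: GenomeLayout) -> SegmentTrack:
    """Read a BED3/BED6 file (tab-separated, no header; track lines ignored).

    Raises ValueError naming the offending chromosome or line for malformed
    or out-of-bounds records.
    """
    chroms, starts, ends, names, values = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom not in layout.lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0 or end > layout.lengths[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: {chrom}:{start}-{end} outside chromosome "
                    f"of length {layout.lengths[chrom]}"
                )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            names.append(parts[3] if len(parts) > 3 else None)
            values.append(float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else None)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "name": names, "value": values})
    if df.empty:
        return SegmentTrack(layout, df)
    return SegmentTrack(layout, df, validate=False)


def write_segment_track(track: SegmentTrack, path: str | Path) -> None:
    """Write BED3 (or BED5 when names/values are present)."""
    with open(path, "w") as fh:
        for seg in track:
            if seg.name is not None or seg.value is not None:
                name = seg.name if seg.name is not None else "."
                value = f"{seg.value:g}" if seg.value is not None else "."
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{name}\t{value}\n")
            else:
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\n")


# ---------------------------------------------------------------------------
# set operations
# ---------------------------------------------------------------------------

def _check_shared_layout(tracks: Sequence[SegmentTrack | PointTrack]) -> GenomeLayout:
    layouts = {id(t.layout): t.layout for t in tracks}
    first = tracks[0].layout
    for lay in layouts.values():
        if lay.lengths != first.lengths:
            raise ValueError("tracks use different genome layouts")
    return first


def merge_union(tracks: Sequence[SegmentTrack]) -> SegmentTrack:
    """Disjoint union of all segments from all tracks (e.g. pooling the
    binding sites of every sample in a vitamin-D group)."""
    if not tracks:
        raise ValueError("merge_union needs at least one track")
    layout = _check_shared_layout(tracks)
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in layout.chroms:
        ss = [t.by_chrom().get(chrom, (np.empty(0, np.int64),) * 2) for t in tracks]
        starts = np.concatenate([s for s, _ in ss])
        ends = np.concatenate([e for _, e in ss])
        if len(starts):
            arrays[chrom] = _merge_arrays(starts, ends)
    return from_arrays(layout, arrays)


def subtract_blacklist(track: SegmentTrack, blacklist: SegmentTrack) -> SegmentTrack:
    """Drop every segment that intersects the blacklist by >= 1 bp.

    Whole peaks are removed, never trimmed: artefact filtering discards
    peaks, it does not reshape them.
    """
    _check_shared_layout([track, blacklist])
    bl = blacklist.merged_by_chrom()
    keep_parts = []
    for chrom, sub in track.df.groupby("chrom", sort=False, observed=True):
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        bs, be = bl.get(chrom, (np.empty(0, np.int64),) * 2)
        if len(bs) == 0:
            keep_parts.append(sub)
            continue
        # overlap iff some blacklist interval has start < e and end > s
        idx = np.searchsorted(bs, e, side="left")
        hits = idx > 0
        hits[hits] = be[idx[hits] - 1] > s[hits]
        keep_parts.append(sub[~hits])
    if keep_parts:
        df = pd.concat(keep_parts)
    else:
        df = track.df.iloc[0:0]
    return SegmentTrack(track.layout, df, validate=False)


def overlap_bp(a: SegmentTrack, b: SegmentTrack) -> int:
    """Base pairs covered by both tracks (symmetric)."""
    _check_shared_layout([a, b])
    am, bm = a.merged_by_chrom(), b.merged_by_chrom()
    return sum(_overlap_bp_arrays(am[c], bm[c]) for c in am if c in bm)


def overlap_count(a: SegmentTrack, b: SegmentTrack) -> int:
    """Number of a's segments that intersect b by >= 1 bp (asymmetric)."""
    _check_shared_layout([a, b])
    bm = b.merged_by_chrom()
    total = 0
    for chrom, (s, e) in a.by_chrom().items():
        bs, be = bm.get(chrom, (np.empty(0, np.int64),) * 2)
        if len(bs) == 0:
            continue
        idx = np.searchsorted(bs, e, side="left")
        hits = idx > 0
        hits[hits] = be[idx[hits] - 1] > s[hits]
        total += int(hits.sum())
    return total


def midpoints(track: SegmentTrack) -> PointTrack:
    """One point per segment at floor((start+end)/2)."""
    df = pd.DataFrame({
        "chrom": track.df["chrom"],
        "pos": (track.df["start"] + track.df["end"]) // 2,
    })
    return PointTrack(track.layout, df, validate=False)
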