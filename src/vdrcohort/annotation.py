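"""Genomic-category annotation of peak midpoints.

Each peak midpoint is assigned exactly one of seven mutually exclusive
categories relative to a gene model: UTR, exons, introns, upstream,
downstream, up_and_downstream, intergenic.  "Upstream"/"downstream" mean
within a flanking window (default 5 kb) 5'/3' of a gene on its own strand;
a midpoint qualifying as downstream of one gene and upstream of another is
"up_and_downstream".

Precedence is genic-first: UTR beats exon beats intron, and any genic
category beats any flanking one, across all genes jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .util import round_half_up
from .genome import (
    GenomeLayout,
    PointTrack,
    SegmentTrack,
    _merge_arrays,
    _points_in_intervals,
    from_arrays,
    midpoints,
)

__all__ = [
    "Gene",
    "GeneModel",
    "CategoryTable",
    "CATEGORIES",
    "read_gene_model",
    "classify_peaks",
    "gene_window_track",
]

CATEGORIES = (
    "downstream",
    "exons",
    "intergenic",
    "introns",
    "up_and_downstream",
    "upstream",
    "utr",
)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")


@dataclass
class GeneModel:
    layout: GenomeLayout
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def spans_track(self) -> SegmentTrack:
        arrays = _interval_arrays(self.layout, [(g.chrom, g.start, g.end) for g in self.genes])
        return from_arrays(self.layout, arrays)


def _interval_arrays(layout, triples):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in triples:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by_chrom.items():
        arr = np.array(ivs, dtype=np.int64)
        out[chrom] = _merge_arrays(arr[:, 0], arr[:, 1])
    return out


def read_gene_model(path: str | Path, layout: GenomeLayout) -> GeneModel:
    """Read genes from BED12 (thickStart/thickEnd delimiting the CDS, so
    exon bases outside the thick interval are UTR) or from a minimal GTF
    with exon / five_prime_utr / three_prime_utr features grouped by gene_id.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path, layout)
    return _read_bed12(path, layout)


def _read_bed12(path: Path, layout: GenomeLayout) -> GeneModel:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            strand = p[5]
            thick_s, thick_e = int(p[6]), int(p[7])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            utrs = []
            for es, ee in exons:
                if es < thick_s:
                    utrs.append((es, min(ee, thick_s)))
                if ee > thick_e:
                    utrs.append((max(es, thick_e), ee))
            genes.append(Gene(name, chrom, strand, start, end, exons, tuple(utrs)))
    return GeneModel(layout, genes)


def _read_gtf(path: Path, layout: GenomeLayout) -> GeneModel:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            chrom, feature, start, end, strand, attrs = p[0], p[2], int(p[3]) - 1, int(p[4]), p[6], p[8]
            gid = None
            for field_ in attrs.split(";"):
                field_ = field_.strip()
                if field_.startswith("gene_id"):
                    gid = field_.split()[1].strip('"')
            if gid is None:
                continue
            rec = rows.setdefault(gid, {"chrom": chrom, "strand": strand, "exons": [], "utrs": []})
            if feature == "exon":
                rec["exons"].append((start, end))
            elif feature.endswith("utr") or feature == "UTR":
                rec["utrs"].append((start, end))
    genes = []
    for gid, rec in rows.items():
        exons = tuple(sorted(rec["exons"]))
        if not exons:
            continue
        genes.append(Gene(gid, rec["chrom"], rec["strand"], exons[0][0], exons[-1][1],
                          exons, tuple(sorted(rec["utrs"]))))
    return GeneModel(layout, genes)


def write_gene_model_bed12(model: GeneModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in model.genes:
            exons = sorted(g.exons)
            utr = sorted(g.utrs)
            # thick interval = span minus leading/trailing UTR bases
            thick_s, thick_e = g.start, g.end
            for us, ue in utr:
                if us == thick_s:
                    thick_s = ue
                if ue == thick_e:
                    thick_e = us
            if thick_s > thick_e:
                thick_s = thick_e = g.start
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{thick_s}\t{thick_e}\t0\t{len(exons)}\t{sizes}\t{offs}\n")


@dataclass
class CategoryTable:
    """Per-category midpoint counts and percentages (1 decimal place)."""

    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: round_half_up(100.0 * self.counts[c] / self.total, 1) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame({
            "category": list(CATEGORIES),
            "count": [self.counts[c] for c in CATEGORIES],
            "percent": [pct[c] for c in CATEGORIES],
        })


def _flank_intervals(genes: Sequence[Gene], layout: GenomeLayout, window: int, side: str):
    """Merged 5' ('up') or 3' ('down') flank intervals across all genes."""
    triples = []
    for g in genes:
        if (side == "up") == (g.strand == "+"):
            s, e = g.start - window, g.start
        else:
            s, e = g.end, g.end + window
        s = max(0, s)
        e = min(layout.lengths[g.chrom], e)
        if s < e:
            triples.append((g.chrom, s, e))
    return _interval_arrays(layout, triples)


def classify_peaks(
    peaks: SegmentTrack,
    genes: GeneModel,
    window: int = 5000,
) -> tuple[pd.DataFrame, CategoryTable]:
    """Assign each peak midpoint to one genomic category.

    Returns a per-peak frame (chrom, start, end, midpoint, category) and the
    aggregated :class:`CategoryTable`.  With an empty gene model everything
    is intergenic.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mids = midpoints(peaks)
    layout = peaks.layout

    glist = list(genes)
    span_iv = _interval_arrays(layout, [(g.chrom, g.start, g.end) for g in glist])
    exon_iv = _interval_arrays(layout, [(g.chrom, s, e) for g in glist for s, e in g.exons])
    utr_iv = _interval_arrays(layout, [(g.chrom, s, e) for g in glist for s, e in g.utrs])
    up_iv = _flank_intervals(glist, layout, window, "up")
    down_iv = _flank_intervals(glist, layout, window, "down")

    cats = np.full(len(peaks), "intergenic", dtype=object)
    mid_pos = (peaks.df["start"].to_numpy() + peaks.df["end"].to_numpy()) // 2
    chroms = peaks.df["chrom"].to_numpy()

    def member(ivs, chrom, pos):
        s, e = ivs.get(chrom, (np.empty(0, np.int64),) * 2)
        return _points_in_intervals(pos, s, e)

    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = mid_pos[sel]
        in_span = member(span_iv, chrom, pos)
        in_exon = member(exon_iv, chrom, pos)
        in_utr = member(utr_iv, chrom, pos)
        in_up = member(up_iv, chrom, pos)
        in_down = member(down_iv, chrom, pos)

        c = np.full(len(pos), "intergenic", dtype=object)
        c[in_up & ~in_span] = "upstream"
        c[in_down & ~in_span] = "downstream"
        c[in_up & in_down & ~in_span] = "up_and_downstream"
        c[in_span] = "introns"
        c[in_exon] = "exons"
        c[in_utr] = "utr"
        cats[sel] = c

    per_peak = peaks.df[["chrom", "start", "end"]].copy()
    per_peak["midpoint"] = mid_pos
    per_peak["category"] = cats
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    return per_peak, CategoryTable(counts, len(peaks))


def gene_window_track(genes: GeneModel, flank: int = 5000) -> SegmentTrack:
    """Merged union of gene spans extended by ``flank`` bp on both sides,
    clipped to chromosome bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    layout = genes.layout
    triples = []
    for g in genes:
        s = max(0, g.start - flank)
        e = min(layout.lengths[g.chrom], g.end + flank)
        triples.append((g.chrom, s, e))
    if not triples:
        return from_arrays(layout, {})
    return from_arrays(layout, _interval_arrays(layout, triples))
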