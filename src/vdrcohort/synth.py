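"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates a small ChIP-seq cohort: per-sample binding-site
counts rise linearly with a serum covariate (25(OH)D, nmol/L) plus
truncated Gaussian noise; peaks are placed by a mixture of uniform
background, disease-associated regions and gene-proximal windows, with
group-dependent mixture weights; peak lengths are log-normal.  An
association catalog plants genome-wide-significant SNPs for chosen traits
among sub-threshold decoys, and a sequence generator plants PWM samples
into background sequences at a stated fraction.

Defaults mirror the cohort the pipeline targets: nine samples with serum
levels {80, 107, 76, 85, 75, 29, 32, 34, 22} nmol/L split 5/4 at the
75 nmol/L sufficiency cutoff, on a 2 x 5 Mb genome carrying 200 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import Gene, GeneModel, gene_window_track, write_gene_model_bed12
from .cohort import CohortSample
from .genome import GenomeLayout, SegmentTrack, write_segment_track
from .gwas import AssociationRecord, write_catalog
from .motif import PWM, pwm_from_counts, write_fasta, write_jaspar

__all__ = [
    "CohortSpec",
    "simulate_genome_and_genes",
    "simulate_association_catalog",
    "simulate_cohort",
    "simulate_motif_sequences",
    "dr3_like_seed_pwm",
    "simulate_all",
]

DEFAULT_COVARIATES = (80.0, 107.0, 76.0, 85.0, 75.0, 29.0, 32.0, 34.0, 22.0)


@dataclass
class CohortSpec:
    """Parameters of the synthetic study.

    The count model is count_i = max(0, round(a + b * x_i + eps)),
    eps ~ N(0, sigma^2); placement weights are (background, disease-region,
    gene-proximal) and may differ between the high (>=75) and low group.
    """

    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    exon_count_range: tuple[int, int] = (2, 6)
    covariates: tuple[float, ...] = DEFAULT_COVARIATES
    count_intercept: float = -1475.0
    count_slope: float = 71.0
    count_sd: float = 800.0
    weights_high: tuple[float, float, float] = (0.55, 0.25, 0.20)
    weights_low: tuple[float, float, float] = (0.65, 0.15, 0.20)
    peak_length_log_mean: float = 6.0     # log-bp; exp(6) ~ 400 bp
    peak_length_log_sd: float = 0.5
    peak_length_bounds: tuple[int, int] = (50, 5_000)
    gene_flank: int = 5_000
    group_cutoff: float = 75.0

    def __post_init__(self):
        for w in (self.weights_high, self.weights_low):
            if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("mixture weights must be >= 0 and sum to 1")
        if self.count_sd < 0:
            raise ValueError("count noise sd must be >= 0")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(spec: CohortSpec, seed=None) -> tuple[GenomeLayout, GeneModel]:
    """A multi-chromosome layout with non-overlapping multi-exon genes."""
    rng = _as_rng(seed)
    layout = GenomeLayout({f"chr{i+1}": spec.chrom_length for i in range(spec.n_chromosomes)})
    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    # distribute genes over chromosomes round-robin, pack with random gaps
    per_chrom: dict[str, list[int]] = {c: [] for c in layout.chroms}
    for i, L in enumerate(lengths):
        per_chrom[layout.chroms[i % spec.n_chromosomes]].append(int(L))
    genes: list[Gene] = []
    gid = 0
    for chrom, ls in per_chrom.items():
        total = sum(ls)
        free = spec.chrom_length - total
        if free < 0:
            raise ValueError(f"genes exceed chromosome {chrom}")
        # split the free space into len(ls)+1 random gaps
        cuts = np.sort(rng.integers(0, free + 1, size=len(ls)))
        gaps = np.diff(np.concatenate(([0], cuts, [free])))
        pos = 0
        order = rng.permutation(len(ls))
        for k, gap in zip(order, gaps[:-1]):
            pos += int(gap)
            L = ls[k]
            start, end = pos, pos + L
            pos = end
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_make_gene(f"gene{gid}", chrom, strand, start, end, spec, rng))
    return layout, GeneModel(layout, genes)


def _make_gene(gene_id, chrom, strand, start, end, spec: CohortSpec, rng) -> Gene:
    L = end - start
    k = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
    k = min(k, max(1, L // 200))
    # 2(k-1) interior breakpoints; intervals alternate exon/intron, the gene
    # starting and ending with an exon so the span is exon-delimited
    if k == 1:
        exons = ((start, end),)
    else:
        inner = np.sort(rng.choice(np.arange(1, L), size=2 * (k - 1), replace=False))
        bounds = np.concatenate(([0], inner, [L])) + start
        exons = tuple((int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(k))
    # terminal portions of the first/last exon are UTR
    utrs = []
    first, last = exons[0], exons[-1]
    u5 = max(1, (first[1] - first[0]) // 3)
    u3 = max(1, (last[1] - last[0]) // 3)
    utrs.append((first[0], first[0] + u5))
    if (last[1] - u3, last[1]) != utrs[0]:
        utrs.append((last[1] - u3, last[1]))
    return Gene(gene_id, chrom, strand, start, end, exons, tuple(utrs))


# ---------------------------------------------------------------------------
# association catalog
# ---------------------------------------------------------------------------

def simulate_association_catalog(
    layout: GenomeLayout,
    planted_traits: dict[str, list[tuple[str, int]]],
    decoy_traits: dict[str, int] | None = None,
    seed=None,
) -> list[AssociationRecord]:
    """Catalog with genome-wide-significant SNPs at the given positions for
    planted traits (p drawn <= 1e-7) and sub-threshold decoys (p > 1e-7)."""
    rng = _as_rng(seed)
    records = []
    i = 0
    for trait, positions in planted_traits.items():
        for chrom, pos in positions:
            if chrom not in layout.lengths or not (0 <= pos < layout.lengths[chrom]):
                raise ValueError(f"planted SNP position {chrom}:{pos} out of bounds")
            i += 1
            p = 10.0 ** (-rng.uniform(8.0, 15.0))
            records.append(AssociationRecord(f"rs{i}", chrom, pos, trait, p))
    for trait, n in (decoy_traits or {}).items():
        for _ in range(n):
            i += 1
            chrom = layout.chroms[int(rng.integers(len(layout.chroms)))]
            pos = int(rng.integers(layout.lengths[chrom]))
            p = 10.0 ** (-rng.uniform(3.0, 6.9))  # always > 1e-7
            records.append(AssociationRecord(f"rs{i}", chrom, pos, trait, p))
    return records


# ---------------------------------------------------------------------------
# cohort peaks
# ---------------------------------------------------------------------------

def _sample_positions_in_track(track: SegmentTrack, m: int, rng) -> list[tuple[str, int]]:
    segs = [(s.chrom, s.start, s.end) for s in track]
    if not segs:
        raise ValueError("cannot place peaks in an empty track")
    lens = np.array([e - s for _, s, e in segs], dtype=float)
    idx = rng.choice(len(segs), size=m, p=lens / lens.sum())
    out = []
    for i in idx:
        chrom, s, e = segs[i]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def simulate_cohort(
    layout: GenomeLayout,
    genes: GeneModel,
    disease_regions: SegmentTrack,
    spec: CohortSpec,
    seed=None,
    sample_ids: list[str] | None = None,
) -> list[CohortSample]:
    """Per-sample peak tracks under the linear count model and the
    three-component placement mixture."""
    rng = _as_rng(seed)
    gene_windows = gene_window_track(genes, spec.gene_flank) if len(genes) else None
    chrom_lens = np.array([layout.lengths[c] for c in layout.chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    samples = []
    ids = sample_ids or [f"s{i+1}" for i in range(len(spec.covariates))]
    for sid, x in zip(ids, spec.covariates):
        eps = rng.normal(0.0, spec.count_sd)
        count = max(0, int(round(spec.count_intercept + spec.count_slope * x + eps)))
        w = spec.weights_high if x >= spec.group_cutoff else spec.weights_low
        comp = rng.choice(3, size=count, p=np.array(w))
        positions: list[tuple[str, int]] = []
        n_bg = int((comp == 0).sum())
        for _ in range(n_bg):
            ci = int(rng.choice(len(chrom_p), p=chrom_p))
            chrom = layout.chroms[ci]
            positions.append((chrom, int(rng.integers(layout.lengths[chrom]))))
        n_dr = int((comp == 1).sum())
        if n_dr:
            positions.extend(_sample_positions_in_track(disease_regions, n_dr, rng))
        n_gene = int((comp == 2).sum())
        if n_gene:
            if gene_windows is None or len(gene_windows) == 0:
                raise ValueError("gene-proximal component requires genes")
            positions.extend(_sample_positions_in_track(gene_windows, n_gene, rng))
        lengths = np.exp(rng.normal(spec.peak_length_log_mean, spec.peak_length_log_sd, size=count))
        lengths = np.clip(np.round(lengths), *spec.peak_length_bounds).astype(np.int64)
        rows = []
        for (chrom, center), L in zip(positions, lengths):
            half = int(L) // 2
            s = max(0, center - half)
            e = min(layout.lengths[chrom], center + (int(L) - half))
            if s >= e:
                s, e = max(0, e - 1), e if e > 0 else 1
            rows.append((chrom, s, e))
        import pandas as pd

        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        samples.append(CohortSample(sid, float(x), SegmentTrack(layout, df)))
    return samples


# ---------------------------------------------------------------------------
# motif sequences
# ---------------------------------------------------------------------------

def simulate_motif_sequences(
    pwm: PWM,
    n: int,
    length: int,
    planted_fraction: float,
    seed=None,
    background: np.ndarray | None = None,
) -> list[tuple[str, str]]:
    """Background sequences with one PWM sample planted (uniform offset,
    random strand) in a ``planted_fraction`` subset."""
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    if length < pwm.width:
        raise ValueError("sequence length shorter than motif width")
    rng = _as_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bases = np.array(list("ACGT"))
    n_planted = int(round(planted_fraction * n))
    planted = set(rng.choice(n, size=n_planted, replace=False).tolist())
    out = []
    for i in range(n):
        seq = "".join(bases[rng.choice(4, size=length, p=bg)])
        if i in planted:
            site = pwm.sample(rng)
            if rng.random() < 0.5:
                site = site.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            o = int(rng.integers(0, length - pwm.width + 1))
            seq = seq[:o] + site + seq[o + pwm.width:]
        out.append((f"seq{i+1}", seq))
    return out


def dr3_like_seed_pwm(strength: float = 0.85) -> PWM:
    """A synthetic DR3-style nuclear-receptor seed motif (two RGKTCA
    hexamer half-sites separated by a 3-bp spacer), constructed as a
    stand-in seed matrix for scan/refine runs."""
    w = 15
    counts = np.full((4, w), 5.0)
    consensus = "AGGTCA"  # R G K T C A with R->A/G and K->G/T split below
    half = {0: consensus, 9: consensus}
    total = 100.0
    for off, cons in half.items():
        for j, base in enumerate(cons):
            col = off + j
            counts[:, col] = (1 - strength) * total / 4
            counts["ACGT".index(base), col] = strength * total
        # degenerate first (R = A/G) and third (K = G/T) positions
        counts[:, off] = [strength * total / 2, (1 - strength) * total / 2,
                          strength * total / 2, (1 - strength) * total / 2]
        counts[:, off + 2] = [(1 - strength) * total / 2, (1 - strength) * total / 2,
                              strength * total / 2, strength * total / 2]
    # spacer columns stay uniform
    return pwm_from_counts(counts, pseudocount=0.25, name="DR3_synthetic")


# ---------------------------------------------------------------------------
# full fixture emission
# ---------------------------------------------------------------------------

def simulate_all(
    out_dir: str | Path,
    seed: int = 0,
    spec: CohortSpec | None = None,
    n_planted_snps: int = 6,
    n_sequences: int = 150,
    sequence_length: int = 60,
    planted_motif_fraction: float = 0.3,
) -> dict[str, Path]:
    """Emit every fixture the pipeline consumes: chrom.sizes, genes (BED12),
    association catalog, sample sheet + per-sample peak BEDs, FASTA
    sequences and a seed motif matrix.  Fully reproducible given the seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, genes = simulate_genome_and_genes(spec, rng)

    paths: dict[str, Path] = {}
    paths["chrom_sizes"] = out / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for c in layout.chroms:
            fh.write(f"{c}\t{layout.lengths[c]}\n")
    paths["genes"] = out / "genes.bed"
    write_gene_model_bed12(genes, paths["genes"])

    planted_pos = [
        (layout.chroms[int(rng.integers(len(layout.chroms)))],
         int(rng.integers(150_000, layout.lengths[layout.chroms[0]] - 150_000)))
        for _ in range(n_planted_snps)
    ]
    catalog = simulate_association_catalog(
        layout,
        planted_traits={"autoimmune_synth": planted_pos},
        decoy_traits={"decoy_trait": 20},
        seed=rng,
    )
    paths["catalog"] = out / "catalog.tsv"
    write_catalog(catalog, paths["catalog"])

    from .gwas import build_disease_regions

    regions = build_disease_regions(catalog, {"autoimmune_synth"}, layout)
    samples = simulate_cohort(layout, genes, regions, spec, rng)
    sheet = out / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tvitd_nmol\tpeaks_path\n")
        for s in samples:
            bed = out / f"{s.sample_id}.bed"
            write_segment_track(s.track, bed)
            fh.write(f"{s.sample_id}\t{s.vitd_nmol:g}\t{bed.name}\n")
    paths["samples"] = sheet

    pwm = dr3_like_seed_pwm()
    paths["seed_motif"] = out / "seed_motif.jaspar"
    write_jaspar(pwm.probs * 100, paths["seed_motif"], name=pwm.name)
    seqs = simulate_motif_sequences(pwm, n_sequences, sequence_length,
                                    planted_motif_fraction, seed=rng)
    paths["sequences"] = out / "sequences.fasta"
    write_fasta(seqs, paths["sequences"])
    return paths
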