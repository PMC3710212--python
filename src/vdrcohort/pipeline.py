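"""Configuration-driven orchestration of the full analysis.

``run_full_analysis`` consumes a :class:`RunConfig` pointing at a sample
sheet, gene model, association catalog and (optionally) blacklist, FASTA
sequences and a seed motif, and emits a report directory with the
cohort table, annotation percentages, enrichment tables, flank sweep,
dendrogram, SNP-in-peak table and motif report.  Every table records the
randomization count and seed used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import classify_peaks, read_gene_model
from .clustering import cluster_by_enrichment, pairwise_enrichment_matrix, to_newick
from .cohort import (
    exact_rank_sum,
    group_summary,
    pearson_with_p,
    read_sample_sheet,
    unique_site_fraction,
)
from .enrichment import (
    CaseControlTrack,
    build_gene_proximity_intensity,
    mc_case_control,
    mc_point_segment,
    mc_segment_segment,
)
from .genome import (
    merge_union,
    midpoints,
    read_chrom_sizes,
    read_segment_track,
    subtract_blacklist,
)
from .gwas import build_disease_regions, flank_sweep, read_catalog, snps_in_peaks
from .motif import (
    iterative_refinement,
    motif_count_curve,
    partition_by_motif,
    pwm_from_counts,
    read_fasta,
    read_jaspar,
    write_jaspar,
)

logger = logging.getLogger("vdrcohort")


@dataclass
class RunConfig:
    chrom_sizes: Path
    samples: Path
    genes: Path
    catalog: Path
    blacklist: Path | None = None
    fasta: Path | None = None
    seed_motif: Path | None = None
    traits: list[str] | None = None       # None = all catalog traits
    group_cutoff: float = 75.0
    n_rand: int = 1000
    n_rand_cc: int = 10000
    flanks: list[int] = field(default_factory=lambda: [10_000, 25_000, 50_000, 100_000])
    gwas_p_max: float = 1e-7
    gwas_flank: int = 100_000
    window: int = 5000
    seed: int = 0
    exclude_chroms: list[str] = field(default_factory=list)
    motif_p_scan: float = 1e-4
    motif_p_partition: float = 5e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        for key in ("chrom_sizes", "samples", "genes", "catalog", "blacklist", "fasta", "seed_motif"):
            if raw.get(key):
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else base / p
        return cls(**raw)

    def validate(self) -> None:
        for key in ("chrom_sizes", "samples", "genes", "catalog"):
            p = getattr(self, key)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing required input {key}: {p}")
        for key in ("blacklist", "fasta", "seed_motif"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} does not exist: {p}")
        if self.n_rand < 1 or self.n_rand_cc < 1:
            raise ValueError("randomization counts must be >= 1")


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write the report; returns the report directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    rng = np.random.default_rng(config.seed)

    layout = read_chrom_sizes(config.chrom_sizes)
    samples = read_sample_sheet(config.samples, layout)
    genes = read_gene_model(config.genes, layout)
    catalog = read_catalog(config.catalog)
    if config.blacklist:
        blacklist = read_segment_track(config.blacklist, layout)
        for s in samples:
            s.track = subtract_blacklist(s.track, blacklist)
    logger.info("loaded %d samples, %d genes, %d catalog records",
                len(samples), len(genes), len(catalog))

    meta = {"version": __version__, "seed": config.seed,
            "n_rand": config.n_rand, "n_rand_cc": config.n_rand_cc}

    # (1) cohort table + correlations
    levels = [s.vitd_nmol for s in samples]
    counts = [len(s.track) for s in samples]
    rows = []
    cats_by_sample = {}
    for s in samples:
        _, table = classify_peaks(s.track, genes, config.window)
        cats_by_sample[s.sample_id] = table.percentages
        rows.append({"sample": s.sample_id, "vitd_nmol": s.vitd_nmol,
                     "group": s.group(config.group_cutoff), "total": len(s.track),
                     **table.percentages})
    cohort_df = pd.DataFrame(rows)
    corr = {"total": pearson_with_p(levels, counts)}
    for cat in cats_by_sample[samples[0].sample_id]:
        vals = [cats_by_sample[s.sample_id][cat] for s in samples]
        try:
            corr[cat] = pearson_with_p(levels, vals)
        except ValueError:
            continue
    corr_df = pd.DataFrame([{"variable": k, "r": round(v.r, 2), "p": v.p, "n": v.n}
                            for k, v in corr.items()])
    groups = group_summary(samples, config.group_cutoff)
    high = [len(s.track) for s in samples if s.group(config.group_cutoff) == "high"]
    low = [len(s.track) for s in samples if s.group(config.group_cutoff) == "low"]
    summary = {
        **meta,
        "groups": {g: vars(s) for g, s in groups.items()},
        "rank_sum_p": exact_rank_sum(high, low) if high and low and len(high) + len(low) <= 20 else None,
        "unique_site_percent": unique_site_fraction([s.track for s in samples]),
    }
    cohort_df.to_csv(out / "cohort_table.tsv", sep="\t", index=False)
    corr_df.to_csv(out / "cohort_correlations.tsv", sep="\t", index=False)

    # (2) per-group annotation percentages
    pooled = {}
    annot_rows = []
    for gname in ("high", "low"):
        tracks = [s.track for s in samples if s.group(config.group_cutoff) == gname]
        if not tracks:
            continue
        pooled[gname] = merge_union(tracks)
        _, table = classify_peaks(pooled[gname], genes, config.window)
        annot_rows.append({"group": gname, "total": len(pooled[gname]), **table.percentages})
    pd.DataFrame(annot_rows).to_csv(out / "group_annotation.tsv", sep="\t", index=False)

    # (3) enrichment vs disease regions: plain, intensity-controlled, case-control
    regions = build_disease_regions(catalog, config.traits, layout,
                                    config.gwas_p_max, config.gwas_flank)
    enr_rows = []
    for gname, track in pooled.items():
        res = mc_segment_segment(track, regions, n=config.n_rand, rng=rng)
        enr_rows.append({"group": gname, "control": "none", "observed": res.observed,
                         "expected": res.expected, "fold": res.fold, "p": res.p_value,
                         "n_rand": res.n_randomizations, "seed": config.seed})
        pts = midpoints(track)
        intensity = build_gene_proximity_intensity(pts, genes, layout)
        resi = mc_point_segment(pts, regions, intensity, n=config.n_rand, rng=rng,
                                exclude_chroms=config.exclude_chroms)
        enr_rows.append({"group": gname, "control": "gene_proximity", "observed": resi.observed,
                         "expected": resi.expected, "fold": resi.fold, "p": resi.p_value,
                         "n_rand": resi.n_randomizations, "seed": config.seed})
    if len(pooled) == 2:
        merged_h = pooled["high"].merged()
        merged_l = pooled["low"].merged()
        cc_track = merge_union([merged_h, merged_l])
        # a pooled site is 'case' when any high-group peak covers it
        from .genome import overlap_count  # noqa: avoid cycle at module load

        labels = []
        hm = merged_h.merged_by_chrom()
        for seg in cc_track:
            s, e = hm.get(seg.chrom, (np.empty(0, np.int64),) * 2)
            idx = np.searchsorted(s, seg.end, side="left")
            labels.append(bool(idx > 0 and e[idx - 1] > seg.start))
        labels = np.array(labels)
        if labels.any() and not labels.all():
            cc = CaseControlTrack(cc_track, labels)
            ccr = mc_case_control(cc, regions, n=config.n_rand_cc, rng=rng)
            summary["case_control"] = {
                "statistic": ccr.statistic, "case_rate": ccr.case_rate,
                "control_rate": ccr.control_rate, "p": ccr.p_value,
                "n_rand": ccr.n_randomizations,
            }
    pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # (4) flank sweep on the full pooled track
    all_pooled = merge_union([s.track for s in samples])
    sweep = flank_sweep(catalog, config.traits, all_pooled, sorted(config.flanks),
                        config.gwas_p_max, n_rand=config.n_rand, rng=rng)
    sweep["n_rand"] = config.n_rand
    sweep["seed"] = config.seed
    sweep.to_csv(out / "flank_sweep.tsv", sep="\t", index=False)

    # (5) clustering (samples without any peak carry no overlap signal)
    clusterable = [s for s in samples if s.track.covered_bp > 0]
    if len(clusterable) < len(samples):
        logger.warning("excluding %d empty sample(s) from clustering",
                       len(samples) - len(clusterable))
    matrix = pairwise_enrichment_matrix([s.track for s in clusterable],
                                        [s.sample_id for s in clusterable],
                                        n=min(config.n_rand, 200), rng=rng)
    linkage, dist = cluster_by_enrichment(matrix)
    dist.to_csv(out / "distance_matrix.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(to_newick(linkage, matrix.sample_ids) + "\n")

    # (6) SNP-in-peak table
    snps_in_peaks(catalog, all_pooled).to_csv(out / "snps_in_peaks.tsv", sep="\t", index=False)

    # (7) motif report
    if config.fasta and config.seed_motif:
        seqs = read_fasta(config.fasta)
        seed_pwm = pwm_from_counts(read_jaspar(config.seed_motif))
        _, _, frac = partition_by_motif(seqs, seed_pwm, config.motif_p_partition)
        refined = iterative_refinement(seqs, seed_pwm, p_scan=config.motif_p_scan,
                                       rounds=2, seed=config.seed)
        curve = motif_count_curve(seqs, seed_pwm, [1e-5, 1e-4, 5e-4, 1e-3, 1e-2])
        curve.to_csv(out / "motif_curve.tsv", sep="\t", index=False)
        write_jaspar(np.round(refined.pwm.probs * 100, 2), out / "refined_motif.jaspar",
                     name="refined")
        summary["motif"] = {
            "positive_percent": frac,
            "refined_mean_ic": float(refined.pwm.information_content.mean()),
            "degenerate": refined.degenerate,
            "rounds": [vars(h) for h in refined.history],
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    logger.info("report written to %s", out)
    return out
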