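# vdrcohort

Interval statistics for cohort ChIP-seq peak analysis, built around the
question of how vitamin D receptor (VDR) binding in primary CD4+ cells
relates to serum vitamin D status and autoimmune disease loci.

Given per-sample peak tracks (BED), a gene model, a GWAS-style SNP
association catalog and per-sample serum 25-hydroxyvitamin D (25(OH)D)
levels, the package provides:

* **Interval core** — genome layouts, segment/point tracks, BED I/O,
  merging, blacklist filtering, overlap statistics (`vdrcohort.genome`).
* **Annotation** — classification of peak midpoints into seven mutually
  exclusive genomic categories (UTR / exons / introns / upstream /
  downstream / up-and-downstream / intergenic, 5 kb flanks)
  (`vdrcohort.annotation`).
* **Monte-Carlo enrichment** — three empirical null models
  (`vdrcohort.enrichment`):
  segment–segment overlap with randomization preserving the per-chromosome
  segment-length *and* gap-length multisets; point–segment overlap with
  points resampled from a confounder-matched intensity track (proximity to
  genes); and case–control preferential overlap with label permutation.
  Fold enrichment is O/E = observed / mean-null, and p-values use the
  add-one convention p = (b+1)/(n+1).
* **GWAS regions** — disease-associated region tracks as merged ±100 kb
  windows around SNPs with association p ≤ 1e-7, flank sweeps, and
  SNP-in-peak reporting (`vdrcohort.gwas`).
* **Clustering** — pairwise overlap-enrichment similarity between samples
  and average-linkage hierarchical clustering on distance = 1/enrichment
  (`vdrcohort.clustering`).
* **Cohort statistics** — Pearson correlation with t-based p-values, an
  exact two-sided rank-sum test, group summaries at the 75 nmol/L
  sufficiency cutoff, and the fraction of pooled binding sites unique to
  one sample (`vdrcohort.cohort`).
* **Motifs** — PWMs with exact score p-values (dynamic-programming
  convolution, as in FIMO), two-strand scanning, ZOOPS EM de novo
  discovery, and an iterative scan→rediscover refinement loop with
  degeneration detection (`vdrcohort.motif`).
* **Synthetic data** — a generator emulating the cohort structure the
  analysis assumes (counts linear in 25(OH)D, placement mixtures over
  background / disease regions / gene windows, log-normal peak lengths,
  planted association catalogs and motifs), so every stage runs without
  downloads (`vdrcohort.synth`).

## Worked example

The package ships the published nine-sample CD4+ cohort summary (per
sample: serum 25(OH)D in nmol/L, number of binding sites, and the
percentage of sites per genomic category):

```python
from vdrcohort.cohort import (load_reference_cohort_table,
                              pearson_with_p, exact_rank_sum)

df = load_reference_cohort_table()
print(pearson_with_p(df["vitd_nmol"], df["total"]))
high = df[df.vitd_nmol >= 75]["total"]
low = df[df.vitd_nmol < 75]["total"]
print(f"exact rank-sum p = {exact_rank_sum(high, low):.4f}")
```

prints

```
r = 0.92, P = 0.0004934 (n = 9)
exact rank-sum p = 0.0159
```

i.e. the number of binding sites rises strongly with serum 25(OH)D, and
the five sufficient (≥75 nmol/L) samples carry significantly more sites
than the four insufficient ones (complete separation; 2/126 under the
exact two-sided rank-sum test).

A full synthetic analysis from the command line:

```sh
vdrcohort simulate --out fixture --seed 3
vdrcohort enrich seg-seg --chrom-sizes fixture/chrom.sizes \
    --query fixture/s1.bed --reference fixture/s2.bed -n 200 --seed 1
```

```
observed=379936 expected=2.953e+05 O/E=1.29 p=0.004975 (n=200, greater)
```

Here sample 1's peaks overlap sample 2's by 29% more base pairs than
expected under position randomization (p ≈ 0.005 from 200 draws).
`vdrcohort run-all --config config.yaml --out report` runs every stage
and writes the cohort table, per-group annotation, enrichment and
flank-sweep tables, distance matrix + Newick dendrogram, SNP-in-peak
table and motif report.

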