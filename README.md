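# poolsweep

Downstream analysis of pooled resequencing (Pool-seq) SNP data: per-line
variant filtration, gold-standard error benchmarking, allele-frequency
characterization by functional annotation category, a pooled-heterozygosity
sliding-window scan for selective sweeps with empirical permutation
thresholds, and cross-line calling of putative selective-sweep (pSS) regions
with prioritization of fixed putatively functional variants (pfVars).

The design target is the kind of study where DNA from 10–15 individuals per
breeding line is pooled and sequenced at modest depth (8–17X), SNPs are
called per line with per-strand alternative-allele read support, and
selection signatures are sought as runs of locally fixed windows shared by
every line of a group (e.g. commercial broiler or layer chicken lines).

## The statistic at the core

For a genomic window, pooled heterozygosity is

```
Hp = 2 · ΣnMAJ · ΣnMIN / (ΣnMAJ + ΣnMIN)²
```

where ΣnMAJ and ΣnMIN sum, over the SNPs in the window, the read counts
supporting each site's major and minor allele.  Hp ranges from 0 (every site
fixed) to 0.5 (balanced read support); windows of unusually low Hp are sweep
candidates.  Windows are 40 kb sliding by 20 kb and only windows with more
than 10 SNPs are analysed.  Significance is chromosome-wise and empirical:
the per-site (major, minor) count pairs are shuffled among the chromosome's
SNP positions, the scan is recomputed, and the minimum Hp per shuffle is
recorded; the α-quantile of those minima is the critical Hp, and observed
windows strictly below it are significant.  Windows significant in every
line of a group are merged (overlapping or abutting) into discrete pSS
regions, overlaid with QTL intervals, and the pfVars inside are classified
as ubiquitous-fixed, group-fixed or group-specific.

A seeded synthetic Pool-seq generator (Poisson depth, binomial allele
sampling, strand-split reads, injected fixation intervals and
sequencing-error false positives) provides inputs for every stage, so the
whole pipeline is testable without any sequencing data.

## Worked example

```python
from poolsweep import (
    GenomeLayout, PooledHpScan, SimConfig, LineSpec, SweepSpec,
    simulate, site_counts_from_calls,
)

layout = GenomeLayout(lengths={"chr1": 500_000})
cfg = SimConfig(
    seed=1, layout=layout,
    lines=(LineSpec("L1", "broiler"), LineSpec("L2", "broiler")),
    sweep_specs=(SweepSpec("chr1", 100_000, 200_000),),   # inject a sweep
)
res = simulate(cfg)
sites = site_counts_from_calls(res.filtered_by_line["L1"])
fit = PooledHpScan(sites, layout, line_id="L1").fit(n_perm=1000, seed=7)
print(fit.summary())
```

prints

```
Pooled heterozygosity scan
==========================
line:            L1
window/step:     40000/20000 bp
min SNPs:        > 10
windows:         24 total, 24 analysable
mean Hp:         0.3103
permutations:    1000 per chromosome
significant @ 0.001 : 6 windows
significant @ 0.01  : 6 windows
significant @ 0.05  : 6 windows
```

The six significant windows tile the injected 100–200 kb fixation interval
(the windows fully inside it have Hp ≈ 0; the two flanking half-overlapping
windows are dragged below the critical Hp as well).  `fit.significant(0.05)`
returns the flagged window table; `poolsweep.regions.common_windows` and
`merge_regions` then intersect the flags across lines and merge them into
pSS regions.

The same functionality is available from the shell:

```bash
poolsweep simulate --config sim.yaml --out-dir data/
poolsweep filter --vcf data/L1.vcf --line-id L1 --line-stats data/line_stats.tsv \
    --out L1_filtered.tsv --report L1_report.json
poolsweep permute --counts L1_counts.tsv --genome sizes.tsv --n 10000 --seed 1 \
    --out-windows L1_windows.tsv --out-thresholds L1_critical.tsv
poolsweep regions --windows L1=L1_windows.tsv ... --group broiler=L1,L2,L3,L4 \
    --qtl qtl.bed --out-dir regions/
poolsweep run --config pipeline.yaml     # everything, with a manifest
```

## Layout

- `poolsweep.io` — record types (SnpCall, AnnotatedSnp, LineStats,
  GenomeLayout) and VCF/TSV/BED readers and writers
- `poolsweep.filtering` — the five-stage filtration cascade with per-stage
  attrition reports
- `poolsweep.goldstandard` — TP/FP/FN/TN evaluation and SNPQ threshold
  sweeps (methods with and without the strand-support rule)
- `poolsweep.frequency` — AAF estimation, fixation/private classification,
  spectra, category summary table and the non-coding/coding ratio
- `poolsweep.hpscan` — the Hp scan: `PooledHpScan` (model) and
  `HpScanResults` (fitted results), plus the low-level operations
- `poolsweep.regions` — common-window intersection, region merging, QTL
  overlap and pfVar prioritization
- `poolsweep.simulate` — the synthetic Pool-seq generator
- `poolsweep.experiments` — the calibration and sweep-recovery studies
- `poolsweep.pipeline` / `poolsweep.cli` — orchestration and the
  `poolsweep` command
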