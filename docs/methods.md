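# Methods

## Setting and model

The package analyses pooled-resequencing (Pool-seq) SNP data from multiple
breeding lines.  Each line is a pool of 10–15 diploid individuals sequenced
at modest depth (defaults emulate 8–17X), so genotypes are never observed:
the alternative-allele frequency (AAF) of a variant in a line is estimated as
the proportion of good-quality reads supporting the alternative allele,
AAF = (alt_fwd + alt_rev) / depth.  The depth reported by the caller is
trusted; base- and map-quality filtering is assumed to have happened
upstream, so no re-filtering by base quality occurs here.

Selection signatures are sought as local fixation.  The window statistic is
pooled heterozygosity,

    Hp = 2 · ΣnMAJ · ΣnMIN / (ΣnMAJ + ΣnMIN)²,

with ΣnMAJ and ΣnMIN the sums over window SNPs of each site's major- and
minor-allele read counts.  The major/minor orientation is decided per site
from read support (ties contribute symmetrically, so their assignment is
irrelevant).  Hp lies in [0, 0.5], equals 0 when every site is locally
fixed, and equals 0.5 exactly when ΣnMAJ = ΣnMIN.

## Coordinates

SNP positions are 1-based (VCF convention) in all record types; windows,
regions and BED output are 0-based half-open.  The conversion happens
exactly once, when calls are binned into windows, which keeps BED output
bit-exact.

## Filtration cascade

Five stages run in a fixed order on each line's call set: quality
(SNPQ ≥ 40, inclusive), coverage (depth ≥ 5 and ≤ mean line coverage + 3 SD
— the lower half of a ±3 SD band would fall below the explicit floor of 5
at the depths this design targets, so only the upper bound is applied),
strand support (≥ 2 alternative reads with at least one per strand),
spacing (adjacent markers must be more than 1 base apart), and density
(any 50-base span holding more than 10 SNPs is masked).

Three behaviours are deliberate choices where the procedure is
under-determined:

- a spacing violation removes **both** members of the offending pair
  (conservative; there is no principled way to pick a survivor);
- density masking examines **every** 50-base span (sliding by one base),
  not tiled bins, so clusters straddling a bin boundary cannot escape;
- filters are strictly per line — a SNP removed in one line may survive in
  another, and "detected in a line" downstream always means "passed all
  filters in that line".

The spacing and density stages are idempotent, and the three pointwise
stages commute with each other; only the position-dependent stages make the
cascade order-sensitive (they intentionally run on the quality-surviving
set, so a rejected low-quality call cannot veto a good neighbour).

## Gold-standard evaluation

A call set is compared with a truth set (e.g. Sanger-derived) over declared
covered intervals.  Calls and truth match on (chrom, pos) only; alleles are
not compared.  TP/FP/FN are per site; TN is per covered base ("bases not
called by either method"), which makes specificity depend on the covered
length — this is faithful to how such benchmarks are reported, and the
per-base inflation of specificity is accepted knowingly.  The headline
"error rate" is FP / (retained calls), reported as a fraction; truncation
to an integer percentage is a presentation option (the worked example's
103/200 prints as 51%).  Threshold sweeps evaluate a SNPQ grid under
method 1 (quality only) and method 2 (quality plus the strand rule);
method 2's FP count can never exceed method 1's because the strand rule
only removes calls.

## Frequency summaries

Mean AAF of a SNP averages the per-line estimates over the lines where it
was detected — undetected lines contribute nothing, they do not count as
zero.  "Fixed or nearly fixed" is strictly AAF > 0.9 throughout (mean-level
and per-line).  A private SNP is detected in exactly one line.  Spectra use
half-open bins (lo, hi] of width 0.05 (the width matches the granularity at
which a 10–15 individual pool can resolve frequency); by default every
detected (SNP, line) pair contributes one observation, with a per-SNP-mean
mode available, since either convention is defensible.  The lowest bin
(0, 0.05] is structurally empty under the default design: with ≥ 2
alternative reads required and depths bounded by mean + 3 SD, the smallest
estimable AAF exceeds 0.05.

A variant is putatively functional (pfVar) when it is AA-altering
(non-synonymous or stop-gain/loss), splicing, inside a most conserved
element (MCE), predicted RNA-structure-altering, or in a non-coding RNA.
The non-coding/coding enrichment ratio divides, per mean-AAF bin, the
non-coding pfVars (MCE-flagged intergenic/intronic/UTR/up-downstream,
ncRNA, and structure-altering non-coding variants) by the AA-altering plus
splicing variants; bins with an empty denominator are reported missing, not
infinite.  Structure-altering coding variants are excluded from the
numerator so no variant can appear on both sides of the same ratio.

## Sweep scan and permutation thresholds

Windows of 40 kb tile each chromosome from coordinate 0 with a 20 kb step.
A partial terminal window is emitted only when the last full window does not
already reach the chromosome end, and only if it is at least half a window
(20 kb) long.  Windows with ≤ 10 SNPs are emitted with an undefined Hp and
excluded from testing.

Significance control is chromosome-wise and empirical.  Per permutation the
(n_maj, n_min) pairs are shuffled among the chromosome's SNP positions —
pairs are shuffled as units, preserving each site's depth and the
chromosome-wide multiset of counts — positions and therefore window
memberships stay fixed.  The scan is recomputed and the **minimum** Hp over
analysable windows recorded; the critical Hp at level α is the lower
empirical quantile (order statistic at ⌈α·n_perm⌉) of the permutation
minima, so the family of windows on a chromosome is controlled jointly via
its extreme statistic.  An observed window is significant when its Hp is
strictly below the critical value; a window exactly at the threshold is not
significant.  A per-window fallback mode (empirical P per window, no
multiplicity control) is provided for diagnostics.

The permutation core is vectorized: window memberships are precomputed once
per chromosome, each batch of shuffles is one shared index permutation
applied to both count vectors, and window sums come from cumulative-sum
differences, which is what makes 1,000+ permutations per chromosome cheap.
All randomness flows through one named, explicitly seeded generator; the
seed is a required argument, and identical seeds give bit-identical
thresholds.

`PooledHpScan` packages one line's scan as a model object; `fit()` runs the
scan plus permutations and returns `HpScanResults` carrying the window
table, the per-chromosome critical values, `significant(alpha)` and a
`summary()`.

## Region calling

Windows significant at α = 0.05 in **every** line of a group are "common";
a single failing line vetoes the window (an explicit drop-line option
re-runs the comparison without named lines, for the case where one line's
high baseline fixation depresses its critical values).  Common windows are
merged transitively when they overlap or abut (end of one equals start of
the next on the 20 kb grid); merging is idempotent and order-independent,
and merged regions can never outnumber the windows they come from.  QTL
overlap is any shared base on half-open intervals.  Within each region the
pfVars are classified from their per-line states (undetected / segregating
/ fixed at AAF > 0.9): ubiquitous-fixed (detected in every group and fixed
wherever detected), group-specific (fixed in every line of exactly one
group and at most segregating everywhere else), group-fixed (fixed
throughout at least one whole group), else segregating.  Cross-group window
sharing is computed at the window level, not the region level.  Sex
chromosomes can be excluded through a chromosome blocklist (default empty).

## Synthetic data generator

The generator emulates the study design, not reads: true SNP sites are
placed uniformly at a target density (default 15 SNPs/kb, the genome-wide
density such designs report); each site gets an annotation category from a
configurable mix (defaults shaped like a commercial-chicken SNP catalogue:
~50% intergenic, ~43% intronic, ~2% coding), an MCE flag (3.5%) and an
RNA-structure flag (0.3%).  Per line, a site is present with probability
0.9 (most variants are shared among related commercial lines, a minority
private) and its true AAF is drawn from the configured law: uniform on
[0.05, 1] by default (0.05 being the resolution floor of a 10–15 individual
pool); a per-category mode draws Beta laws instead — deleterious classes
(AA-altering, splicing) left-skewed with means near 0.3–0.4, putatively
neutral classes mildly right-skewed with means near 0.6 — reproducing the
frequency-spectrum contrasts the analysis is meant to expose; a degenerate
"fixed" law supports closed-form oracle checks.

Reads are sampled as depth ~ Poisson(λ) (λ per line, default 12) and
alternative reads ~ Binomial(depth, AAF), each alternative read assigned a
strand by a fair coin.  This ignores the finite pool of 2n chromosomes (no
hypergeometric double-sampling of individuals then reads), a documented
simplification: it is adequate for testing the pipeline's logic, but it
means the generator slightly underestimates the sampling variance of AAF
estimates relative to a true finite pool, and passing tests say nothing
about artifacts absent from the model (alignment error, indel realignment,
reference bias, depth autocorrelation).

Error sites (false positives) occur at 0.002 per base per line, carry true
AAF 0 everywhere, draw SNPQ from Exponential(mean 25) versus
40 + Exponential(mean 60) for true sites, and put all their alternative
reads on a single strand half of the time — so the SNPQ and strand filters
each have genuine discrimination to exercise, without making either filter
trivially perfect.  Sweep injection sets the true AAF to 1.0 for the
specified lines inside the interval.  Everything is driven by one seeded
generator: equal seeds give byte-identical output files.

Detection loss has a closed form under the strand rule alone: with depth
~ Poisson(λ) and binomial thinning, the per-strand alternative counts are
independent Poisson(λ·AAF/2), so P(detect) = (1 − e^(−λ·AAF/2))²; the
generator's empirical loss is tested against this oracle.

## Validation experiments and problem sizes

Two simulation studies validate the method end to end, at sizes chosen to
give tight Monte-Carlo error while keeping a desktop run in minutes:

- **Neutral calibration** — 200 independent 2 Mb chromosomes (one line,
  λ = 12, 15 SNPs/kb, no sweeps), 1,000 permutations each: the fraction of
  chromosomes with ≥ 1 significant window at α = 0.05 is checked against
  the 99% binomial band around 0.05.  1,000 permutations resolve the 0.05
  quantile to ±~0.007 and keep the full study near three minutes.
- **Sweep recovery** — 50 replicates of a 4-line group on a 1.2 Mb
  chromosome with a 200 kb interval driven to fixation in every line:
  the pipeline (filter → scan → permute → common windows → merge) must
  report a merged region overlapping the injection in ≥ 90% of replicates,
  and merged regions never outnumber common windows.

`scripts/acceptance.py` reruns both studies plus the gold-standard worked
example, the Hp brute-force oracle, the detection-loss oracle scenario and
the non-coding enrichment trend, under a caller-supplied seed.

## Numerical and degenerate-input conventions

- Empty windows have undefined Hp (NaN), never 0; windows on chromosomes
  without thresholds are reported untested, not non-significant.
- Zero depth is a hard error wherever a frequency or count orientation is
  required, as is a site beyond its chromosome's stated length, an AAF
  outside [0, 1], an unknown annotation category, and a VCF record without
  per-strand alternative depths (DP4-style); totals-only files are rejected
  rather than guessed at.
- Multiallelic SNP records are split into one call per alternative allele;
  because DP4-style fields carry only joint non-reference strand counts,
  each split call carries the record-level counts (a documented
  approximation; such records are rare in practice).
- Undefined rates (sensitivity with no truth SNPs, FP proportion with no
  retained calls) are reported as missing, never as 0 or 1.
- The empirical quantile is the ⌈α·n⌉-th order statistic, declared so that
  thresholds are bit-reproducible under a fixed seed.

## Known limitations

- No correction for Pool-seq sampling bias in AAF estimates; rare and
  low-frequency variants are systematically lost at these depths, and the
  detection-loss routine quantifies rather than corrects this.
- TN-per-base makes specificity scale-dependent (see above).
- The scan offers no Z-transformation of Hp and no LD- or haplotype-based
  statistics; the permutation null holds depth and SNP positions fixed and
  only exchanges counts, so it does not model demography — cross-line
  intersection is the guard against demographic false positives.
- The generator's per-line presence events are independent across lines;
  real lines share drift history, so cross-line allele-frequency
  correlations are not reproduced.
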