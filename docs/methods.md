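# Methods

## Coordinate model

All intervals are 0-based half-open (BED convention). GFF3 gene features
(1-based inclusive) and allc positions (1-based) are converted at the I/O
boundary and nowhere else, so interval lengths are always `end − start` and
a shared endpoint never counts as an overlap. Genes within a seqid are
ranked by `(start, end, gene_id)`; ranks drive all "genes between a pair"
counting.

## Candidate classification

An intergenic region is the span between the termini of two genes adjacent
by rank. Overlapping or nested pairs yield no region (they have no
intergenic space) but do not block the next consecutive pair. Orientation is
a pure function of the ordered strand pair: `(−,+)` divergent, `(+,−)`
convergent, equal strands tandem.

A region passes the core filter iff all of:

* length within `[min_len, max_len]` = [50, 20 000] bp, both ends inclusive;
* orientation divergent or convergent (tandem pairs never pass);
* expression fold change = max(FPKM)/min(FPKM) ≥ `min_fc` = 1.5. With one
  zero FPKM the fold change is +∞ (maximally different expression, passes
  any threshold); with both zero there is no expression evidence and the
  pair fails;
* the higher-expressed flanking gene lies in the top `top_fraction` = 50 %
  of all transcripts. The cutoff is the k-th largest FPKM with
  k = ⌈n·top_fraction⌉, membership is `fpkm ≥ cutoff`, so ties at the cutoff
  are in — deterministic and monotone;
* convergent pairs additionally need *exactly one* flanking gene in the top
  set. "Highly expressed" is read as top-set membership because that is the
  only quantified definition available in the classification; divergent
  pairs have no exactly-one condition ("either gene higher expressed").

All thresholds are inclusive; the short-region filter keeps length ≤ 1 kb.
The module's behaviour is pinned by an independent brute-force predicate
evaluation (exact agreement on hundreds of random instances) and by planted
recovery: on noiseless synthetic genomes sensitivity and specificity are
both exactly 1.0.

## Microsynteny classification

For a candidate's flanking pair and one subject genome, every pair of
BLASTP hits (left-gene hit × right-gene hit) on one subject seqid with at
most `max_between` = 5 intervening genes (inclusive) is admissible. Among
admissible pairs the scanner keeps the one with the fewest intervening
genes, breaking ties by smaller summed e-value then lexicographic subject
gene ids — a deterministic rule that considers all hits rather than
best-hit-only, which would miss conserved pairs.

Orientation is compared on the *relative* configuration: if the subject
counterparts appear in reversed rank order, the subject pair is mirrored
(order reversed, both strands flipped) before the gene-by-gene strand
comparison. This makes every verdict invariant under reversal of a whole
subject chromosome — absolute strand is meaningless across assemblies.
Classification:

| strand matches | intervening counts | verdict |
|---|---|---|
| 2 | equal | high_quality |
| 2 | differ | indel |
| 1 | equal | inversion |
| otherwise | — | none |

Both-genes-flipped is `none`: only single-gene flips count as inversions.
Intervening counts are compared on both sides (the query count is computed
generically, 0 for adjacent pairs) so the scanner also works for
non-adjacent query pairs. E-value filtering is inclusive (≤ 1e-5); the
boundary inclusivity at a float threshold is practically irrelevant but has
to be fixed somewhere, and is documented here.

High-confidence candidates are ≤ 1 kb, fold change strictly > 10, with a
high_quality verdict in ≥ 1 genome; the reported percentage is of the
syntenic set (conserved anywhere, any class). Validation shortlists take
the top k = 9 by fold change (infinite fold changes first, then by the high
gene's FPKM) and the top k = 9 by synteny breadth, ties broken by shorter
region then region id, ignoring orientation class.

## Tile methylation and UMRs

Sites are binned by `floor(pos/100)` into non-overlapping 100-bp tiles
(terminal tiles may be shorter and participate normally, with their true bp
length used in span computations). Per context the tile stores cytosine
count, methylated and total read sums; the level is the weighted value
`Σmc/Σcov`. Tiles with zero sites are emitted as missing so runs and
missing fractions cover the full seqid extent.

A tile is **missing** when it has fewer than 2 cytosines OR mean coverage
(total reads per covered cytosine) below 5×. The OR connective is the
default because a one-cytosine tile cannot support a three-context
methylation call regardless of depth; the AND reading is available via
`missing_rule: and` in the config. Coverage is per covered cytosine because
per-base genome coverage is not recoverable from site records. A tile is
**unmethylated** when every context with at least one cytosine present has
level < 0.10 (strict; exactly 10 % is methylated); a context absent from
the tile passes vacuously.

UMRs are maximal runs of consecutive non-methylated (unmethylated or
missing) tiles, trimmed of leading/trailing missing tiles so that UMR
boundaries are supported by data, then kept iff span ≥ 300 bp and
missing-tile fraction ≤ 1/3. The fraction test is exact in integers
(`3·n_missing ≤ n_tiles`), so a one-in-three-missing run sits on the
boundary and is retained. Candidate–UMR overlap requires ≥ 1 shared bp
under half-open semantics.

Global per-context levels are weighted levels (`Σmc/Σcov` over covered
sites), reported as such.

## Reporter statistics

Ratios are GFP/mCherry per replicate (the fold-change formula's
convention); replicates with zero mCherry are excluded with a warning.
A construct's FC uses the mean of per-replicate ratios, not the ratio of
means — the variance-safer reading for three biological replicates. FC is
scale-invariant under global rescaling of both channels, equals −1 at zero
signal and 0 at control level. Group comparison is one-way ANOVA plus
all-pairs Tukey HSD (statsmodels) at α = 0.05, summarised by an
insert-and-absorb compact letter display ordered by descending group mean,
which is deterministic and guarantees two constructs share no letter iff
their Tukey comparison is significant. With noiseless synthetic data the
within-group variance is zero and the studentized range is infinite; the
resulting always-reject decisions are correct and the division warning is
suppressed.

## Synthetic data: what it emulates, and what it does not

The generator lays genes out in two-gene "pair slots" separated by spacer
gaps (25 kb) longer than the miner's maximum intergenic length, so only
within-slot pairs can pass the filter and recovery statistics are exact by
construction. A configured fraction of slots (default 40 %) is planted as
true candidates, split evenly divergent/convergent; the remainder cycles
through explicit negatives — tandem pairs, divergent pairs with fold change
sampled in [1.05, 1.45], sub-50-bp gaps, convergent pairs with both genes
highly expressed, and overlapping pairs — so specificity is measured, not
just sensitivity.

Expression is drawn from two truncated log-normal bands (low: lnN(0, 0.5)
capped at 2 FPKM; high: lnN(4, 0.5) floored at 20 FPKM) with *exactly* half
of all genes in the high band, so the top-50 % cutoff separates the bands
and planted top-set membership is guaranteed. Gene lengths are log-normal
around 1.5 kb; planted gaps log-normal within [60, 950] bp.

Subject genomes are gene-order copies of the query with one planted outcome
per candidate locus: conserved, insertion of 1–5 dummy genes (indel), a
single flanking-gene strand flip (inversion), or loss via flank-gene
deletion or insertion of 6–8 genes (none). Hits are emitted per surviving
ortholog with log-uniform e-values ≤ 1e-6; optional dropout removes hits at
random (and truth downgrades affected verdicts to none).

The methylome places cytosines with geometric spacing, mean 3 bp counting
both strands — matching typical plant base composition (~19 % C per strand,
roughly 33 cytosines per 100-bp tile) — with CG/CHG/CHH proportions
(0.30, 0.25, 0.45). Coverage is Poisson (default 20×) and methylated reads
binomial at per-context background levels (CG 0.50, CHG 0.45, CHH 0.40)
outside planted intervals and a shared low level (default 0.01–0.02)
inside. The assay simulates mCherry as log-normal around 10⁴ RFU and
GFP = strength × base-ratio × mCherry × noise with multiplicative
log-normal noise of configurable CV (default 0 for exact recovery tests).

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: genes are independent between slots (no gene
density gradients or pericentromeric structure); FPKM bands are cleanly
separated, so the top-50 % rule is never stressed near the quantile;
subject genomes share perfect one-to-one orthology apart from planted
events (no paralogy, tandem duplication or assembly fragmentation);
methylation has no local autocorrelation beyond the planted intervals, no
sequence-driven context bias and no partially methylated domains; and the
reporter model has no plate effects or channel bleed-through. Results on
real inputs depend on annotation and hit-table quality in ways the planted
tests do not probe.

## Problem sizes and numerics

Default test and acceptance runs use genomes of 100–200 genes, 2–5 subject
genomes, 8–10 kb methylomes at 20× and three-replicate plates; these sizes
exercise every rule while keeping the whole suite and the acceptance script
fast. Determinism is end to end: every random draw flows from one
`numpy.random.default_rng` seed per generator, and identical seeds produce
byte-identical fixture files and reports. Degenerate inputs are defined
behaviour, not errors: empty seqids yield no regions, zero-coverage
methylomes yield all-missing tiles and no UMRs, a k larger than the
candidate pool returns the whole pool with a warning, and a construct whose
replicates are all unusable is a hard error.
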