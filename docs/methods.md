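# Methods

This note documents the models, estimators and numerical choices behind
`qremap`, and what the synthetic-data generators do and do not emulate.

## Conventions

All genomic intervals are 0-based half-open (BED convention);
`qremap.io.to_display` is the only place 1-based coordinates are made.
Sequences handed to motif code are always sense-strand: minus-strand
features are reverse-complemented at extraction, so "upstream" always
means 5′ on the RNA.  T and U are interchangeable for matching; Y is
{C, T/U}; lowercase (soft-masked) bases match; IUPAC-ambiguous subject
bases never match.  The literal string `NA` is the only missing-data
sentinel in tables; NA propagates and excludes a record from any
statistic, it is never coerced to 0.

## QRE scanning

The QRE is modelled as UACUAAY, an unconstrained spacer of 1–20 nt, then
UAAY.  Enumeration is greedy and non-overlapping by default: scanning
left to right, each upstream half-site is paired with the *nearest*
admissible downstream UAAY and scanning resumes past that match.  Greedy
pairing is deterministic and conservative; the exhaustive alternative
(`pairing="all"`, every admissible pairing) is available because
overlap handling is genuinely underdetermined — the two differ only when
half-sites overlap, and parameter-recovery tests use `all` when asking
"was the planted site found" since a chance half-site just upstream can
legitimately consume a planted site's UAAY under greedy rules.  One
related caveat: greedy matches are only stable under sequence extension
once the scan has passed one maximal site span (31 nt); the property
tests state exactly that.

The upstream half-site's first position is configurable (`first_pos` =
`U` strict, or `N`): the motif has been written both ways, and the
stricter form is the default.  Target classification counts QREs on the
mature sequence of each gene's *longest* transcript (ties broken by
smallest transcript id); the RNA-map analysis applies the same matcher
to intron sequence.

## Junction-array analysis

**Normalization.**  Per-array log₂ intensities are quantile-normalized
to the mean empirical distribution (median scaling would also be
defensible; quantile normalization is the documented default and makes
all downstream statistics invariant to per-array scale factors).

**Presence.**  Without mismatch probes, detection is empirical: within
each GC stratum (deciles of probe GC by default; strata under 20 probes
merged with their neighbour) a probe's p-value on an array is
`#(probes in stratum with intensity ≥ x) / stratum size`, so the
brightest probe gets 1/n and p is never 0.  A probe set is present when
the *median* probe p-value is ≤ `presence_p` (default 0.05, inclusive;
the even-size median is the mean of the central two) on at least one
single array.  An event is scored when its constitutive probe set is
present (the gene-expression gate) and at least two isoform probe sets
are present.  The presence threshold is a free parameter: it is
meaningful only when the chip is dominated by probes of unexpressed
genes, which is what the generator's unexpressed background pool
provides (see below).

**Event test.**  For each scored event, the include/skip-normalized
probe values are the log₂ ratios of every (include probe, skip probe)
pair on every array, grouped by condition, tested with the
tie-corrected Kruskal–Wallis H (χ², df = groups−1; an all-tied event
gives p = 1, and H is clamped at 0 against floating-point undershoot in
the tie correction).  Ratios carry the full inclusion-odds effect — a
splicing swap moves include and skip probes in opposite directions and
the ratio twice — while pure expression changes cancel.  Alternative
groupings (per-probe values minus the skip-set median; exactly centered
pair ratios) were evaluated on simulated data and recover planted
effects less efficiently, the latter because exact centering forces an
antisymmetric null that collapses the empirical alpha.

**Calibration.**  The values entering one event's test are mutually
dependent (pairs share probes; ratios share arrays), so the χ² tail is
not trusted.  Instead the same statistic is run on `n_null_tests`
randomly selected probe sets of the chip (random events, which on a
genome-scale chip are overwhelmingly null), the empirical α is the 1%
quantile of those null p-values, and the significance cutoff is
α / n_null_tests (Bonferroni).  With the published numbers this is
1.975486×10⁻³ / 12 740 = 1.550617×10⁻⁷.  On fully null simulated
arrays the fraction of events with p ≤ α matches the quantile within
binomial error, which is the calibration's defining property.

**Effect sizes.**  Probe-set summaries are medians of normalized
intensities across the set's probes (per array; per condition, the
median over its arrays).  Sepscore = log₂ of the include/skip summary
ratio, experimental over reference (positive = more inclusion).  The
separation score fits, per condition, a through-origin regression of
skip (y) on include (x) per-array summaries, b = Σxy/Σx², and reports
ss = log₂ b_exp − log₂ b_ref (negative = more inclusion; 2^|ss| is the
fold change in inclusion odds).  The two published sign conventions are
kept as two named columns and never mixed.  On noiseless data
ss = −Sepscore exactly.

## Expression analysis

Summed exonic coverage becomes a fragment count by dividing by 100 (the
coverage footprint of one 2×50-bp paired-end fragment) and rounding
half away from zero.  Counts become CPM and are quantile-normalized
across samples.  Genes pass the expression floor when the two
conditions' CPM sum to ≥ 1 (inclusive); log₂ fold changes use a 0.5
pseudocount — the floor makes its exact value nearly immaterial, it only
prevents infinities.  Differential calls are inclusive at ±1.5-fold; in
array mode a supplied q-value column must additionally satisfy
q ≤ 0.05 (the differential model that produces those q-values is
upstream of this package and deliberately not reimplemented).  The
CDF-shift test is a two-sided Wilcoxon rank-sum (normal approximation)
on log₂ fold changes of QRE-target vs non-target genes; direction is
the sign of the median difference.  Genes with NA QRE annotation are
excluded from the stratified statistics.

## RNA maps

For each exon in the activated / repressed / background sets, intronic
flanks (default 500 nt, truncated at the neighbouring exon) are scanned
with 50-nt windows in 5-nt steps.  A window counts motif occurrences
that lie fully inside it.  Windows are anchored at the splice site so
grids of exons with different flank lengths align, and each window is
*labelled by its center offset*: with edge labelling a motif planted at
−100 produces a run of significant windows centred near −72, so peak
centers would systematically miss the physical motif position; center
labelling puts the peak where the motif is, which is what a reader of
an RNA map expects.  Exons whose flank is too short at a grid position
are excluded from that position's mean (per-position n is reported).

The background band is a bootstrap over background exons (resampled
with replacement, B = 1000 by default; 2.5/97.5 percentiles of the
per-position mean).  Candidate peaks are maximal runs of grid points
with the foreground mean *strictly* above the upper band edge (ties to
the edge are inside — conservative); runs below the lower edge are
reported separately as depletion intervals.  Each peak point gets a
one-sided Mann–Whitney p (foreground per-exon window counts greater
than background; mirrored for depletion), and the peak q-value applies
Bonferroni twice to the best point p: for the number of points in the
peak and for the number of grid positions on the analysed side
(upstream and downstream are corrected separately, since pooling the
two sides is not obviously intended and per-side correction changes q
by at most a factor of 2).  The complementary word-enrichment table
compares total k-mer counts (foreground vs background, each word vs all
others) with two-sided Fisher's exact tests, Bonferroni-corrected over
all 4^k words.

## Synthetic data

The generators define the study conditions for all tests.

*Transcriptomes*: per gene, 2–10 exons (100–300 nt) with 100–400-nt
introns on its own chromosome, 1–3 transcripts (the longest uses all
exons), i.i.d. uniform ACGT background — so chance motif rates are
analytic (4⁻⁵ per position for ACUAA) — with QRE sites written wholly
inside exons and their mature-coordinate offsets recorded.

*Junction arrays*: three probe sets per event (include / skip /
constitutive, 3–8 probes each, GC ∈ [0.3, 0.7]).  Per probe and array,
log₂ intensity = baseline + isoform-fraction term + GC term + probe
affinity + noise: expressed baselines N(10, 1) vs unexpressed N(6, 1)
in log₂ units, a GC slope of 2 (GC-rich probes hybridize hotter, which
is what the GC stratification corrects), per-probe affinities N(0,
0.25²) constant across arrays, and i.i.d. N(0, probe_sd²) measurement
noise — log-normal multiplicative noise, the standard microarray model.
Planted effects move the log₂ inclusion odds by ±effect between
conditions (reference inclusion drawn uniform in [0.3, 0.7]).  An
unexpressed background pool (default 30× the expressed events) supplies
the empirical-CDF detection background; without such a pool, presence
calling is meaningless, since it ranks probes against the whole chip.
With all noise at zero every downstream statistic equals its closed
form (ss = −effect exactly).

*Expression tables*: per-gene abundances log-normal (a configurable
fraction planted below the expression floor), gamma-Poisson counts
(dispersion 0.1), a per-gene biological log₂ variation of sd 0.3 on the
fold change, the planted shift added to QRE-target genes only, and a 5%
NA fraction in the QRE annotation.  With no planted shift the CDF-shift
p-value is uniform across seeds (checked by KS test).

*RNA-map sets*: three-exon cassette genes, one per exon under test;
repressed exons get ACUAA planted in the upstream intron at the stated
offset, activated exons mirrored downstream, background exons carry
chance motifs only.  Strands are randomized to exercise the
reverse-complement path.

What the generators do **not** emulate: real exon/intron length and
composition distributions, sequence-dependent probe cross-hybridization,
correlated splicing of neighbouring events, GC-content biases of real
transcripts, or library-preparation artefacts.  Passing tests therefore
demonstrate that the estimators recover what they claim to measure
under their stated noise model — not that biological inputs satisfy that
model.

## Problem sizes and determinism

The shipped analyses run at desk scale, chosen so the whole suite and
the acceptance script each complete in minutes on one CPU: 2,000-event
null arrays for calibration, 50-event recovery runs, 200-exon-per-set
RNA maps with B = 500 bootstrap, 2,000-gene expression tables, and a
chained `all` pipeline at smaller sizes.  Every stage takes a seed and
identical (configuration, seed) pairs produce byte-identical output
files (logs carry no timestamps).

## Known limitations

- The package analyses two-condition designs; the Kruskal–Wallis
  machinery accepts more groups but effect sizes (Sepscore, ss) are
  defined for experimental-vs-reference pairs.
- Differential-expression q-values are consumed, not estimated.
- The empirical alpha assumes the chip's randomly selected probe sets
  are overwhelmingly null; on a chip saturated with true effects the
  calibration would be conservative.
- Presence calling depends on the unexpressed-background assumption
  above; `presence_p` should be revisited for chips where most probe
  sets are expressed.
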