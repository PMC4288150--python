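# Methods

## Data model and coordinates

All internal coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted exactly once, at the file boundary. Every feature
and segment carries an explicit strand. For protein-coding genes the TSS and
terminator default to the ORF-proximal boundaries when the annotation
provides no UTR features; this matches the use of ORF-adjacent distances in
the calling rules and avoids inventing UTR coordinates the input does not
contain.

The expression matrix holds log2-normalized signals for segments and genes
over a fixed sample vocabulary: strain ∈ {MATa, MATa/alpha, MATalpha/alpha},
medium ∈ {YPD, YPA, SPII, sync}, timepoint in minutes (mitotic
synchronization) or hours (SPII). The canonical design has 45 samples:
28 mitotic timepoints (0–135 min, step 5), YPD, YPA and SPII 1–12 h for the
sporulating diploid, and YPA + SPII 8, 10 h for the sporulation-deficient
MATα/α control. The design is fixed apart from a replicate count because the
correlation test's 12 degrees of freedom presuppose exactly 14 condition
values (YPD, YPA, SPII 1–12 h, replicates averaged first).

## The calling procedure

Selection filters, in order:

1. **Annotation filter** — any same-strand overlap with an annotated ORF,
   snoRNA, rRNA, tRNA, SUT, CUT or MUT excludes a segment. Zero overlap
   tolerance is the conservative reading; opposite-strand overlap is
   allowed because the segments derive from strand-specific measurements.
2. **Sporulation specificity** — strictly above the background threshold τ in
   at least 2 SPII timepoints of the sporulating diploid and never above τ in
   any mitotic or starvation sample. τ is a configuration scalar (default
   6.0 log2 units) because background estimation is array-specific and out
   of scope with segments as input; the minimum of 2 timepoints guards
   against single-sample noise. Comparisons at exactly τ do not count as
   expression.
3. **Gene assignment** — a candidate must lie < 100 bp (configurable
   `max_gap`) from a same-strand ORF's TSS (5' side) or terminator (3'
   side). The gap counts bases strictly between segment boundary and anchor;
   abutting or overlapping the anchor counts as gap 0 provided the segment
   does not extend past the opposite ORF boundary — segments properly inside
   the ORF never qualify (they are removed by filter 1 in any case). Among
   several qualifying genes the smallest gap wins, ties broken by
   lexicographic gene id; if a tiny ORF qualifies a segment on both sides,
   the smaller gap wins with 5' preferred on ties. The cognate ORF must be
   expressed (mean above τ) in YPD or YPA ("either" by default).
4. **Decorrelation** — Pearson correlation between segment and ORF over the
   14 condition values; t = cc·√(df/(1−cc²)) with df = 12, two-sided P from
   the t distribution; Benjamini–Hochberg adjustment jointly over all 5' and
   3' candidates (the single-family choice is the more conservative one);
   segments with adjusted P > α (default 0.05) are selected. Selecting
   *non-significance* is deliberate — a segment that co-varies with its ORF
   is most likely the same transcript — and carries the known weakness that
   low power favours selection; zero-variance profiles are flagged
   (`degenerate_variance`, cc treated as 0, P = 1). α is validated in
   (0, 1]; at α = 1 nothing can be selected since adjusted P ≤ 1.

The output is deterministic and invariant under input segment order
(candidates are processed in sorted segment-id order).

## PWM scoring

Matrices are frequency tables with a per-cell pseudocount (default 0.25,
preventing −∞ log weights on zero counts): f(i,b) = (count +
pseudocount)/(n + 4·pseudocount). The information weight of a column is
I(i) = Σ_b f(i,b)·ln(4·f(i,b)), zero for a uniform column and ln 4 for a
unanimous one; natural log is used and cancels in the normalization. A word
scores S = Σᵢ I(i)·f(i, wᵢ), reported min-max normalized over the reachable
score range (MSS), and identically over the core — the 5 consecutive columns
of maximal summed information, leftmost on ties (CSS). A matrix whose
selected columns are all uniform has zero score range and is defined as
maximally permissive (score 1). Scanning evaluates every offset on both
strands; minus-strand hits are reported at forward coordinates, ordered by
offset with + before −. Default thresholds are CSS ≥ 0.9 and MSS ≥ 0.7, the
conventional cut-offs for high-confidence URS1 prediction in this scoring
scheme.

The shipped URS1 matrix is consensus-derived: ten synthetic sites around
TAGCCGCCGA with mild flank degeneracy and a fully conserved GCCGCC core
(`mutrscan.pwm.URS1_SITES`). It is an approximation — the curated URS1
matrices are proprietary — and users with a TRANSFAC licence can load real
matrices through `read_transfac`, which honours permuted P0 headers.

## Enrichment

The permutation test scores each sequence once by its mean likelihood ratio
over all windows and both strands, Π f(i,wᵢ)/q(wᵢ) with uniform q = 0.25 by
default (configurable mononucleotide frequencies). The observed statistic is
the mean over targets; the null re-draws size-matched subsets from the
background without replacement (with replacement, flagged, only when the
background is smaller than the target set); P = (1 + #{null ≥
observed})/(1 + n_perm), never exactly zero. Sequences shorter than the
matrix contribute score 0. A single background mode is implemented — the
cognate mitotic promoters — because that is the comparison the analysis
design calls for. The count-based alternative is a one-sided hypergeometric
test on the number of sequences carrying at least one thresholded hit, and
`motif_percent` reports hit-carrying fractions as integer percentages
(half-up rounding).

## Length and timing statistics

Lengths are segment end − start. Fold change is the median over the mitotic
reference median, reported to one decimal (matching the precision such
ratios are conventionally given at). The mitotic references are aggregate
literature values (68 bp for 5' UTRs, 91 bp for 3'), so the Wilcoxon
signed-rank test is one-sample against the reference rather than gene-paired
— per-gene mitotic lengths are not part of the input. Zero differences are
dropped, tied absolute differences receive averaged ranks, and the null
distribution of W+ is computed exactly for n ≤ 25 by dynamic programming
over (doubled, hence integer) rank sums; above that a normal approximation
with continuity and tie corrections is used. The two-sided exact P is the
probability mass at least as far from n(n+1)/4 as observed. The in-package
exact implementation exists because the widely used library routine silently
leaves exact mode in the presence of ties or zeros.

Timing classes use the peak SPII hour: early ≤ 4 h, middle 5–8 h, late
≥ 9 h (configurable boundaries), smallest hour on ties; the score is peak
minus profile median, and flat profiles are flagged low-confidence. The
boundaries mirror the staggered induction waves of early, middle and
mid-late meiotic transcripts.

## Synthetic data

The generator is the package's testbed and defines its study conditions.
Genes are laid out in equal slots (upstream margin 1100 bp, ORF 300–600 bp,
downstream margin ≥ 700 bp); exceeding the packing capacity raises an
explicit error. Planted 5'/3' extension segments sit 0–50 bp from their
gene's TSS/terminator with log-normal lengths around medians of 241 bp (5')
and 173 bp (3') (σ = 0.45, clipped to 56–900 / 57–600 bp), emulating the
observed meiotic UTR length scale at miniature sample sizes. Expression is
additive Gaussian noise (σ = 0.25 log2 units) around a background of 4.0 for
silent rows and 9.0 for expressed rows, with τ = 6.0 in between; meiotic
rows carry a Gaussian-shaped SPII bump (width 1.5 h) peaking at an hour
drawn from the segment's timing class. Decoys each violate exactly one
criterion: constitutively expressed (fails sporulation specificity), placed
120–250 bp away (fails assignment), or sharing its bump with the cognate ORF
(fails decorrelation); additional segments coincide with planted non-coding
features (fails the annotation filter). URS1 sites — the literal consensus
in 75% of plants, otherwise a uniform single-substitution variant, on either
strand — are written into the 100-bp window upstream of each 5' segment's
distal end at the target rate (default 0.66) and upstream of every gene's
mitotic TSS at the background rate (default 0.10), avoiding collisions with
previously planted sites (a plant is skipped, and recorded as absent, if no
collision-free position exists). The exact/variant mixture reflects that
both perfect and near-perfect URS1 matches occur at functional sites.

What the generator does **not** emulate: probe-level array noise and
segmentation artifacts, overlapping genes and complex locus structure,
biological covariance between neighbouring transcripts, realistic genome
base composition, and the true (wide) meiotic UTR length tails. Passing
tests therefore demonstrate correctness of the procedure's logic and
calibration of its statistics under the stated model, not performance on
raw tiling-array data.

`generate_genome` returns segments along with genome/annotation/truth
because URS1 planting positions depend on the 5' segment coordinates;
`generate_expression` consumes the same object. All outputs are
deterministic and byte-identical under a fixed seed.

## Numerical choices and edge cases

- BH adjustment delegates to `scipy.stats.false_discovery_control` after
  range validation; a brute-force step-up oracle verifies it in the tests.
- Pearson cc is clipped to [−1, 1]; |cc| = 1 maps to P = 0.
- Core-window and timing argmax ties resolve leftmost/smallest, with a
  1e-12 tolerance against float summation order.
- `upstream_window` truncates (never pads) at chromosome edges and returns
  the reverse complement for minus-strand anchors.
- The BED score for a call is round(1000·(1 − adjusted P)) clamped to
  [0, 1000].

## Problem sizes

Default synthetic datasets use 40 genes on 2 × 50 kb chromosomes with 16
planted mUTRs, 9 decoys and 5 annotated non-coding segments; the recovery
study in the acceptance script aggregates 20 such datasets, the enrichment
calibration uses 200 null datasets of 40 × 80 bp windows with 199
permutations each, and the planted-enrichment run uses 25 targets vs 40
background windows with 999 permutations. These sizes were chosen as the
smallest at which the planted effects are comfortably separated and the
calibration estimates are stable.

## Known limitations

- The selection-by-non-significance rule inherits its published weakness:
  candidates with noisy, low-information profiles are easy to select. The
  report flags degenerate profiles but cannot rescue low power.
- The shipped URS1 matrix is a documented approximation of the curated
  matrices; absolute hit counts at fixed thresholds will differ from scans
  with licensed matrices (the enrichment statistics are threshold-free and
  more robust to this).
- Single-site P-value calibration and non-uniform dinucleotide backgrounds
  are out of scope for the scanner.
- Complex overlapping-gene segmentation ambiguities are not handled; such
  cases require strand-specific sequencing data rather than segment
  intervals.
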