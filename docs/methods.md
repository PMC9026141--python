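# Methods

## Scope and model

The package quantifies synonymous codon usage bias in sets of viral
coding sequences and attributes it to mutation pressure, translational
selection and dinucleotide-level constraints. All statistics operate on
codon count tables pooled per isolate from its validated ORFs; group
summaries (per clade, per host) are arithmetic means of per-isolate
values, with pooled-count variants behind a `pooled` flag. Overlapping
ORFs are each counted in full — codon statistics are per-ORF, so
overlap nucleotides contribute to every ORF containing them.

Sequences are held internally as RNA (`U`); DNA input is converted on
read. Coordinates are 0-based half-open. Only the forward strand is
scanned for ORFs, matching the mRNA / positive-strand-virus context.
Records containing ambiguity codes are excluded from codon counting
(the triplets are skipped and tallied) but retained for reporting.

### CDS validation

A putative CDS passes when it starts with AUG, ends with UAA/UAG/UGA,
has length divisible by three, contains no internal in-frame stop, no
ambiguity codes, and codes for at least `min_length` (default 30) amino
acids between start and stop. Failures are reported reason-by-reason,
never raised, so quality filtering is auditable.

### RSCU and classification

RSCU_ij = x_ij · n_i / Σ_j x_ij within each synonymous family. Families
with zero total are *missing*, never zero — a zero would spuriously
classify every member as significantly unpreferred. Classification
follows the conventional thresholds with exclusive boundaries:
significantly preferred > 1.5, preferred (1.0, 1.5], no bias = 1.0,
unpreferred [0.6, 1.0), significantly unpreferred < 0.6. Because
printed RSCU tables round to two decimals, values of exactly 1.00 are
common; both the strict (> 1.0) and inclusive (≥ 1.0) preferred-codon
counts are therefore reported. AUG and UGG are excluded from
classification (59 classifiable codons).

### Composition

GC1/GC2/GC3 are computed over all sense codons (stops excluded), which
reproduces the table output of the CodonW program; a synonymous-only
GC3s variant is available behind `synonymous_only_gc3` since published
tables are often ambiguous about which was used. The "3s" base
fractions (A3s/C3s/G3s/U3s) are restricted to synonymously degenerate
families — AUG, UGG and stops never contribute — and sum to one.
GC12 is exactly (GC1 + GC2)/2.

### Effective number of codons

Wright's estimator with CodonW-compatible conventions: per-family
homozygosity F = (nΣp² − 1)/(n − 1); families with n < 2 skipped;
families with F = 0 (possible at tiny counts) excluded from their class
mean to avoid division blow-ups; a missing three-fold class (Ile is its
only member) imputed as (F̄₂ + F̄₄)/2, other missing classes from the
mean of available ones; the combined value clamped to [20, 61]. Note
that F carries a finite-sample correction, so ENC is invariant to count
scaling only asymptotically. The ENC-plot null curve is
ENC_exp(s) = 2 + s + 29/(s² + (1−s)²); a point is flagged "below the
curve" on a strict inequality.

### Neutrality regression

Ordinary least squares of GC12 on GC3, one point per isolate, no
length weighting. The correlation is Pearson's r with the two-sided
t-test p-value (identical to the regression F-test for simple OLS).
slope·100 is reported as the mutation-pressure percentage and
(1 − slope)·100 as the selection percentage; the dominant-force label
uses 0.5 as an advisory boundary and always accompanies the numbers.

### Dinucleotide odds ratios

ρ*_XY = f_XY/(f_X·f_Y) with mononucleotide frequencies taken from the
same region as the overlapping dinucleotide counts. Region pieces
(e.g. the several UTR fragments between ORFs) are never concatenated:
no pairs are counted across junctions. Calls use inclusive thresholds,
≤ 0.78 underrepresented and ≥ 1.23 overrepresented. Ratios whose
mononucleotide product is zero are reported missing rather than zero.
UTR is defined as the complement of the (merged) CDS spans.

### Host adaptation

Pearson correlation between virus and host RSCU vectors over shared
non-missing classifiable codons (at least 10 required); Spearman is
available behind a flag because RSCU vectors are bounded and skewed.
Host RSCU is built from validated CDS only, as RSCU of pooled counts.
Rankings break ties by shared-codon count then label order, and exact
ties are reported explicitly.

## Synthetic data generator

The generator emulates the three structures the analyses assume:

1. **Codon frequencies.** Codons are drawn per amino acid from
   within-family probabilities; the defaults are the published CpMMV
   RSCU vector divided by family size (renormalised), with a generic
   database-average amino-acid profile. Under these defaults the
   implied usage has ENC ≈ 50.3.
2. **GC12-on-GC3 structure.** Isolate GC3 targets are spread evenly
   over `gc3_range` and GC12 targets follow
   intercept + slope·GC3 + N(0, noise_sd). Each isolate's 61-codon
   distribution is exponentially tilted,
   p(c) ∝ q(c)·exp(t₃·g₃(c) + t₁₂·(g₁(c)+g₂(c))) with g_k indicating
   G/C at position k, and (t₃, t₁₂) solved by root-finding so the
   expected composition hits the targets. When suppression is active
   the expectation is taken under the stationary law of the suppressed
   sampler (the last base of the previous codon is a 4-state Markov
   chain), so the imposed slope survives suppression. Unreachable
   targets raise a feasibility error.
3. **CpG/UpA depletion.** Sequential sampling multiplies the weight of
   any codon (or UTR base) whose choice would create CpG or UpA —
   within the codon or across the junction with the previous one — by
   the corresponding suppression factor in (0, 1]. A separate
   `suppress_dinucleotides` operation applies the same rule as a
   synonymous-only resampling of an existing CDS, leaving the encoded
   protein unchanged; factors of 1.0 are an exact identity.

The default "virus-like" fixture (`cpmmv_like_spec`) has 33 isolates of
six ORFs and ~2,900 codons each, base composition
A 0.29 / U 0.30 / C 0.18 / G 0.23 for untranslated segments, slope
0.3863 with intercept 0.2555 (placing GC12 near 0.41 at GC3 0.40),
noise_sd 0.005, and suppression factors CpG 0.65 / UpA 0.60. The
factors are mild because the RSCU-derived codon frequencies already
embed most of the virus's codon-level CpG/UpA avoidance (the
unsuppressed CDS CpG ratio is already ≈ 0.64); they chiefly carry the
depletion into the untranslated regions, where an iid background would
otherwise show none. The GC3 spread (0.30–0.50) is wider than real
isolate sets, which cluster tightly; the width makes the regression
identifiable at n = 33.

What the generator does **not** emulate: phylogenetic correlation
among isolates (isolates are independent draws), recombination, codon
order structure beyond first-order dinucleotide effects, amino-acid
composition differences between genes, and UTR secondary-structure
constraints. Passing recovery tests therefore demonstrates correctness
of the statistics, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- Empty tables, all-ambiguous sequences, zero-variance regressors,
  single-group range requests and sub-10-codon RSCU overlaps raise
  typed errors rather than returning sentinel values.
- Tilting is solved with `scipy.optimize.root` (hybr) from a zero
  start; residuals above 1e-8 raise a feasibility error.
- Regression, correlations and p-values come from
  `scipy.stats.linregress` / `pearsonr` / `spearmanr`.
- RSCU family sums are validated to the family size within 1e-9 in
  tests; externally supplied (printed, two-decimal) tables are checked
  loosely (±0.05·family size).
- Classification uses exact float comparison for the no-bias class
  (RSCU = 1.0), which is intentional: it matters only for printed
  tables, where 1.00 is exact.

## Problem sizes used in the test suite

Recovery tests use 100k-codon draws for RSCU (3-binomial-SE bands plus
a 0.02 allowance for the two-decimal rounding of the published
frequencies), 200k-base draws for composition and dinucleotide nulls,
500 replicates of 33 isolates for neutrality-slope bias (count-table
sampling path), and a 9-isolate scaled fixture for pipeline plumbing.
These sizes keep the full suite under a minute while leaving sampling
error far below the tested tolerances.

## Known limitations

- ENC uses Wright's original estimator; background-corrected variants
  (ENC′, Sun et al.) are out of scope.
- The neutrality regression is plain OLS; errors-in-variables
  attenuation from finite codon counts slightly biases recovered
  slopes toward zero (≈ 2% at the default fixture sizes), and
  phylogenetic non-independence is not modelled.
- Host adaptation is RSCU-vector correlation only; CAI/tAI-style
  reference-set indices are not implemented.
- GenBank feature parsing is limited to what the fetch helper extracts
  (CDS span coordinates); joined/spliced locations are not supported.
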