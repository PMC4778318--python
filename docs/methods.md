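# Methods

This note documents the models behind `motiforient`, the defaults and why
they were chosen, what the synthetic worlds do and do not emulate, and the
numerical and design decisions a maintainer should know about.

## Coordinates and sequence conventions

Upstream positions are 1-based-negative closed intervals on the coding
strand: position −1 is the base immediately 5' of the TSS, a full region of
length L spans −L..−1.  Internal 0-based offsets never cross a module
boundary.  Interval scans operate on the excised subsequence, so a motif
match can never straddle an interval boundary; a hit belongs to an interval
by its 5'-most base.  Ambiguity codes in genomic sequence are counted
fractionally in compositions (an N adds ¼ to each base) but are never
matched by motif scanning: a motif position accepts only concrete A/C/G/T
bases in its variant set, so masked sequence cannot inflate hit counts.

## Motif curation

The cascade runs in a fixed order: trim terminal Ns; drop motifs with fewer
than 4 unambiguous bases (`min_unambiguous`); drop motifs containing a run
of ≥4 consecutive Ns (`n_run_limit` — read as a *run* because isolated Ns
are common in protein-binding-microarray consensi and are retained);
flag exact duplicate consensi (first kept); flag palindromes (excluded from
all orientation analyses — they are orientation-invariant by construction);
flag containment, both explicit (plain substring) and by per-position
variant-set subsets at any offset.  Contained motifs stay in single-motif
analyses but are excluded from pair analyses, where a contained motif's
hits are not independent of its container's.  Containment is checked in the
forward orientation only; a reverse-complement check exists behind a switch
(`rc_containment`, default off) because its proper behaviour is a genuinely
open choice and off is the conservative one.

## Orientation preference

On a strand with asymmetric base composition a non-palindromic motif is
expected to map to one orientation more often under a null of no biology.
The expected forward fraction corrects for this:

    F = P_fw / (P_fw + P_rc),  P_fw/rc = ∏_i Σ_{b ∈ variants(i)} p(b),

with p(·) the fractional base frequencies of the scanned interval.  The
observed forward count is tested with an exact two-sided binomial test at
success probability F.  Two-sidedness follows the minimum-likelihood
convention (scipy's `binomtest`); the doubled-smaller-tail alternative
differs only in asymmetric cases and was pinned for reproducibility.
Preference is the sign of `log((n_fw/n_rc)/(F/(1−F)))`, with the obvious
0-count limits.  Motifs with fewer than `min_hits = 10` total hits are
marked non-assessable and excluded from the BH family; BH families are
formed per interval over all assessable motifs of a run, and the adjusted
q is used in the filter cascade by default (raw p available via
`use_adjusted_orientation_p=False`).

## Positional entropy

PE is Shannon entropy, in nats, of the distribution of hit start positions
over ten equal bins of the 500-bp region, with 0·ln 0 = 0: ln 10 ≈ 2.303
for uniform spread, 0 for single-bin confinement.  PE is only computed on
the full-length scan — in a 100-bp interval "positional preference" is
confined by definition.  The sign convention (−Σ p ln p, a positive
quantity) is the only one under which uniform placement yields the
published-scale values near ln 10; a literal Σ p log p is non-positive and
is therefore not what the statistic means.

## Filter cascade

Per motif and interval, with thresholds p < 0.05 and Cohen's d > 0.01:

* **C** — presence effect: genes carrying the motif (either orientation)
  vs a motif-free negative sample are more co-expressed (p and d above
  thresholds, d positive).
* **D1** — orientation preference: BH-adjusted binomial q < 0.05.
* **D2** — D1 and the exclusively-forward vs exclusively-reverse gene-set
  comparison favours the preferred orientation (p < 0.05, |d| > 0.01,
  means ordered accordingly).
* **D3** — D2 and strictly lower PE in the preferred orientation.
* **E** — the D2 criteria evaluated within the C-passing subset, with the
  orientation-test BH family re-formed over that subset (the
  multiple-testing family must match the conditioned universe).
* **F** — E plus the PE condition.

Nesting (D3 ⇒ D2 ⇒ D1, F ⇒ E ⇒ C) holds by construction and is
property-tested.  Motifs missing any component statistic (e.g. too few
exclusive-orientation genes to correlate) are excluded from the verdict
list rather than half-scored.

A note on calibration: C fires for *any* real co-expression difference
between the positive set and a random negative sample, including
differences inherited from overlapping modules of other motifs; with very
large pair samples, tiny d values become "significant" because pairs
sharing a gene are not independent observations.  This is a faithful
reproduction of the protocol, not an endorsement; the permutation-null
test shows the rank-sum p is approximately calibrated for sets of ≥ ~30
genes and the null-world false-positive rates stay below nominal + 3 SE.

## Gene sets for co-expression

Positive set: measurable genes with ≥1 hit in the interval, either
orientation.  Negative set: a seeded uniform sample of motif-free
measurable genes of size max(|positive|, 100) — the floor guarantees power
for rare motifs, the cap prevents tens-of-thousands-strong negative sets.
The draw is per-motif with an explicit seed.  Orientation sets are the
exclusive ones: genes hit in both orientations belong to neither.
Pairwise Pearson correlations are computed for all C(n,2) gene pairs, or a
seeded uniform subsample of `pair_cap = 500,000` pairs beyond that; the
subsample is drawn directly from the flattened index triangle, so every
pair is equally likely.  Cohen's d uses the average-variance denominator
`(mean_a − mean_b)/√((var_a+var_b)/2)`.

## Dinucleotide orientation ratios

Overlapping dinucleotides (step 1) are counted within each excised window,
never across gene boundaries; positions containing ambiguity codes are
skipped.  `R = f_B1B2/(p_B1 p_B2)` uses the same window's fractional base
frequencies, and `DOR = R / R_rc`.  Palindromic dinucleotides (AT, TA, CG,
GC) are reported as exactly 1 rather than recomputed, avoiding spurious
floating-point departures from an identity.  Counts are pooled across
genes before normalization (the simplest reading; per-gene normalization
would weight short/ambiguous windows differently and is noted as a
sensitivity-analysis variant).  DOR(d)·DOR(rc(d)) = 1 and the
reverse-complement equivariance of the profile are property-tested.

## Randomized controls

Each true motif is replaced by `multiplier = 5` random motifs of identical
length.  R1 draws concrete A/C/G/T from the upstream interval composition;
R2 draws characters — ambiguity codes included, each an atomic symbol —
from the true set's observed character frequencies.  Random sets pass
through the same curation (palindromes excluded, etc.) before analysis, so
pass-rate comparisons are like-for-like; per-filter comparisons use
two-sided Fisher exact tests, BH-corrected across the comparison family.
The palindrome-enrichment test is an upper-tail binomial: observed
palindromes among true motifs against the palindrome rate of a large
length- and composition-matched random set.

## Motif pairs

A pair instance is one non-overlapping hit combination of the two motifs
in one gene's interval (every combination counts toward arrangement
totals; a gene counts once in the hypergeometric gene tallies — instance
counts legitimately exceed gene counts).  Arrangements are the 8
order×orientation cells (4 for same-motif pairs, where order is
meaningless and cells read orientation in positional order).  The
arrangement statistic is Shannon entropy of the cell counts after adding a
pseudocount of 1 to every cell; the empirical p is the fraction of 100,000
multinomial-uniform null draws (same total, same pseudocount) with
*smaller* entropy.  p is reported as r/B (so 0 means "below the shuffle
resolution"); the (r+1)/(B+1) variant is a one-line change if an unbiased
estimator is preferred.  A pair is arrangement-preferring when the 8-cell
test and both per-order 4-cell tests are BH-significant — the conditional
tests separate genuine orientation structure from pure order imbalance.
An order block with zero instances is uniform after pseudocounts and thus
never significant; a pair occupying only one order can therefore not be
arrangement-preferring, which is the intended conservative behaviour.
Order preference itself is an exact binomial test at p₀ = 0.5 on the two
order totals, different-motif pairs with ≥ 50 instances only.
Co-occurrence enrichment is upper-tail hypergeometric with the gene
universe defaulting to all genes with upstream sequence (configurable to
the expression-measurable set).  "Most frequent arrangement" co-expression
compares the top cell's genes against the three least frequent cells'
genes, ties broken by lexicographically first cell label.

## Synthetic worlds

Sequences are generated window-by-window from per-window first-order
Markov models (4×4 transition matrix plus initial distribution), which is
exactly the order of structure the dinucleotide analysis detects — higher
orders would add nothing testable here.  Implants overwrite sequence at a
start position drawn from a distribution over the ten PE bins (the motif
always fits inside its bin), forward with configurable probability;
implants never overlap one another, and every implant is recorded in a
truth table whose coordinates are re-locatable by the scanner (property-
tested).  Expression follows a latent-factor model: genes sharing an
implanted motif load on a standard-normal factor with loading λ over
Gaussian noise of SD σ, giving within-module pairwise correlation
λ²/(λ²+σ²) — the closed form used for calibration (λ = 0.5, σ = 1 →
r ≈ 0.2).

Default study conditions: 2,000 genes × 500 nt × 200 samples; implant
probability 0.15; orientation bias 80:20; positional confinement to the
three TSS-proximal bins; module loading 0.5.  Null-calibration worlds use
150 genes × 60 noise-only samples and eight 6-mer motifs so that chance
hits clear the 10-hit assessability floor, and 100 such worlds keep the
suite inside a desk-scale run.  What the generator does *not* emulate:
repeat structure, nucleosome or methylation signal, array-specific noise,
gene-length or GC covariates, and dependence between expression modules —
so passing tests demonstrate correctness of the statistics on data
matching their assumptions, not robustness to real-genome confounders.

## Numerical choices

* Exact tests via scipy (`binomtest`, `fisher_exact`, `hypergeom`,
  `mannwhitneyu` — exact for small tie-free samples, tie-corrected normal
  otherwise); BH via statsmodels.  Each is cross-checked against an
  independent enumeration oracle in the test suite.
* CG-skew ratio with a zero G count is reported as +∞ rather than an
  error: it is a legitimate degenerate value on tiny inputs.
* Occurrence ratios for dinucleotides whose component base never occurs
  are NaN (undefined), not an error; an observed dinucleotide with a
  zero-frequency base is an input inconsistency and is rejected.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns are bit-identical.

## Known limitations

* The rank-sum test over correlation pairs ignores pair dependence; p
  values for very large, strongly overlapping sets are anti-conservative.
* Leftmost-greedy non-overlapping matching is pinned (global-regex
  semantics); for equal-length patterns it coincides with
  maximal-cardinality packing, but other conventions exist.
* The hypergeometric universe and the choice of raw vs BH-adjusted p in
  the D1 column are configurable because the canonical choices are
  ambiguous; defaults are documented above.
* PWM/HMM motif models, mismatch-tolerant scanning and real-genome inputs
  are out of scope.
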