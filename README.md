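# motiforient

Does the orientation of a transcription-factor binding site (TFBS) in a
gene's promoter matter?  A motif and its reverse complement present the
identical double-helix interaction surface, but the bound factor is rotated
180° relative to the transcription start site (TSS) — so orientation *could*
matter, and deciding whether it does is a statistics problem, not a
sequence-gazing problem.  `motiforient` implements that statistical
framework end to end for promoter-proximal consensus motifs, together with
a ground-truth synthetic-data generator so that every stage is testable
without any genome or microarray download.

## What it computes

Given a catalog of IUPAC consensus motifs, a set of fixed-length
coding-strand upstream sequences (position −1 adjacent to the TSS), and a
normalized log-scale expression matrix:

* **Curation** — terminal-N trimming, ≥4 unambiguous bases, N-run removal,
  duplicate removal, palindrome exclusion, containment flagging.
* **Mapping** — leftmost-greedy non-overlapping string matching of each
  motif and its reverse complement against each upstream interval.
* **Orientation preference** — the expected forward-mapping fraction under
  the interval's base composition,

  `F = P_fw / (P_fw + P_rc)`,  `P_fw/rc = ∏_i Σ_{b ∈ variants(i)} p(b)`,

  and an exact two-sided binomial test of the observed forward count
  against `F`; preference is the sign of
  `log((n_fw/n_rc) / (F/(1−F)))`.  Benjamini–Hochberg correction per
  interval family.
* **Positional entropy** — `PE = −Σ_i p_i ln p_i` over ten 50-bp bins of
  hit start positions; `ln 10 ≈ 2.30` means uniform spread, 0 means
  complete confinement.
* **Dinucleotide orientation ratios** — `R_B1B2 = f_B1B2 / (p_B1 p_B2)` and
  `DOR = R_B1B2 / R_rc(B1B2)`; log2 DOR ≠ 0 reveals intrinsic first-order
  strand directionality (palindromic dinucleotides are identically 1).
* **Co-expression comparisons** — Wilcoxon rank-sum plus Cohen's `d`
  between the pairwise-Pearson-correlation samples of two motif-defined
  gene sets (presence vs absence; forward-only vs reverse-only).
* **Filter cascade** — per-motif verdicts C (presence effect), D1
  (orientation preference), D2 (preferred orientation more co-expressed),
  D3 (lower PE in preferred orientation), E (D2 criteria within the
  C-passing subset, BH re-formed), F (E plus the PE condition).
* **Randomized controls** — length-matched random motifs drawn from the
  upstream composition (R1) or the motif character distribution (R2),
  compared filter-by-filter with two-sided Fisher exact tests; plus the
  palindrome-enrichment binomial test.
* **Motif pairs** — hypergeometric co-occurrence enrichment, binomial
  order preference, and an entropy statistic over the 8 order×orientation
  arrangement cells (4 for same-motif pairs) with an empirical
  multinomial-uniform null of 100,000 shuffles, refined by per-order
  4-cell tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
worlds with known truth.  `analysis/02_single_motif_filters.py` implants
one motif with an 80:20 forward bias confined near the TSS and one
orientation-neutral motif, both tied to co-expression modules
(factor loading λ = 0.5), then runs the cascade:

```
motif_id interval  n_fw  n_rc  F_expected     q_orient  cohens_d    PE_fw    PE_rc    C    D1    D2    D3     E     F
  BIASED -500..-1   240    82    0.500000 7.992824e-19  2.026383 1.216085 1.595853 True  True  True  True  True  True
 NEUTRAL -500..-1   166   171    0.499273 8.276124e-01  1.809830 2.286715 2.279930 True False False False False False
```

Reading the rows: the biased motif maps forward 240 : 82 against an
expected 50:50 (q ≈ 8e−19 → D1), its implanted genes are strongly
co-expressed (Cohen's d ≈ 2.0 → C), the forward-only set is the more
co-expressed one (D2) and its forward hits are positionally confined
(PE 1.22 < 1.60 → D3); the neutral motif shows the presence effect only
(C true, everything orientation-specific false), exactly as constructed.
`analysis/03_dinucleotide_asymmetry.py` localises an implanted P(C|T)
inflation to the TSS-proximal window (log2 DOR(TC) = +0.20 there, ≈ 0
elsewhere), and `analysis/05_motif_pairs.py` recovers a co-implanted,
order- and orientation-correlated motif pair as enriched
(q ≈ 9e−133), order-preferring (135:33, q ≈ 8e−16) and
arrangement-preferring.

A `motiforient` CLI (subcommands `curate`, `orient`, `dinuc`, `pairs`)
exposes the same pipeline for on-disk TSV/FASTA inputs.

## Layout

```
src/motiforient/   library: catalog, upstream, mapping, orientation,
                   dinucleotide, coexpression, randomization, pairs,
                   synthetic, pipeline, cli
analysis/          numbered narrative drivers writing tables to results/
tests/             unit, property and acceptance suites
docs/methods.md    models, assumptions, parameter choices, limitations
```
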