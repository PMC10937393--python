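# Methods

## Problem and approach

`repeatladder` quantifies somatic instability of trinucleotide repeat
tracts (CAG at *HTT* exon 1 or *ATXN3* exon 10) from single-end amplicon
sequencing of sorted cell populations. Because a repeat tract differs
between reference alleles only in copy number, conventional single-reference
alignment cannot size it; instead a *reference ladder* is built — a family
of amplicon sequences identical except for the number of uninterrupted
repeat units i — and every read is classified to the ladder member it
matches uniquely best. The counts R_i of uniquely assigned reads form the
repeat-length histogram from which all downstream statistics are computed.

## Read classification

Each read is scored against every ladder member by **semi-global edit
distance** (unit costs for mismatch and indel), with the read constrained
to align to a *prefix* of the reference: read 1 of the amplicon begins at
the upstream primer and may end anywhere inside the construct. Both
orientations are scored. The implementation uses edlib's banded
algorithm; the band is tightened on the fly to `best + margin - 1`, which
is provably sufficient to detect both a strictly better member and any
competitor inside the uniqueness margin, so the banded scan is exactly
equivalent to an exhaustive full scan (the test suite verifies this
against an independent `Bio.Align.PairwiseAligner` oracle on randomized
batteries).

A read is assigned to index i only if all of the following hold,
otherwise it is counted unassigned with an explicit reason:

| rule | parameter | default | rationale |
|---|---|---|---|
| unique minimum | `margin` | 1 | any cost tie → `ambiguous`; biased tie-breaking would shift R_i by ±1 systematically |
| error budget | `max_error_frac` | 0.10 | cost ≤ ⌈0.10 × read length⌉, else `max_error` |
| downstream anchor | `min_downstream_anchor` | 12 nt | the read must reach ≥ 12 nt past the tract, else `too_short` |

The anchor rule realizes the detection ceiling of the assay: with 400-nt
reads and the default flanks, tracts above ~113 repeat units cannot be
anchored, so the ladder is capped at i = 113 and longer somatic expansions
are invisible — a documented limitation of the read geometry, not of the
classifier. Base qualities are ignored; `N` bases count as mismatches;
reads with other characters are rejected per read, never fatally.

## Progenitor-allele calling

N (normal allele) and M (unexpanded mutant allele) are defined from the
two modes of the histogram of a designated non-expanding reference cell
type (manifest role `allele_reference`, e.g. glia). Mode finding is local
maxima on raw counts (optional 3-point smoothing, off by default): the two
highest peaks separated by ≥ `min_separation` (default 5 RU), the
secondary reaching ≥ `prominence_frac` (default 0.05) of the primary.
N is the smaller mode. A single qualifying mode (homozygosity, absent
mutant allele) is an explicit error, never a silent guess. The defaults
tolerate PCR-stutter shoulders up to ~20% of a peak because shoulders at
±1/±2 are not local maxima and are closer than `min_separation`.

## Tract-structure detection and re-laddering

Donors vary in the post-tract cassette structure (presence of the CAA-CAG
interruption, CCG-tract length). Structure is detected per read by
anchoring the upstream flank (≤ 2 edits), skipping the uninterrupted
repeat run, then consuming the expected cassettes in order — exact run
counting for single-codon cassettes, ≤ 1-edit block matching for fixed
cassettes. The modal structure across reads is compared with the
template; an atypical modal structure triggers rebuilding the ladder from
the adjusted template and re-sizing. Two structures at near-equal
frequency (≥ 30% each) are both reported and flagged for per-allele
re-laddering rather than choosing one. Note that a *mild* structural
change keeps reads within the error budget on the canonical ladder, so
the symptom of an undetected atypical structure is a constant offset in
the modes, not a spike in unassigned reads — which is why the structure
check runs on every sample rather than being triggered by QC.

## Instability statistics

With i_max = 113:

- normal-allele RoSE = (R_{N+1} + R_{N+2} + R_{N+3}) / R_N
- mutant-allele RoSE = Σ_{i=M+1}^{113} R_i / R_M
- MSLG (RU) = Σ_{i=M}^{113} (R_i · i) / Σ_{i=M}^{113} R_i − M

The supports are exactly the formula supports: reads with N+3 < i < M are
tallied as `intermediate_reads` for QC but enter no statistic, and
contractions of the mutant allele (i < M) are not measured. All three
statistics are invariant under uniform rescaling of counts; histogram
normalization (scaling to 1,000 reads, real-valued, no rounding) is
display-only and provably leaves MSLG unchanged.

## Cohort comparisons

Per-donor statistics grouped by cell type are compared with a classical
fixed-effects one-way ANOVA (unpaired, as literally named; a repeated-
measures design is not assumed), followed by pairwise two-sided
pooled-variance t-tests adjusted by the Holm–Šidák step-down formula
adjusted_k = 1 − (1 − p_(k))^(m−k+1) with enforced monotonicity. The
"ratio paired t-test" is the paired t-test on log-transformed values
(the log base cancels in t and p). Zero within-group variance with
distinct means is reported as an underflow-floored p with a flag.

## Synthetic data generator

The simulator emulates the assay's study conditions, not an abstract
error model. Per molecule: allele (mutant with probability
`allele_balance` = 0.5), somatic gain (with probability
1 − `p_unexpanded`, g drawn from a discretized gamma, truncated so
M + g ≤ 113), PCR stutter over {−2, −1, 0, +1} with contraction bias
(P(−1) = s, P(−2) = s²/2, P(+1) = s/4; default s = 0.05), sequence
rendering from the locus template, i.i.d. substitutions at rate ε
(default 0.002), truncation to 400 nt from the upstream-primer end,
constant base qualities. One global seed drives per-sample substreams
hashed from the sample id, so cohorts are reproducible while samples stay
independent of manifest order.

Cell-type presets encode the reported expansion severity of the sorted
populations:

| preset | p_unexpanded | gain mean (shape) | truth MSLG |
|---|---|---|---|
| `msn_like` | 0.10 | 24.4 (2.2) | ≈ 22 RU; ≈ half of mutant molecules gain > 20 RU |
| `chat_like` | 0.15 | 21.2 (2.2) | ≈ 18 RU |
| `pc_like` | 0.50 | 10.0 (2.0) | ≈ 5 RU |
| `glia_like` | 0.97 | 2.0 (1.5) | < 1 RU (allele-reference role) |

The MSN-like parameters were chosen so that only a small fraction of
mutant molecules remain unexpanded while about half gain more than 20
units, which fixes (p_unexpanded, gain mean) ≈ (0.10, 24.4) for a gamma
of moderate shape. Real stutter magnitude at 40–110 CAG units is not
well quantified; the stutter defaults are conventions, and the gamma gain
family is a modeling choice — the pipeline itself is
distribution-agnostic.

**What the simulator does not model:** chimeric reads, index hopping,
quality-score error profiles, length-dependent PCR efficiency (longer
alleles amplifying less), somatic contractions beyond stutter, and
cell-to-cell contamination of sorted populations. Passing tests
therefore demonstrate correctness of the sizing/statistics machinery
under the stated noise model, not robustness to every artifact of real
amplicon libraries.

## Default locus templates

The shipped `HTT_ex1` template has the canonical exon-1 architecture —
(CAG)i, CAA-CAG interruption, CCG-CCA spacer, (CCG)7, (CCT)2 — and
`ATXN3_ex10` a pure CAG tract. Their flank sequences are synthetic
placeholders of realistic length; the algorithm is structure-parametric,
so correctness does not depend on the clinical flank sequences, but real
analyses must supply templates with the true amplicon flanks (YAML,
flanks inline or by FASTA reference).

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 5 donors × 4–5 cell types
at 2,000–5,000 reads per sample — enough for MSLG standard errors well
below the 0.5-RU recovery tolerance — with parameter recovery checked
across 20 seeds. All statistics are exact rational arithmetic on integer
counts (no smoothing); peak finding breaks height ties toward the larger
index before the N < M ordering is applied; empty denominators raise
explicit `UndefinedStatisticError`s that the pipeline records as
per-sample failures without aborting the run.
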