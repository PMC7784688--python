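# Methods

This note documents the models and procedures implemented in
`prophagenet`, the parameter defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
conventions that matter for reproducing results.

## Prophage similarity: wGRR

For two prophages *A* and *B* with proteome sizes #A and #B, the weighted
gene repertoire relatedness is

    wGRR(A, B) = Σᵢ id(Aᵢ, Bᵢ) / min(#A, #B),

summed over the *p* reciprocal-best-hit (BBH) protein pairs, with
identities as fractions in [0, 1]. The score is 0 with no homologs and 1
when every protein of the smaller prophage has a 100 %-identical BBH. The
pipeline treats the homology search itself as input (a BLAST-like tabular
file from e.g. mmseqs2 or blastp); identities arrive as percents at I/O
and are converted to fractions inside the sum.

Hit filtering defaults: e-value strictly below 10⁻⁴ ("lower than"),
identity at least 35 % and coverage at least 50 % (inclusive, "at least").
The coverage filter applies to both query and subject — the stricter,
standard BBH reading of a coverage criterion stated over "the proteins";
a `coverage_mode: query` switch restores a query-only filter. Best hits
rank by higher bitscore, then lower e-value, then higher identity, then
lexicographically smaller subject id (a deterministic total order). When
the two directional hits of a BBH differ in identity, the pair identity is
their arithmetic mean — the only symmetric choice. The diagonal of the
wGRR matrix is defined as 1.0 by convention; a prophage is never compared
with itself in the analyses. The similarity network connects pairs whose
wGRR *strictly* exceeds the threshold (default 0.5, "higher than 50 %").

## Superinfection immunity proxies

Repressor similarity between two candidate repressor proteins is the
number of matched positions of a global alignment with zero mismatch and
gap costs — which is exactly the longest-common-subsequence length —
divided by the length of the smaller sequence. The same statistic is used
wherever repressor "sequence identity" thresholds (e.g. > 80 %) appear.
Candidate repressors come from profile searches filtered at viral
quotient > 0.8, best-domain e-value ≤ 10⁻⁴, profile coverage ≥ 60 %, and a
description containing one of *immunity*, *superinfection*, *repressor*,
*exclusion* (case-insensitive).

## CRISPR targeting

Arrays with fewer than three spacers are discarded as annotation noise.
Spacer–protospacer matching is an ungapped scan of both strands over
window lengths from ⌈0.9·L⌉ to L (contiguous truncation of the spacer from
either end), reporting windows with identity ≥ 90 %; overlapping reports
on one strand collapse to the best (fewest mismatches, then longest, then
leftmost). Gapped matching is deliberately out of scope: 25–40-nt spacers
essentially never align with gaps under blastn-short settings. A
database-size-dependent e-value cutoff is replaced by the identity +
coverage thresholds, which dominate at panel scale. Note one consequence
of allowing truncations: a mismatch in the outer 10 % of a spacer can be
legitimately shed by a shorter window, so "k mismatches" rejects a planted
protospacer only when the mismatches are interior.

A strain pair (producer A, target B) is CRISPR-targeted when any spacer of
B matches any (intact) prophage of A.

## R-M targeting

Two R-M proteins of the same type and role are considered able to target
similar recognition sites when their global-alignment identity (identical
columns over aligned columns, terminal gaps excluded; BLOSUM62, gap open
−11 / extend −1) reaches the per-type threshold: 50 % for Type II and IV
REases, 55 % for Type IIG, 60 % for Type II MTases, 80 % for Type I and
III MTases and REases. Combinations without a published threshold
(Type IV MTases, auxiliary components) raise an error rather than guess.
The comparison is role- and type-restricted — the most conservative
reading of the threshold list.

Recognition motifs are degenerate IUPAC strings supplied as annotation
(motif inference from REBASE is out of scope; systems lacking motifs are
skipped with a logged warning). Motif scanning matches every
IUPAC-compatible window on the forward strand and, only when the motif is
not its own reverse complement, also the complementary strand — palindromic
sites occur identically on both strands and would otherwise double-count.

A prophage of producer A is putatively targeted by target B when B has a
motif-bearing system with no equivalent same-type/same-role counterpart in
A and the motif occurs at least once in the prophage. Because some systems
need two recognition sites to cleave, a two-site mode requires each motif
twice per prophage; its positive calls are a subset of the one-site calls.

## Infection-matrix statistics

The infection experiment is producer × target × replicate (default 3). A
pair is *infected* when at least one replicate cleared (configurable to
all replicates); the per-strain infection score is the mean clearing
frequency over all targets (self included), pooling replicates.
Reproducibility is the fraction of infected pairs positive in every
replicate, optionally stratified into same-CLT vs cross-CLT pairs.

Capsule-serotype modularity is a 2×2 contingency of ordered pairs —
same-CLT vs cross-CLT against infected vs not. Self-pairs are included by
default: on a 35-strain panel this yields 105 same-CLT plus 1120 cross-CLT
= 1225 = 35² combinations, the arithmetic of the study design; a flag
excludes them. Caveat: with self-pairs included, *any* label shared by a
strain with itself (e.g. LPS) inherits the self-infection signal, so null
analyses of alternative serotypes are cleaner with `include_self: false`.

The exact test is hand-authored: the two-sided p-value sums the
hypergeometric probabilities of all tables with the observed margins whose
point probability is at most that of the observed table. The enumeration
uses exact big-integer binomials; a 1 × 10⁻⁷ relative tolerance guards
floating ties when comparing probabilities (with integer arithmetic, exact
ties are already exact). The odds ratio is (a·d)/(b·c), reported as +inf
when b·c = 0 with a·d > 0 and as NaN (undefined) when both products are
zero; no Haldane-type correction is applied. The implementation agrees
with full rational enumeration on every 2×2 table with N ≤ 30 and with
`scipy.stats.fisher_exact` on random tables (both checked in the suite).

Spearman's rho is the Pearson correlation of mid-ranks; its p-value comes
from a seeded two-sided permutation test (9999 permutations by default)
rather than the t-approximation, which is the safer choice at n ≈ 35.
Constant input yields a flagged null, not a number. The prophage-vs-host
GC comparison uses paired differences in percentage points and the
two-sided Wilcoxon signed-rank test (exact null for n ≤ 25 without zero
differences, normal approximation with continuity correction otherwise);
ambiguous bases (N) are excluded from both numerator and denominator of
GC content, which avoids biasing GC downward.

## Capsule-loss trajectories

Populations are summarized by the trapezoidal area under the
capsulated-fraction curve over days 0–5 (the window is configurable; most
capsule loss happens early). A missing day 0 defaults to fully capsulated
founders (fraction 1.0); missing interior days are linearly interpolated
with a logged warning; a trajectory ending before the window end is an
error rather than a silent extrapolation. Treatments are compared per
strain with the two-sided Mann–Whitney U test, exact for combined n ≤ 20
and normal-approximated with tie correction otherwise.

## Synthetic-data generators

All generators draw from independent, named substreams of a single root
seed, so outputs are bit-reproducible and adding a generator never
perturbs another's stream.

* **Proteome pairs** — background proteins i.i.d. uniform over the 20
  residues; each planted homolog substitutes exactly round((1−q)·L)
  positions to a different residue, so the realized identity is (L−k)/L
  (exactly q when q·L is integral, e.g. L = 100). The companion hit table
  is lossless: one hit per planted pair per direction, full coverage,
  e-value 10⁻⁵⁰, bitscore ∝ identity × length, no background hits — the
  BBH stage therefore recovers exactly the planted pairs.
* **Infection panels** — default 35 strains with CLT group sizes
  (7, 5, 3, 2, 1×18), chosen because Σnᵢ = 35 and Σnᵢ² = 105 reproduce
  the 105 same-CLT / 1120 cross-CLT ordered-pair arithmetic of the study
  panel. Each producer × target × replicate clearing is an independent
  Bernoulli draw with probability 0.33 for same-CLT pairs and 0.036 for
  cross-CLT pairs (the study's observed same- and cross-serotype infection
  frequencies). LPS labels are assigned independently of CLT. Because
  replicates are independent, the replicate-level positive frequency
  concentrates at p_same/p_diff, while the pair-level (≥ 1 of 3) frequency
  is 1−(1−p)³; the generator does **not** model the between-replicate
  correlation of real lysate production, so observed reproducibility is
  lower than in real data and the pair-level infected fraction is higher.
* **Defense scenarios** — random background genomes (configurable GC) with
  recognition motifs planted on random strands and protospacers copied
  with a requested number of substitutions; a truth JSON records every
  planted feature plus, for motifs, all occurrences actually present after
  planting (chance background hits included, found by re-scanning).
* **Trajectories** — per generation the capsulated frequency follows the
  deterministic selection–mutation recursion
  f′ = f(1−μ) / (f(1−μ) + (1−f(1−μ))(1+s)); daily observations are
  binomial samples of `sampling_n` clones (default 100). Defaults: 10
  days at 7 generations/day (≈ 70 generations), 6 populations per strain ×
  environment, μ = 10⁻³ per generation, and selection coefficients
  s = 0.30 (MMC), 0.10 (LB), 0.05 (MMC + citrate), 0.02 (LB + citrate) —
  a regime in which induced predation (MMC) accelerates capsule loss,
  citrate suppresses it, and spontaneous induction in LB sits in between,
  matching the qualitative ordering the analysis is meant to detect. This
  is a fixture for the analysis code, not a mechanistic claim: it omits
  demography, clonal interference, capsule reacquisition, and
  phage-density feedback.

Passing tests on these generators therefore demonstrate correctness of
the *procedures* (filters, BBH, exact tests, scans, AUC) under the study's
statistical regime — not that real genomes or lysates behave like the
generators.

## Problem sizes and numerics

The test suite and acceptance checks run at desk scale: exact-test oracle
equivalence on all 2×2 tables with N ≤ 30; 200 study-regime panels and
1000 null panels for power and type-I checks; 200 random planted cases for
the scan oracles; proteome pairs up to a few hundred proteins. Exact
big-integer arithmetic makes the Fisher p-values scale-independent; all
stochastic checks use fixed seeds. Identity comparisons at thresholds use
a 10⁻⁹ slack so that e.g. 27/30 = 0.9 passes a ≥ 0.9 filter regardless of
binary rounding.

## Known limitations

* Prophage detection, serotyping, CRISPR/R-M annotation and motif
  inference are upstream tools; their outputs are inputs here.
* Spacer matching is ungapped; R-M equivalence uses one substitution
  matrix/gap setting rather than the original search stack, so identities
  near a threshold can differ from other aligners.
* The infection generator's independent replicates understate real
  reproducibility (see above).
* The repressor statistic (LCS / min length) is one of several reasonable
  readings of "sequence identity" for repressor pairs; it is used
  consistently throughout.
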