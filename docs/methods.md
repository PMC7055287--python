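# Methods

This note records the models, parameter choices and numerical decisions
behind `ankfam`, and what its simulators do and do not emulate.

## Repeat identification

A family member is recognized by tandem copies of a ~33-residue repeat.
The scanner is a position-specific scoring matrix (PSSM) built from a seed
alignment of repeat instances:

    log_odds[i][a] = log2( (count[i][a] + pc * bg[a]) / (rows + pc) / bg[a] )

with pseudocount `pc = 1` and a uniform background by default. The packaged
seed alignment is synthetic (eight width-33 rows around a canonical
helix-turn-helix consensus); any seed alignment of equal-width rows can be
supplied instead. A protein is scanned at every window; windows scoring
above `SCAN_SCORE_THRESHOLD = 10` bits are selected greedily in descending
score order (ties to the smaller start) subject to non-overlap. Greedy
selection is not guaranteed to maximize total score in adversarial cases,
but it equals the dynamic-programming optimum on every instance produced
by the family simulator, and it mirrors the common practice of reporting
best non-overlapping hits.

Hit significance is the empirical exceedance fraction of the hit score over
≥ 1000 window scores from shuffled copies of the same sequence (composition
preserved). A hit that outscores every null window receives significance
exactly 0; the resolution floor is therefore 1/n_null, and the acceptance
cutoff of 1e-5 is met by any hit above all nulls. Candidates whose best hit
misses the cutoff are dropped, as are sequence-identical duplicates (the
lexicographically smallest identifier is kept).

Physicochemical properties use ExPASy average residue masses plus one
water, and the isoelectric point is found by bisection of the
Henderson–Hasselbalch net-charge function to within 0.005 pH units
(termini included), reported to two decimals.

## Subfamily classification and census

A member's subfamily is named after its non-ANK domains: none → ANK-U;
otherwise the highest-priority recognized domain in the fixed order
TM > PK > ZnF > BTB > ACBP > GPCR > BPA > IQ > RF > TPR; anything
unrecognized → ANK-O. Percent-of-proteome is computed in exact rational
arithmetic and rounded half-away-from-zero to two decimals, which
reproduces the packaged published census rows (one published row is off by
one unit in its last digit; the test suite allows exactly one ulp there
and nowhere else).

## Genome structure

Gene models come from GFF3 via `gffutils` (exon children, falling back to
the gene span; CDS start is strand-aware). Density clusters are maximal
merges of sliding windows (2 Mb window, 100 kb step by default) containing
at least 3 gene midpoints. Exon and intron lengths are reported in
transcription order (reversed on the minus strand) and satisfy
`sum(exons) + sum(introns) = span` by construction.

## Ka/Ks (NG86)

Site counting is fractional per codon: each position contributes the
fraction of its three possible changes that are synonymous (changes
creating stop codons count as non-synonymous). Computation uses exact
`Fraction` arithmetic, so S + N = 3L holds as an identity, not to
tolerance. Differences between two codons are averaged over all orderings
of the differing positions with equal weight; orderings that pass through
a stop codon are excluded (if all are blocked, all are used, counting the
blocked step as non-synonymous). Proportions are corrected for multiple
hits with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 saturates the
correction and raises an error rather than returning a fabricated value.
Gapped and ambiguous codons are dropped pairwise; ω is left undefined when
Ks is zero or undefined. The model deliberately omits transition/
transversion and codon-usage bias — that is the classical NG86 trade-off.

Selection calls follow standard usage: ω < 1 purifying, ω > 1 positive,
ω = 1 neutral, with an optional symmetric neutral band. Some published
summaries describe near-zero ω as "neutral"; that conflicts with standard
usage and is not followed here.

## Paralogs, duplication classes and dating

Candidate pairs are scored by global protein alignment (BLOSUM62, gap open
−10, extend −0.5); both alignment coverage and identity must exceed 70%.
Qualifying pairs form a graph and only connected components with at least
2 edges are kept (a minimum-duplication-events rule). A pair is tandem
when both genes share a sequence and at most 5 family members lie between
their midpoints; otherwise segmental.

Duplication age is T = Ks/(2λ) with λ = 6.96 × 10⁻⁹ substitutions per
site per year by default. Note a genuine inconsistency in the published
reference values packaged with this library: their printed times (mean
≈ 1.1 MYA) are far smaller than T = Ks/2λ yields at that λ (Ks = 0.33
gives 23.7 MYA). The packaged table stores the printed times verbatim;
`kaks_ng86` computes times from the formula with the configured λ and
reports λ alongside the result so the assumption is always explicit.

## Promoters

The promoter window is the 1500 bp immediately upstream of the translation
start (reverse-complemented on the minus strand), flagged when truncated by
a contig edge. Elements are IUPAC degenerate patterns scanned on both
strands with all overlapping occurrences reported; a minus-strand hit at
position p means the element reads 5'→3' on the opposite strand with its
leftmost base at p. A sequence `N` matches only a pattern `N` (an
ambiguous base is never claimed as a concrete match). A palindromic
pattern can optionally be reported once per site. The packaged element
catalog contains 30 PLACE-style entries.

## Expression

RPKM = 10⁹ · count / (library size · gene length in bp); log matrices are
log2(RPKM + 1). Tissue specificity is the full membership partition (Venn
cells) of the per-sample expressed sets, with "expressed" meaning strictly
above threshold (0 by default). Heatmap orderings use average-linkage
hierarchical clustering on Euclidean distance. qPCR fold change is
2^−ΔΔCt with arithmetic-mean Ct over replicates.

## Simulators

Every generator is a pure function of its spec (seed included) and emits a
truth table.

- **Family proteome**: members are noisy (10% per-position substitution)
  tandem copies of the profile consensus between random flanks, with a
  repeat-count distribution concentrated on 2–5 copies; decoys are
  shuffled member sequences — identical composition, no tandem structure.
  Not emulated: repeat degeneration gradients, insertions/deletions inside
  repeats, homology between distinct members.
- **Codon pairs**: proposal/acceptance divergence from a random sense-codon
  ancestor. Proposals arrive at intensity `true_ks` per site; synonymous
  proposals are always accepted, non-synonymous ones with probability ω,
  stop-creating ones are discarded. This makes the expected synonymous
  divergence per synonymous site equal `true_ks` and the realized
  Ka/Ks ratio ω in expectation. Not emulated: rate heterogeneity among
  sites, transition/transversion bias, indels.
- **Counts**: gamma-Poisson (negative-binomial-type) draws whose mean is
  `truth_rpkm · length · library_size / 10⁹`.
- **Promoters**: i.i.d. background at a chosen GC content with concrete
  instantiations of degenerate elements spliced at fixed positions.
- **Gene models**: random exon chains on chromosomes and scaffolds,
  guaranteed internally consistent.

## Problem sizes and runtimes

The acceptance suite uses 61×61 exhaustive single-codon alignments plus
sampled multi-codon ones (NG86 is additive over codons, so single-codon
exhaustiveness plus additivity covers longer alignments), 10 000 random
sequences for the site identity, 200 simulated pairs per ω regime
(0.2/0.5/1.0 at Ks = 0.3, 300 codons), 100 proteins for brute-force scan
agreement, 1000 (sequence, pattern) pairs against a regex oracle, the
default 100-member/100-decoy family simulation for recall/precision, and
500 random gene models for the length identity. The full test suite runs
in ~12 s and `scripts/acceptance.py` in ~10 s on one CPU.

## Limitations

- The repeat profile is a PSSM, not a profile HMM: no position-specific
  indel states, so repeats with insertions score poorly.
- Empirical significance cannot resolve below 1/n_null; strong hits are
  reported as 0 rather than a positive lower bound.
- NG86 underestimates divergence when substitution biases are strong;
  saturated alignments are rejected, not extrapolated.
- Duplication dating is linear in the assumed clock rate; absolute times
  should be read as rate-conditional.
- The packaged seed alignment is synthetic; for production use supply a
  curated alignment of real repeat instances.
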