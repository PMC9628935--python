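# Methods

## Scope and data model

`markerscan` operates on a *strain panel*: a set of strains with species
labels and one DNA sequence per (strain, locus) cell. Panels are read from
per-locus FASTA files plus a five-column metadata TSV (`strain_id`,
`species`, `locus`, `fasta_path`, `seq_id`), or produced by the bundled
simulator. Sequences are normalized to uppercase over `{A,C,G,T,N,-}`
with U mapped to T. Missing cells are allowed; each statistic simply
skips the strain at that locus rather than dropping it panel-wide, since
real panels often include type strains with sequence for only a few loci.
Strain and locus order is first appearance in the metadata, and all
outputs follow that order, so shuffling input rows permutes labels but
never changes a statistic.

## Typing statistics

**Alleles.** Two strains share an allele at a locus iff their sequences
are exactly identical after uppercasing. Allele ids are assigned in
first-occurrence order, giving contiguous ids 1..k. This requires the
per-locus sets to be equal-length and gap-free (true for simulated data;
user data must be pre-aligned), and it is what makes allele counts
reproducible across runs.

**Polymorphic sites.** A column counts as polymorphic when at least two
distinct bases from `{A,C,G,T}` occur in it. Columns containing `N` or
`-` in *any* sequence are excluded entirely — the conservative
SNP-calling convention, chosen so that a single ambiguous strain cannot
inflate a locus's polymorphism.

**Typing efficiency.** TE = k / s, alleles per polymorphic site. A low
TE means many sites contribute to few genotypes (redundant signal); a
high TE means nearly every variable site creates a new genotype. TE is
*undefined* for a monomorphic locus (s = 0) and is reported as NA rather
than 0 — a deliberate refusal to hide a division by zero.

**Discriminatory power.** The Hunter–Gaston form
DP = 1 − Σ n_j(n_j−1) / (N(N−1)): the probability that two strains drawn
without replacement carry different alleles. The implementation is
checked exactly against a brute-force enumeration of all unordered strain
pairs (property-based up to N = 30).

**dN/dS.** Nei–Gojobori (1986) counting with equal pathway weighting and
Jukes–Cantor correction:

* per-codon site counts: each position contributes the fraction of its
  three single-base alternatives that are synonymous; changes into stop
  codons count as nonsynonymous; s + n = 3 for every sense codon;
* differences between codon pairs: all orderings of the differing
  positions (1, 2 or 6 pathways) weighted equally; a step is synonymous
  iff both codons are sense codons with the same amino acid. Pathways
  through stop codons are *not* excluded — their steps simply count as
  nonsynonymous. This keeps the pathway average a total function of the
  codon pair;
* codons containing `N`/`-` in either sequence, and stop codons, are
  skipped pairwise; trailing bases beyond the last full codon are
  ignored;
* p-distances pS = Sd/S and pN = Nd/N are corrected with
  d = −(3/4)·ln(1 − 4p/3). A proportion ≥ 3/4 leaves the rate undefined
  (NaN, "saturated"); saturated pairs are excluded from locus summaries
  with a logged warning. Note that at toy scale this bites early: a
  single synonymous difference within one codon already saturates pS.

The locus-wide ratio is (mean dN over all unordered strain pairs) /
(mean dS over the same pairs); a zero mean dS gives NA. All 64×64 codon
bookkeeping is precomputed once, so pairwise comparisons reduce to two
vectorized table lookups; the tables are verified in the test suite
against an independent enumerator over every sense-codon pair.

**Marker ranking.** Two rankings are reported: (a) descending
polymorphic-site count (ties: descending allele count, then name) and
(b) ascending minimum between-species identity. The top of each ranking
is flagged as a candidate marker — the two views that, on the published
panel, select *pycA* (most polymorphic) and *aroE* (lowest homology).

## Identity and trees

Pairwise identity derives from a Needleman–Wunsch global alignment with
match +1, mismatch −1, linear gap −2 (Biopython's C aligner; the first
reported optimal traceback, which is deterministic). Identity counts
matched columns over all alignment columns except doubly-gapped ones;
singly-gapped columns are mismatches (the BLAST-style "alignment length"
convention). Polymorphic sites against a reference count aligned columns
where both characters are unambiguous bases and differ.

MLST concatenation joins each strain's locus sequences in the exact gene
order of the scheme; the five published *Bacillus* schemes are bundled.
Two of the published scheme listings abbreviate locus names (`ptA`,
`pur`, `tpi`); the bundled versions normalize these to the canonical
`pta`, `purH`, `tpiA` so the schemes resolve against any panel that uses
the standard gene names.

Trees are neighbor joining (Saitou–Nei Q-criterion) on raw p-distance
(differing sites over sites where both sequences have unambiguous bases).
NJ ties are broken by the smallest pair in current node order; negative
branch lengths are clamped to zero with the deficit moved to the sister
branch, preserving the joined pair's path length. On additive matrices
NJ provably recovers the generating tree, which the suite verifies over
random 5–8 leaf trees, and the implementation is cross-checked against
scikit-bio's independent NJ on generic matrices. Maximum-likelihood
inference and bootstrap support are deliberately out of scope: the
quantity of interest here is species monophyly, which is robust to the
tree method.

## Primer model

Annealing is ungapped Hamming matching: a primer binds wherever it has at
most `max_mismatches_per_primer` mismatches (default 2) and zero
mismatches in its 3'-terminal `three_prime_anchor_len` bases (default 3).
This replaces thermodynamic duplex models with a deterministic, testable
contract; the defaults encode the usual rule of thumb that 3'-end
mismatches abolish extension and ≥3 total mismatches prevent annealing at
stringent temperatures. Melting temperature is the Wallace rule
2·(A+T) + 4·(G+C) — composition-only, hence identical for a primer and
its reverse complement. Products span the 5' end of the forward
footprint through the 5' end of the reverse footprint (both footprints
included), the convention under which the published assay sizes (233 bp,
278 bp) are exact. Both template orientations are searched by default,
and product lengths are invariant under reverse-complementing the
template. Degenerate bases in primers are rejected.

A *species-specific window* is a stretch invariant across every
target-species strain with ≥ `min_mismatches` differences against the
corresponding stretch of every non-target strain, at least one of them in
the window's 3'-terminal three positions. Candidates are scored by their
minimum mismatch count against any non-target strain. Pair design takes
an upstream window as forward primer and the reverse complement of a
downstream window as reverse primer, filters on product length and Tm,
and ranks by combined specificity score (output truncated to
`max_pairs`, default 50). Coordinates in all reports are 1-based
inclusive; internally everything is 0-based half-open.

## Synthetic panels

The simulator emulates the comparative-genomics panel the analysis is
built for: 5 species with 6/3/5/4/3 strains (21 total), the 17
housekeeping loci at their published lengths, and one slow 16S-like locus
(1550 bp). The phylogeny is a star: per locus, one random root sequence
(uniform sense codons for coding loci), one ancestor per species, and
each strain derived from its species ancestor. This is deliberately
simpler than a realistic species tree — it is sufficient to reproduce
the identity bands and the monophyly signal, and it makes ground truth
trivial to record.

Divergence is parameterized by target *pairwise* proportions:
`p_inter = 0.25` between species for protein loci (0.008 for the
16S-like locus) and `p_intra = 0.005` within species (0.001 for 16S),
values that place between-species identity at ~74–78%, within-species
identity at ~99.5%, and 16S cross-species identity at ~99.2% — the bands
reported for real panels of these species. Substitution *counts* per
branch are deterministic while positions are random, keeping the bands
tight; each branch receives
n = −(3/4)·L·ln(1 − 4r/3) with r = (3/4)(1 − √(1 − 4p/3)),
the inversion of the expected multiple-hit shrinkage, so the realized
pairwise Hamming divergence centers on p rather than undershooting it.

Coding loci evolve codon-aware: a proposal (uniform site, uniform
alternative base) is rejected outright if it creates a stop codon,
accepted with probability `omega_target` (default 0.4) if nonsynonymous,
and always if synonymous; rejected proposals are redrawn until exactly
n substitutions are accepted. The realized Nei–Gojobori dN/dS then lands
near `omega_target` (slightly below, since stop-bound mutations that the
site counts treat as nonsynonymous opportunity are never realized). One
locus length (1892 bp) is not a codon multiple; such loci evolve
codon-aware over the largest codon-multiple prefix with the trailing
bases neutral, and dN/dS drops the partial codon.

Primer windows are *planted*: window regions are frozen against random
mutation in every lineage, target-species strains carry the root window
verbatim, and each non-target species ancestor receives forced window
mismatches — at least one in the 3'-terminal three positions and well
above the ≥3 contract (60% of the window length), so planted windows
outscore naturally divergent windows and top the candidate ranking. The
default design plants two windows on *pycA* (20 and 22 nt, 191 bp apart)
and two on *aroE* (20 and 21 nt, 237 bp apart), so primers lifted
verbatim from them produce 233 bp and 278 bp products, matching the
published assay geometry.

Randomness comes from independent streams keyed by
(seed, locus, species, strain), so adding a strain or locus never
perturbs other sequences, and emitted datasets are byte-identical across
runs for a fixed seed.

What the simulator does *not* model: realistic species-tree shape,
coalescent variation, recombination, indels, and codon-usage bias.
Passing tests therefore demonstrate that the statistics, trees and primer
logic behave correctly under the intended divergence structure — not that
the pipeline is robust to alignment error or rearrangement in real
genomes, where an upstream alignment step is the user's responsibility.

## Problem sizes and numerical choices

* Pairwise-identity checks run at the published locus lengths over all
  strain pairs for two simulation seeds, and over ten seeds with two
  strains per species (within-species strains differ by well under a
  percent, so the sampled extremes stand for the panel). Full-length
  alignment of a 3450 bp pair costs tens of milliseconds; these sizes
  keep the default test run in minutes without changing any conclusion.
* dN/dS recovery uses 20 seeds, both for a single 9999-codon sequence
  with 600 substitutions and for the full 21-strain panel averaged over
  the 17 coding loci.
* Species-monophyly checks cover all five schemes and all 17 coding loci
  on 10 seeds.
* Display rounding (TE to 3 decimals, dN/dS to 4, identities to 1) is
  applied only in formatted tables; all internal math is double
  precision. NA is the literal string `NA` in TSV output.
* Degenerate inputs fail loudly: empty loci, unequal lengths, monomorphic
  TE, single-strain DP, saturated corrections, and windows colliding in a
  simulation config all raise typed exceptions (mapped to exit code 2 in
  the CLI; internal errors exit 1; empty biological results exit 0).
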