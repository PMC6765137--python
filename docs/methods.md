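# Methods

## The inference problem

Amplicon sequencing of the full-length 16S rRNA gene with circular-
consensus (CCS) long reads produces libraries in which roughly half of
all ~1.5 kb reads are entirely error-free and the rest carry a handful
of substitutions and indels. The goal is to recover the exact true
sequences (amplicon sequence variants, ASVs) and their abundances —
including distinct alleles of the multi-copy 16S gene within a single
genome, which may differ by only one nucleotide — while emitting no
spurious variants.

## Error model

The model is a transition-rate matrix `p(observed nt | true nt, q)` over
the four nucleotides and quality scores q ∈ 0..93. Its central
assumption is that the quality/error relationship is identical at every
base position of a read; position enters nowhere in the model (verified
by a permutation test in the suite).

Estimation, given reads aligned to their assigned true sequences:

* Aligned columns are tallied by (true base, read base, q); indel
  columns are tallied separately and excluded from the matrix.
* For q ≤ 92, each of the 12 error transitions is fit by a
  tricube-weighted local linear regression of log10(rate) on q, with a
  pseudocount of 1 added to the error count of each (transition, q) cell
  before the log (avoids log 0), weights proportional to the number of
  observations, and a span of half the observed quality range (minimum
  2). The smoothed curve is then made non-increasing in q by a weighted
  pool-adjacent-violators pass — a higher reported quality must never
  imply a higher modeled error rate, which the denoiser's discounting
  logic relies on — and clamped to [10⁻⁷, 0.25]. The floor keeps
  likelihoods finite over long error-free reads; the ceiling guarantees
  a positive self-transition remainder, so each (true nt, q) row sums to
  exactly 1 with no renormalization step that could disturb
  monotonicity.
* q = 93 is special-cased: CCS pins most bases at the maximum score, and
  a smooth extrapolation from 0..92 would badly misestimate the rate
  where most of the likelihood mass lives. The q = 93 rate is
  (errors + 1)/(total + 2) computed only from q = 93 observations.
* The indel rate used in read likelihoods is quality-independent:
  (total indel columns + 1)/(total aligned columns + 1). Deletions carry
  no quality score, so a quality-conditioned indel model has no
  covariate to condition on.

Learning alternates with denoising: starting from a deliberately
pessimistic quality-independent model (every wrong base at 0.01/3, so no
quality is trusted a priori), the reads are denoised, each read is
assigned the sequence of its partition center as truth, and the matrix
is re-estimated. The loop stops when the largest |Δ log10 rate| drops
below 0.05 or after 10 rounds; in practice it converges in 2–3 rounds.
By default learning uses the first 2000 reads (~3×10⁶ bases), which
bounds runtime while leaving rate estimates tight at the scales that
matter.

## Denoising

Reads are dereplicated into unique sequences (abundance plus a
position-wise mean quality profile; the rounded mean is used in
likelihoods, since dereplication collapses the per-read qualities).
Partitioning is greedy and divisive:

1. All uniques start in one partition centered on the most abundant
   unique (abundance ties break lexicographically).
2. For each non-center unique, λ = Π over alignment columns of
   rate(center base → member base, member q), with each indel column
   contributing the flat indel rate. λ is accumulated in log10; values
   like 10⁻⁵⁰⁰ arise routinely for cross-strain comparisons and must not
   underflow to zero.
3. The abundance p-value of a member seen a times in a partition of n
   reads is p_A = P(X ≥ a | X ≥ 1), X ~ Poisson(nλ), computed through
   the regularized incomplete gamma function, with a small-μ log-space
   branch (p ≈ μ^(a−1)/a!) below μ = 10⁻⁸. Singletons have p_A = 1 by
   construction and can never be promoted.
4. The globally most significant member is promoted to a new center if
   p_A · (number of uniques) < Ω_A (default 10⁻⁴⁰ — promotion is meant
   to be conservative; the Bonferroni factor accounts for scanning all
   uniques). After each promotion every unique is reassigned to the
   center with the largest λ; the loop ends when nothing is significant.

Pairwise comparisons are gated: if the kmer distance
1 − overlap/min(kmer count) (k = 8, multiset overlap) exceeds 0.42 the
pair is skipped (λ treated as 0); if the in-order kmer overlap equals
the multiset overlap and lengths match, the positional ungapped
alignment is provably optimal and the banded alignment is skipped.
Otherwise a banded Needleman–Wunsch global alignment is computed
(band 32, match +5, mismatch −4, gap −8, end gaps penalized, ties
preferring diagonal then up then left); pairs whose length difference
reaches the band are treated as unrelated. The aligner is checked
against an independent unbanded implementation in the suite. Inference
is deterministic: identical inputs give identical outputs.

ASVs are the partition centers (always verbatim observed sequences) with
partition read totals as abundances; per-sample results merge into a
samples × ASVs table ordered by total abundance.

## Chimera removal

A candidate ASV is a bimera if some ordered pair of same-sample ASVs
reconstructs it exactly as a one-crossover mosaic (left segment matching
one parent perfectly, remainder matching the other, under banded
alignment with shifts ≤ 16 columns) while neither parent alone matches
it. Only pool members at least `min_fold = 3.5` times more abundant than
the candidate qualify as parents: intragenomic alleles appear at small
integral abundance ratios (3:1 and below), so the fold requirement
prevents a genuine low-copy allele from being judged a chimera of its
higher-copy siblings. Across samples an ASV is removed when flagged in a
strict majority of the samples containing it. Only two-parent mosaics
are considered (multimeras are out of scope).

## Mock-community analytics

Genomic abundance of a strain = Σ(assigned ASV abundances)/(16S copy
number); dividing each ASV abundance by it gives copies per genome,
which for genuine alleles is an integer within ±0.2. An ASV is judged
accurate if it exactly matches a reference allele, or if its ratio
passes the integral check in a bin with ≥ 2 alleles; otherwise it is
unsupported. Raw-read error profiling aligns each read to its
best-scoring truth (kmer-nearest candidates first, ties to the earlier
truth) and tallies differences by type, 1-based read position and
quality; insertions take the inserted base's quality, deletions have
none. Rarefaction uses a multivariate hypergeometric draw (uniform
subsampling without replacement). Replicate concordance counts
(sample, ASV) observations shared and unique between two tables and the
Pearson correlation of abundances over their union, absences as zero.

## Strain binning and full-complement classification

Within a taxonomic group, candidate genome units g are every observed
abundance divided by 1..copy_number. A bin accepts ASVs whose
abundance/g rounds to an integer ≥ 1 within ±0.2, filled greedily in
descending abundance under the copy-number budget; the candidate with
the most members (then least total deviation) wins, bins grow from the
most abundant unassigned ASV, and well-separated abundance scales yield
separate bins. Classification tabulates accession occurrences across
per-ASV best-hit sets, keeps the accessions with the maximal count, and
reads a metadata field across them ignoring missing entries: unanimity
classifies, disagreement is ambiguous, all-missing is unclassified. Live
database searches are deliberately excluded — hit tables are ingested as
TSV so results are reproducible. V3V4/V4V5 sub-region extraction ships
the Illumina- and JGI-recommended primer pairs as defaults.

## Simulator

The generator emulates the measured CCS error structure: per-type rates
default to substitutions 1.1×10⁻⁴, insertions 2.2×10⁻⁴, deletions
1.0×10⁻⁴ per base. Qualities are 93 with probability 0.9 and uniform on
30–92 otherwise — an approximation to the real joint
quality/position distribution, of which only the broad shape
(predominantly maximum-quality bases, low-quality positions enriched for
errors) is characterized. Substitution probability per base is
c·10^(−q/20), with c calibrated against the quality distribution so the
marginal rate equals the configured rate (and the per-base probability
capped at 0.25); insertions and deletions are placed uniformly,
insertions inheriting a freshly drawn quality, deletions none. A
configurable fraction of reads (default 2%) are one-crossover mosaics of
two sampled templates with the crossover uniform over the middle half;
half of all reads are emitted reverse-complemented; degenerate primers
are realized per read and attached at both ends. Allele sampling weight
is genome proportion × copy number. Homopolymer-targeted error
enrichment is not modeled: the 16S gene is nearly devoid of long
homopolymers, which is also why indel rates this low are attainable at
all.

Synthetic references are random backbones: strains derive from a shared
ancestor with 5% of positions substituted per strain, and within-strain
alleles carry private substitutions (default divergence 4). This
reproduces the statistical structure the algorithms care about
(within-strain near-identity, cross-strain distance beyond the kmer
cutoff, integral copy ratios) but not real 16S biology — no conserved
regions, no shared variable-region motifs across strains, no
context-dependent error modes. Passing tests therefore demonstrate the
correctness of the inference machinery under the modeled error process,
not performance on real instrument data.

## Problem sizes and numerical choices

The benchmark runs use 10 000 reads for the equimolar 8-strain design
and 20 000 for the staggered 20-strain design — depths at which every
equimolar allele receives ~200 reads while the staggered design's
rarest strains receive a handful, exercising both the specificity and
the detection-limit behavior; the error-model recovery check uses
4 000 chimera-free reads (5.8×10⁶ bases). Alignment band 32 tolerates
the indel counts seen at CCS error rates; kdist 0.42 with k = 8 admits
within-species comparisons while skipping cross-genus ones. Ω_A = 10⁻⁴⁰
makes promotion extremely conservative; sensitivity is retained because
even a two-read variant four substitutions from its nearest center is
overwhelmingly significant under learned CCS rates. Degenerate inputs:
empty read sets raise; an ASV unreachable from every center (band
refused) stays with the first partition and is excluded from error
tallying; integral-ratio tolerance comparisons allow a 10⁻⁹ float
guard.

## Known limitations

* Chimeric reads assigned to partitions contaminate the learned q = 93
  substitution rates upward (conservative for specificity, slightly
  lowering sensitivity to ultra-rare alleles); learning does not
  pre-exclude chimeras.
* λ uses the unique's rounded mean quality profile, not per-read
  qualities.
* Binning is per-sample; cross-sample consistency of bins is not used.
* Reference-based chimera detection, paired-end merging, pooled/prior
  inference across samples, and taxonomy assignment are out of scope.
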