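# Methods

## The ANI statistic

`anikit` computes CDS-based average nucleotide identity. For an ordered
genome pair (Q, T), genes are predicted on Q only and aligned against the
raw nucleotide sequence of T; T's annotation is never used. A directed
comparison keeps, per CDS, the single local alignment with the most
identical sites among hits that have ≥ 60% overall identity and cover
strictly more than 70% of the CDS; the directed ANI is the unweighted
arithmetic mean of the kept best-hit identity percentages. The unweighted
mean treats each shared gene as one observation regardless of length,
following the original shared-gene formulation of ANI; a length-weighted
mean is available (`weighted=True` / `--weighted`) for users who prefer
per-base averaging — at the divergences where ANI is informative the two
differ by far less than the biological signal.

Boundary semantics are deliberate and locked in tests: identity exactly
60.0% passes (the rule is "at least"), CDS coverage of exactly 70% fails
(the rule is strict), and total genome coverage of exactly 50% passes
(only comparisons *below* half coverage are discarded). The 50% rule's
denominator is the full query genome length, not the summed CDS length;
gene-sparse genomes therefore fail it sooner. That is the intended,
conservative reading: a comparison where most of the query genome has no
kept homolog says little about relatedness either way.

Identity is computed over all alignment columns including gap columns
(the BLAST identity denominator), and a column involving N is never
identical. Undefined matrix entries (filtered in both directions) are
exported as `NA` and, for tree building, capped at distance 100 with a
logged warning.

## Gene prediction

Gene calling is a deterministic maximal-ORF scan, not a trained
gene-finder: both strands, all three frames, first in-frame start codon
(ATG/GTG/TTG) after the previous in-frame stop (contig edges count as
stop boundaries), through the next stop (TAA/TAG/TGA), stop included.
Defaults: minimum span 110 bp, maximum retained overlap 50 bp (the
familiar `-g110 -o50` settings of prokaryotic gene callers). Overlaps are
resolved greedily longest-first, with deterministic tie-breaks (smaller
start, then + strand). No coding-potential score is applied, so random
DNA yields spurious short ORFs. This is harmless by construction: a
spurious ORF either has a homolog in the target (it then contributes a
perfectly legitimate identity observation) or has none and is removed by
the identity/coverage filters. The first-start convention errs long,
which the >70%-coverage filter tolerates. Partial genes at contig edges
are not called (a frame with no stop yields nothing), and alternate
genetic codes are out of scope.

## Alignment

The heuristic mirrors the classic nucleotide-BLAST recipe. The target
genome is indexed by exact 11-mers (k-mers containing N excluded; contigs
concatenated with 100-N spacers wide enough that no extension bridges
them). Query CDSs are scanned in both orientations; seed matches are
clustered by diagonal (radius 20), each cluster is extended ungapped with
an X-drop of 20, then a banded affine-gap (Gotoh) local DP runs over a
target window sized to fit the whole CDS plus band slack. Scoring
defaults are the classic +2/−3 with gap cost 5 + 2·L — chosen to mirror
the tool this workflow historically wrapped; all values are
configurable. Hits are deduplicated so no two overlap on the query by
more than the word size, and sorted by descending score with fixed
tie-breaks. E-values are not computed: hit admission is raw score > 0
plus the downstream filters, which are identity- and coverage-based.

The exact Smith–Waterman oracle is the same Gotoh recurrence with an
unrestricted band, full-matrix traceback, and fixed tie-breaking (optimum
cell with smallest query-end then target-end; traceback prefers diagonal
over up over left). It is intended for sequences up to a few kb and
anchors the test suite: the heuristic's best hit must track it on
homologous pairs, and the oracle itself is checked against exhaustive
alignment-path enumeration on tiny pairs and an independent affine-gap
implementation on short random pairs. Both kernels are numba-compiled;
the first call in a fresh environment pays a few seconds of compilation.

Numerical/determinism notes: all coordinates are 0-based half-open
internally (1-based inclusive only in human-readable output); every
stage's output is a pure function of its inputs — there is no randomness
anywhere in the pipeline, and ties are always broken by fixed rules — so
reports are byte-identical across reruns.

## Tree building

Distance is 100 − symmetrized ANI: the simplest strictly decreasing map,
which preserves neighbor-joining topology whenever taxa are well
separated. Symmetrization averages the two directed values (uses the
single valid one if the other direction was filtered). Neighbor joining
is standard Saitou–Nei with deterministic tie-breaking (smallest index
pair), negative branch lengths clamped to zero with the deficit moved to
the sibling so leaf-path distances are preserved, and an unrooted
trifurcating Newick serialization with 6-decimal branch lengths (path
distances recovered from the serialized tree are therefore exact only to
about 1e-6). On additive matrices NJ provably recovers the generating
tree, which the tests exploit. Trees need ≥ 3 genomes; with 2 the
pairwise report stands alone.

## The synthetic genome generator

`random_genome` emulates what the pipeline needs from a bacterial genome
— length, plantable protein-coding ORFs, neutral background — and nothing
more. Background is uniform-random ACGT; genes (lengths a multiple of 3,
drawn uniformly from the requested range, random strand) are placed
without overlap, each as a cassette carrying an in-frame stop codon
immediately upstream of its start codon. That upstream stop is a
deliberate design choice: under the first-start-after-stop convention it
makes the planted coordinates the unique ground truth, so "recovered
exactly" is well defined. Without it, uniform background would place an
earlier in-frame start upstream of most planted genes and exact recovery
would be impossible for reasons that have nothing to do with the scanner.

`evolve` applies whole-gene loss, then short indels, then point
substitutions, in that fixed order, all driven by one seed; it returns
the realized event counts alongside the evolved genome. Substitutions
are uniform over the three alternative bases — no transition bias, no
rate heterogeneity — so the expected identity of homologous sequence at
rate d is exactly 1 − d, which is what makes the parameter-recovery tests
sharp. What the generator does *not* emulate: codon usage, GC skew,
rearrangements, repeats, horizontal transfer, sequencing error. Passing
tests on these fixtures therefore demonstrate the correctness of the
machinery (filters, alignment, averaging, trees) under clean homology,
not robustness to repeat-rich or rearranged real genomes — on real data
the alignment step, like any local aligner, can be confounded by
paralogy and repeats.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run at desk scale, chosen so a
full check completes in about a minute on one core: genomes of 15–200 kb
with 6–120 planted genes, 200–500 aligner pairs of 0.3–1.5 kb, trees of
4–12 taxa. Divergence recovery is asserted to ±0.7 percentage points of
100·(1 − d) for d ∈ {0.01, 0.05, 0.10}; the tolerance covers per-CDS
binomial sampling noise and a small upward bias (~0.1–0.35 points,
growing with d) from local alignment trimming mismatch-rich CDS ends.
Planted-gene recovery is asserted at ≥ 95%: the rare misses are planted
genes overridden by a longer overlapping spurious ORF during greedy
overlap resolution, which is the intended behavior of the `-o50` rule,
not a scanning error.

## Known limitations

- Gene prediction has no coding-potential model, so CDS counts include
  spurious ORFs; counts are not comparable to a trained gene-finder's,
  even though the ANI value is insensitive to this.
- The aligner is not a BLAST reimplementation: no E-values, no
  low-complexity masking, no translated searches; band radius 20 can
  truncate alignments with very large indel offsets.
- The 50% coverage rule uses genome length as denominator (see above);
  plasmid-rich or gene-sparse queries fail it sooner than gene-dense ones.
- Neighbor joining is the only tree method, and undefined ANI pairs enter
  it at the capped distance, which compresses deep structure when many
  pairs are unalignable.
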