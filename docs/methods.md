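# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical conventions a maintainer would need before changing anything.

## TE model and simulator

A subfamily is represented by an LTR consensus and an internal-region
consensus (`TEModel`); the canonical full-length element (FLE) is
`LTR + internal + LTR`. Defaults (370-bp LTR, 5,160-bp internal; canonical
5,900 bp) match the size class of yeast Ty4. The terminal `TG…CA`
dinucleotides of every LTR are held invariant during simulated evolution:
they are required for integration in vivo and are the motif the structural
detector checks, so treating them as absolutely constrained is the
biologically sensible idealization.

Repertoires evolve along a rooted host tree (Yule topology, ultrametric,
rescaled to a stated root-to-tip height; 0.05 substitutions/site is the
within-species default). Per-branch Poisson events act on the element list:

* **transposition** — copy a random FLE (rate in events per unit branch
  length; 20–40 in the standard worlds, giving a handful of copies per
  strain);
* **solo-LTR formation** — a random FLE collapses to its 5′ LTR. Real
  LTR–LTR recombination yields a chimeric LTR; since both LTRs descend from
  the same founder the 5′ choice is an arbitrary, documented simplification;
* **truncation** — a random FLE is clipped to a sub-interval of its
  *internal* region (20–90 %, ≥150 bp). Restricting truncations to the
  internal region keeps every simulated architecture unambiguous: a
  fragment retaining one intact LTR would be indistinguishable from a solo
  LTR, and class labels would no longer be well-defined ground truth;
* **loss** — a random element is deleted.

Scheduled events plant known histories: **horizontal transfers** copy a
randomly chosen donor-branch FLE into a recipient branch at a stated branch
fraction (branches are addressed by their child node's label; donor
branches are always processed first, cycles are a config error);
**extinctions** purge a subfamily on a branch; **recombination** splices
internal-region segments of two co-resident subfamilies at stated
breakpoints, recording per-segment provenance. Sequence evolution is
Jukes–Cantor, substitutions only — homologous copies stay colinear, which
removes the external aligner from every downstream step. Estimation uses
K2P throughout; this mild model mismatch (JC generation, K2P correction) is
intentional and harmless because K2P subsumes JC.

In the two-species HTT world, TE sequences evolve at 0.3× the host branch
lengths (`te_substitution_scale`). Extant TE copies descend from recent
transposition bursts, so their divergence trails host divergence; this is
also precisely the regime in which HTT detection by sequence similarity is
meaningful. A realized world is rejected and redrawn (deterministically,
bounded attempts) if stochastic decay sterilizes a diagnostic lineage,
e.g. the donor species' last FLE turning solo before transposing.

Genomes plant each element into fresh random background with a 5-bp
target-site duplication (matching the detector's fixed `-mintsd 5 -maxtsd
5` bounds), random orientation, ≥1 kb spacing (so separate elements can
never be chained by annotation) and ≥500 bp contig margins. Reads are
uniform single-end draws (Poisson count = coverage·G/L, both strands,
per-base substitution errors at 1 % by default, constant Phred qualities
encoding that rate). The alignment emitter maps reads to the LTR/internal
queries *through their recorded provenance*: it is an idealized mapper with
perfect sensitivity for any read overlapping a planted element by ≥20 bp
(MAPQ 60; smaller overlaps are emitted at MAPQ 0), one record per
overlapped element part, soft-clipping the remainder. Real mappers add
mismapping and cross-family ambiguity that this emitter deliberately
excludes, so passing tests bound algorithmic error, not mapping error.

All internal random streams are seeded as `default_rng([purpose_key,
seed])`; distinct purpose keys make streams independent even when two
components receive the same integer seed (a plain `seed+k` convention once
caused a background genome to replicate the TE consensus draws verbatim).

## Copy number and presence

`cn = mean per-base depth over the query / single-copy genome depth`;
`breadth` = fraction of covered positions; the full query is profiled (no
edge trimming). The genome-depth normalizer is computed as total sequenced
bases / genome length, which for uniform simulated reads equals the median
background depth up to sampling noise (repeats are a small fraction of the
simulated genomes); callers may pass any externally computed depth.
Presence thresholds: LTR cn > 1, internal cn > 0.5 (strict inequalities).
Samples above 100× are thinned read-wise (Bernoulli, target/current) before
profiling; samples under 10× are flagged and excluded. Depth profiling
counts aligned match columns only (soft-clips and deletions contribute
nothing) with `min_mapq = 0` by default — the MAPQ 20 filter is a
consensus-stage rule, not a depth rule — exposed as a flag.

Expected values used in tests derive from planted architecture: a strain
with N FLEs and S solo LTRs has E[cn_internal] = N and E[cn_LTR] = 2N + S.

## Annotation

Homology search seeds exact 12-mers, clusters them by alignment diagonal
(valid because simulated homology is substitution-only; an indel-bearing
genome would need banded extension here), expands each cluster to the full
query span, and trims to the maximal-scoring ungapped segment with match
+1 / mismatch −(min_identity/(100−min_identity)) (−4 at the 80 % floor), so
a retained segment is exactly one with ≥80 % identity. Hits <50 bp are
discarded. Defragmentation chains same-subfamily, same-strand hits with
genomic gap ≤500 bp whose canonical-coordinate assignments advance
monotonically (LTR hits are ambiguous between 5′ and 3′ positions; the
chainer picks the smallest admissible assignment, reversed for − strands).
Classification: FLE = covers ≥0.9 of canonical length with both terminal
LTRs and internal hits (the 0.9 is exposed; "full length" is not defined
numerically in the literature this mirrors); solo LTR = LTR-only chain
covering ≥80 % of the LTR with no internal hit within 500 bp; else
truncated. Nested hits from another subfamily set a flag, they are not
resolved. With a library of sister subfamilies every copy is hit by all
queries above the 80 % floor, so overlapping calls are resolved to the
subfamily with the best length-weighted identity (`select_best_calls`);
a recombinant element is thereby assigned to the subfamily contributing
most of its sequence and still classified FLE.

FLE internal regions are extracted by projecting the longest internal hit
onto the full internal query, so every extracted sequence has exactly the
query's internal length; as subfamily queries are colinear, the extracted
set is a valid alignment without an external aligner, and − strand elements
are reverse-complemented to element orientation.

The structural detector seeds exact 20-mer pairs at a common separation
within the inter-LTR distance bounds [1500, 15000] (start-to-start),
chains same-separation seeds, extends un-gapped by x-drop (match +2,
mismatch −2, drop 5), and then requires: ≥100 identical bases in the
extended repeat pair (the `seed` parameter — enforced on the extended
alignment rather than on a single maximal exact repeat, because at ~10 %
inter-LTR divergence a 100-bp exact repeat almost never survives while the
anchored arm still contains hundreds of matches); TG starts and CA ends on
both arms (0 mismatches allowed); an identical flanking 5-bp TSD; arm
length in [100, 1000]; and ≥80 % inter-LTR identity. Boundary placement
searches the x-drop ends ±60 bp first and widens to any motif/TSD-consistent
placement containing the seed run within the length bounds. Overlapping
candidates keep the higher similarity. On 1 Mb of uniform random sequence
the expected number of seed chains reaching 100 identical anchored bases is
effectively zero, which is the false-positive control.

## Consensus

Pileups count aligned match/mismatch columns from reads with MAPQ ≥ 20 and
bases ≥ Q20; inserted and deleted columns are skipped. The consensus is
majority-rule per position (majority fraction > 0.5; exact ties → N, never
the reference, to limit reference bias), with reference fill only below
`min_depth` (default 1; reference-filled sites are counted and can never
exceed 1 − breadth). This replaces a call-variants-then-apply-consensus
route: for haploid strains with clear majorities the result is identical
and the contract is simpler; no variant-probability cutoff is applied.
Retention requires normalized depth ≥ 0.75 AND breadth ≥ 0.9 (inclusive).

## Divergence and breakpoints

K2P with explicit transition/transversion decomposition; pairwise deletion
of non-ACGT columns per comparison (a dialect choice — other gap rules
shift windowed d slightly in gapped regions); <10 comparable sites →
`undefined`; log argument ≤ 0 → `saturated`; both are markers, never
numbers, so plots and segment logic skip them. Windows: 50 bp, 10-bp step,
centers at start + 25; a window with >50 % non-ACGT in the query is
undefined. Breakpoints: s(w) = d(query, refA) − d(query, refB); exact zeros
continue the previous sign; a sign change flanked by ≥5 consistent windows
(min_run, i.e. 50 bp of sustained signal) places a breakpoint at the
midpoint of the bounding window centers; shorter excursions are jitter.
Adjacent same-label segments (possible after jitter suppression) are
merged. In the pipeline the parental references are chosen as the pure
elements *nearest* to the query on each side, which maximizes in-segment
contrast; the study this mirrors used outgroup representatives and read the
plots visually. Partitioning slices columns at floor(breakpoint);
concatenation reproduces the alignment exactly.

## Phylogenetics and HTT inference

Neighbor joining with deterministic tie-breaking (minimum Q, ties to the
lexicographically smallest representative-label pair; a cluster's
representative is its smallest leaf label). Negative branch lengths are
clamped to zero with the deficit moved to the sister branch (the joined
pair's distance is preserved); the final three-branch join clamps only. On
an exactly additive matrix NJ returns the generating tree with exact branch
lengths. NJ + nonparametric bootstrap (column resampling, default 100
replicates; supports = % of replicate trees containing each bipartition of
the point tree) and midpoint rooting stand in for maximum-likelihood
inference throughout: self-contained, desk-scale, and sufficient for clade
recovery at the divergences simulated; this substitution is recorded in
output manifests. Inside bootstrap replicates, saturated resampled pairs
take a fixed cap distance (5.0) instead of erroring; point estimates error
with the offending pair named. Midpoint rooting takes the longest
leaf-to-leaf path (ties toward the smallest label pair) and roots at its
middle; RF distance counts non-trivial bipartitions present in exactly one
tree; monophyly asks whether some edge isolates exactly the query taxa.

Dollo parsimony places the single gain at the MRCA of present leaves and
one loss on the stem of each maximal all-absent subtree below it; Fitch
gives the unrestricted minimum changes. Both are validated against
exhaustive enumeration over all internal-state assignments on all rooted
topologies with ≤6 leaves. The HTT ratio test computes, per species pair,
r = min inter-species TE distance / host distance and flags r < 0.5; under
vertical transmission r ≈ 1, after a recent transfer r → 0. The 0.5
threshold is deliberately permissive — at 2 kb+ alignments the sampling
noise of r is far smaller than the factor-2 margin — and exposed in config.

Tree-recovery benchmarks use random Yule topologies whose branch lengths
are redrawn uniformly from [0.005, 0.03] substitutions/site: an ultrametric
Yule tree contains arbitrarily short internal edges that no method can
resolve, which would measure the tree prior rather than the estimator;
bounding branch lengths (≥10 expected substitutions per edge at 2 kb) is
the standard benchmark design, keeping pairwise divergence ≤20 %.

## Problem sizes

Worlds used by the analyses, tests, and the acceptance script: 20 strains
(single species) for copy-number recovery at 50×/1 % error on 40-kb
backgrounds; 8 strains for annotation accuracy; 6 replicate multi-copy
strains at 30× for consensus; 100 synthetic recombinants (5-kb internal
regions, parents 5–15 % diverged) for breakpoint recovery; 100 8-taxon ×
2-kb replicates for tree recovery; 2 species × 12 strains for the
end-to-end HTT inference; parsimony oracle sweeps cover every rooted
topology with ≤6 leaves in the tests (≤5 in the acceptance script's
quicker sweep). These sizes are the package's chosen study conditions; all
are set in `retrotrace.scenarios`.

## Known limitations

No indels or structural variation (sequences stay colinear by design); no
nested insertions of one family into another (flagged only); no realistic
quality-score profiles or paired-end reads; haploid strains only; the
alignment emitter is an idealized, provenance-based mapper, so
coverage/consensus accuracies exclude real-world mapping error; solo-LTR
formation keeps the 5′ LTR rather than generating a chimeric LTR; the
structural detector's seed semantics are an interpretation (anchored
identical bases in the extended pair) of a tool parameter whose literal
semantics (single maximal exact repeat) would contradict the detector's
stated sensitivity goals at realistic LTR divergence.
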