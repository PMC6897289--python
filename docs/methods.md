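# Methods

`rnastructclust` clusters RNA sequences by joint sequence and secondary-
structure similarity in time linear in the number of inputs, optionally
guided by structure-probing reactivities. This note documents the model and
procedure, the parameters that matter, the synthetic data the test suite
runs on, and the numerical and design choices behind the implementation.

## The clustering procedure

The pipeline runs in five stages.

1. **Pre-processing.** Input sequences (DNA is converted to RNA on ingest)
   are optionally collapsed for redundancy and fragmented into sliding
   windows. Two presets mirror the two standard use cases: `global`
   (window 250 nt, shift 0.7) for whole-transcript ncRNA clustering and
   `local` (window 100 nt, shift 0.7) for motif discovery inside longer
   sequences. The final window is end-anchored at the 3' end so no position
   is dropped. Windows inherit per-nucleotide reactivity slices positionally,
   without renormalization.

2. **Folding.** Each window gets one nested (pseudoknot-free) structure from
   an O(n^3) weighted base-pair-maximization dynamic program (GC 3, AU 2,
   GU 1; minimum hairpin loop 3). The predictor is a deliberately simple,
   self-contained stand-in for a thermodynamic folding engine; externally
   computed dot-bracket structures can be supplied instead and bypass it.
   When a window carries probing reactivities, each position receives a
   pseudo-score `m·ln(1 + reactivity) + b` (defaults m = 1.8, b = −0.6,
   the scale commonly used in SHAPE-directed folding) and pairing position
   i and j costs an extra `λ·(score_i + score_j)` (λ = 1). High reactivity
   marks accessible, unpaired nucleotides, so the penalty steers the fold
   away from pairing them; reactivity 0 yields a negative score, i.e. a
   pairing bonus. Missing values contribute 0 (no bias). Profiles with fewer
   than 1% non-zero values — the signature of coverage-starved probing
   experiments — are ignored entirely.

3. **Graph encoding and kernel features.** A window becomes a labeled
   graph: one vertex per nucleotide (label A/C/G/U/N), backbone edges
   between neighbors, base-pair edges from the predicted structure (N never
   pairs). A disjoint "path graph" copy of the plain nucleotide string is
   appended by default so sequence-only features contribute independently
   of the predicted structure; it is worth disabling for paralog-heavy
   inputs where sequence similarity would dominate. The graph is embedded
   as a sparse feature vector by a decomposition kernel over pairs of
   radius-r neighborhood subgraphs at shortest-path distance d (r ≤ R = 3,
   d ≤ D = 3, base-pair edges count as ordinary adjacencies). Two details
   matter and were settled empirically during design:

   * Neighborhood canonical labels are computed by Weisfeiler–Lehman
     relabeling **confined to the induced ball subgraph**. Labeling with
     whole-graph WL iterations leaks information from outside the ball
     (effective radius 2r), which makes every feature so mutation-sensitive
     that homologs at 70% identity share almost nothing.
   * Counts are normalized in two levels: L2 within each (r, d) block, then
     L2 overall. Without the block step the handful of massively repeated
     radius-0 composition features dominate the norm and all similarities
     collapse toward a composition baseline (~0.88 for any two windows of
     like length).

   Features are hashed into 2^20 indices with a stable seeded 64-bit hash;
   hashing error against the exact count-based kernel is below 0.01 in
   similarity on the graph sizes used here.

4. **Fast clustering.** MinHash signatures (K = 512 permutation hashes) of
   the unweighted feature supports feed a single-slot inverse index; two
   windows sharing at least `min_collisions = 8` of their 512 slots (an
   estimated support Jaccard of ~0.016) become neighbor candidates. Buckets
   larger than `max_bucket = 200` are skipped, which bounds the per-window
   work and keeps the stage linear. We index single slots rather than
   multi-row bands because homologous families at ~70% identity reach
   support Jaccard of only ~0.1 under exact-label subgraph features — a
   regime where banded collision probabilities vanish but expected slot
   collisions (K·J ≈ 50) remain a strong signal. Each window's neighbors
   are then ranked by exact weighted similarity; a window whose top 3
   neighbors average at least `min_density = 0.4` seeds a candidate (up to
   `max_cluster_size = 25` members, members below a quarter of the density
   are dropped as chance collisions). Candidates are emitted densest-first,
   skipping any with more than 50% overlap with already-emitted ones.

5. **Refinement, extension, reporting.** Within each candidate, all member
   pairs are scored by a global sequence–structure alignment (match +2,
   mismatch −1, +1 when the aligned positions share pairing state, linear
   gap −2); scores map to distances `1 − s/max(self_a, self_b)`; a UPGMA
   tree is built (deterministic lexicographic tie-break) and the subtree
   with the highest mean pairwise score (≥ 3 leaves) is kept. The pruned
   members are progressively aligned along the tree, a consensus structure
   is predicted by the same DP machinery over alignment columns (a column
   pair is admissible when ≥ 50% of rows can form a canonical pair and
   scores support × mean pair weight), and the cluster is annotated with
   the structure conservation index (SCI = consensus score / mean member
   fold score; clusters under 1% are flagged as not conserved), a
   compensatory-double-substitution count (consensus pairs where ≥ 2 rows
   differ from the majority residue pair at both positions while still
   pairing — a simple covariation count, not a statistical test), and mean
   pairwise identity. The cluster is then extended: unclustered windows
   with centroid similarity ≥ 0.4 are recruited, but each recruit must also
   align to up to five cluster exemplars at ≥ 50% of the self-alignment
   score. The centroid scan is a recall-only prescreen (homologs and
   shuffled background overlap on that statistic, so it merely bounds how
   many alignments are attempted); the alignment gate is the precision
   filter, playing the role of the hit threshold in a covariance-model
   homology search. Extension iterates up to 3 times because recruiting
   sharpens the centroid; the alignment gate is what prevents the iteration
   from snowballing into the data mean. Clustering
   rounds repeat (default 2) over whatever remains unclustered. The final
   report is a hard partition (multiply-claimed members go to the cluster
   with the highest centroid similarity, ties to the lower cluster id) or a
   soft partition that keeps overlaps.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window_len / shift | 250/0.7 global, 100/0.7 local | fragment length (nt) and shift fraction |
| pair weights | GC 3, AU 2, GU 1 | fold DP pair scores (score units) |
| min_loop | 3 | minimum hairpin loop (nt) |
| m, b | 1.8, −0.6 | reactivity→pseudo-score conversion (score units) |
| λ | 1.0 | weight of the pseudo-score penalty |
| R, D, bits | 3, 3, 20 | kernel radius, distance, hash width |
| K, min_collisions | 512, 8 | signature length; neighbor collision floor |
| min_density / density_top | 0.4 / 3 | candidate acceptance on top-member similarity |
| min_cluster_size | 3 | smallest allowed cluster core |
| extension_threshold | 0.4 | centroid-similarity recall prescreen |
| extension_score_gate | 0.5 | normalized alignment precision filter |
| max_rounds | 2 | clustering iterations |

All are exposed through `PipelineParams` / `ClusterParams` and the CLI.

## Synthetic data and what passing tests show

The generator emulates a homologous structured-RNA family: a random nested
structure (~55% of positions paired, helices of 2–8 bp with occasional
multiloop splits — tRNA-like pairing density), an ancestor with GC-biased
stems and A-rich loops, and members mutated to a target mean pairwise
identity (default 0.7). Substitutions at paired positions are compensatory
double substitutions with probability 0.8, otherwise pairability-preserving
single substitutions, so every member remains compatible with the family
structure — the covariation pattern that defines structure-conserving
families. Backgrounds are mono- or dinucleotide-preserving shuffles
(Euler-path method) of the input, so decoys match length and (di)nucleotide
composition exactly. Simulated reactivities draw paired positions from
Exp(mean 0.1) and unpaired from Exp(mean 0.9), which reproduces the
paired/unpaired ranking quality (AUC ≥ 0.8) typical of probing data.

The benchmark suite plants 5 families × 20 members among 100
dinucleotide-shuffled decoys and requires ARI ≥ 0.8 within two rounds; at
the defaults the pipeline recovers all five families exactly (ARI 1.0).
The probing-benefit experiment restricts the generator to families whose
unguided fold misses ≥ 45% of true pairs (the regime where probing has
room to act), runs the identical sequences with and without reactivity
profiles on paired seeds, and requires the guided run to match or beat the
unguided one in 5/5 replicates.

What this does **not** show about real data: members are i.i.d. mutants of
one ancestor (no phylogeny, no indels — alignments of real families gap),
decoys carry no secondary signal (real genomic backgrounds contain
structure), reactivity noise is i.i.d. exponential (real SHAPE/DMS noise is
sequence- and coverage-correlated), and the internal fold scorer is far
cruder than a nearest-neighbor thermodynamic model. Scores, thresholds and
the achieved ARI therefore do not transfer quantitatively to biological
datasets; the suite validates the machinery, not field performance.

## Numerical choices, determinism, degenerate inputs

* All DP tracebacks, tree merges, candidate orderings and partitions use
  explicit lexicographic tie-breaks; identical inputs and seeds give
  byte-identical outputs on any platform (the feature hash is a seeded
  BLAKE2b, not Python's salted `hash`).
* Fold traceback compares scores with tolerance 1e−9; pairs with negative
  net contribution are never forced into a structure.
* Empty feature vectors get a sentinel MinHash signature and are excluded
  from indexing; empty alignments, all-gap column pairs and zero mean fold
  scores yield SCI 0 rather than dividing by zero.
* `filter_redundant` at threshold 1.0 switches to exact sequence equality,
  since a k-mer estimate can reach 1.0 for non-identical sequences.
* Unclustered elements enter the ARI as singletons (switchable to dropping
  them); the ARI denominator-zero case (both partitions trivial) returns 1
  for identical partitions and 0 otherwise.
* Reactivity profiles must match sequence length exactly — mismatches are
  hard errors, never truncated.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
desk scale: folding oracles enumerate all nested structures up to 12 nt,
kernel oracles compare hashed against exact counting on graphs up to 50
vertices, the recovery benchmark uses 200 windows of 80 nt, and the
linearity check times the candidate stage on 1,000–8,000 synthetic
vectors. These sizes were chosen so the full suite gives quick feedback on
a single CPU while each check still exercises the asymptotic behavior or
statistical property it targets.

## Known limitations

* The internal folding objective is base-pair maximization with three pair
  weights; it has no stacking, dangles or loop-length terms, so absolute
  fold scores are not energies and predicted structures are rougher than a
  thermodynamic engine's. The pluggable dot-bracket import exists for
  exactly this reason.
* The covariation count is descriptive; it is not a significance test
  against a null of independent column evolution.
* Clusters found in later rounds are never merged with earlier ones, so a
  family split across rounds stays split (mitigated by the extension
  stage, which usually absorbs the family in round 1).
* Performance degrades sharply below ~65% pairwise identity: exact-label
  subgraph features lose overlap and the candidate stage stops seeing
  neighborhoods. Handling that regime needs softer labels or an external
  aligner-quality folding engine.
* Pseudoknots, multi-structure ensembles and base-pair probability
  matrices are out of scope throughout.
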