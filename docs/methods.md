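# Methods

This note documents the models, scoring definitions, numerical choices and
known limitations behind `traitscan`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Homology search and orthology

Family membership is decided by optimal local alignment (Smith–Waterman
with affine gaps; a gap of length k costs `gap_open + k·gap_extend`,
defaults 11/1, BLOSUM62) of each annotated protein against family seed
sequences. Significance uses the ungapped Karlin–Altschul expectation
`E = K·m·n·exp(−λS)` with the standard published BLOSUM62 constants
λ = 0.318, K = 0.134 as configurable defaults; these are a ranking
calibration, not a claim of gapped-statistics accuracy. The inclusion
cutoff E ≤ 0.1 is deliberately permissive — at this threshold unrelated
desk-scale sequences pass at an appreciable rate, and specificity is
restored downstream by the reciprocal-best-hit requirement.

Orthology is assigned per family by bidirectional best hits between each
genome's proteome and the seed set: gene x is the ortholog of family F in
genome g iff some seed s of F is x's best seed overall (the *seed-set
vote*, which replaces external domain-database corroboration) and x is
s's best gene in g. Ties break by raw score, then E-value, then
lexicographic ID; a tie that survives all breaks disqualifies the pair.
At most one ortholog per family per genome is called; additional genes
above the cutoff are reported as paralogs. Deterministic traceback rules
(best cell at lowest row then column; moves prefer diagonal > up > left;
gap closure preferred over extension) make alignments reproducible.

## Trait signature

The resolution trait is called from presence alone: `RuvABC` when
ruvA ∧ ruvB ∧ ruvC ∧ ¬recU, `RuvAB+RecU` when ruvA ∧ ruvB ∧ recU ∧ ¬ruvC,
`both` when all four are present, `RuvAB-only` when the helicase pair
lacks any resolvase, `absent` otherwise. RuvC present without RuvAB is
biologically anomalous and flagged. The statuses partition genomes, so
per-taxon status fractions always sum to 1.

## Linkage scoring

The co-occurrence channel is the one-tailed (enrichment) Fisher exact
p-value of the 2×2 table between a candidate family's presence vector
and the anchor presence vector, mapped to `s_cooc = 1 − p` (capped below
1). Jaccard and the mutual information of the empirical 2×2 joint (in
nats) are computed alongside for inspection. The pipeline's anchor vector
is the trait signature (a genome counts as anchor-positive when it has
RuvAB plus either resolvase), so genomes whose resolvase is RecU are not
spuriously treated as anchor-negative; a plain AND of anchor columns is
the library default.

The neighborhood channel aggregates, per genome, the best proximity of
the candidate's genes to any anchor gene on the same contig:
weight 1 when they share an operon, 0.5 when within 3 gene ranks,
else 0; `s_nbr = min(0.999, mean weight over all genomes)`. Operons are
maximal same-strand runs with intergenic gap ≤ 100 bp (a common
operon-prediction heuristic; configurable). The 1/0.5/0 weights, the
rank window D = 3 and the 0.999 cap are package definitions
operationalizing qualitative "very close / same operon" evidence.

Gene fusion contributes a binary bonus (`s_fus = 0.5`) when one gene's
hits cover ≥ 60% of seeds from two different families on disjoint gene
spans. The channels combine as a noisy-OR,
`combined = 1 − (1−s_cooc)(1−s_nbr)(1−s_fus)`, and families are ranked by
`combined` with lexicographic tie-breaks.

Profiles are treated as i.i.d. across genomes: no phylogenetic
(tree-aware) correction is applied to co-occurrence statistics. This is a
known simplification — shared ancestry inflates apparent co-occurrence —
and the permissive channel design should be read accordingly.

## Alignment and phylogeny

The progressive aligner computes 3-mer set distances, an average-linkage
(UPGMA) guide tree via scipy, and profile–profile global alignment where
the column score is the expected substitution score over residue
frequencies (gap frequencies score zero) under the same affine penalties
as the search stage. It is a standard guide-tree aligner, documented and
deterministic, not a reimplementation of any specific external tool.
Columns with gap fraction > 0.5 are masked before distance estimation,
with a retained-to-original column map kept for coordinate reporting.

Distances use the closed-form Kimura protein correction
`d = −ln(1 − p − 0.2p²)` with p the mismatch fraction over mutually
ungapped columns; the correction is undefined for p ≥ 0.8541, where d is
set to a ceiling (default 10) with a warning. Neighbor joining follows
Saitou–Nei with the Q-criterion, joins resolved deterministically
(smallest row-index pair on ties), negative branch lengths clamped to
zero with the deficit moved to the sister branch, and the final three
lineages joined at a trifurcating node (the unrooted representation). On
additive matrices NJ is exact; the tests verify topology and branch
lengths to 1e−9 on random additive matrices.

Bootstrap support resamples alignment columns with replacement
(default 100 replicates, seeded), rebuilds the distance+NJ tree and
counts recurrences of the original bipartitions. Parsimony is unit-cost
small parsimony computed by dynamic programming over the observed column
states (equivalent to Fitch counting on binary trees, exact also on the
trifurcating NJ root); gaps and X are missing data, contributing neither
states nor cost. Tree *search* under parsimony is out of scope — the
trees of record are NJ trees, and parsimony is a scoring diagnostic.

Subtypes are the two clades under the midpoint root (outgroup rooting is
available); subtype I is the clade containing a user-designated reference
leaf, else the larger clade, ties broken by the smallest leaf ID. A
zero-length tree has no midpoint and yields `unassigned` labels with a
warning. The midpoint-root split is this package's operationalization of
a two-subtype partition; the underlying family tree is built from
orthologs of one focal family across genomes.

## Specificity-determining positions

Within each subtype, a column's conservation is the frequency of its most
common non-gap residue over *all* members (gaps count against
conservation and can never be the consensus). A column is I-specific when
conservation in I ≥ `strict` for residue a and a's frequency in II is
≤ 1 − `strict`; II-specific symmetrically; *diagnostic* when both hold
with different residues; shared-conserved when both subtypes conserve the
same residue; else variable. `strict = 1.0` is the default reading of
"strictly conserved"; 0.9 is recommended (and used by the pipeline) for
noisy data. Lowering `strict` can only grow the diagnostic set
(monotonicity, property-tested). Reports map columns back to original
alignment coordinates through the masking column map. Statistical SDP
scoring with null calibration is out of scope.

## Synthetic data

The generator is the package's ground-truth instrument; its defaults are
the study conditions under which recovery is measured.

* **Species tree**: Yule (pure-birth) tree, default 50 leaves, simulated
  by explicit exponential waiting times so branch lengths are strictly
  positive and ultrametric; leaves are labeled deterministically and
  grouped into "phyla" by the clades two splits below the root.
* **Gene content**: each family's presence evolves independently along
  the tree as a two-state Markov chain with gain and loss rates (default
  0.3/0.3 per unit branch length; stationary presence
  gain/(gain+loss) = 0.5), no rate heterogeneity. The trait is one such
  character started present at the root; trait genomes carry ruvA, ruvB
  and a resolvase (recU with probability 0.2, else ruvC). The partner
  family's presence equals the trait state with probability
  `linkage_strength` (default 0.95) and is flipped otherwise, making
  empirical co-occurrence monotone in the parameter.
* **Gene order**: each genome is one contig; anchor genes form a block
  with small intra-block gaps (5–40 bp), the partner is placed
  immediately downstream of the resolvase on the same strand with gap
  U[0, 50] bp in 75% of co-occurring genomes (`operon_fraction`),
  and all other genes are shuffled with intergenic gaps U[120, 400] bp —
  above the operon threshold, so decoy operons with anchors arise only
  rarely. Coordinates are 3·(protein length) plus gaps; proteins default
  to 200 aa. Family sequences are random 20-letter proteins mutated
  per-genome at 5% per site, far inside the detection range of the
  search stage while keeping decoy families mutually unrelated.
* **Subtype family**: the partner family carries a planted two-subtype
  structure. Members are split into two balanced clades. From a random
  root sequence, each clade ancestor mutates non-diagnostic sites at
  `subtype_divergence/4`; each member then mutates from its clade
  ancestor at `subtype_divergence` (default 0.3). The
  `n_diagnostic_columns` (default 10) planted columns are fixed to
  residue a in clade I and b ≠ a in clade II and are exempt from
  mutation. The quarter-rate backbone divergence was chosen analytically
  so that the between-clade signal suffices for tree-based clade
  recovery while incidental fully-conserved between-clade differences —
  which would count against SDP precision — stay rare; tip noise breaks
  the conservation of most of the remainder.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` substreams; outputs are reproducible
bit-for-bit, and generated FASTA/GFF3 round-trip through the I/O layer.

What the simulator does **not** emulate: codon-level evolution,
insertions/deletions within family sequences (family members are
equal-length, so planted column indices are alignment coordinates),
rearrangements/inversions, horizontal transfer, rate heterogeneity across
families or sites, multi-contig assemblies, or database-scale genome
collections. Passing recovery tests therefore demonstrates correctness of
the inference chain under the planted model, not performance on real
proteomes with domain shuffling, low-complexity sequence or annotation
noise.

## Problem sizes and runtime choices

Recovery metrics use 20 independent simulations per condition: linkage
ranking on the default 50-genome condition, subtype recovery on 30-member
families at divergence 0.3, SDP recovery at divergence 0 (strict 1.0) and
0.2 (strict 0.9). Primitive oracles run exhaustively where the space is
small (all short sequence pairs on a 3-letter alphabet, all unrooted
topologies with ≤ 5 leaves × all 4-state columns, all 2×2 tables up to
n = 30 in the tests) and on seeded samples otherwise. The determinism
check runs the full pipeline twice on a 20-genome dataset with 25
bootstrap replicates and compares artifacts byte for byte. These sizes
keep the whole battery to a few minutes while leaving the acceptance
margins far from their thresholds.

## Numerical and degenerate-input conventions

* Internal coordinates are 0-based half-open; GFF3 converts at the
  boundary (1-based inclusive), and the conversion is self-inverse.
* Genes are keyed (contig, start, ID) with lexicographic ID tie-breaks;
  duplicate coordinates keep the first gene by ID with a warning.
* A family absent from every genome yields Jaccard = MI = 0 and
  Fisher p = 1 with a warning rather than an error.
* An all-negative scoring pair yields local score 0 with an empty
  alignment and zero-width spans.
* `smith_waterman(a,b)` equals `smith_waterman(b,a)` in score, and
  self-score dominates cross-score (property-tested).
* Empty sequences, non-positive lengths, asymmetric distance matrices,
  subtype groups below `min_group`, and a trees/MSA leaf mismatch are
  hard errors; masking away all columns advises raising the threshold.

## Known limitations

Single-copy orthology (BBH against seeds) will pick one gene in genomes
with genuine duplications; paralog reports partially mitigate this. The
E-value model is ungapped theory applied to gapped scores. Operon calls
are a distance heuristic, not transcription units. Co-occurrence ignores
phylogeny. The subtype split assumes exactly two subtypes separated at
the root. These match the package's scope as a desk-scale, fully
reproducible reimplementation of a classic comparative-genomics inference
chain.
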