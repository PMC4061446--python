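# Methods

## Model and pipeline

`blockvep` scores an amino acid substitution (protein, position, ref → mut)
in four stages.

**1. Query-anchored stacking and NAS.** Homologous hits arrive as gapped
pairwise alignments (HSPs) against the query, with a raw BLOSUM62 alignment
score. Each HSP is projected onto query coordinates: columns that are
insertions relative to the query are discarded, deletions become "no
residue". No progressive re-alignment is attempted — every downstream
feature is column-wise at query positions, and pairwise HSPs carry exactly
that information. A hit's normalized alignment score is
`NAS = raw_score / self_score(query)`, where the self score is the sum of
BLOSUM62 diagonal entries over the query; NAS is clamped to [0, 1] because
repeat-region artifacts can push the raw score past the self score. Hits
are ordered by NAS descending with ties broken by hit id, so the order is
total and runs are bit-reproducible. When several HSPs share a hit, only
the highest-scoring HSP is kept (each database sequence contributes one MSA
row; the merge rule is this package's choice). Input hits are filtered at
e-value ≤ 1e-4 and capped at 5,000 per query.

**2. Species categories and blocks.** Source organisms map to five ordered
categories by clade-name matching on their lineage: Primates → 1,
Mammalia → 2, Vertebrata or Craniata → 3, Metazoa → 4, everything else → 5.
Matching on names rather than walking taxid ranks lets a simplified
two-column lineage file behave identically to an NCBI dump; Craniata is
accepted because some exports omit Vertebrata. Block starts are found
sequentially down the NAS-sorted stack: the level-k block starts at the
first category-k hit after all previously found starts. This ordering rule
matters: category first-occurrences need not be monotone down the stack
(a contaminant "other species" sequence can outrank the first mammal), and
the sequential rule is the reading that keeps block-start NAS non-increasing
and the first sequence of block k of category k. Every hit between two
starts belongs provisionally to the earlier block; hits whose category
differs from their provisional block's level are relocated to the paralog
block, in both directions — a primate ranked among vertebrates is a paralog,
a bacterium ranked among primates is contamination. Relocation is
single-pass and order-preserving, and re-partitioning the ortholog rows is
a no-op.

**3. Features.** Per block and query column: frequencies of the reference
and mutant residues, Shannon entropy (base 2), NAS of the block's first
sequence, block size, position-covering count, and their ratio. Frequencies
and entropy are normalized by the number of *position-covering* sequences
(those contributing one of the 20 standard codes at the column), not block
size, so column frequencies always form a probability distribution —
ambiguity codes (B, Z, X, U), stops and gaps count as "no residue".
Absent blocks contribute zeros for all seven numerics; the covering counts
already signal absence, so no extra indicator is added. The lowest conserved
block is the deepest k such that every covering sequence in blocks 1..k
carries the reference residue; 0 means the primate block already violates
(the published ordinal starts at "primate", but a below-primate sentinel is
needed for exactly that case); empty blocks are vacuously conserved but a
deeper non-empty violating block still stops the count; the paralog block is
never consulted. With one-hot reference and mutant residues this gives
2×20 + 6×7 + 1 = 83 features, or 48 in the single-block ablation mode, which
collapses all six blocks into one before computing features (the ordinal
then degenerates to {0, 1}).

**4. Classifier.** A random forest with 500 trees and √p candidate features
per split — the default hyperparameters of the classical randomForest
method. The score is the fraction of trees voting "neutral" (literal
majority-vote semantics over the fitted sub-estimators, not the mean of
leaf probabilities), so scores are multiples of 1/500. A variant is called
damaging when its score is *strictly below* the cutoff; the cutoff is chosen
by exhaustive scan over 0, 1 and midpoints of adjacent sorted unique scores,
minimizing the misclassification count with ties broken toward the smaller
threshold. Published operating points for this family of models are 0.6
(broad disease-variant training data) and 0.28 (Mendelian-only training
data); models trained here re-optimize the cutoff on their own training
scores, since the provenance of the published values (out-of-bag vs
held-out) is not documented.

## Evaluation

Damaging is the positive class. The ROC sweep moves a threshold up the
score axis, calling a variant positive when score ≤ threshold; equal scores
collapse into one step, and AUC is the trapezoidal area — verified in tests
against a brute-force Mann–Whitney pairwise oracle. Cross-validation is
grouped at the protein level (proteins shuffled with the seed, dealt
round-robin into k folds), so no protein contributes variants to both sides
of a split; fold disjointness is asserted on every run. Both the pooled
(concatenated held-out scores) report and per-fold reports are produced.
Undefined metric ratios (e.g. precision with no positive calls) are reported
as 0 with a `degenerate` flag.

## Synthetic data

The generator emulates the regime the predictor assumes: per-residue
conservation decaying with evolutionary distance, interleaved paralogs, and
variants whose effect is knowable from the block structure.

Defaults (one protein): query length 200, uniform over the 20 residues;
10 hits per category mutated at per-site rates (0.01, 0.05, 0.15, 0.30,
0.45); 3 paralogs at rate 0.60 carrying primate taxids; NAS computed from
the simulated alignment with the same scoring code as real input. Hits are
generated at their category's rate but organism labels are assigned by NAS
rank, making NAS monotone in distance — the idealized ortholog regime. We
chose this after observing that independent per-category draws let the NAS
tails of adjacent categories interleave, so that genuine orthologs get
relocated as paralogs; rank assignment keeps the planted block structure
exact while the rates still set the NAS levels and gaps. An optional
truncation fraction makes hits cover only a sub-interval of the query,
exercising the partial-coverage feature paths.

Variants: "damaging" at positions conserved through at least
`conserved_depth_for_damaging` (default 3) blocks, with a mutant residue
absent from those conserved blocks' columns — it may occur by chance in
deeper blocks, as real pathogenic substitutions often match residues of
distant species; "neutral" at positions already polymorphic within the
primate block, with a mutant residue observed there (falling back, for
proteins short on primate polymorphisms, to shallowly conserved positions
with the mutant observed anywhere in the column). Half the variants are
damaging by default. A dataset is 50 such proteins × 10 variants from
spawned child seeds of one master seed.

What the generator does *not* emulate: tree-structured substitution
processes (sites mutate independently per hit, so there is no phylogenetic
correlation between hits), indels beyond truncation, rate variation across
sites, and any sequence-composition realism. Passing tests therefore show
that the pipeline recovers block-structured conservation signal when it
exists and that the machinery is correct — not that real-data accuracies
are reproduced.

Under the default conditions, protein-grouped 10-fold cross-validation
recovers the planted signal essentially perfectly (pooled AUC > 0.9 is the
asserted bound) and the single-block ablation scores strictly lower
accuracy, matching the direction reported for the real-data ablation of
block-wise conservation analysis. The equal-rates negative control (one
substitution rate everywhere, 0.05 so that deeply conserved positions still
exist) brings the two modes within 0.1 accuracy of each other; exact
equivalence is not expected because the variant-planting rules themselves
refer to NAS strata even when rates are flat.

## Numerical choices

- Entropy sums run in fixed residue order (`ARNDCQEGHILKMFPSTWYV`) and
  return +0.0 for conserved or empty columns; the worked example's shipped
  expectations are reproduced bit-exactly.
- Empty columns: frequencies and entropy 0; ratio 0 for empty blocks.
- NAS ties: resolved by hit id; sorting is stable and deterministic.
- All randomness (generator, fold shuffling, forest) flows from explicit
  integer seeds; same seed ⇒ bit-identical scores.
- Problem sizes in the test suite (fixture dimensions, tree counts for
  plumbing tests) are chosen to keep the default run light while the
  headline end-to-end check uses the full default conditions above.

## Known limitations

- The blocking edge case where the top of the stack precedes the first
  block start (no primate hit at the top) assigns those hits to the first
  block found and then relocates category mismatches; other readings are
  defensible, but this one satisfies all structural invariants.
- The cutoff returned by the optimizer can be 0 or 1 on degenerate score
  sets; persisted models clamp it into (0, 1).
- Feature extraction assumes the variant table's reference residue; a
  mismatch with the query sequence warns and proceeds rather than failing,
  to tolerate sequence-version drift in batch runs.
- Multi-HSP hits keep only the best HSP; split alignments of one hit are
  not merged.
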