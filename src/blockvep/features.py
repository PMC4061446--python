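"""Block-wise conservation features for one amino acid substitution.

For a query position, every block contributes seven numbers:

``f_ref``, ``f_mut``
    Frequencies of the reference/mutant residue among the block's
    position-covering sequences.
``entropy``
    Shannon entropy (bits, base 2) of the residue distribution at the
    position; 0 = no diversity, log2(20) ~ 4.322 = uniform over the 20
    standard residues.
``nas_first``
    NAS of the block's first (highest-scoring) sequence — a per-protein
    measure of how fast the protein has been evolving down to that block.
``n_all``, ``n_qp``, ``ratio_nn``
    Block size, number of sequences covering the position, and their ratio.

Frequencies and entropy are computed over position-covering sequences only
(sequences whose residue at the position is one of the 20 standard codes),
so the column frequencies always form a probability distribution. On top of
the per-block numbers, the *lowest conserved block* records the deepest
block k such that the reference residue is perfectly conserved in blocks
1..k (paralog block excluded; 0 when even the primate block is not
conserved), and the reference/mutant residues enter as one-hot indicators.

The full vector has 2x20 one-hot + 6x7 block numerics + 1 ordinal =
83 fields. The single-block ablation mode collapses all six blocks into one
before computing features, giving 2x20 + 7 + 1 = 48 fields.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from typing import Mapping, Sequence

from .blocking import ALL_BLOCKS, ORTHOLOG_BLOCKS, PARALOG_BLOCK, BlockPartition
from .io import AMINO_ACIDS, VariantQuery
from .msa import HomologHit, StackedMSA

MAX_ENTROPY_BITS = math.log2(len(AMINO_ACIDS))  # 4.3219...

BLOCK_NUMERIC_FIELDS = (
    "f_ref", "f_mut", "entropy", "nas_first", "n_all", "n_qp", "ratio_nn",
)

BLOCKWISE = "blockwise"
SINGLE_BLOCK = "single_block"
_SINGLE_LABEL = "ALL"


def feature_schema(mode: str = BLOCKWISE) -> list[str]:
    """Ordered feature-column names for a mode (83 blockwise, 48 single)."""
    cols = [f"aa_ref_{aa}" for aa in AMINO_ACIDS]
    cols += [f"aa_mut_{aa}" for aa in AMINO_ACIDS]
    labels = ALL_BLOCKS if mode == BLOCKWISE else (_SINGLE_LABEL,)
    for label in labels:
        cols += [f"{label}_{field}" for field in BLOCK_NUMERIC_FIELDS]
    cols.append("lowest_conserved_block")
    return cols


def column_counts(
    block: Sequence[HomologHit], position: int
) -> tuple[Counter, int]:
    """Residue counts at a 0-based query position over one block.

    Only the 20 standard codes are tallied; gaps, uncovered positions and
    ambiguity codes count as "no residue". Returns ``(counts, n_qp)`` where
    ``n_qp`` is the number of sequences contributing a counted residue.
    """
    counts: Counter = Counter()
    for hit in block:
        aa = hit.residue_at(position)
        if aa is not None and aa in AMINO_ACIDS:
            counts[aa] += 1
    return counts, sum(counts.values())


def frequencies(
    counts: Mapping[str, int], n_qp: int, aa_ref: str, aa_mut: str
) -> tuple[float, float]:
    """(f_ref, f_mut) at the position; both 0 for an empty column."""
    if n_qp == 0:
        return 0.0, 0.0
    return counts.get(aa_ref, 0) / n_qp, counts.get(aa_mut, 0) / n_qp


def shannon_entropy(counts: Mapping[str, int], n_qp: int) -> float:
    """Shannon entropy in bits of the column's residue distribution.

    H = -sum_a p(a) log2 p(a) over the 20 standard residues, with empty
    columns defined as 0. Summation runs in fixed residue order so repeated
    calls are bit-identical.
    """
    if n_qp == 0:
        return 0.0
    total = 0.0
    for aa in AMINO_ACIDS:
        c = counts.get(aa, 0)
        if c:
            p = c / n_qp
            total += p * math.log2(p)
    return -total if total else 0.0  # avoid -0.0 for conserved columns


def lowest_conserved_block(
    part: BlockPartition, position: int, aa_ref: str
) -> int:
    """Deepest block k such that blocks 1..k perfectly conserve ``aa_ref``.

    A block is conserved when every position-covering sequence in it carries
    the reference residue; empty (or position-free) blocks are vacuously
    conserved. Returns 0..5; 0 means the primate block already violates.
    The paralog block is never considered.
    """
    depth = 0
    for k, label in enumerate(ORTHOLOG_BLOCKS, start=1):
        counts, n_qp = column_counts(part.blocks[label], position)
        if n_qp > 0 and (len(counts) > 1 or aa_ref not in counts):
            return depth
        depth = k
    return depth


def _block_numerics(
    block: Sequence[HomologHit], position: int, aa_ref: str, aa_mut: str
) -> dict[str, float]:
    counts, n_qp = column_counts(block, position)
    f_ref, f_mut = frequencies(counts, n_qp, aa_ref, aa_mut)
    n_all = len(block)
    return {
        "f_ref": f_ref,
        "f_mut": f_mut,
        "entropy": shannon_entropy(counts, n_qp),
        "nas_first": block[0].nas if block else 0.0,
        "n_all": float(n_all),
        "n_qp": float(n_qp),
        "ratio_nn": (n_qp / n_all) if n_all else 0.0,
    }


def _collapse(msa: StackedMSA) -> tuple[HomologHit, ...]:
    return msa.hits


def build_feature_vector(
    msa: StackedMSA,
    part: BlockPartition,
    variant: VariantQuery,
    mode: str = BLOCKWISE,
) -> dict[str, float]:
    """Assemble the full feature mapping for one substitution.

    The variant's position must lie within the query; a mismatch between the
    query residue there and the variant's stated reference residue is
    reported as a warning (sequence versions and variant tables drift) and
    the stated reference is used.
    """
    if mode not in (BLOCKWISE, SINGLE_BLOCK):
        raise ValueError(f"unknown mode {mode!r}")
    pos0 = variant.position - 1
    if not (0 <= pos0 < len(msa.query_seq)):
        raise ValueError(
            f"{variant.protein_id}: position {variant.position} beyond query "
            f"length {len(msa.query_seq)}"
        )
    if msa.query_seq[pos0] != variant.aa_ref:
        warnings.warn(
            f"{variant.protein_id}:{variant.position}: query residue "
            f"{msa.query_seq[pos0]} differs from stated reference "
            f"{variant.aa_ref}; using the stated reference",
            stacklevel=2,
        )

    vec: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        vec[f"aa_ref_{aa}"] = 1.0 if aa == variant.aa_ref else 0.0
    for aa in AMINO_ACIDS:
        vec[f"aa_mut_{aa}"] = 1.0 if aa == variant.aa_mut else 0.0

    if mode == BLOCKWISE:
        for label in ALL_BLOCKS:
            nums = _block_numerics(
                part.blocks[label], pos0, variant.aa_ref, variant.aa_mut
            )
            for field, value in nums.items():
                vec[f"{label}_{field}"] = value
        vec["lowest_conserved_block"] = float(
            lowest_conserved_block(part, pos0, variant.aa_ref)
        )
    else:
        merged = _collapse(msa)
        nums = _block_numerics(merged, pos0, variant.aa_ref, variant.aa_mut)
        for field, value in nums.items():
            vec[f"{_SINGLE_LABEL}_{field}"] = value
        counts, n_qp = column_counts(merged, pos0)
        conserved = n_qp > 0 and len(counts) == 1 and variant.aa_ref in counts
        # With one undivided block the ordinal collapses to {0, 1}; an empty
        # column is vacuously conserved, mirroring the blockwise rule.
        vec["lowest_conserved_block"] = float(1 if (conserved or n_qp == 0) else 0)
    return vec


def build_feature_table(
    msas: Mapping[str, StackedMSA],
    partitions: Mapping[str, BlockPartition],
    variants: Sequence[VariantQuery],
    mode: str = BLOCKWISE,
):
    """Feature DataFrame (one row per variant, schema-ordered columns).

    Returned alongside are the variants' protein ids and labels as columns
    ``protein_id``/``label`` on a separate index-aligned DataFrame, keeping
    the feature matrix purely numeric.
    """
    import pandas as pd

    schema = feature_schema(mode)
    rows = []
    meta = []
    for v in variants:
        if v.protein_id not in msas:
            raise KeyError(f"no MSA for protein {v.protein_id}")
        vec = build_feature_vector(
            msas[v.protein_id], partitions[v.protein_id], v, mode=mode
        )
        rows.append([vec[c] for c in schema])
        meta.append((v.protein_id, v.position, v.aa_ref, v.aa_mut, v.label))
    X = pd.DataFrame(rows, columns=schema)
    info = pd.DataFrame(
        meta, columns=["protein_id", "position", "aa_ref", "aa_mut", "label"]
    )
    return X, info
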