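"""Query-anchored alignment stacking and normalized alignment scores (NAS).

The homology search returns one gapped pairwise alignment (HSP) per hit.
Because every downstream conservation feature is column-wise at query
positions, the hits are not re-aligned into a true progressive MSA: each
HSP is simply projected onto query coordinates (columns that are insertions
relative to the query are dropped), producing a stacked, query-anchored MSA.

A hit's NAS is its raw BLOSUM62 alignment score divided by the query's
self-alignment score (the sum of BLOSUM62 diagonal entries over the query).
NAS ~ 1 means a sequence nearly identical to the human query; NAS decays
with evolutionary distance, and the stack is sorted by NAS descending
(ties broken by hit id) so that blocking can read evolutionary distance
straight off the row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

from Bio.Align import substitution_matrices

from .io import AMINO_ACIDS, BlastHitRecord
from .taxonomy import SpeciesCategory

GAP = "-"


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def blosum62_score(a: str, b: str) -> float:
    """BLOSUM62 substitution score for a residue pair."""
    return float(_blosum62()[a, b])


def self_score(query_seq: str) -> float:
    """BLOSUM62 score of the query aligned against itself.

    This is the NAS denominator: the sum of diagonal matrix entries over
    the query residues. All residues must be standard amino acids.
    """
    if not query_seq:
        raise ValueError("empty query sequence")
    m = _blosum62()
    total = 0.0
    for aa in query_seq:
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard residue {aa!r} in query sequence")
        total += m[aa, aa]
    return total


def compute_nas(raw_score: float, self_score_value: float) -> float:
    """Normalized alignment score: raw score over the query self score.

    Clamped to [0, 1]; repeat-region artifacts can push the raw score past
    the self score and must not break downstream feature ranges.
    """
    if self_score_value <= 0:
        raise ValueError(
            f"query self score must be positive, got {self_score_value}"
        )
    return min(1.0, max(0.0, raw_score / self_score_value))


@dataclass(frozen=True)
class HomologHit:
    """One homologous sequence projected onto query coordinates.

    ``row`` has the query's length; positions outside the HSP's query range
    and deletion gaps inside it hold ``-``. Non-standard residue codes
    (B, Z, X, U, *) are retained verbatim but count as "no residue" in all
    downstream tallies. ``covered`` is the half-open 0-based query interval
    of the HSP.
    """

    hit_id: str
    nas: float
    category: SpeciesCategory
    covered: tuple[int, int]
    row: str

    def residue_at(self, position: int) -> Optional[str]:
        """Residue at a 0-based query position, or None for gap/uncovered."""
        start, end = self.covered
        if not (start <= position < end):
            return None
        ch = self.row[position]
        return None if ch == GAP else ch


@dataclass(frozen=True)
class StackedMSA:
    """Query-anchored stack of homologous hits, NAS-descending."""

    query_id: str
    query_seq: str
    hits: tuple[HomologHit, ...]


def _project(record: BlastHitRecord, query_seq: str) -> tuple[tuple[int, int], str]:
    qstart, qend = record.query_start, record.query_end
    L = len(query_seq)
    if not (1 <= qstart <= qend <= L):
        raise ValueError(
            f"hit {record.hit_id}: query coordinates {qstart}..{qend} "
            f"outside query of length {L}"
        )
    ungapped = record.aligned_query.replace(GAP, "")
    expected = query_seq[qstart - 1 : qend]
    if ungapped != expected:
        raise ValueError(
            f"hit {record.hit_id}: ungapped aligned query does not match the "
            f"query subsequence at {qstart}..{qend}"
        )
    row = [GAP] * L
    qpos = qstart - 1
    for qc, sc in zip(record.aligned_query, record.aligned_hit):
        if qc == GAP:
            # Insertion in the hit relative to the query: no query column.
            continue
        row[qpos] = sc
        qpos += 1
    return (qstart - 1, qend), "".join(row)


def stack(
    query_id: str,
    query_seq: str,
    hits: Sequence[BlastHitRecord],
    categories: Mapping[str, SpeciesCategory],
) -> StackedMSA:
    """Project hits onto query coordinates and sort by NAS descending.

    ``categories`` maps each hit's taxid to its species category. Ties in
    NAS are broken by hit id ascending so the order is total and repeated
    calls are bit-identical.
    """
    if not query_seq:
        raise ValueError("empty query sequence")
    denom = self_score(query_seq)
    projected = []
    for rec in hits:
        if rec.organism_taxid not in categories:
            raise KeyError(
                f"hit {rec.hit_id}: taxid {rec.organism_taxid} has no lineage "
                "entry; cannot assign a species category"
            )
        covered, row = _project(rec, query_seq)
        projected.append(
            HomologHit(
                hit_id=rec.hit_id,
                nas=compute_nas(rec.raw_score, denom),
                category=categories[rec.organism_taxid],
                covered=covered,
                row=row,
            )
        )
    projected.sort(key=lambda h: (-h.nas, h.hit_id))
    return StackedMSA(query_id=query_id, query_seq=query_seq, hits=tuple(projected))
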