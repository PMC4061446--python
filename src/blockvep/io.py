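"""Readers and writers for the plain-text formats the tool consumes and emits.

No science lives here: this module only moves data between disk and the
in-memory types used by the rest of the package.

Formats
-------
FASTA
    Query and hit protein sequences (``Bio.SeqIO`` underneath).
Hit table (TSV, no header, ``#`` comments allowed)
    One row per HSP with the gapped aligned strings included::

        qseqid  sseqid  evalue  raw_score  qstart  qend  sstart  send
        qseq_aligned  sseq_aligned  staxid

    The standard 12-column BLAST ``outfmt 6`` lacks the aligned strings the
    query-anchored stacking step needs, hence this fixed custom dialect.
Lineage table
    Either a two-column TSV ``taxid<TAB>clade;clade;...;species`` or a
    directory containing NCBI-taxonomy-style ``nodes.dmp`` and ``names.dmp``.
Variant table (TSV, no header)
    ``protein_id  position(1-based)  aa_ref  aa_mut  [label]``.
Prediction table (TSV, one header row)
    ``protein_id  position  aa_ref  aa_mut  score  prediction`` with the
    score (probability that the substitution is neutral) printed to six
    decimals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
"""The 20 standard amino acid one-letter codes, in the classic matrix order."""

VALID_LABELS = ("neutral", "damaging")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class VariantQuery:
    """One amino acid substitution to be scored.

    Attributes
    ----------
    protein_id : str
        Accession of the protein the substitution occurs in.
    position : int
        1-based residue index in the protein sequence.
    aa_ref, aa_mut : str
        Reference and mutant residues; distinct members of the 20 standard
        amino acid codes.
    label : str, optional
        ``"neutral"`` or ``"damaging"`` when known (training/evaluation).
    """

    protein_id: str
    position: int
    aa_ref: str
    aa_mut: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        for name, aa in (("aa_ref", self.aa_ref), ("aa_mut", self.aa_mut)):
            if aa not in AMINO_ACIDS or len(aa) != 1:
                raise ValueError(
                    f"{self.protein_id}: {name} {aa!r} is not one of the 20 "
                    "standard amino acid codes"
                )
        if self.aa_ref == self.aa_mut:
            raise ValueError(
                f"{self.protein_id}:{self.position}: aa_ref equals aa_mut "
                f"({self.aa_ref}); not a substitution"
            )
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(
                f"{self.protein_id}: label must be one of {VALID_LABELS}, "
                f"got {self.label!r}"
            )


@dataclass(frozen=True)
class BlastHitRecord:
    """One HSP of one database hit against the query protein.

    ``aligned_query``/``aligned_hit`` are the gapped aligned strings of the
    HSP (equal length); ``raw_score`` is the alignment score in BLOSUM62
    units; coordinates are 1-based inclusive on the query/subject.
    """

    hit_id: str
    raw_score: float
    e_value: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_hit: str
    organism_taxid: str

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_hit):
            raise ValueError(
                f"hit {self.hit_id}: aligned strings differ in length "
                f"({len(self.aligned_query)} vs {len(self.aligned_hit)})"
            )
        if self.e_value < 0:
            raise ValueError(f"hit {self.hit_id}: negative e-value {self.e_value}")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are upper-cased; the id is the first whitespace-delimited token
    of the description line. An empty file or a duplicated id is an error.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


_HIT_COLUMNS = 11


def read_blast_tabular(
    path: str | os.PathLike,
    max_hits: int = 5000,
    e_cutoff: float = 1e-4,
) -> list[BlastHitRecord]:
    """Read the 11-column hit table, filter by e-value, cap the hit count.

    Rows with ``e_value > e_cutoff`` are dropped (the homology-search cutoff;
    default 1e-4). When several HSPs share a hit id only the highest-raw-score
    HSP is kept, at the position of the hit's first appearance. At most
    ``max_hits`` records (default 5000, the retrieval cap per query) are
    returned, in input order.
    """
    order: list[str] = []
    best: dict[str, BlastHitRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} tab-separated "
                    f"columns (qseqid sseqid evalue raw_score qstart qend "
                    f"sstart send qseq_aligned sseq_aligned staxid), "
                    f"got {len(fields)}"
                )
            (_qid, sid, evalue, raw, qstart, qend, sstart, send,
             qseq, sseq, staxid) = fields
            try:
                rec = BlastHitRecord(
                    hit_id=sid,
                    raw_score=float(raw),
                    e_value=float(evalue),
                    query_start=int(qstart),
                    query_end=int(qend),
                    subject_start=int(sstart),
                    subject_end=int(send),
                    aligned_query=qseq.upper(),
                    aligned_hit=sseq.upper(),
                    organism_taxid=staxid,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if rec.e_value > e_cutoff:
                continue
            if sid not in best:
                order.append(sid)
                best[sid] = rec
            elif rec.raw_score > best[sid].raw_score:
                best[sid] = rec
    return [best[sid] for sid in order[:max_hits]]


def _read_simple_lineage(path: str | os.PathLike) -> dict[str, list[str]]:
    lineages: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'taxid<TAB>lineage', "
                    f"got {len(parts)} columns"
                )
            taxid, lineage = parts
            clades = [c.strip() for c in lineage.split(";") if c.strip()]
            if not clades:
                raise FormatError(f"{path}:{lineno}: empty lineage for {taxid}")
            lineages[taxid.strip()] = clades
    return lineages


def _parse_dmp(path: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("|").rstrip("\t")
            if not line.strip():
                continue
            rows.append([f.strip() for f in line.split("\t|\t")])
    return rows


def _read_ncbi_dump(directory: str | os.PathLike) -> dict[str, list[str]]:
    nodes_path = os.path.join(str(directory), "nodes.dmp")
    names_path = os.path.join(str(directory), "names.dmp")
    parent: dict[str, str] = {}
    for row in _parse_dmp(nodes_path):
        parent[row[0]] = row[1]
    name: dict[str, str] = {}
    for row in _parse_dmp(names_path):
        # Keep the scientific name; fall back to the first name seen.
        if len(row) >= 4 and row[3] == "scientific name":
            name[row[0]] = row[1]
        else:
            name.setdefault(row[0], row[1])
    lineages: dict[str, list[str]] = {}
    for taxid in parent:
        chain: list[str] = []
        seen: set[str] = set()
        node = taxid
        while True:
            if node in seen:
                raise FormatError(
                    f"{nodes_path}: cyclic parent chain at taxid {node}"
                )
            seen.add(node)
            chain.append(name.get(node, node))
            up = parent.get(node)
            if up is None:
                raise FormatError(
                    f"{nodes_path}: taxid {node} has no parent entry"
                )
            if up == node:  # NCBI convention: the root is its own parent
                break
            node = up
        lineages[taxid] = chain[::-1]
    return lineages


def read_lineage_table(path: str | os.PathLike) -> dict[str, list[str]]:
    """Map taxids to root-to-leaf lineages (lists of clade names).

    ``path`` is either a two-column ``taxid<TAB>semicolon-joined-lineage``
    file or a directory holding NCBI-style ``nodes.dmp`` + ``names.dmp``.
    """
    if os.path.isdir(path):
        return _read_ncbi_dump(path)
    return _read_simple_lineage(path)


def read_variant_table(path: str | os.PathLike) -> list[VariantQuery]:
    """Read the 4/5-column variant TSV into validated :class:`VariantQuery`."""
    variants = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise FormatError(
                    f"{path}:{lineno}: expected 4 or 5 columns "
                    f"(protein_id position aa_ref aa_mut [label]), "
                    f"got {len(parts)}"
                )
            try:
                variants.append(
                    VariantQuery(
                        protein_id=parts[0],
                        position=int(parts[1]),
                        aa_ref=parts[2].upper(),
                        aa_mut=parts[3].upper(),
                        label=parts[4] if len(parts) == 5 else None,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return variants


def write_variant_table(path: str | os.PathLike, variants: Iterable[VariantQuery]) -> None:
    """Write variants back out in the dialect :func:`read_variant_table` reads."""
    with open(path, "w") as fh:
        for v in variants:
            cols = [v.protein_id, str(v.position), v.aa_ref, v.aa_mut]
            if v.label is not None:
                cols.append(v.label)
            fh.write("\t".join(cols) + "\n")


PREDICTION_HEADER = (
    "protein_id", "position", "aa_ref", "aa_mut", "score", "prediction"
)


def write_predictions(
    path: str | os.PathLike,
    rows: Iterable[tuple[str, int, str, str, float, str]],
) -> None:
    """Write prediction rows; score printed to six decimals."""
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_HEADER) + "\n")
        for protein_id, position, aa_ref, aa_mut, score, call in rows:
            fh.write(
                f"{protein_id}\t{position}\t{aa_ref}\t{aa_mut}"
                f"\t{score:.6f}\t{call}\n"
            )


def read_predictions(
    path: str | os.PathLike,
) -> list[tuple[str, int, str, str, float, str]]:
    """Read back a prediction table written by :func:`write_predictions`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_HEADER:
            raise FormatError(f"{path}: unexpected prediction header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, pos, ref, mut, score, call = line.split("\t")
            rows.append((pid, int(pos), ref, mut, float(score), call))
    return rows
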