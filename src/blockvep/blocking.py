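"""Partition the NAS-sorted MSA into five ortholog blocks plus a paralog block.

Walking the stack from the top (highest NAS, usually human/primate), the
first hit of each species category marks the start of that category's block;
everything between two consecutive block starts belongs to the earlier
block. Hits whose species category disagrees with the block they fall in are
relocated to the paralog block: a primate sequence ranked among vertebrates
is a paralog (the TP63/TP73-among-TP53-orthologs situation), and a distant
sequence ranked among primates is repeated-sequencing noise or database
contamination. Relocation preserves relative order and is single-pass.

The NAS gap between adjacent rows is characteristically larger across a
block boundary than within a block; :func:`adjacent_nas_gaps` measures
exactly that as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .msa import HomologHit, StackedMSA
from .taxonomy import SpeciesCategory

ORTHOLOG_BLOCKS = ("B1", "B2", "B3", "B4", "B5")
PARALOG_BLOCK = "PARALOG"
ALL_BLOCKS = ORTHOLOG_BLOCKS + (PARALOG_BLOCK,)

#: Clip applied to adjacent-row NAS differences in the gap diagnostic.
NAS_GAP_CLIP = 0.4


@dataclass(frozen=True)
class BlockPartition:
    """Assignment of every MSA hit to one of B1..B5 or PARALOG.

    ``blocks`` maps each block label to its hits in MSA (NAS-descending)
    order; ``boundaries`` maps each ortholog block to the hit id of its
    first sequence, or None when the category is absent from the MSA.
    """

    blocks: dict[str, tuple[HomologHit, ...]]
    boundaries: dict[str, Optional[str]]

    def block_of(self, hit_id: str) -> str:
        for label, hits in self.blocks.items():
            if any(h.hit_id == hit_id for h in hits):
                return label
        raise KeyError(hit_id)


def partition(msa: StackedMSA) -> BlockPartition:
    """Group the stacked MSA into five ortholog blocks and a paralog block.

    Block starts are located sequentially down the stack: the start of the
    level-k block is the first hit of category k occurring after all block
    starts already found. Each hit is provisionally assigned to the block
    whose start interval contains it (hits above the first start join the
    first block found); any hit whose category differs from its provisional
    block's level is moved to PARALOG, keeping relative order.
    """
    hits = msa.hits
    for a, b in zip(hits, hits[1:]):
        if b.nas > a.nas:
            raise ValueError("MSA hits are not sorted by NAS descending")

    # Sequential block-start search; absent categories stay absent and the
    # search resumes at the same index for the next level.
    starts: dict[int, int] = {}  # level -> index of block start
    pos = 0
    for level in range(1, 6):
        idx = next(
            (i for i in range(pos, len(hits)) if hits[i].category == level),
            None,
        )
        if idx is not None:
            starts[level] = idx
            pos = idx + 1

    ordered = sorted(starts.items(), key=lambda kv: kv[1])  # increasing index
    blocks: dict[str, list[HomologHit]] = {label: [] for label in ALL_BLOCKS}
    boundaries: dict[str, Optional[str]] = {label: None for label in ORTHOLOG_BLOCKS}
    for level, idx in starts.items():
        boundaries[f"B{level}"] = hits[idx].hit_id

    if ordered:
        # Provisional level per hit index.
        first_start = ordered[0][1]
        bounds = [(idx, level) for level, idx in ordered]
        cursor = 0
        for i, hit in enumerate(hits):
            if i < first_start:
                level = ordered[0][0]
            else:
                while cursor + 1 < len(bounds) and i >= bounds[cursor + 1][0]:
                    cursor += 1
                level = bounds[cursor][1]
            if int(hit.category) == level:
                blocks[f"B{level}"].append(hit)
            else:
                blocks[PARALOG_BLOCK].append(hit)

    return BlockPartition(
        blocks={label: tuple(v) for label, v in blocks.items()},
        boundaries=boundaries,
    )


def adjacent_nas_gaps(
    part: BlockPartition,
) -> tuple[list[float], list[float]]:
    """NAS differences between adjacent rows within and between blocks.

    Returns ``(within, between)``: ``within`` holds the NAS difference of
    every consecutive pair inside one ortholog block; ``between`` pairs the
    last hit of each non-empty ortholog block with the first hit of the next
    non-empty one. Differences are clipped at 0.4.
    """
    within: list[float] = []
    between: list[float] = []
    nonempty = [part.blocks[label] for label in ORTHOLOG_BLOCKS if part.blocks[label]]
    for block in nonempty:
        for a, b in zip(block, block[1:]):
            within.append(min(NAS_GAP_CLIP, a.nas - b.nas))
    for blk, nxt in zip(nonempty, nonempty[1:]):
        between.append(min(NAS_GAP_CLIP, blk[-1].nas - nxt[0].nas))
    return within, between
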