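"""Species categories by evolutionary distance to human.

Every source organism of a homologous hit is mapped onto one of five ordered
categories: 1 = primate (human included), 2 = non-primate mammal,
3 = non-mammal vertebrate, 4 = invertebrate, 5 = other species (plants,
bacteria, fungi, ...). The category ladder is what the blocking step turns
into ortholog blocks, so the mapping must be total and deterministic.

Categories are decided from clade names in the lineage rather than by walking
taxonomic ranks, so a simplified two-column lineage file behaves exactly like
a full NCBI dump. "Craniata" is accepted alongside "Vertebrata" because some
lineage exports omit the latter.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Sequence


class SpeciesCategory(IntEnum):
    """Ordered distance-to-human category; 1 is closest to human."""

    PRIMATE = 1
    NONPRIMATE_MAMMAL = 2
    NONMAMMAL_VERTEBRATE = 3
    INVERTEBRATE = 4
    OTHER = 5


# Rule order matters: the most specific (closest to human) clade wins.
_RULES: tuple[tuple[frozenset[str], SpeciesCategory], ...] = (
    (frozenset({"Primates"}), SpeciesCategory.PRIMATE),
    (frozenset({"Mammalia"}), SpeciesCategory.NONPRIMATE_MAMMAL),
    (frozenset({"Vertebrata", "Craniata"}), SpeciesCategory.NONMAMMAL_VERTEBRATE),
    (frozenset({"Metazoa"}), SpeciesCategory.INVERTEBRATE),
)


def categorize(lineage: Sequence[str]) -> SpeciesCategory:
    """Map a root-to-leaf lineage (clade-name list) to its species category.

    The first matching rule wins: Primates -> 1, Mammalia -> 2,
    Vertebrata/Craniata -> 3, Metazoa -> 4, anything else -> 5 (catch-all,
    so the function is total). Clades below the matched rank never change
    the outcome.
    """
    if not lineage:
        raise ValueError("empty lineage")
    clades = set(lineage)
    for markers, category in _RULES:
        if clades & markers:
            return category
    return SpeciesCategory.OTHER
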