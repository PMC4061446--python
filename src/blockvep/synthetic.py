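"""Synthetic homolog sets with controllable block-structured conservation.

The generator emulates the situation the predictor is built for: a human
query protein whose homologs lose per-residue identity with evolutionary
distance. Each species category gets hits mutated from the query at its own
per-site substitution rate (non-decreasing with distance), NAS is computed
from the simulated alignment exactly as for real hits, paralogs are heavily
diverged copies carrying primate lineages (so the blocking step must
relocate them), and labeled variants are planted with ground truth:
"damaging" at positions conserved through the shallow blocks, with a mutant
residue absent from those blocks' columns; "neutral" at positions already
polymorphic within the primate block, with a mutant residue observed there.

Everything is driven by one seeded random stream, so fixtures are exactly
reproducible; no file ever needs to ship with the package.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .blocking import ORTHOLOG_BLOCKS, PARALOG_BLOCK, BlockPartition, partition
from .features import column_counts, lowest_conserved_block
from .io import (
    AMINO_ACIDS,
    BlastHitRecord,
    VariantQuery,
    write_variant_table,
)
from .msa import StackedMSA, blosum62_score, stack
from .taxonomy import categorize

# (taxid, root-to-leaf lineage) pools per species category. The lineages are
# abbreviated but carry the marker clades the category rules test for.
_CHORDATE = "cellular organisms;Eukaryota;Metazoa;Chordata;Craniata;Vertebrata"
TAXON_POOL: dict[int, tuple[tuple[str, str], ...]] = {
    1: (
        ("9606", f"{_CHORDATE};Mammalia;Primates;Hominidae;Homo sapiens"),
        ("9598", f"{_CHORDATE};Mammalia;Primates;Hominidae;Pan troglodytes"),
        ("9593", f"{_CHORDATE};Mammalia;Primates;Hominidae;Gorilla gorilla"),
        ("9601", f"{_CHORDATE};Mammalia;Primates;Hominidae;Pongo abelii"),
        ("9544", f"{_CHORDATE};Mammalia;Primates;Cercopithecidae;Macaca mulatta"),
    ),
    2: (
        ("10090", f"{_CHORDATE};Mammalia;Rodentia;Mus musculus"),
        ("10116", f"{_CHORDATE};Mammalia;Rodentia;Rattus norvegicus"),
        ("9913", f"{_CHORDATE};Mammalia;Artiodactyla;Bos taurus"),
        ("9615", f"{_CHORDATE};Mammalia;Carnivora;Canis lupus familiaris"),
    ),
    3: (
        ("7955", f"{_CHORDATE};Actinopterygii;Danio rerio"),
        ("9031", f"{_CHORDATE};Aves;Gallus gallus"),
        ("8364", f"{_CHORDATE};Amphibia;Xenopus tropicalis"),
    ),
    4: (
        ("7227", "cellular organisms;Eukaryota;Metazoa;Ecdysozoa;Arthropoda;Insecta;Drosophila melanogaster"),
        ("6239", "cellular organisms;Eukaryota;Metazoa;Ecdysozoa;Nematoda;Caenorhabditis elegans"),
        ("7668", "cellular organisms;Eukaryota;Metazoa;Echinodermata;Strongylocentrotus purpuratus"),
    ),
    5: (
        ("4932", "cellular organisms;Eukaryota;Fungi;Saccharomycetes;Saccharomyces cerevisiae"),
        ("3702", "cellular organisms;Eukaryota;Viridiplantae;Streptophyta;Arabidopsis thaliana"),
        ("562", "cellular organisms;Bacteria;Proteobacteria;Escherichia coli"),
    ),
}

#: One representative lineage per category, for sanity checks and docs.
REFERENCE_LINEAGES = {
    "human": TAXON_POOL[1][0][1].split(";"),
    "mouse": TAXON_POOL[2][0][1].split(";"),
    "zebrafish": TAXON_POOL[3][0][1].split(";"),
    "fruit fly": TAXON_POOL[4][0][1].split(";"),
    "yeast": TAXON_POOL[5][0][1].split(";"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the generator; defaults are the package's study conditions.

    ``substitution_rate_per_category`` must be non-decreasing with the
    category level — conservation decays with evolutionary distance.
    ``conserved_depth_for_damaging`` is the minimum number of shallow blocks
    a damaging variant's position must be perfectly conserved through.
    ``truncation_fraction`` makes that share of hits cover only a random
    sub-interval of the query, exercising the partial-coverage paths.
    """

    query_length: int = 200
    hits_per_category: tuple[int, int, int, int, int] = (10, 10, 10, 10, 10)
    n_paralogs: int = 3
    substitution_rate_per_category: tuple[float, float, float, float, float] = (
        0.01, 0.05, 0.15, 0.30, 0.45,
    )
    paralog_rate: float = 0.60
    damaging_fraction: float = 0.5
    conserved_depth_for_damaging: int = 3
    truncation_fraction: float = 0.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.query_length < 10:
            raise ValueError("query_length must be >= 10")
        if len(self.hits_per_category) != 5 or any(
            c < 0 for c in self.hits_per_category
        ):
            raise ValueError("hits_per_category must be five counts >= 0")
        rates = self.substitution_rate_per_category
        if len(rates) != 5 or any(not 0 <= r <= 1 for r in rates):
            raise ValueError("need five substitution rates in [0,1]")
        if any(a > b for a, b in zip(rates, rates[1:])):
            raise ValueError("substitution rates must be non-decreasing")
        if not 0 <= self.damaging_fraction <= 1:
            raise ValueError("damaging_fraction must be in [0,1]")
        if not 1 <= self.conserved_depth_for_damaging <= 5:
            raise ValueError("conserved_depth_for_damaging must be 1..5")
        if self.n_paralogs < 0:
            raise ValueError("n_paralogs must be >= 0")
        if not 0 <= self.truncation_fraction <= 1:
            raise ValueError("truncation_fraction must be in [0,1]")


@dataclass
class ProteinFixture:
    """One protein's simulated query, hits, lineages and planted variants."""

    protein_id: str
    query_seq: str
    hits: list[BlastHitRecord]
    lineages: dict[str, list[str]]
    variants: list[VariantQuery]
    msa: StackedMSA
    part: BlockPartition


@dataclass
class DatasetFixture:
    proteins: dict[str, ProteinFixture]
    spec: FixtureSpec

    @property
    def variants(self) -> list[VariantQuery]:
        return [v for p in self.proteins.values() for v in p.variants]

    @property
    def msas(self) -> dict[str, StackedMSA]:
        return {pid: p.msa for pid, p in self.proteins.items()}

    @property
    def partitions(self) -> dict[str, BlockPartition]:
        return {pid: p.part for pid, p in self.proteins.items()}

    @property
    def lineages(self) -> dict[str, list[str]]:
        merged: dict[str, list[str]] = {}
        for p in self.proteins.values():
            merged.update(p.lineages)
        return merged


def _mutate(query: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(query)
    for i, aa in enumerate(chars):
        if rng.random() < rate:
            alternatives = AMINO_ACIDS.replace(aa, "")
            chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _pairwise_raw(a: str, b: str) -> float:
    return float(sum(blosum62_score(x, y) for x, y in zip(a, b)))


def _make_hit(
    protein_id: str,
    hit_id: str,
    query: str,
    seq: str,
    taxid: str,
    rng: np.random.Generator,
    truncate: bool,
) -> BlastHitRecord:
    L = len(query)
    qstart, qend = 1, L
    if truncate:
        span = int(rng.integers(L // 2, L))  # at least half the query
        qstart = int(rng.integers(1, L - span + 1))
        qend = qstart + span - 1
    q_sub = query[qstart - 1 : qend]
    s_sub = seq[qstart - 1 : qend]
    return BlastHitRecord(
        hit_id=hit_id,
        raw_score=_pairwise_raw(q_sub, s_sub),
        e_value=1e-30,
        query_start=qstart,
        query_end=qend,
        subject_start=1,
        subject_end=qend - qstart + 1,
        aligned_query=q_sub,
        aligned_hit=s_sub,
        organism_taxid=taxid,
    )


def _plant_variants(
    fixture_query: str,
    part: BlockPartition,
    n_variants: int,
    damaging_fraction: float,
    depth: int,
    rng: np.random.Generator,
    protein_id: str,
) -> list[VariantQuery]:
    L = len(fixture_query)
    all_hits = [h for label in part.blocks for h in part.blocks[label]]
    lcb = [lowest_conserved_block(part, p, fixture_query[p]) for p in range(L)]

    damaging_pool, neutral_pool, fallback_pool = [], [], []
    for p in range(L):
        ref = fixture_query[p]
        b1_counts, b1_n = column_counts(part.blocks["B1"], p)
        whole_counts, _ = column_counts(all_hits, p)
        if lcb[p] >= depth:
            shallow = set()
            for label in ORTHOLOG_BLOCKS[:depth]:
                shallow |= set(column_counts(part.blocks[label], p)[0])
            absent = [aa for aa in AMINO_ACIDS if aa != ref and aa not in shallow]
            if absent:
                damaging_pool.append((p, absent))
        elif any(aa != ref for aa in b1_counts):
            neutral_pool.append((p, sorted(aa for aa in b1_counts if aa != ref)))
        elif any(aa != ref for aa in whole_counts):
            fallback_pool.append((p, sorted(aa for aa in whole_counts if aa != ref)))

    n_damaging = round(n_variants * damaging_fraction)
    n_neutral = n_variants - n_damaging
    if len(damaging_pool) < n_damaging:
        raise ValueError(
            f"{protein_id}: only {len(damaging_pool)} positions conserved "
            f"through {depth} blocks; cannot plant {n_damaging} damaging "
            "variants (increase query_length or lower the depth)"
        )
    # Neutral variants prefer primate-polymorphic positions; if the protein
    # happens to have too few, fall back to shallowly conserved positions
    # whose column elsewhere carries an alternative residue.
    if len(neutral_pool) + len(fallback_pool) < n_neutral:
        raise ValueError(
            f"{protein_id}: not enough polymorphic positions for "
            f"{n_neutral} neutral variants"
        )

    def sample(pool, n):
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(int(j) for j in idx)]

    chosen = []
    for p, alts in sample(damaging_pool, n_damaging):
        mut = alts[int(rng.integers(len(alts)))]
        chosen.append(
            VariantQuery(protein_id, p + 1, fixture_query[p], mut, "damaging")
        )
    n_primary = min(n_neutral, len(neutral_pool))
    picks = sample(neutral_pool, n_primary)
    if n_neutral > n_primary:
        picks += sample(fallback_pool, n_neutral - n_primary)
    for p, alts in picks:
        mut = alts[int(rng.integers(len(alts)))]
        chosen.append(
            VariantQuery(protein_id, p + 1, fixture_query[p], mut, "neutral")
        )
    order = rng.permutation(len(chosen))
    return [chosen[int(i)] for i in order]


def generate_fixture(
    spec: FixtureSpec,
    n_variants: int = 10,
    protein_id: str = "SYN00001",
    rng: Optional[np.random.Generator] = None,
) -> ProteinFixture:
    """Simulate one protein: query, category-graded hits, paralogs, variants."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    query = "".join(
        AMINO_ACIDS[int(i)]
        for i in rng.integers(len(AMINO_ACIDS), size=spec.query_length)
    )
    lineages: dict[str, list[str]] = {}
    hits: list[BlastHitRecord] = []

    # Ortholog hits: each is mutated at its generation category's rate, but
    # the source-organism labels are assigned by NAS rank afterwards, so that
    # NAS is monotone in evolutionary distance — the idealized ortholog
    # regime the block structure presumes. Without this, the tails of
    # adjacent categories' NAS distributions interleave and true orthologs
    # get relocated as paralogs.
    draft: list[BlastHitRecord] = []
    j = 0
    for level in range(1, 6):
        count = spec.hits_per_category[level - 1]
        rate = spec.substitution_rate_per_category[level - 1]
        for _ in range(count):
            truncate = rng.random() < spec.truncation_fraction
            draft.append(
                _make_hit(
                    protein_id,
                    f"{protein_id}_H{j:03d}",
                    query,
                    _mutate(query, rate, rng),
                    "0",  # taxid assigned below
                    rng,
                    truncate,
                )
            )
            j += 1
    denom = float(sum(blosum62_score(aa, aa) for aa in query))
    draft.sort(
        key=lambda h: (-min(1.0, max(0.0, h.raw_score / denom)), h.hit_id)
    )
    rank = 0
    for level in range(1, 6):
        pool = TAXON_POOL[level]
        for _ in range(spec.hits_per_category[level - 1]):
            taxid, lineage = pool[int(rng.integers(len(pool)))]
            lineages[taxid] = lineage.split(";")
            hits.append(dataclasses.replace(draft[rank], organism_taxid=taxid))
            rank += 1

    primate_pool = TAXON_POOL[1]
    for k in range(spec.n_paralogs):
        taxid, lineage = primate_pool[int(rng.integers(len(primate_pool)))]
        lineages[taxid] = lineage.split(";")
        hits.append(
            _make_hit(
                protein_id,
                f"{protein_id}_P{k:02d}",
                query,
                _mutate(query, spec.paralog_rate, rng),
                taxid,
                rng,
                truncate=False,
            )
        )
    categories = {taxid: categorize(lin) for taxid, lin in lineages.items()}
    msa = stack(protein_id, query, hits, categories)
    part = partition(msa)
    variants = _plant_variants(
        query,
        part,
        n_variants,
        spec.damaging_fraction,
        spec.conserved_depth_for_damaging,
        rng,
        protein_id,
    )
    return ProteinFixture(
        protein_id=protein_id,
        query_seq=query,
        hits=hits,
        lineages=lineages,
        variants=variants,
        msa=msa,
        part=part,
    )


def generate_dataset(
    spec: FixtureSpec,
    n_proteins: int = 50,
    variants_per_protein: int = 10,
) -> DatasetFixture:
    """Simulate a labeled multi-protein dataset (default 50 x 10 variants)."""
    seeds = np.random.SeedSequence(spec.seed).spawn(n_proteins)
    proteins = {}
    for i, ss in enumerate(seeds):
        pid = f"SYN{i + 1:05d}"
        proteins[pid] = generate_fixture(
            spec,
            n_variants=variants_per_protein,
            protein_id=pid,
            rng=np.random.default_rng(ss),
        )
    return DatasetFixture(proteins=proteins, spec=spec)


def write_fixture(dataset: DatasetFixture, out_dir: str | os.PathLike) -> None:
    """Write the four-file fixture layout the CLI consumes.

    Per protein: ``<id>.fasta`` (query) and ``<id>.hits.tsv``; shared:
    ``lineage.tsv`` and ``variants.tsv``.
    """
    os.makedirs(out_dir, exist_ok=True)
    for pid, prot in dataset.proteins.items():
        with open(os.path.join(out_dir, f"{pid}.fasta"), "w") as fh:
            fh.write(f">{pid} synthetic query\n{prot.query_seq}\n")
        with open(os.path.join(out_dir, f"{pid}.hits.tsv"), "w") as fh:
            for h in prot.hits:
                fh.write(
                    "\t".join(
                        [
                            pid, h.hit_id, repr(h.e_value), repr(h.raw_score),
                            str(h.query_start), str(h.query_end),
                            str(h.subject_start), str(h.subject_end),
                            h.aligned_query, h.aligned_hit, h.organism_taxid,
                        ]
                    )
                    + "\n"
                )
    with open(os.path.join(out_dir, "lineage.tsv"), "w") as fh:
        for taxid, lineage in sorted(dataset.lineages.items()):
            fh.write(f"{taxid}\t{';'.join(lineage)}\n")
    write_variant_table(os.path.join(out_dir, "variants.tsv"), dataset.variants)


# ---------------------------------------------------------------------------
# Worked example: a 7-hit toy whose every feature value is hand-derivable.
# ---------------------------------------------------------------------------

_WE_QUERY = "MKVAHWSE"
# BLOSUM62 diagonal of the query: M5 K5 V4 A4 H8 W11 S4 E5 -> self score 46.
_WE_SELF = 46.0

# hit_id, taxid, sequence, raw BLOSUM62 score against the query
# (hand sums: substituted positions use the off-diagonal entry).
_WE_HITS: tuple[tuple[str, str, str, float], ...] = (
    ("PRIM1", "9606", "MKVAHWSE", 46.0),  # identical -> NAS 1
    ("PRIM2", "9598", "MKIAHWSE", 45.0),  # V3I: 46-4+B62(V,I)=3
    ("PRIM3", "9593", "MKVAHWTE", 43.0),  # S7T: 46-4+B62(S,T)=1
    ("PRIM4", "9601", "MKVAHWSD", 43.0),  # E8D: 46-5+B62(E,D)=2 (NAS tie w/ PRIM3)
    ("MAM1", "10090", "MRVAHWTE", 40.0),  # K2R(2), S7T(1)
    ("VERT1", "7955", "MRVGHWTE", 36.0),  # K2R(2), A4G(0), S7T(1)
    ("PARA1", "9606", "LRIGYWTD", 23.0),  # heavily diverged human paralog
)

_WE_LINEAGES = {
    "9606": TAXON_POOL[1][0][1].split(";"),
    "9598": TAXON_POOL[1][1][1].split(";"),
    "9593": TAXON_POOL[1][2][1].split(";"),
    "9601": TAXON_POOL[1][3][1].split(";"),
    "10090": TAXON_POOL[2][0][1].split(";"),
    "7955": TAXON_POOL[3][0][1].split(";"),
}

_WE_VARIANTS = (
    # Position 3 V->I: PRIM2 carries I, so the primate block is polymorphic.
    VariantQuery("TOY1", 3, "V", "I", "neutral"),
    # Position 6 W->C: tryptophan conserved in every sequence incl. paralog.
    VariantQuery("TOY1", 6, "W", "C", "damaging"),
)


def _we_expected() -> list[dict[str, float]]:
    """Hand-derived feature expectations for the two worked-example variants.

    NAS order of the stack: PRIM1 (46/46), PRIM2 (45/46), PRIM3 (43/46),
    PRIM4 (43/46, id tie-break after PRIM3), MAM1 (40/46), VERT1 (36/46),
    PARA1 (23/46 = 0.5). Categories down the stack: 1,1,1,1,2,3,1 — block
    starts at PRIM1 (B1), MAM1 (B2), VERT1 (B3); B4/B5 absent; PARA1 is a
    primate inside B3's range, hence relocated to the paralog block.
    """
    def onehot(ref: str, mut: str) -> dict[str, float]:
        d = {f"aa_ref_{aa}": 0.0 for aa in AMINO_ACIDS}
        d.update({f"aa_mut_{aa}": 0.0 for aa in AMINO_ACIDS})
        d[f"aa_ref_{ref}"] = 1.0
        d[f"aa_mut_{mut}"] = 1.0
        return d

    def block(label, f_ref, f_mut, entropy, nas_first, n_all, n_qp):
        return {
            f"{label}_f_ref": f_ref,
            f"{label}_f_mut": f_mut,
            f"{label}_entropy": entropy,
            f"{label}_nas_first": nas_first,
            f"{label}_n_all": float(n_all),
            f"{label}_n_qp": float(n_qp),
            f"{label}_ratio_nn": (n_qp / n_all) if n_all else 0.0,
        }

    empty = lambda label: block(label, 0.0, 0.0, 0.0, 0.0, 0, 0)

    # Variant 1 (pos 3, V->I): B1 column V,I,V,V -> f_ref 3/4, f_mut 1/4,
    # H = -(1/4 log2 1/4 + 3/4 log2 3/4); B2 column V; B3 column V;
    # paralog column I. Primate block polymorphic -> lowest conserved 0.
    v1 = onehot("V", "I")
    h_31 = -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))
    v1.update(block("B1", 0.75, 0.25, h_31, 46 / 46, 4, 4))
    v1.update(block("B2", 1.0, 0.0, 0.0, 40 / 46, 1, 1))
    v1.update(block("B3", 1.0, 0.0, 0.0, 36 / 46, 1, 1))
    v1.update(empty("B4"))
    v1.update(empty("B5"))
    v1.update(block("PARALOG", 0.0, 1.0, 0.0, 23 / 46, 1, 1))
    v1["lowest_conserved_block"] = 0.0

    # Variant 2 (pos 6, W->C): every sequence has W. Empty B4/B5 are
    # vacuously conserved, so conservation extends through block 5.
    v2 = onehot("W", "C")
    v2.update(block("B1", 1.0, 0.0, 0.0, 46 / 46, 4, 4))
    v2.update(block("B2", 1.0, 0.0, 0.0, 40 / 46, 1, 1))
    v2.update(block("B3", 1.0, 0.0, 0.0, 36 / 46, 1, 1))
    v2.update(empty("B4"))
    v2.update(empty("B5"))
    v2.update(block("PARALOG", 1.0, 0.0, 0.0, 23 / 46, 1, 1))
    v2["lowest_conserved_block"] = 5.0
    return [v1, v2]


@dataclass
class WorkedExample:
    """Tiny bundled fixture with exact expected feature values."""

    query_id: str
    query_seq: str
    hits: list[BlastHitRecord]
    lineages: dict[str, list[str]]
    variants: list[VariantQuery]
    expected_features: list[dict[str, float]]

    def build(self) -> tuple[StackedMSA, BlockPartition]:
        categories = {t: categorize(l) for t, l in self.lineages.items()}
        msa = stack(self.query_id, self.query_seq, self.hits, categories)
        return msa, partition(msa)


def worked_example() -> WorkedExample:
    """The bundled 7-hit toy: 4 primates, mouse, zebrafish, human paralog."""
    L = len(_WE_QUERY)
    hits = [
        BlastHitRecord(
            hit_id=hid,
            raw_score=raw,
            e_value=1e-20,
            query_start=1,
            query_end=L,
            subject_start=1,
            subject_end=L,
            aligned_query=_WE_QUERY,
            aligned_hit=seq,
            organism_taxid=taxid,
        )
        for hid, taxid, seq, raw in _WE_HITS
    ]
    return WorkedExample(
        query_id="TOY1",
        query_seq=_WE_QUERY,
        hits=hits,
        lineages=dict(_WE_LINEAGES),
        variants=list(_WE_VARIANTS),
        expected_features=_we_expected(),
    )
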