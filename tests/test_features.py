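import math
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from blockvep.blocking import ORTHOLOG_BLOCKS, partition
from blockvep.features import (
    BLOCKWISE,
    SINGLE_BLOCK,
    build_feature_vector,
    column_counts,
    feature_schema,
    frequencies,
    lowest_conserved_block,
    shannon_entropy,
)
from blockvep.io import AMINO_ACIDS, VariantQuery
from blockvep.msa import HomologHit, StackedMSA
from blockvep.taxonomy import SpeciesCategory

from test_blocking import make_msa


def hit(hit_id, row, category=1, nas=0.9, covered=None):
    return HomologHit(
        hit_id=hit_id, nas=nas, category=SpeciesCategory(category),
        covered=covered or (0, len(row)), row=row,
    )


class TestColumnCounts:
    def test_simple_column(self):
        block = [hit(f"H{i}", r) for i, r in enumerate(["A", "A", "A", "V"])]
        counts, n_qp = column_counts(block, 0)
        assert counts == {"A": 3, "V": 1} and n_qp == 4

    def test_noncovering_hit_excluded(self):
        block = [hit("H0", "AK"), hit("H1", "AK"),
                 hit("H2", "-K", covered=(1, 2))]
        counts, n_qp = column_counts(block, 0)
        assert n_qp == 2

    def test_empty_block(self):
        assert column_counts([], 0) == (Counter(), 0)

    def test_ambiguity_codes_not_counted(self):
        block = [hit("H0", "A"), hit("H1", "X"), hit("H2", "B")]
        counts, n_qp = column_counts(block, 0)
        assert counts == {"A": 1} and n_qp == 1


class TestFrequencies:
    def test_three_of_four(self):
        assert frequencies({"A": 3, "V": 1}, 4, "A", "V") == (0.75, 0.25)

    def test_perfect_conservation(self):
        assert frequencies({"R": 7}, 7, "R", "H") == (1.0, 0.0)

    def test_empty_column(self):
        assert frequencies({}, 0, "A", "V") == (0.0, 0.0)


class TestShannonEntropy:
    def test_uniform_twenty(self):
        counts = {aa: 1 for aa in AMINO_ACIDS}
        assert round(shannon_entropy(counts, 20), 3) == 4.322

    def test_single_residue(self):
        assert shannon_entropy({"W": 9}, 9) == 0.0

    def test_two_equiprobable(self):
        assert shannon_entropy({"A": 1, "V": 1}, 2) == 1.0

    def test_empty_column(self):
        assert shannon_entropy({}, 0) == 0.0

    @given(st.dictionaries(st.sampled_from(AMINO_ACIDS),
                           st.integers(min_value=1, max_value=50),
                           min_size=1, max_size=20))
    def test_bounds_and_duplication_invariance(self, counts):
        n = sum(counts.values())
        h = shannon_entropy(counts, n)
        assert 0.0 <= h <= math.log2(20) + 1e-12
        doubled = {aa: 2 * c for aa, c in counts.items()}
        assert shannon_entropy(doubled, 2 * n) == pytest.approx(h)


@given(st.lists(st.sampled_from(AMINO_ACIDS), min_size=1, max_size=40))
def test_column_distribution_sums_to_one(residues):
    block = [hit(f"H{i}", aa) for i, aa in enumerate(residues)]
    counts, n_qp = column_counts(block, 0)
    assert n_qp == len(residues)
    assert sum(c / n_qp for c in counts.values()) == pytest.approx(1.0)


class TestLowestConservedBlock:
    def _partition(self, block_rows):
        """Build a partition whose block k holds hits with given residues."""
        cats, rows = [], []
        for level, residues in enumerate(block_rows, start=1):
            for aa in residues:
                cats.append(level)
                rows.append(aa)
        msa = make_msa(cats)
        hits = tuple(
            HomologHit(h.hit_id, h.nas, h.category, (0, 1), rows[i])
            for i, h in enumerate(msa.hits)
        )
        return partition(StackedMSA("Q1", "M", hits))

    def test_violation_in_third_block(self):
        part = self._partition(["RR", "R", "RV"])
        assert lowest_conserved_block(part, 0, "R") == 2

    def test_all_blocks_conserved(self):
        part = self._partition(["R", "R", "R", "R", "R"])
        assert lowest_conserved_block(part, 0, "R") == 5

    def test_primate_violation_gives_zero(self):
        part = self._partition(["V", "R"])
        assert lowest_conserved_block(part, 0, "R") == 0

    def test_empty_block_is_vacuous(self):
        # B2 absent: conservation extends past it to the violating B3.
        part = self._partition(["R", "", "RV"])
        assert lowest_conserved_block(part, 0, "R") == 2

    def test_paralog_block_ignored(self):
        # Paralog (primate ranked among vertebrates) carries V; irrelevant.
        part = partition(make_msa([1, 2, 3, 1]))
        rows = {"H00": "R", "H01": "R", "H02": "R", "H03": "V"}
        hits = tuple(
            HomologHit(h.hit_id, h.nas, h.category, (0, 1), rows[h.hit_id])
            for h in sorted(
                (x for b in part.blocks.values() for x in b),
                key=lambda h: (-h.nas, h.hit_id),
            )
        )
        part2 = partition(StackedMSA("Q1", "R", hits))
        assert [x.hit_id for x in part2.blocks["PARALOG"]] == ["H03"]
        assert lowest_conserved_block(part2, 0, "R") == 5

    def test_never_increases_when_mismatch_added(self):
        base = self._partition(["RR", "R", "R"])
        with_mismatch = self._partition(["RR", "RV", "R"])
        assert (
            lowest_conserved_block(with_mismatch, 0, "R")
            <= lowest_conserved_block(base, 0, "R")
        )


class TestBuildFeatureVector:
    def test_schema_sizes(self):
        assert len(feature_schema(BLOCKWISE)) == 83
        assert len(feature_schema(SINGLE_BLOCK)) == 48

    def test_worked_example_blockwise(self, toy):
        we, msa, part = toy
        for variant, expected in zip(we.variants, we.expected_features):
            vec = build_feature_vector(msa, part, variant)
            assert vec == expected

    def test_exactly_two_onehot_bits(self, toy):
        we, msa, part = toy
        vec = build_feature_vector(msa, part, we.variants[0])
        bits = [k for k, v in vec.items() if k.startswith("aa_") and v == 1.0]
        assert bits == ["aa_ref_V", "aa_mut_I"]

    def test_uncovered_position_all_zero(self):
        h = hit("H0", "MK-", covered=(0, 2))
        msa = StackedMSA("Q1", "MKV", (h,))
        part = partition(msa)
        vec = build_feature_vector(
            msa, part, VariantQuery("Q1", 3, "V", "A")
        )
        for label in ("B1", "B2", "B3", "B4", "B5", "PARALOG"):
            assert vec[f"{label}_f_ref"] == 0.0
            assert vec[f"{label}_entropy"] == 0.0
            assert vec[f"{label}_n_qp"] == 0.0

    def test_single_block_mode_fields(self, toy):
        we, msa, part = toy
        vec = build_feature_vector(msa, part, we.variants[0], mode=SINGLE_BLOCK)
        assert len(vec) == 48
        assert vec["ALL_n_all"] == 7.0
        # Column pos 3 over all 7 rows: V,I,V,V,V,V,I -> 5/7 and 2/7.
        assert vec["ALL_f_ref"] == pytest.approx(5 / 7)
        assert vec["ALL_f_mut"] == pytest.approx(2 / 7)
        assert vec["ALL_nas_first"] == 1.0
        assert vec["lowest_conserved_block"] == 0.0

    def test_position_beyond_query_rejected(self, toy):
        we, msa, part = toy
        with pytest.raises(ValueError, match="beyond"):
            build_feature_vector(msa, part, VariantQuery("TOY1", 99, "V", "I"))

    def test_reference_mismatch_warns_and_proceeds(self, toy):
        we, msa, part = toy
        # Query position 1 is M; claim it is A.
        with pytest.warns(UserWarning, match="differs"):
            vec = build_feature_vector(
                msa, part, VariantQuery("TOY1", 1, "A", "V")
            )
        assert vec["aa_ref_A"] == 1.0

    def test_nas_first_monotone_over_blocks(self, default_fixture):
        part = default_fixture.part
        firsts = [part.blocks[b][0].nas for b in ORTHOLOG_BLOCKS if part.blocks[b]]
        assert all(a >= b for a, b in zip(firsts, firsts[1:]))
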