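import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blockvep.classifier import DAMAGING, NEUTRAL
from blockvep.evaluation import (
    ablation_compare,
    assign_folds,
    confusion_metrics,
    grouped_cv,
    roc_auc,
)
from blockvep.synthetic import FixtureSpec, generate_dataset

D, N = DAMAGING, NEUTRAL


def mann_whitney_auc(scores, labels):
    """Pairwise-comparison oracle: P(damaging scores below neutral)."""
    dmg = [s for s, l in zip(scores, labels) if l == D]
    neu = [s for s, l in zip(scores, labels) if l == N]
    total = 0.0
    for a in dmg:
        for b in neu:
            total += 1.0 if a < b else (0.5 if a == b else 0.0)
    return total / (len(dmg) * len(neu))


class TestConfusionMetrics:
    def test_hand_counted_example(self):
        preds = [D] * 3 + [D] + [N] * 4 + [N] * 2
        labels = [D] * 3 + [N] + [N] * 4 + [D] * 2
        r = confusion_metrics(preds, labels)
        assert (r.tp, r.fp, r.tn, r.fn) == (3, 1, 4, 2)
        assert r.accuracy == pytest.approx(0.7)
        assert r.precision == pytest.approx(0.75)
        assert r.sensitivity == pytest.approx(0.6)
        assert r.specificity == pytest.approx(0.8)

    def test_perfect_predictions(self):
        r = confusion_metrics([D, N, D], [D, N, D])
        assert (r.accuracy, r.precision, r.sensitivity, r.specificity) == (1, 1, 1, 1)
        assert not r.degenerate

    def test_all_neutral_flags_degenerate(self):
        r = confusion_metrics([N, N, N], [D, N, N])
        assert r.precision == 0.0 and r.degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    @given(st.data())
    def test_permutation_invariant(self, data):
        n = data.draw(st.integers(min_value=4, max_value=30))
        labels = [data.draw(st.sampled_from([D, N])) for _ in range(n)]
        preds = [data.draw(st.sampled_from([D, N])) for _ in range(n)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = D, N
        perm = data.draw(st.permutations(range(n)))
        r1 = confusion_metrics(preds, labels)
        r2 = confusion_metrics([preds[i] for i in perm], [labels[i] for i in perm])
        assert (r1.tp, r1.fp, r1.tn, r1.fn) == (r2.tp, r2.fp, r2.tn, r2.fn)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [D, D, N, N])
        assert auc == 1.0

    def test_anti_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [N, N, D, D])
        assert auc == 0.0

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=30)
        labels = [D if rng.random() < 0.5 else N for _ in range(30)]
        labels[0], labels[1] = D, N
        points, _ = roc_auc(scores, labels)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        assert all(a[0] <= b[0] and a[1] <= b[1]
                   for a, b in zip(points, points[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [D, D])

    def test_matches_mann_whitney_with_ties(self):
        rng = np.random.default_rng(7)
        scores = list(rng.choice([0.1, 0.3, 0.3, 0.5, 0.9], size=30))
        labels = [D if rng.random() < 0.4 else N for _ in range(30)]
        labels[0], labels[1] = D, N
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels))

    def test_matches_sklearn_reference(self):
        """Second independent route: sklearn's AUC with damaging ranked by
        descending neutrality score."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = [D if rng.random() < 0.5 else N for _ in range(n)]
            labels[0], labels[1] = D, N
            _, auc = roc_auc(scores, labels)
            y = np.array([1 if l == D else 0 for l in labels])
            assert auc == pytest.approx(roc_auc_score(y, -scores))


class TestAssignFolds:
    def test_each_protein_one_fold(self):
        folds = assign_folds([f"P{i}" for i in range(20)], k=10, seed=3)
        assert set(folds.values()) == set(range(10))
        sizes = [list(folds.values()).count(f) for f in range(10)]
        assert all(s == 2 for s in sizes)

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(13)]
        assert assign_folds(ids, 5, 42) == assign_folds(ids, 5, 42)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            assign_folds(["P1", "P2"], k=3, seed=0)


class TestGroupedCV:
    def test_no_protein_leakage(self, small_dataset):
        result = grouped_cv(
            small_dataset.variants, small_dataset.msas,
            k=4, seed=2, n_trees=50,
            partitions=small_dataset.partitions,
        )
        for f in range(4):
            test_prot = {p for p, ff in result.fold_of_protein.items() if ff == f}
            fold_rows = result.scores[result.scores["fold"] == f]
            assert set(fold_rows["protein_id"]) <= test_prot

    def test_two_proteins_two_folds(self):
        spec = FixtureSpec(query_length=120, hits_per_category=(5,) * 5,
                           n_paralogs=1, seed=3)
        ds = generate_dataset(spec, n_proteins=2, variants_per_protein=8)
        result = grouped_cv(ds.variants, ds.msas, k=2, seed=0, n_trees=40,
                            partitions=ds.partitions)
        assert len(set(result.fold_of_protein.values())) == 2

    def test_same_seed_same_folds(self, small_dataset):
        r1 = grouped_cv(small_dataset.variants, small_dataset.msas, k=4,
                        seed=8, n_trees=20, partitions=small_dataset.partitions)
        r2 = grouped_cv(small_dataset.variants, small_dataset.msas, k=4,
                        seed=8, n_trees=20, partitions=small_dataset.partitions)
        assert r1.fold_of_protein == r2.fold_of_protein
        assert np.array_equal(r1.scores["score"], r2.scores["score"])

    def test_unlabeled_variants_rejected(self, small_dataset):
        import dataclasses

        variants = [dataclasses.replace(small_dataset.variants[0], label=None)]
        with pytest.raises(ValueError, match="label"):
            grouped_cv(variants, small_dataset.msas, k=2, seed=0)


class TestAblation:
    def test_folds_shared_between_modes(self, small_dataset):
        bw, sb = ablation_compare(
            small_dataset.variants, small_dataset.msas, k=4, seed=6, n_trees=40
        )
        assert bw.fold_of_protein == sb.fold_of_protein
        assert bw.mode == "blockwise" and sb.mode == "single_block"

    def test_equal_rates_negative_control(self):
        """With one substitution rate everywhere the block ladder carries no
        extra distance signal, and the two modes score alike."""
        spec = FixtureSpec(substitution_rate_per_category=(0.05,) * 5, seed=5)
        ds = generate_dataset(spec, n_proteins=15, variants_per_protein=10)
        bw, sb = ablation_compare(ds.variants, ds.msas, k=5, seed=5, n_trees=150)
        assert abs(bw.pooled.accuracy - sb.pooled.accuracy) < 0.1
        assert sb.pooled.auc > 0.9  # both arms remain strong classifiers
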