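"""Metrics, ROC/AUC, and protein-grouped cross-validation.

Damaging is the positive class throughout. Because the score is the
probability that a variant is *neutral*, the ROC sweep declares a variant
positive when its score is at or below the moving threshold.

Cross-validation is grouped at the protein level: all variants of one
protein land in the same fold, so no protein contributes to both the
training and the test side of any split — the leakage that per-variant
folds would otherwise introduce through shared alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from . import features as feat
from .blocking import BlockPartition, partition
from .classifier import DAMAGING, NEUTRAL
from .io import VariantQuery
from .msa import StackedMSA


@dataclass
class EvalReport:
    """Confusion metrics plus (optionally) the ROC curve for one score set."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    degenerate: bool = False
    auc: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "degenerate": self.degenerate,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.roc_points is not None:
            d["roc_points"] = [list(p) for p in self.roc_points]
        return d


def confusion_metrics(
    predictions: Sequence[str], labels: Sequence[str]
) -> EvalReport:
    """Accuracy/precision/sensitivity/specificity with damaging positive.

    An undefined ratio (e.g. precision with no positive calls) is reported
    as 0 with ``degenerate=True``.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    y = np.asarray(labels, dtype=object)
    p = np.asarray(predictions, dtype=object)
    if set(y) - {NEUTRAL, DAMAGING} or set(p) - {NEUTRAL, DAMAGING}:
        raise ValueError("labels/predictions must be 'neutral' or 'damaging'")
    if len(set(y)) < 2:
        raise ValueError("labels must contain both classes")
    tp = int(np.sum((p == DAMAGING) & (y == DAMAGING)))
    fp = int(np.sum((p == DAMAGING) & (y == NEUTRAL)))
    tn = int(np.sum((p == NEUTRAL) & (y == NEUTRAL)))
    fn = int(np.sum((p == NEUTRAL) & (y == DAMAGING)))
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / len(y),
        precision=ratio(tp, tp + fp),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        degenerate=degenerate,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC for neutral-probability scores.

    The threshold sweeps the score axis ascending; a variant is called
    damaging (positive) when score <= threshold, so low scores rank as most
    damaging. Equal scores collapse into a single threshold step. Returns
    ``(points, auc)`` with points as (FPR, TPR) from (0,0) to (1,1).
    """
    y = np.asarray(labels, dtype=object)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(y == DAMAGING))
    n_neg = int(np.sum(y == NEUTRAL))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(np.sum(y[i:j] == DAMAGING))
        fp += int(np.sum(y[i:j] == NEUTRAL))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class CVResult:
    """Per-fold and pooled evaluation of a protein-grouped cross-validation."""

    per_fold: list[EvalReport]
    pooled: EvalReport
    fold_of_protein: dict[str, int]
    scores: pd.DataFrame  # protein_id, position, aa_ref, aa_mut, label, score, call, fold
    mode: str

    @property
    def fold_aucs(self) -> list[float]:
        return [r.auc for r in self.per_fold]


def assign_folds(
    protein_ids: Sequence[str], k: int, seed: int
) -> dict[str, int]:
    """Deal proteins round-robin into k folds after a seeded shuffle."""
    uniq = sorted(set(protein_ids))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} proteins for {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(uniq))
    return {pid: i % k for i, pid in enumerate(shuffled)}


def grouped_cv(
    variants: Sequence[VariantQuery],
    msas: Mapping[str, StackedMSA],
    k: int = 10,
    seed: int = 0,
    mode: str = feat.BLOCKWISE,
    n_trees: int = clf.DEFAULT_N_TREES,
    partitions: Optional[Mapping[str, BlockPartition]] = None,
) -> CVResult:
    """k-fold cross-validation grouped by protein.

    Each fold's model is trained on the other folds' variants; its cutoff is
    re-optimized on the training scores before calling the held-out fold.
    The pooled report concatenates all held-out scores and calls.
    """
    if any(v.label is None for v in variants):
        raise ValueError("all variants must be labeled for cross-validation")
    if partitions is None:
        partitions = {pid: partition(m) for pid, m in msas.items()}
    X, info = feat.build_feature_table(msas, partitions, variants, mode=mode)
    folds = assign_folds(info["protein_id"].tolist(), k, seed)
    fold_idx = info["protein_id"].map(folds).to_numpy()

    per_fold: list[EvalReport] = []
    out_rows = []
    for f in range(k):
        test_mask = fold_idx == f
        train_prot = set(info.loc[~test_mask, "protein_id"])
        test_prot = set(info.loc[test_mask, "protein_id"])
        assert not (train_prot & test_prot), "protein leaked across the split"
        model = clf.train(
            X.loc[~test_mask], info.loc[~test_mask, "label"].tolist(),
            n_trees=n_trees, seed=seed, mode=mode,
        )
        cutoff = clf.optimize_cutoff(
            clf.score_many(model, X.loc[~test_mask]),
            info.loc[~test_mask, "label"].tolist(),
        )
        s = clf.score_many(model, X.loc[test_mask])
        y = info.loc[test_mask, "label"].tolist()
        calls = [DAMAGING if v < cutoff else NEUTRAL for v in s]
        report = confusion_metrics(calls, y)
        report.roc_points, report.auc = roc_auc(s, y)
        per_fold.append(report)
        sub = info.loc[test_mask, ["protein_id", "position", "aa_ref", "aa_mut", "label"]].copy()
        sub["score"] = s
        sub["call"] = calls
        sub["fold"] = f
        out_rows.append(sub)

    scores = pd.concat(out_rows, ignore_index=True)
    pooled = confusion_metrics(scores["call"].tolist(), scores["label"].tolist())
    pooled.roc_points, pooled.auc = roc_auc(
        scores["score"].to_numpy(), scores["label"].tolist()
    )
    return CVResult(
        per_fold=per_fold,
        pooled=pooled,
        fold_of_protein=folds,
        scores=scores,
        mode=mode,
    )


def ablation_compare(
    variants: Sequence[VariantQuery],
    msas: Mapping[str, StackedMSA],
    k: int = 10,
    seed: int = 0,
    n_trees: int = clf.DEFAULT_N_TREES,
) -> tuple[CVResult, CVResult]:
    """Blockwise vs single-block cross-validation on identical folds.

    The single-block arm removes the block structure and treats the whole
    MSA as one block; everything else (folds, seed, forest size) is shared,
    so the comparison isolates the value of block-wise conservation.
    """
    blockwise = grouped_cv(
        variants, msas, k=k, seed=seed, mode=feat.BLOCKWISE, n_trees=n_trees
    )
    single = grouped_cv(
        variants, msas, k=k, seed=seed, mode=feat.SINGLE_BLOCK, n_trees=n_trees
    )
    assert blockwise.fold_of_protein == single.fold_of_protein
    return blockwise, single
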