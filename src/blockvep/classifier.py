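"""Random-forest scoring of amino acid substitutions.

A forest of classification trees is trained on labeled feature vectors; a
variant's score is the fraction of trees voting "neutral", so 0 is the most
confidently damaging and 1 the most confidently neutral. The call is made
against a cutoff: a variant is predicted damaging when its score is strictly
below the cutoff (published operating points are 0.6 for a broad
disease-variant training set and 0.28 for a Mendelian-only one; the cutoff
here is re-optimized on whatever the model is trained on).

Hyperparameters follow the long-standing random-forest defaults the method
family uses: 500 trees, sqrt(p) candidate features per split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

NEUTRAL = "neutral"
DAMAGING = "damaging"

DEFAULT_N_TREES = 500


@dataclass(frozen=True)
class TrainedModel:
    """A fitted forest plus everything needed to apply it reproducibly."""

    forest: RandomForestClassifier
    cutoff: float
    schema: tuple[str, ...]
    seed: int
    mode: str

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError(f"cutoff must be in (0,1), got {self.cutoff}")


@dataclass(frozen=True)
class Prediction:
    score: float
    call: str


def _check_labels(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    bad = set(arr) - {NEUTRAL, DAMAGING}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    if len(set(arr)) < 2:
        raise ValueError("training data must contain both classes")
    return arr


def train(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    mode: str = "blockwise",
) -> TrainedModel:
    """Fit the forest; the cutoff starts at 0.5 until explicitly optimized."""
    y = _check_labels(labels)
    if len(y) != len(features):
        raise ValueError("features and labels differ in length")
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(features.to_numpy(dtype=float), y)
    return TrainedModel(
        forest=forest,
        cutoff=0.5,
        schema=tuple(features.columns),
        seed=seed,
        mode=mode,
    )


def _check_schema(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    got = tuple(features.columns)
    if got != model.schema:
        missing = [c for c in model.schema if c not in got]
        extra = [c for c in got if c not in model.schema]
        raise ValueError(
            f"feature columns do not match the model schema; "
            f"missing={missing}, extra={extra}"
        )
    return features.to_numpy(dtype=float)


def score_many(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Vote-fraction scores (probability neutral) for each row.

    The score is the fraction of individual trees whose own majority vote
    at the row's leaf is "neutral" — the ensemble's literal majority-vote
    semantics, not the mean of leaf class probabilities.
    """
    X = _check_schema(model, features)
    # Sub-estimators of a fitted forest predict encoded class indices.
    neutral_idx = list(model.forest.classes_).index(NEUTRAL)
    votes = np.zeros(len(X), dtype=float)
    for tree in model.forest.estimators_:
        votes += tree.predict(X) == neutral_idx
    return votes / len(model.forest.estimators_)


def score(model: TrainedModel, feature_vector: dict[str, float]) -> float:
    """Score one variant from its feature mapping."""
    row = pd.DataFrame([feature_vector], columns=list(model.schema))
    if set(feature_vector) != set(model.schema):
        missing = [c for c in model.schema if c not in feature_vector]
        extra = [c for c in feature_vector if c not in model.schema]
        raise ValueError(
            f"feature vector does not match the model schema; "
            f"missing={missing}, extra={extra}"
        )
    return float(score_many(model, row)[0])


def predict(model: TrainedModel, feature_vector: dict[str, float]) -> Prediction:
    """Score and call one variant: damaging iff score < cutoff."""
    s = score(model, feature_vector)
    return Prediction(score=s, call=DAMAGING if s < model.cutoff else NEUTRAL)


def optimize_cutoff(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Threshold with the lowest misclassification rate.

    Candidates are 0, 1 and the midpoints of adjacent sorted unique scores;
    a variant is called damaging when its score is strictly below the
    threshold. Ties in error count are broken toward the smallest threshold.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    uniq = np.unique(s)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    dmg = y == DAMAGING
    best_c, best_err = None, None
    for c in candidates:
        called_dmg = s < c
        err = int(np.sum(called_dmg != dmg))
        if best_err is None or err < best_err:
            best_c, best_err = float(c), err
    return best_c


def with_cutoff(model: TrainedModel, cutoff: float) -> TrainedModel:
    """Copy of the model with a new operating cutoff."""
    return replace(model, cutoff=cutoff)


def save_model(model: TrainedModel, path) -> None:
    """Persist the model (forest, cutoff, schema, seed, mode) to one file."""
    joblib.dump(
        {
            "forest": model.forest,
            "cutoff": model.cutoff,
            "schema": list(model.schema),
            "seed": model.seed,
            "mode": model.mode,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        forest=payload["forest"],
        cutoff=payload["cutoff"],
        schema=tuple(payload["schema"]),
        seed=payload["seed"],
        mode=payload["mode"],
    )
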