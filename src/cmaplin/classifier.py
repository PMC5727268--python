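"""Healthy/injured classification of fitted nerve-model parameters.

Each nerve condition contributes one point (a, b) in parameter space.  The
initial and lightest-injury (damage1) conditions count as *healthy*; the two
severe conditions (damage2, damage3) count as *injured*.  A linear-kernel
soft-margin SVM trained on these points yields the intervention criterion: a
straight decision line in the (a, b) plane.

The transfer experiment mirrors the intended clinical use: the boundary is
learned from baseline-normalized data (which needs a pre-injury recording)
and then applied to per-trial-normalized data (which does not), condition by
condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .nerve_model import CmapMatrix, LinearNerveModel, fit_condition

__all__ = [
    "HEALTHY",
    "INJURED",
    "ModelPoint",
    "SplitConfig",
    "DecisionBoundary",
    "EvaluationResult",
    "label_points",
    "split_data",
    "train_svm",
    "classify",
    "evaluate",
    "points_from_matrices",
    "cross_normalization_eval",
]

HEALTHY = "healthy"
INJURED = "injured"

#: Damage levels considered still-functional for the intervention criterion.
HEALTHY_CONDITIONS = frozenset({0, 1})


@dataclass(frozen=True)
class ModelPoint:
    """An (a, b) parameter pair with its condition and ground-truth label."""

    a: float
    b: float
    condition_index: int
    label: str
    mode: str = "per_trial"
    subject_id: str = "subject"


@dataclass(frozen=True)
class SplitConfig:
    """Train/test partition settings (70/30 stratified by default)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class DecisionBoundary:
    """Linear separator w_a * a + w_b * b + bias = 0 in parameter space.

    The positive side is the injured side; a point exactly on the line is
    called healthy (the conservative tie rule: the intervention alarm fires
    only on strictly positive evidence of injury).
    """

    weights: tuple
    bias: float
    kernel: str = "linear"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = tuple(float(v) for v in self.weights)
        object.__setattr__(self, "weights", w)
        if all(v == 0 for v in w):
            raise ValueError("degenerate boundary: all weights zero")

    def decision_value(self, a: float, b: float) -> float:
        return self.weights[0] * a + self.weights[1] * b + self.bias


@dataclass
class EvaluationResult:
    """Classification accuracy, overall and per nerve condition (percent)."""

    accuracy: float
    per_condition: Dict[int, float]
    n: int

    def rounded(self, ndigits: int = 1) -> "EvaluationResult":
        return EvaluationResult(
            accuracy=round(self.accuracy, ndigits),
            per_condition={k: round(v, ndigits) for k, v in self.per_condition.items()},
            n=self.n,
        )


def condition_label(condition_index: int) -> str:
    if condition_index in HEALTHY_CONDITIONS:
        return HEALTHY
    if condition_index in (2, 3):
        return INJURED
    raise ValueError(f"unknown condition index {condition_index}")


def label_points(models: Iterable[LinearNerveModel]) -> List[ModelPoint]:
    """Attach healthy/injured labels to fitted models by damage level."""
    return [
        ModelPoint(
            a=m.a,
            b=m.b,
            condition_index=m.condition_index,
            label=condition_label(m.condition_index),
            mode=m.mode,
            subject_id=m.subject_id,
        )
        for m in models
    ]


def split_data(
    points: Sequence[ModelPoint], cfg: SplitConfig
) -> Tuple[List[ModelPoint], List[ModelPoint]]:
    """Deterministic train/test partition; train size = floor(fraction * N)."""
    points = list(points)
    n_train = int(np.floor(cfg.train_fraction * len(points)))
    if n_train < 1 or n_train >= len(points):
        raise ValueError("split leaves an empty train or test set")
    labels = [p.label for p in points]
    if cfg.stratified:
        for lab in set(labels):
            if labels.count(lab) < 2:
                raise ValueError(
                    f"cannot stratify: fewer than 2 points labeled {lab!r}"
                )
    idx = np.arange(len(points))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=n_train,
        random_state=cfg.seed,
        shuffle=True,
        stratify=labels if cfg.stratified else None,
    )
    return [points[i] for i in train_idx], [points[i] for i in test_idx]


def train_svm(train: Sequence[ModelPoint], C: float = 1.0) -> DecisionBoundary:
    """Fit the linear-kernel soft-margin SVM on (a, b) features.

    No feature standardization is applied by default (the boundary lives in
    the same coordinates as the parameter scatter); standardize upstream if
    a and b scales differ wildly.
    """
    train = list(train)
    X = np.array([[p.a, p.b] for p in train])
    y = np.array([p.label for p in train])
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    # classes_ is sorted alphabetically: ['healthy', 'injured'], so the
    # positive decision side is already the injured side
    w = svc.coef_[0]
    return DecisionBoundary(
        weights=(float(w[0]), float(w[1])),
        bias=float(svc.intercept_[0]),
        training_meta={"n_train": len(train), "C": C},
    )


def classify(
    boundary: DecisionBoundary, points: Sequence[ModelPoint]
) -> List[str]:
    """Predict labels; ties (decision value exactly 0) resolve to healthy."""
    return [
        INJURED if boundary.decision_value(p.a, p.b) > 0 else HEALTHY
        for p in points
    ]


def evaluate(
    predicted: Sequence[str], points: Sequence[ModelPoint]
) -> EvaluationResult:
    """Percent accuracy against ground-truth labels, with a per-condition map."""
    if len(predicted) != len(points):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions for {len(points)} points"
        )
    if len(points) == 0:
        raise ValueError("nothing to evaluate")
    hits = [pred == p.label for pred, p in zip(predicted, points)]
    per_condition: Dict[int, float] = {}
    for cond in sorted({p.condition_index for p in points}):
        sel = [h for h, p in zip(hits, points) if p.condition_index == cond]
        per_condition[cond] = 100.0 * sum(sel) / len(sel)
    return EvaluationResult(
        accuracy=100.0 * sum(hits) / len(hits),
        per_condition=per_condition,
        n=len(points),
    )


def points_from_matrices(
    matrices: Sequence[CmapMatrix], mode: str
) -> List[ModelPoint]:
    """Fit every (subject, condition) under one normalization and label it."""
    models = [
        fit_condition(m, cond, mode)
        for m in matrices
        for cond in range(m.n_conditions)
    ]
    return label_points(models)


def cross_normalization_eval(
    matrices: Sequence[CmapMatrix], cfg: SplitConfig, C: float = 1.0
) -> dict:
    """Train on baseline-normalized data, test the transfer to per-trial data.

    Returns a report with the within-mode test accuracy (baseline mode,
    held-out split) and the per-condition transfer accuracy obtained by
    applying the same boundary to the per-trial-normalized points of all
    subjects.
    """
    base_points = points_from_matrices(matrices, "baseline")
    trial_points = points_from_matrices(matrices, "per_trial")
    train, test = split_data(base_points, cfg)
    boundary = train_svm(train, C=C)
    within = evaluate(classify(boundary, test), test)
    transfer = evaluate(classify(boundary, trial_points), trial_points)
    return {
        "mode_train": "baseline",
        "mode_eval": "per_trial",
        "seed": cfg.seed,
        "n_train": len(train),
        "n_test": len(test),
        "boundary": {
            "w_a": boundary.weights[0],
            "w_b": boundary.weights[1],
            "bias": boundary.bias,
        },
        "baseline_test_accuracy": within.accuracy,
        "transfer_overall_accuracy": transfer.accuracy,
        "transfer_per_condition": transfer.per_condition,
    }
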