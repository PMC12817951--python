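"""Accuracy / macro-F1 scoring and the two experiment designs: inverted
stratified cross-validation (the small fold is the labeled set) and the
labeled-fraction sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, LabeledSet, UnlabeledSet, encode_labels
from .preprocess import split_by_label_fraction

__all__ = ["EvaluationReport", "score", "stratified_cv", "label_fraction_sweep"]

# runner signature shared by both experiment designs: given a labeled set,
# the unlabeled complement and a seed, return predicted 0-based codes for
# the unlabeled cells.
Runner = Callable[[LabeledSet, UnlabeledSet, int], np.ndarray]


@dataclass
class EvaluationReport:
    accuracy: float  # percentage
    macro_f1: float  # percentage
    per_class_f1: np.ndarray  # fractions, length C
    confusion: np.ndarray  # C x C counts, rows = truth
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": [float(v) for v in self.per_class_f1],
            "confusion": self.confusion.tolist(),
            "n_cells": self.n_cells,
        }


def reports_to_frame(
    reports: Sequence[EvaluationReport], **constants
) -> pd.DataFrame:
    """Flat table (one row per fold/run) for TSV export; ``constants`` adds
    identifying columns such as method or fixture name."""
    rows = [
        {**constants, "fold": i, "accuracy": r.accuracy, "macro_f1": r.macro_f1}
        for i, r in enumerate(reports)
    ]
    return pd.DataFrame(rows)


def score(
    truth: np.ndarray, predicted: np.ndarray, n_classes: int | None = None
) -> EvaluationReport:
    """Accuracy (%) and macro-F1 (%) from 0-based class code vectors.

    Per-class F1 = 2PR/(P+R), defined as 0 when P+R is 0; macro-F1 is the
    unweighted mean over all C classes.
    """
    truth = np.asarray(truth, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {truth.shape} truth vs {predicted.shape} predicted"
        )
    n = len(truth)
    if n == 0:
        raise ValueError("cannot score an empty vector")
    c = int(n_classes or max(truth.max(), predicted.max()) + 1)
    if truth.min() < 0 or predicted.min() < 0 or max(truth.max(), predicted.max()) >= c:
        raise ValueError(f"class codes must lie in [0, {c})")
    confusion = np.zeros((c, c), dtype=np.int64)
    np.add.at(confusion, (truth, predicted), 1)
    correct = np.diag(confusion).astype(np.float64)
    pred_tot = confusion.sum(axis=0).astype(np.float64)
    true_tot = confusion.sum(axis=1).astype(np.float64)
    per_class_f1 = np.zeros(c)
    denom = pred_tot + true_tot  # == (P+R) scaled; 2TP / (pred+true)
    nz = denom > 0
    per_class_f1[nz] = 2.0 * correct[nz] / denom[nz]
    undefined = ~nz
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} class(es) absent from both truth and "
            "prediction; their F1 counts as 0"
        )
    return EvaluationReport(
        accuracy=100.0 * float(correct.sum()) / n,
        macro_f1=100.0 * float(per_class_f1.mean()),
        per_class_f1=per_class_f1,
        confusion=confusion,
        n_cells=n,
    )


def _stratified_folds(
    codes: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Disjoint folds preserving per-class proportions: each class is
    shuffled and dealt round-robin across folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(codes):
        members = rng.permutation(np.flatnonzero(codes == cls))
        for f in range(n_folds):
            folds[f].extend(members[f::n_folds])
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def stratified_cv(
    matrix: ExpressionMatrix,
    labels: Sequence,
    runner: Runner,
    n_folds: int = 10,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> tuple[list[EvaluationReport], float, float]:
    """Inverted stratified CV: each fold in turn is the LABELED set and the
    remaining folds are the unlabeled cells being annotated and scored.

    Returns (per-fold reports, mean accuracy, standard error sd/sqrt(k)).
    """
    codes, names = encode_labels(labels, class_names)
    min_class = int(np.bincount(codes).min())
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} cells < {n_folds} folds; "
            f"reducing to {min_class} folds"
        )
        n_folds = min_class
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(codes, n_folds, rng)
    reports = []
    for f, lab_idx in enumerate(folds):
        mask = np.zeros(matrix.n_cells, dtype=bool)
        mask[lab_idx] = True
        unlab_idx = np.flatnonzero(~mask)
        labeled = LabeledSet(matrix.subset_cells(lab_idx), codes[lab_idx], list(names))
        unlabeled = UnlabeledSet(matrix.subset_cells(unlab_idx))
        predicted = np.asarray(runner(labeled, unlabeled, seed * 1000 + f))
        reports.append(score(codes[unlab_idx], predicted, n_classes=len(names)))
    accs = np.array([r.accuracy for r in reports])
    return reports, float(accs.mean()), float(accs.std(ddof=1) / np.sqrt(len(accs)))


def label_fraction_sweep(
    matrix: ExpressionMatrix,
    labels: Sequence,
    p_values: Sequence[float],
    runner: Runner,
    repeats: int = 10,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean accuracy / macro-F1 per labeled fraction p over independent
    stratified splits; one row per p."""
    codes, names = encode_labels(labels, class_names)
    rows = []
    for p in p_values:
        accs, f1s = [], []
        for r in range(repeats):
            split_seed = seed * 100_000 + int(round(p * 10_000)) * 10 + r
            labeled, unlabeled, truth = split_by_label_fraction(
                matrix, [names[cint] for cint in codes], p, split_seed, names
            )
            predicted = np.asarray(runner(labeled, unlabeled, split_seed))
            rep = score(truth, predicted, n_classes=len(names))
            accs.append(rep.accuracy)
            f1s.append(rep.macro_f1)
        rows.append(
            {
                "p": p,
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_sd": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
                "macro_f1_mean": float(np.mean(f1s)),
                "macro_f1_sd": float(np.std(f1s, ddof=1)) if repeats > 1 else 0.0,
                "repeats": repeats,
            }
        )
    return pd.DataFrame(rows)
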