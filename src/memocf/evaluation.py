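"""Ranking metrics and evaluation protocols.

Two protocols are implemented.  Ten-fold cross-validation partitions the
known positive pairs into ten near-equal folds; within a fold the held-out
positives are scored against every unobserved (zero) pair, which serves as
the test negative set.  The cold-start ("new drug") protocol removes every
drug that has exactly one known association, places that association in the
test set, and trains on the rest, so the removed drugs are seen with an
empty history.

Metric conventions, stated because they matter for exactness: AUC uses
midranks for ties; AUPR is the step-wise sum of precision times recall
increments over descending score thresholds with equal scores grouped;
HR@k ranks each held-out positive's disease among all diseases with no
training association to the drug, breaking score ties by ascending disease
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.stats import rankdata

from .dataset_io import AssociationMatrix, DatasetBundle
from .fusion_model import TrainedModel, predict_scores

__all__ = [
    "FoldSplit",
    "EvaluationReport",
    "auc",
    "aupr",
    "hr_at_k",
    "cv_split",
    "cold_start_split",
    "cold_start_fold",
    "fold_train_matrix",
    "fold_train_bundle",
    "evaluate_model",
]


@dataclass
class FoldSplit:
    """One fold: training positives, held-out positives, test negatives."""

    fold_id: int
    train_positives: np.ndarray  # (k, 2) drug/disease index pairs
    test_positives: np.ndarray
    test_negatives: np.ndarray


@dataclass
class EvaluationReport:
    """Metrics of one evaluation run."""

    auc: float
    aupr: float
    hr_at: Dict[int, float]
    n_test_pos: int
    n_test_neg: int

    def to_dict(self) -> Dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "hr_at": {str(k): v for k, v in sorted(self.hr_at.items())},
            "n_test_pos": self.n_test_pos,
            "n_test_neg": self.n_test_neg,
        }


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (midranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels > 0.5
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, step-wise summation.

    Thresholds sweep the distinct scores in descending order; at each
    threshold precision P_k and recall R_k are computed over everything at
    or above it and the area accumulates (R_k - R_{k-1}) * P_k.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels > 0.5).sum())
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a group of equal scores ends
    ends = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([ends, [len(s) - 1]])
    tp = np.cumsum(y)[ends]
    total = ends + 1.0
    precision = tp / total
    recall = tp / n_pos
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev) * precision).sum())


def hr_at_k(
    model: TrainedModel,
    test_positives: np.ndarray,
    train: AssociationMatrix,
    k: int,
) -> float:
    """Fraction of held-out positives ranked within the top k candidates.

    For each held-out pair (i, j) the candidate list is every disease with
    no training association to drug i (which includes j); a hit means j's
    rank is at most k, with score ties broken by ascending disease index.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    test_positives = np.asarray(test_positives, dtype=int)
    if len(test_positives) == 0:
        raise ValueError("no held-out positives to rank")
    hits = 0
    by_drug: Dict[int, List[int]] = {}
    for i, j in test_positives:
        by_drug.setdefault(int(i), []).append(int(j))
    for i, held in by_drug.items():
        candidates = np.flatnonzero(train.values[i] == 0)
        if k > len(candidates):
            raise ValueError(
                f"k={k} exceeds the {len(candidates)} candidates of drug {i}"
            )
        scores = predict_scores(model, np.full(len(candidates), i), candidates)
        for j in held:
            pos = int(np.searchsorted(candidates, j))
            s_j = scores[pos]
            rank = 1 + int(
                ((scores > s_j) | ((scores == s_j) & (candidates < j))).sum()
            )
            if rank <= k:
                hits += 1
    return hits / len(test_positives)


def cv_split(a: AssociationMatrix, n_folds: int = 10, seed: int = 0) -> List[FoldSplit]:
    """Seeded partition of the known positives into near-equal folds.

    Every fold's test negatives are all unobserved (zero) pairs, following
    the convention that unverified pairs are treated as test negatives.
    """
    pos = np.argwhere(a.values == 1)
    if len(pos) < n_folds:
        raise ValueError(f"{len(pos)} positives cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    chunks = np.array_split(perm, n_folds)
    zeros = np.argwhere(a.values == 0)
    folds = []
    for fid, chunk in enumerate(chunks):
        mask = np.zeros(len(pos), dtype=bool)
        mask[chunk] = True
        folds.append(
            FoldSplit(
                fold_id=fid,
                train_positives=pos[~mask],
                test_positives=pos[mask],
                test_negatives=zeros,
            )
        )
    return folds


def cold_start_split(a: AssociationMatrix) -> Tuple[AssociationMatrix, np.ndarray]:
    """Move each singleton drug's only association into the test set.

    A singleton drug has row sum exactly 1; its row becomes all-zero in the
    returned training matrix.  Returns ``(train, test_positives)``.
    """
    values = np.array(a.values, copy=True)
    singleton_rows = np.flatnonzero(values.sum(axis=1) == 1)
    test_positives = []
    for i in singleton_rows:
        j = int(np.flatnonzero(values[i])[0])
        test_positives.append((int(i), j))
        values[i, j] = 0
    train = AssociationMatrix(values, a.drug_ids, a.disease_ids)
    return train, np.asarray(test_positives, dtype=int).reshape(-1, 2)


def cold_start_fold(a: AssociationMatrix) -> Tuple[AssociationMatrix, FoldSplit]:
    """Cold-start split packaged as a FoldSplit (negatives = original zeros)."""
    train, test_pos = cold_start_split(a)
    return train, FoldSplit(
        fold_id=0,
        train_positives=np.argwhere(train.values == 1),
        test_positives=test_pos,
        test_negatives=np.argwhere(a.values == 0),
    )


def fold_train_matrix(a: AssociationMatrix, split: FoldSplit) -> AssociationMatrix:
    """Association matrix containing only the split's training positives."""
    values = np.zeros_like(a.values)
    tp = np.asarray(split.train_positives, dtype=int)
    if len(tp):
        values[tp[:, 0], tp[:, 1]] = 1
    return AssociationMatrix(values, a.drug_ids, a.disease_ids)


def fold_train_bundle(bundle: DatasetBundle, split: FoldSplit) -> DatasetBundle:
    """Bundle whose associations are restricted to the split's training positives."""
    return DatasetBundle(
        fold_train_matrix(bundle.associations, split),
        bundle.drug_sim,
        bundle.disease_sim,
    )


def evaluate_model(
    model: TrainedModel, split: FoldSplit, hr_ks: Tuple[int, ...] = (1, 5, 10)
) -> EvaluationReport:
    """Score a split's held-out pairs and compute AUC, AUPR and HR@k."""
    test_pos = np.asarray(split.test_positives, dtype=int)
    test_neg = np.asarray(split.test_negatives, dtype=int)
    if len(test_pos) == 0:
        raise ValueError("split has no held-out positives")
    pairs = np.concatenate([test_pos, test_neg])
    labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
    scores = predict_scores(model, pairs[:, 0], pairs[:, 1])
    return EvaluationReport(
        auc=auc(scores, labels),
        aupr=aupr(scores, labels),
        hr_at={
            k: hr_at_k(model, test_pos, model.training_associations, k) for k in hr_ks
        },
        n_test_pos=len(test_pos),
        n_test_neg=len(test_neg),
    )
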