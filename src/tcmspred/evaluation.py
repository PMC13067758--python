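"""Stratified k-fold cross-validation, ROC/AUC, and confusion reporting.

AUC is the rank-statistic (Mann-Whitney) estimator: the probability that a
random positive outscores a random negative, with ties counted half.
Cross-validation is transductive with respect to features: embeddings and
proximity features are computed once on the full knowledge base and only
the association labels are held out — the standard framing for link
prediction on a fixed graph, and a documented leakage caveat for any other
reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .model import ModelConfig, predict, train
from .network import PairFeatures

__all__ = ["FoldAssignment", "ConfusionMatrix", "CVResult",
           "stratified_kfold", "roc_auc", "confusion", "cross_validate"]


@dataclass
class FoldAssignment:
    fold: np.ndarray      # fold index per row
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold != fold)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    per_class_rate: dict[int, float] = field(default_factory=dict)
    per_category: dict[str, "ConfusionMatrix"] = field(default_factory=dict)


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    confusion: ConfusionMatrix
    per_category_tp_rate: dict[str, float] = field(default_factory=dict)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None


def stratified_kfold(labels: np.ndarray | list[int], k: int,
                     seed: int = 0) -> FoldAssignment:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Within each class stratum the fold sizes differ by at most one.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} rows; use smaller k")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    start = 0  # carry the round-robin position across class strata
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = (start + np.arange(len(idx))) % k
        start = (start + len(idx)) % k
    return FoldAssignment(fold=fold, k=k, seed=seed)


def roc_auc(scores: np.ndarray | list[float],
            labels: np.ndarray | list[int]) -> float:
    """AUC = P(score+ > score-) + 0.5 P(tie), by the rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs at every distinct threshold, for plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    tpr = np.concatenate(([0.0], tps / max(tps[-1], 1)))
    fpr = np.concatenate(([0.0], fps / max(fps[-1], 1)))
    return np.column_stack([fpr, tpr])


def confusion(scores: np.ndarray | list[float], labels: np.ndarray | list[int],
              tau: float = 0.5,
              categories: list[str] | None = None) -> ConfusionMatrix:
    """Threshold at tau and count; per-class rate = correct/total in class.

    With ``categories`` the matrix is also decomposed per category label;
    the decomposition sums to the pooled counts.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= tau).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    rates: dict[int, float] = {}
    for cls in (0, 1):
        total = int((labels == cls).sum())
        if total:
            rates[cls] = float(((pred == labels) & (labels == cls)).sum() / total)
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, per_class_rate=rates)
    if categories is not None:
        cats = np.asarray(categories)
        for cat in sorted(set(categories)):
            sel = cats == cat
            cm.per_category[cat] = confusion(scores[sel], labels[sel], tau)
    return cm


def cross_validate(
    features: list[PairFeatures],
    labels: np.ndarray | list[int],
    model_config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    tau: float = 0.5,
    categories: list[str] | None = None,
) -> CVResult:
    """Train k models, each scored only on its held-out fold.

    Features are assumed precomputed on the full knowledge base
    (transductive contract); only labels are partitioned.
    """
    labels = np.asarray(labels, dtype=int)
    folds = stratified_kfold(labels, k, seed)
    fold_aucs: list[float] = []
    pooled_scores = np.empty(len(labels))
    for f in range(k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        cfg = ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + f})
        model = train([(features[i], int(labels[i])) for i in tr], cfg)
        scores = predict(model, [features[i] for i in te])
        s = np.array([x.probability for x in scores])
        pooled_scores[te] = s
        fold_aucs.append(roc_auc(s, labels[te]))
    cm = confusion(pooled_scores, labels, tau, categories)
    per_cat = {c: m.per_class_rate.get(1, float("nan"))
               for c, m in cm.per_category.items()}
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        sd_auc=float(np.std(fold_aucs, ddof=0)),
        confusion=cm,
        per_category_tp_rate=per_cat,
        scores=pooled_scores,
        labels=labels,
    )
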