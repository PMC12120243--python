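"""Metrics, cross-validation, exact Wilcoxon comparison and differential
feature ranking.

Annotation quality is summarized by accuracy, Cohen's kappa and macro-F1
computed from a confusion matrix; models are compared fold-by-fold with a
one-sided EXACT paired Wilcoxon signed-rank test (dynamic programming over
the sign-flip null — for 25 uniformly positive differences the p-value is
2^-25 ≈ 2.980e-8). Differential features (DEGs/DAPs) between a cell group
and the rest are ranked by a tie-corrected rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .augmentation import AugmentationPlan, augment_dataset
from .containers import PairedDataset
from .preprocess import PreprocessConfig, Preprocessor
from .training import TrainConfig, fit, predict_proba


# -- confusion matrix and metrics ------------------------------------------

@dataclass
class ConfusionMatrix:
    """K × K counts, rows = truth, cols = prediction, shared class order."""

    counts: np.ndarray
    classes: List[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} for {k} classes")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    truth: Sequence[str], pred: Sequence[str], classes: Optional[Sequence[str]] = None
) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=str)
    pred = np.asarray(pred, dtype=str)
    if len(truth) != len(pred):
        raise ValueError(f"{len(truth)} truth labels vs {len(pred)} predictions")
    if classes is None:
        classes = sorted(set(truth) | set(pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """κ = (p_o − p_e) / (1 − p_e); the degenerate all-one-class perfect
    table (p_e = p_o = 1) returns 1."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / (n * n)
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def f1_macro(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1; a class with precision + recall = 0
    contributes 0 (never NaN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    pred_pos = cm.counts.sum(axis=0).astype(float)
    true_pos = cm.counts.sum(axis=1).astype(float)
    denom = pred_pos + true_pos
    f1 = np.divide(2.0 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    return float(f1.mean())


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    kappa: float
    f1_macro: float

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricSet":
        return cls(accuracy=accuracy(cm), kappa=cohen_kappa(cm), f1_macro=f1_macro(cm))

    def as_dict(self) -> Dict[str, float]:
        return {"accuracy": self.accuracy, "kappa": self.kappa, "f1_macro": self.f1_macro}


# -- stratified cross-validation -------------------------------------------

@dataclass
class CVResult:
    fold_assignments: np.ndarray
    per_fold: List[MetricSet]
    class_names: List[str]

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.per_fold]))

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.per_fold])

    def as_dict(self) -> dict:
        return {
            "fold_assignments": self.fold_assignments.tolist(),
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": {
                k: self.mean(k) for k in ("accuracy", "kappa", "f1_macro")
            },
            "class_names": self.class_names,
        }


def stratified_folds(labels: Sequence[str], n_folds: int, seed: int = 0) -> np.ndarray:
    """Per-class seeded shuffle then round-robin assignment: within every
    class the fold sizes differ by at most one cell."""
    labels = np.asarray(labels, dtype=str)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    small = [c for c in sorted(set(labels)) if (labels == c).sum() < n_folds]
    if small:
        raise ValueError(
            f"classes with fewer than {n_folds} cells cannot be stratified: {small}"
        )
    for cls in sorted(set(labels)):
        members = np.flatnonzero(labels == cls)
        members = members[rng.permutation(len(members))]
        folds[members] = np.arange(len(members)) % n_folds
    return folds


def _leakage_check(donor_barcodes: Set[str], train_barcodes: Set[str]) -> None:
    leaked = donor_barcodes - train_barcodes
    if leaked:
        raise AssertionError(
            f"augmentation donors outside the training fold: {sorted(leaked)[:5]}"
        )


def cross_validate(
    data: PairedDataset,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    train_config: TrainConfig = TrainConfig(),
    plan: Optional[AugmentationPlan] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of the full annotation pipeline.

    Per fold: preprocessing is fitted on the training cells only, the
    training fold is augmented (training-fold donors only — enforced), the
    classifier is trained, and the held-out fold scored. ``plan=None``
    disables augmentation.
    """
    if data.labels is None:
        raise ValueError("cross-validation requires labels")
    folds = stratified_folds(data.labels, n_folds, seed=seed)
    per_fold: List[MetricSet] = []
    classes = sorted(set(data.labels))
    for f in range(n_folds):
        train_idx = np.flatnonzero(folds != f)
        test_idx = np.flatnonzero(folds == f)
        train = data.subset_cells(train_idx)
        test = data.subset_cells(test_idx)
        pre = Preprocessor(preprocess_config).fit(train)
        x_train = pre.transform(train)
        x_test = pre.transform(test)
        y_train = train.labels
        if plan is not None:
            fold_plan = replace(plan, seed=plan.seed + f)
            x_train, y_train, records = augment_dataset(
                x_train, y_train, train.barcodes, pre.rna_width, fold_plan
            )
            donors = {r.rna_donor for r in records} | {r.atac_donor for r in records}
            _leakage_check(donors, set(train.barcodes))
        fold_config = replace(train_config, seed=train_config.seed + f)
        model = fit(x_train, y_train, fold_config, manifest_hash=pre.manifest_hash())
        pred = predict_proba(model, x_test, barcodes=test.barcodes)
        cm = confusion_matrix(test.labels, pred.labels, classes=classes)
        per_fold.append(MetricSet.from_confusion(cm))
    return CVResult(fold_assignments=folds, per_fold=per_fold, class_names=classes)


# -- exact one-sided paired Wilcoxon signed-rank ----------------------------

def _signed_rank_statistic(diffs: np.ndarray) -> Tuple[float, np.ndarray]:
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(diffs))  # midranks under ties
    w_pos = float(ranks[diffs > 0].sum())
    return w_pos, ranks


def wilcoxon_signed_rank_exact(diffs: Sequence[float], exact_max_n: int = 50) -> float:
    """One-sided p = Pr(W+ ≥ w_obs) under the 2^n sign-flip null.

    Zero differences are dropped. For n ≤ ``exact_max_n`` the null
    distribution of the positive rank sum is computed by dynamic
    programming over doubled midranks, carried as dyadic probabilities
    (each sign contributes a factor 1/2, which is exact in binary floating
    point), so n uniformly positive differences give exactly 2^-n. Beyond
    ``exact_max_n`` a tie-corrected normal approximation is used.
    """
    w_pos, ranks = _signed_rank_statistic(diffs)
    n = len(ranks)
    if n <= exact_max_n:
        r2 = np.rint(2.0 * ranks).astype(np.int64)  # midranks -> integers
        w2_obs = int(np.rint(2.0 * w_pos))
        prob = np.zeros(int(r2.sum()) + 1)
        prob[0] = 1.0
        upto = 0  # largest attainable doubled rank sum so far
        for r in r2:
            shifted = np.zeros_like(prob)
            shifted[r : upto + r + 1] = prob[0 : upto + 1]
            prob = 0.5 * (prob + shifted)
            upto += r
        return float(prob[w2_obs:].sum())
    # tie-corrected normal approximation on W+
    mean = ranks.sum() / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(stats.norm.sf(z))


# -- robustness to the number of cell types --------------------------------

def celltype_removal_robustness(
    data: PairedDataset,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    train_config: TrainConfig = TrainConfig(),
    plan: Optional[AugmentationPlan] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> List[Tuple[List[str], CVResult]]:
    """Remove one uniformly chosen cell type at a time (seeded) down to two
    types, re-running cross-validation after each removal.

    Returns the (remaining classes, CVResult) trajectory — K − 2 steps for
    K starting classes.
    """
    if data.labels is None:
        raise ValueError("labels required")
    classes = sorted(set(data.labels))
    if len(classes) < 3:
        raise ValueError("need at least 3 cell types to run the removal experiment")
    rng = np.random.default_rng(seed)
    current = data
    remaining = list(classes)
    trajectory: List[Tuple[List[str], CVResult]] = []
    while len(remaining) > 2:
        removed = remaining[rng.integers(0, len(remaining))]
        remaining = [c for c in remaining if c != removed]
        keep_idx = np.flatnonzero(np.isin(current.labels, remaining))
        current = current.subset_cells(keep_idx)
        result = cross_validate(
            current, preprocess_config, train_config, plan=plan,
            n_folds=n_folds, seed=seed,
        )
        trajectory.append((list(remaining), result))
    return trajectory


# -- differential feature ranking (DEGs / DAPs) ----------------------------

@dataclass
class RankedFeatureList:
    """Features ordered by differential evidence (ascending p, then
    descending |location shift|, then feature index)."""

    feature_ids: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    shift: np.ndarray = field(default=None)

    def top(self, k: int) -> np.ndarray:
        return self.feature_ids[:k]


def rank_diff_features(
    x: np.ndarray,
    group: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
) -> RankedFeatureList:
    """Two-sided rank-sum test of in-group vs rest, per feature.

    Normal approximation with tie correction (scipy's asymptotic
    Mann–Whitney U). A feature constant across all cells gets p = 1 by
    convention. The location shift is the difference of group means.
    """
    x = np.asarray(x, dtype=float)
    group = np.asarray(group, dtype=bool)
    if group.sum() == 0 or (~group).sum() == 0:
        raise ValueError("both the group and its complement must be nonempty")
    n_features = x.shape[1]
    if feature_ids is None:
        feature_ids = np.arange(n_features).astype(str)
    feature_ids = np.asarray(feature_ids, dtype=str)
    pvals = np.ones(n_features)
    statistic = np.zeros(n_features)
    shift = x[group].mean(axis=0) - x[~group].mean(axis=0)
    for j in range(n_features):
        col = x[:, j]
        if np.all(col == col[0]):
            continue  # constant feature: p = 1 by convention
        res = stats.mannwhitneyu(
            col[group], col[~group], alternative="two-sided", method="asymptotic"
        )
        statistic[j] = float(res.statistic)
        pvals[j] = float(res.pvalue)
    order = np.lexsort((np.arange(n_features), -np.abs(shift), pvals))
    return RankedFeatureList(
        feature_ids=feature_ids[order],
        statistic=statistic[order],
        pvalue=pvals[order],
        shift=shift[order],
    )


def topk_overlap(
    a: RankedFeatureList, b: RankedFeatureList, k: int
) -> Tuple[float, List[str]]:
    """Fraction (and ids) of the top-k features shared by two rankings."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(a.feature_ids) or k > len(b.feature_ids):
        raise ValueError("k exceeds the length of a ranked list")
    top_a = set(a.top(k).tolist())
    top_b = set(b.top(k).tolist())
    shared = sorted(top_a & top_b)
    return len(shared) / k, shared
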