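"""Monte Carlo cross-validation and confusion-matrix performance measures.

A trained multiclass model is assessed by repeatedly drawing random
stratified train/test splits (default: 20 splits, 10% test), training a
fresh forest per split and pooling test predictions into one confusion
matrix. Per-class one-vs-rest measures (sensitivity, specificity,
precision) and global measures (accuracy, Cohen's kappa) are derived from
the pooled matrix; per-split accuracies are also reported so the split
dispersion is visible.

Undefined ratios (zero denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import CLASS_IDS
from .forest import LabeledSpectraSet, RDFConfig, train_rdf

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "GlobalMetrics",
    "CVReport",
    "class_metrics",
    "global_metrics",
    "monte_carlo_cv",
]


@dataclass
class ConfusionMatrix:
    """Square count table indexed (true class, predicted class)."""

    counts: np.ndarray
    class_ids: tuple[str, ...] = CLASS_IDS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.class_ids):
            raise ValueError("matrix size does not match class list")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray,
        class_ids: tuple[str, ...] = CLASS_IDS,
    ) -> "ConfusionMatrix":
        k = len(class_ids)
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_true, dtype=int),
                           np.asarray(y_pred, dtype=int)), 1)
        return cls(counts=counts, class_ids=class_ids)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_ids != other.class_ids:
            raise ValueError("class lists differ")
        return ConfusionMatrix(self.counts + other.counts, self.class_ids)


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest measures; NaN where the ratio is undefined."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    class_ids: tuple[str, ...] = CLASS_IDS


@dataclass
class GlobalMetrics:
    accuracy: float
    kappa: float


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(den), np.nan, dtype=float)
    nz = np.asarray(den) > 0
    out[nz] = np.asarray(num, dtype=float)[nz] / np.asarray(den, dtype=float)[nz]
    return out


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP)."""
    c = cm.counts.astype(np.int64)
    n = c.sum()
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = n - tp - fn - fp
    return ClassMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        class_ids=cm.class_ids,
    )


def global_metrics(cm: ConfusionMatrix) -> GlobalMetrics:
    """Accuracy and Cohen's kappa = (p_o - p_e)/(1 - p_e).

    Kappa corrects the observed agreement for the agreement expected by
    chance under the marginals; with unbalanced classes it sits below the
    accuracy. p_e = 1 yields NaN.
    """
    c = cm.counts.astype(np.float64)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(c) / n)
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / n**2)
    kappa = float("nan") if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    return GlobalMetrics(accuracy=accuracy, kappa=float(kappa))


@dataclass
class CVReport:
    """Aggregated Monte Carlo CV outcome."""

    split_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    per_class: ClassMetrics
    global_measures: GlobalMetrics
    split_accuracies: np.ndarray
    test_indices: list[np.ndarray]
    n_splits: int
    test_fraction: float
    seed: int

    def as_table(self) -> str:
        """Text table: one row per class plus a global block."""
        lines = [f"{'class':<10}{'sensitivity':>13}{'specificity':>13}{'precision':>11}"]
        for i, cid in enumerate(self.pooled.class_ids):
            if self.pooled.counts[i].sum() == 0 and self.pooled.counts[:, i].sum() == 0:
                continue
            s = self.per_class.sensitivity[i]
            p = self.per_class.specificity[i]
            r = self.per_class.precision[i]
            fmt = lambda v: "   n/a" if np.isnan(v) else f"{v:.4f}"
            lines.append(f"{cid:<10}{fmt(s):>13}{fmt(p):>13}{fmt(r):>11}")
        lines.append("")
        lines.append(f"accuracy = {self.global_measures.accuracy:.4f}")
        lines.append(f"kappa    = {self.global_measures.kappa:.4f}")
        lines.append(f"splits   = {self.n_splits} x {self.test_fraction:.0%} test, "
                     f"pooled N = {self.pooled.n}")
        return "\n".join(lines)


def _stratified_test_indices(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified hold-out with largest-remainder allocation.

    The total test count equals round(test_fraction * N) exactly; class
    quotas are the fractional shares rounded by largest remainder.
    """
    n = len(labels)
    total = int(round(test_fraction * n))
    classes, counts = np.unique(labels, return_counts=True)
    ideal = counts * test_fraction
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    take: list[np.ndarray] = []
    for cls, quota in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        take.append(rng.permutation(members)[:quota])
    return np.sort(np.concatenate(take))


def monte_carlo_cv(
    data: LabeledSpectraSet,
    n_splits: int = 20,
    test_fraction: float = 0.10,
    config: RDFConfig = RDFConfig(),
    seed: int = 0,
    *,
    stratified: bool = True,
) -> CVReport:
    """Monte Carlo (repeated random sub-sampling) cross-validation.

    For each split a random ``test_fraction`` is held out (stratified per
    class by default), a forest is trained on the rest and its test
    predictions accumulated into that split's confusion matrix. The
    pooled matrix is the entrywise sum over splits. Deterministic given
    ``seed``.
    """
    if n_splits < 1 or not (0.0 < test_fraction < 1.0):
        raise ValueError("need n_splits >= 1 and 0 < test_fraction < 1")
    classes, counts = np.unique(data.labels, return_counts=True)
    if np.any(counts < 2):
        lacking = [CLASS_IDS[c] for c, k in zip(classes, counts) if k < 2]
        raise ValueError(f"every class needs >= 2 spectra; too few: {lacking}")

    rng = np.random.default_rng(seed)
    split_matrices: list[ConfusionMatrix] = []
    split_acc: list[float] = []
    test_idx_all: list[np.ndarray] = []
    for s in range(n_splits):
        if stratified:
            test_idx = _stratified_test_indices(data.labels, test_fraction, rng)
        else:
            test_idx = np.sort(rng.permutation(len(data))[
                :int(round(test_fraction * len(data)))])
        train_mask = np.ones(len(data), dtype=bool)
        train_mask[test_idx] = False

        train = LabeledSpectraSet(
            spectra=data.spectra[train_mask],
            labels=data.labels[train_mask],
            axis=data.axis,
        )
        cfg = RDFConfig(
            n_trees=config.n_trees,
            features_per_split=config.features_per_split,
            min_leaf=config.min_leaf,
            max_depth=config.max_depth,
            bootstrap=config.bootstrap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        model = train_rdf(train, cfg)
        pred = model.predict(data.spectra[test_idx])
        cm = ConfusionMatrix.from_predictions(data.labels[test_idx], pred)
        split_matrices.append(cm)
        split_acc.append(global_metrics(cm).accuracy)
        test_idx_all.append(test_idx)

    pooled = split_matrices[0]
    for cm in split_matrices[1:]:
        pooled = pooled + cm

    return CVReport(
        split_matrices=split_matrices,
        pooled=pooled,
        per_class=class_metrics(pooled),
        global_measures=global_metrics(pooled),
        split_accuracies=np.asarray(split_acc),
        test_indices=test_idx_all,
        n_splits=n_splits,
        test_fraction=test_fraction,
        seed=seed,
    )
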