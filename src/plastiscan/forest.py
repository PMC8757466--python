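"""Random decision forest over IR spectra.

An ensemble of axis-aligned CART trees, grown on bootstrap resamples with
random feature subspaces at every node, combined by majority vote —
the classical random-forest construction. The implementation is fully
deterministic under a fixed seed, with documented tie-breaks:

* split search: best Gini impurity decrease; thresholds at midpoints of
  consecutive distinct feature values; ties broken toward the lowest band
  index, then the lowest threshold;
* voting: ties between classes broken toward the earlier class in the
  model's class order;
* training rows are canonically reordered (by a digest of the row bytes
  and label) before any random draw, so predictions are invariant to the
  order in which training spectra are supplied.

Feature vectors are by default the raw absorbance values resampled onto
the model's wavenumber grid; vector normalization and a smoothed first
derivative are available as preprocessing options.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .classes import CLASS_IDS
from .envi import WavenumberAxis, default_axis

__all__ = [
    "PreprocessConfig",
    "RDFConfig",
    "RDFModel",
    "LabeledSpectraSet",
    "preprocess_spectrum",
    "train_rdf",
    "audit_labels",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# preprocessing

@dataclass(frozen=True)
class PreprocessConfig:
    """Spectral preprocessing applied before training and prediction.

    ``normalize`` rescales each vector to unit Euclidean norm;
    ``derivative`` replaces the spectrum by its Savitzky-Golay smoothed
    first derivative (window ``savgol_window`` points, polynomial order
    ``savgol_poly``). Defaults: raw absorbance, no options.
    """

    normalize: bool = False
    derivative: bool = False
    savgol_window: int = 9
    savgol_poly: int = 3


def preprocess_spectrum(
    raw: np.ndarray,
    raw_axis: WavenumberAxis,
    target_axis: WavenumberAxis,
    config: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray:
    """Resample a spectrum onto the model grid and apply preprocessing.

    Linear interpolation onto ``target_axis``; target bands outside the
    raw range are filled with the nearest edge value. Raises if the raw
    axis covers less than 90% of the target range.
    """
    was_1d = np.asarray(raw).ndim == 1
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    rv = raw_axis.values
    tv = target_axis.values
    lo = max(rv.min(), tv.min())
    hi = min(rv.max(), tv.max())
    span = tv.max() - tv.min()
    overlap = max(0.0, hi - lo)
    if span > 0 and overlap < 0.9 * span:
        raise ValueError(
            f"raw axis covers only {100 * overlap / span:.1f}% of the target range"
        )

    # np.interp needs ascending sample points
    xp = rv if raw_axis.ascending else rv[::-1]
    out = np.empty((raw.shape[0], tv.size), dtype=float)
    for i, row in enumerate(raw):
        fp = row if raw_axis.ascending else row[::-1]
        out[i] = np.interp(tv, xp, fp)

    if config.derivative:
        win = min(config.savgol_window, tv.size if tv.size % 2 == 1 else tv.size - 1)
        out = savgol_filter(out, win, min(config.savgol_poly, win - 1),
                            deriv=1, axis=1)
    if config.normalize:
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        np.divide(out, norms, out=out, where=norms > 0)
    return out[0] if was_1d else out


# --------------------------------------------------------------------------
# data containers

@dataclass
class LabeledSpectraSet:
    """Reference spectra with class labels on a shared wavenumber axis."""

    spectra: np.ndarray          # (n, bands)
    labels: np.ndarray           # (n,) integer class codes
    axis: WavenumberAxis
    provenance: list[str] | None = None   # optional annotator tag per spectrum

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (n, bands) array")
        if len(self.spectra) != len(self.labels):
            raise ValueError("spectra and labels must have equal counts")
        if self.spectra.shape[1] != len(self.axis):
            raise ValueError("spectrum length does not match axis")
        if np.any(self.labels < 0) or np.any(self.labels >= len(CLASS_IDS)):
            raise ValueError("labels must be valid class codes")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RDFConfig:
    """Forest hyperparameters.

    ``features_per_split`` may be an integer count, a float fraction of the
    band count, or None for the usual ceil(sqrt(n_features)) heuristic.
    ``max_depth`` None means unlimited.
    """

    n_trees: int = 100
    features_per_split: int | float | None = None
    min_leaf: int = 1
    max_depth: int | None = None
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        f = self.features_per_split
        if f is None:
            m = int(np.ceil(np.sqrt(n_features)))
        elif isinstance(f, float) and 0 < f <= 1:
            m = int(np.ceil(f * n_features))
        else:
            m = int(f)
        if not 1 <= m <= n_features:
            raise ValueError("features_per_split out of range")
        return m


# --------------------------------------------------------------------------
# tree fitting

class _Tree:
    """Flat-array CART tree: leaves have feature == -1 and value == class."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[int] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(-1)
        return len(self.feature) - 1

    def finalize(self) -> dict[str, np.ndarray]:
        return {
            "feature": np.asarray(self.feature, dtype=np.int32),
            "threshold": np.asarray(self.threshold, dtype=np.float64),
            "left": np.asarray(self.left, dtype=np.int32),
            "right": np.asarray(self.right, dtype=np.int32),
            "value": np.asarray(self.value, dtype=np.int32),
        }


def _best_split(
    Xc: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float] | None:
    """Best (column, threshold) in ``Xc`` by weighted Gini; None if no split.

    Columns of ``Xc`` must already be ordered by ascending band index so
    that np.argmin's first-occurrence rule realizes the lowest-band-index
    tie-break; within a column the lowest threshold wins because candidate
    thresholds are scanned in increasing order. ``y`` must be compact codes
    0..c-1 (Gini is label-agnostic).
    """
    n, f = Xc.shape
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order].astype(np.int32)                        # (n, f)

    # occurrence ranks: occ[i] = same-class elements before i in sort order,
    # occ_rev[i] = same-class elements after i. Adding a sample to a side
    # holding k samples of its class raises that side's sum of squared
    # class counts by 2k+1, which gives the Gini of every split position
    # from two cumulative sums with no class dimension.
    g = np.argsort(ys, axis=0, kind="stable")
    ys_g = np.take_along_axis(ys, g, axis=0)
    idx = np.arange(n, dtype=np.int64)[:, None]
    newg = np.empty((n, f), dtype=bool)
    newg[0] = True
    newg[1:] = ys_g[1:] != ys_g[:-1]
    gstart = np.maximum.accumulate(np.where(newg, idx, 0), axis=0)
    lastg = np.empty((n, f), dtype=bool)
    lastg[-1] = True
    lastg[:-1] = newg[1:]
    gend = np.minimum.accumulate(np.where(lastg, idx, n - 1)[::-1], axis=0)[::-1]
    occ_g = idx - gstart
    occ_rev_g = gend - idx
    occ = np.empty((n, f), dtype=np.int64)
    occ_rev = np.empty((n, f), dtype=np.int64)
    np.put_along_axis(occ, g, occ_g, axis=0)
    np.put_along_axis(occ_rev, g, occ_rev_g, axis=0)

    sumsq_l = np.cumsum(2 * occ + 1, axis=0)              # (n, f)
    contrib_r = 2 * occ_rev + 1
    sumsq_r = contrib_r.sum(axis=0, keepdims=True) - np.cumsum(contrib_r, axis=0)

    n_left = np.arange(1, n, dtype=np.float64)[:, None]   # split after row i
    n_right = n - n_left
    # weighted Gini: (n_l*g_l + n_r*g_r)/n == (n - ssq_l/n_l - ssq_r/n_r)/n
    score = (n - sumsq_l[:-1] / n_left - sumsq_r[:-1] / n_right) / n

    valid = xs[1:] > xs[:-1]
    if min_leaf > 1:
        pos = np.arange(1, n)[:, None]
        valid = valid & (pos >= min_leaf) & (n - pos >= min_leaf)
    if not valid.any():
        return None
    score = np.where(valid, score, np.inf)

    best_per_feat = np.argmin(score, axis=0)              # lowest threshold on ties
    feat_scores = score[best_per_feat, np.arange(score.shape[1])]
    j = int(np.argmin(feat_scores))                       # lowest band index on ties
    if not np.isfinite(feat_scores[j]):
        return None
    i = int(best_per_feat[j])
    thr = 0.5 * (xs[i, j] + xs[i + 1, j])
    return j, float(thr)


def _draw_candidates(
    X: np.ndarray, idx: np.ndarray, mtry: int, rng: np.random.Generator
) -> np.ndarray:
    """First ``mtry`` bands, in a seeded random order, that vary in the node."""
    perm = rng.permutation(X.shape[1])
    picked: list[np.ndarray] = []
    n_picked = 0
    for start in range(0, len(perm), mtry):
        block = perm[start:start + mtry]
        sub = X[np.ix_(idx, block)]
        varying = block[sub.min(axis=0) < sub.max(axis=0)]
        if varying.size:
            picked.append(varying[: mtry - n_picked])
            n_picked += picked[-1].size
        if n_picked >= mtry:
            break
    if not picked:
        return np.empty(0, dtype=np.intp)
    return np.sort(np.concatenate(picked))


def _grow(
    tree: _Tree,
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    depth: int,
    cfg: RDFConfig,
    mtry: int,
    rng: np.random.Generator,
) -> int:
    node = tree._new_node()
    yy = y[idx]
    counts = np.bincount(yy)
    majority = int(np.argmax(counts))                     # earliest class on ties

    pure = counts[majority] == len(idx)
    depth_out = cfg.max_depth is not None and depth >= cfg.max_depth
    if pure or depth_out or len(idx) < 2 * cfg.min_leaf:
        tree.value[node] = majority
        return node

    candidates = _draw_candidates(X, idx, mtry, rng)
    if candidates.size == 0:
        tree.value[node] = majority
        return node

    lut = np.cumsum(counts > 0, dtype=np.int32) - 1   # compact class codes
    yc = lut[yy]
    Xc = X[np.ix_(idx, candidates)]
    split = _best_split(Xc, yc, cfg.min_leaf)
    if split is None:
        tree.value[node] = majority
        return node
    j, thr = split
    f = int(candidates[j])
    go_left = Xc[:, j] <= thr
    tree.feature[node] = f
    tree.threshold[node] = thr
    tree.left[node] = _grow(tree, X, y, idx[go_left], depth + 1, cfg, mtry, rng)
    tree.right[node] = _grow(tree, X, y, idx[~go_left], depth + 1, cfg, mtry, rng)
    return node


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row permutation by digest of (row bytes, label): order-invariant."""
    keys = [
        hashlib.md5(np.ascontiguousarray(X[i], dtype=np.float64).tobytes()
                    + int(y[i]).to_bytes(4, "little")).digest()
        for i in range(len(y))
    ]
    return np.asarray(sorted(range(len(y)), key=keys.__getitem__), dtype=np.intp)


@dataclass
class RDFModel:
    """Trained forest: tree arrays, class order, axis, preprocessing."""

    trees: list[dict[str, np.ndarray]]
    class_order: tuple[str, ...]
    axis: WavenumberAxis
    preprocess: PreprocessConfig
    config: RDFConfig
    classes_present: np.ndarray      # sorted integer codes seen in training

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _apply_tree(self, tree: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int32)
        feat, thr = tree["feature"], tree["threshold"]
        left, right = tree["left"], tree["right"]
        active = feat[node] >= 0
        while active.any():
            a = np.flatnonzero(active)
            nd = node[a]
            go_left = X[a, feat[nd]] <= thr[nd]
            node[a] = np.where(go_left, left[nd], right[nd])
            active[a] = feat[node[a]] >= 0
        return tree["value"][node]

    def predict_proba(self, X: np.ndarray, *, raw_axis: WavenumberAxis | None = None
                      ) -> np.ndarray:
        """Per-class tree-vote fractions; rows sum to 1.

        ``X`` is (n, bands) on the model axis, or on ``raw_axis`` if given
        (then it is resampled/preprocessed first).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if raw_axis is not None:
            X = np.atleast_2d(preprocess_spectrum(X, raw_axis, self.axis, self.preprocess))
        if X.shape[1] != len(self.axis):
            raise ValueError(
                f"feature length {X.shape[1]} does not match model axis {len(self.axis)}"
            )
        n_classes = len(self.class_order)
        votes = np.zeros((len(X), n_classes), dtype=np.float64)
        rows = np.arange(len(X))
        for tree in self.trees:
            votes[rows, self._apply_tree(tree, X)] += 1.0
        return votes / self.n_trees

    def predict(self, X: np.ndarray, *, raw_axis: WavenumberAxis | None = None
                ) -> np.ndarray:
        """Argmax vote; ties toward the earlier class in class order."""
        return np.argmax(self.predict_proba(X, raw_axis=raw_axis), axis=1)


def train_rdf(data: LabeledSpectraSet, config: RDFConfig = RDFConfig()) -> RDFModel:
    """Fit a random decision forest on labeled spectra.

    Each tree sees a bootstrap resample (if enabled) and at every node the
    best Gini split among a fresh random subset of band indices.
    Deterministic given ``config.seed``; invariant to input row order.
    """
    if len(data) == 0:
        raise ValueError("empty training set")
    present = np.unique(data.labels)
    if present.size < 2:
        raise ValueError("training data must contain at least two classes")

    X = np.asarray(data.spectra, dtype=np.float64)
    y = data.labels
    order = _canonical_order(X, y)
    X, y = np.ascontiguousarray(X[order]), y[order]

    mtry = config.resolve_mtry(X.shape[1])
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_trees)
    trees: list[dict[str, np.ndarray]] = []
    n = len(y)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, n) if config.bootstrap else np.arange(n)
        tree = _Tree()
        _grow(tree, X, y, np.asarray(idx, dtype=np.intp), 0, config, mtry, rng)
        trees.append(tree.finalize())

    return RDFModel(
        trees=trees,
        class_order=CLASS_IDS,
        axis=data.axis,
        preprocess=PreprocessConfig(),
        config=config,
        classes_present=present,
    )


# --------------------------------------------------------------------------
# persistence

def save_model(model: RDFModel, path: str | os.PathLike) -> None:
    """Write a model as a self-describing versioned JSON container."""
    doc = {
        "format": "plastiscan-rdf",
        "version": MODEL_FORMAT_VERSION,
        "class_order": list(model.class_order),
        "axis": [float(v) for v in model.axis.values],
        "preprocess": asdict(model.preprocess),
        "config": asdict(model.config),
        "classes_present": [int(c) for c in model.classes_present],
        "trees": [
            {k: v.tolist() for k, v in tree.items()} for tree in model.trees
        ],
    }
    tmp = os.fspath(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
    os.replace(tmp, path)


def load_model(path: str | os.PathLike) -> RDFModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "plastiscan-rdf":
        raise ValueError("not a plastiscan RDF model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file version {doc.get('version')} is incompatible with "
            f"this reader (version {MODEL_FORMAT_VERSION})"
        )
    trees = [
        {
            "feature": np.asarray(t["feature"], dtype=np.int32),
            "threshold": np.asarray(t["threshold"], dtype=np.float64),
            "left": np.asarray(t["left"], dtype=np.int32),
            "right": np.asarray(t["right"], dtype=np.int32),
            "value": np.asarray(t["value"], dtype=np.int32),
        }
        for t in doc["trees"]
    ]
    return RDFModel(
        trees=trees,
        class_order=tuple(doc["class_order"]),
        axis=WavenumberAxis(np.asarray(doc["axis"], dtype=float)),
        preprocess=PreprocessConfig(**doc["preprocess"]),
        config=RDFConfig(**doc["config"]),
        classes_present=np.asarray(doc["classes_present"], dtype=np.int64),
    )


# --------------------------------------------------------------------------
# cross-annotator label audit

def audit_labels(
    annotator_sets: list[LabeledSpectraSet],
    config: RDFConfig = RDFConfig(),
    *,
    majority_fraction: float = 0.5,
) -> list[dict]:
    """Cross-annotator label-noise audit.

    For each annotator's set, forests trained on every *other* annotator's
    set predict its spectra; a spectrum is flagged when more than
    ``majority_fraction`` of those cross-models disagree with its own
    label. Returns one record per spectrum with the own label, every
    cross-model's prediction, and the flag.
    """
    if len(annotator_sets) < 2:
        raise ValueError("need at least two annotator sets")
    axis_len = len(annotator_sets[0].axis)
    if any(len(s.axis) != axis_len for s in annotator_sets):
        raise ValueError("annotator sets must share one axis")

    models = []
    for k, s in enumerate(annotator_sets):
        cfg = RDFConfig(**{**asdict(config), "seed": config.seed + k})
        models.append(train_rdf(s, cfg))

    report: list[dict] = []
    for k, s in enumerate(annotator_sets):
        cross = [m for j, m in enumerate(models) if j != k]
        preds = np.stack([m.predict(s.spectra) for m in cross], axis=1)
        for i in range(len(s)):
            own = int(s.labels[i])
            disagree = int(np.sum(preds[i] != own))
            report.append({
                "set": k,
                "index": i,
                "own_label": own,
                "cross_labels": preds[i].tolist(),
                "flagged": disagree > majority_fraction * preds.shape[1],
            })
    return report
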