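"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (dict counting, BFS flood fill,
exhaustive split enumeration) kept free of any code shared with the
package, so agreement is evidence of correctness rather than tautology.
The greedy-tree oracle keeps the *arithmetic shape* of the split score
identical (``(n - ssq_l/n_l - ssq_r/n_r)/n``) so that exact-tie cases
resolve the same way in both implementations.
"""

from __future__ import annotations

from collections import Counter, deque

import numpy as np


# --------------------------------------------------------------------------
# connected components

def flood_fill_components(labels: np.ndarray, substrate: int = -1):
    """Same-class 4-connected components, discovered in raster-scan order.

    Returns a list of (class, frozenset of (row, col)) tuples.
    """
    labels = np.asarray(labels)
    rows, cols = labels.shape
    seen: set[tuple[int, int]] = set()
    comps = []
    for r in range(rows):
        for c in range(cols):
            if labels[r, c] == substrate or (r, c) in seen:
                continue
            cls = int(labels[r, c])
            comp = set()
            queue = deque([(r, c)])
            seen.add((r, c))
            while queue:
                rr, cc = queue.popleft()
                comp.add((rr, cc))
                for nr, nc in ((rr - 1, cc), (rr + 1, cc), (rr, cc - 1), (rr, cc + 1)):
                    if (0 <= nr < rows and 0 <= nc < cols
                            and (nr, nc) not in seen
                            and labels[nr, nc] == cls):
                        seen.add((nr, nc))
                        queue.append((nr, nc))
            comps.append((cls, frozenset(comp)))
    return comps


# --------------------------------------------------------------------------
# exhaustive greedy Gini tree

def brute_cart(X, y, min_leaf: int = 1, max_depth: int | None = None, depth: int = 0):
    """Exhaustive greedy CART: nested ('leaf', cls) / ('split', f, thr, l, r).

    Features scanned in ascending index, thresholds (midpoints of
    consecutive distinct values) in ascending order, strict improvement
    required -- so ties resolve to the lowest band index, lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = [int(v) for v in y]
    n = len(y)
    counts = Counter(y)
    majority = min(counts, key=lambda k: (-counts[k], k))
    if (len(counts) == 1 or n < 2 * min_leaf
            or (max_depth is not None and depth >= max_depth)):
        return ("leaf", majority)

    best = None
    for f in range(X.shape[1]):
        u = sorted(set(X[:, f].tolist()))
        for a, b in zip(u[:-1], u[1:]):
            thr = 0.5 * (a + b)
            left = [i for i in range(n) if X[i, f] <= thr]
            right = [i for i in range(n) if X[i, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sl = sum(v * v for v in Counter(y[i] for i in left).values())
            sr = sum(v * v for v in Counter(y[i] for i in right).values())
            score = (n - sl / len(left) - sr / len(right)) / n
            if best is None or score < best[0]:
                best = (score, f, thr, left, right)
    if best is None:
        return ("leaf", majority)
    _, f, thr, left, right = best
    return (
        "split", f, thr,
        brute_cart(X[left], [y[i] for i in left], min_leaf, max_depth, depth + 1),
        brute_cart(X[right], [y[i] for i in right], min_leaf, max_depth, depth + 1),
    )


def tree_to_nested(tree: dict, node: int = 0):
    """Convert the package's flat tree arrays to the oracle's nested form."""
    if tree["feature"][node] < 0:
        return ("leaf", int(tree["value"][node]))
    return (
        "split",
        int(tree["feature"][node]),
        float(tree["threshold"][node]),
        tree_to_nested(tree, int(tree["left"][node])),
        tree_to_nested(tree, int(tree["right"][node])),
    )


# --------------------------------------------------------------------------
# confusion-matrix measures

def metrics_bruteforce(counts: np.ndarray) -> dict:
    """Direct TP/FN/FP/TN evaluation of all measures; NaN on 0 denominators."""
    counts = np.asarray(counts)
    k = counts.shape[0]
    n = int(counts.sum())
    out = {"sensitivity": [], "specificity": [], "precision": []}
    for i in range(k):
        tp = int(counts[i, i])
        fn = int(counts[i, :].sum()) - tp
        fp = int(counts[:, i].sum()) - tp
        tn = n - tp - fn - fp
        out["sensitivity"].append(tp / (tp + fn) if tp + fn > 0 else float("nan"))
        out["specificity"].append(tn / (tn + fp) if tn + fp > 0 else float("nan"))
        out["precision"].append(tp / (tp + fp) if tp + fp > 0 else float("nan"))
    acc = sum(int(counts[i, i]) for i in range(k)) / n
    p_e = sum(int(counts[i, :].sum()) * int(counts[:, i].sum()) for i in range(k)) / n**2
    out["accuracy"] = acc
    out["kappa"] = float("nan") if p_e == 1.0 else (acc - p_e) / (1.0 - p_e)
    out["p_e"] = p_e
    return out
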