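"""Independent reference implementations used as test oracles.

Everything here is deliberately written without reusing the package's loss
or split code: brute-force enumeration, closed forms from different
formulas, scipy/statsmodels likelihoods, and an exhaustive CART grower.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special, stats


def sse_two_pass(values) -> float:
    """Sum of squared deviations by the naive two-pass formula."""
    values = list(values)
    mean = sum(values) / len(values)
    return sum((v - mean) ** 2 for v in values)


def gini_loss_enumeration(labels) -> float:
    """Size-weighted Gini by explicit proportion enumeration."""
    labels = list(labels)
    n = len(labels)
    props = [labels.count(lv) / n for lv in set(labels)]
    return n * (1.0 - sum(p * p for p in props))


def poisson_neg2_loglik(counts, exposure=None) -> float:
    """-2 log-likelihood at the pooled MLE rate, via scipy's Poisson pmf
    with the factorial terms added back out (so the y! term is absent)."""
    y = np.asarray(counts, dtype=float)
    E = np.ones_like(y) if exposure is None else np.asarray(exposure, dtype=float)
    lam = y.sum() / E.sum()
    mu = lam * E
    if lam == 0:
        return 0.0
    ll = stats.poisson.logpmf(y.astype(int), mu).sum() + special.gammaln(y + 1).sum()
    return -2.0 * float(ll)


def exponential_neg2_loglik(times, events) -> float:
    """-2 max censored-exponential log-likelihood found by numeric search."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if d.sum() == 0:
        return 0.0

    def neg_ll(log_lam):
        lam = math.exp(log_lam)
        return -(d.sum() * math.log(lam) - lam * t.sum())

    res = optimize.minimize_scalar(neg_ll, bounds=(-30, 30), method="bounded")
    return 2.0 * res.fun


# ---------------------------------------------------------------------------
# exhaustive single-target CART reference


class RefNode:
    def __init__(self, n):
        self.n = n
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None

    @property
    def is_leaf(self):
        return self.feature is None


def grow_cart_reference(X, y, d, nodesize, splitmin, cp, reuse=True):
    """Exhaustive variance-reduction CART on numeric features.

    Mirrors the engine's contract (cp gate on proportion of parent SSE
    explained, splitmin/nodesize constraints, midpoint thresholds, ties to
    earlier feature then lower threshold) but searches by direct SSE
    computation with no shared code.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    features = list(range(X.shape[1]))

    def build(idx, depth, used):
        node = RefNode(len(idx))
        if depth >= d or len(idx) < nodesize:
            return node
        parent_sse = sse_two_pass(y[idx])
        best = None  # (gain, f, thr, left_idx, right_idx)
        for f in features:
            if not reuse and f in used:
                continue
            vals = np.unique(X[idx, f])
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2.0
                left = idx[X[idx, f] <= thr]
                right = idx[X[idx, f] > thr]
                if len(left) < splitmin or len(right) < splitmin:
                    continue
                gain = parent_sse - sse_two_pass(y[left]) - sse_two_pass(y[right])
                prop = gain / parent_sse if parent_sse > 0 else 0.0
                if prop < cp:
                    continue
                if best is None or gain > best[0]:
                    best = (gain, f, thr, left, right)
        if best is None:
            return node
        _, f, thr, left, right = best
        node.feature = f
        node.threshold = thr
        node.left = build(left, depth + 1, used | {f})
        node.right = build(right, depth + 1, used | {f})
        return node

    return build(np.arange(len(y)), 0, frozenset())


def trees_equal(ref: RefNode, node, feature_names, atol=1e-9) -> bool:
    """Structural + threshold equality between a reference tree and a model node."""
    if ref.is_leaf != node.is_leaf:
        return False
    if ref.is_leaf:
        return True
    if feature_names[ref.feature] != node.split.feature:
        return False
    if abs(ref.threshold - node.split.threshold) > atol:
        return False
    return trees_equal(ref.left, node.children[0], feature_names, atol) and trees_equal(
        ref.right, node.children[1], feature_names, atol
    )
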