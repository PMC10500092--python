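"""Per-target node losses, information gain, proportion IG, and split p-values.

Loss conventions (chosen so parent-minus-children is the canonical
single-target splitting criterion for each type):

* continuous  — within-node sum of squared deviations (deviance),
* categorical — size-weighted Gini impurity ``n * (1 - sum p_k^2)``,
* count       — ``-2 * log-likelihood`` of the Poisson model at the node MLE
  rate (the ``log y!`` term is omitted; it cancels in every gain),
* survival    — ``-2 * log-likelihood`` of the exponential model at the node
  MLE hazard, computed on cumulative-hazard-rescaled times.

With the likelihood-based forms, the gain *is* the likelihood-ratio
statistic of the split.

The raw likelihood losses are non-negative only up to an additive constant
(the saturated-model log-likelihood, a fixed sum over the node's rows that
cancels in every parent-minus-children difference). Each NodeLoss therefore
also carries its *deviance* — the loss minus that constant, always >= 0 and
zero exactly for a perfectly fitted node — which is what proportion IG and
all cross-target normalizations divide by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import MTTreeError

_TINY_P = float(np.finfo(float).tiny)
_EPS = 1e-12


class LossDomainError(MTTreeError):
    """Loss requested on an empty or otherwise out-of-domain sample."""


@dataclass(frozen=True)
class NodeLoss:
    """Loss value for one target at one node, with sufficient statistics.

    ``deviance`` is the loss minus the per-node saturated constant: always
    non-negative, and identical to ``value`` for continuous and categorical
    targets.
    """

    value: float
    n: int
    stats: dict

    @property
    def deviance(self) -> float:
        return self.stats.get("dev", self.value)


@dataclass(frozen=True)
class TargetGain:
    """Raw IG, standardized proportion IG, and split p-value for one target."""

    ig: float
    prop_ig: float
    p_value: float
    df: float


# ---------------------------------------------------------------------------
# vectorized closed forms (array in, array out); scalar node_loss_* wrap these


def continuous_loss_from_sums(n, s, ss):
    """Sum of squared deviations from counts, sums, and sums of squares."""
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.asarray(ss - np.where(n > 0, s * s / np.maximum(n, 1), 0.0))
    return np.maximum(out, 0.0)


def categorical_loss_from_counts(counts):
    """Size-weighted Gini from class counts; last axis indexes classes."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, n - (counts * counts).sum(axis=-1) / np.maximum(n, 1), 0.0)
    return np.maximum(out, 0.0)


def count_loss_from_sums(y_sum, ylogE_sum, E_sum):
    """-2 log-likelihood (sans y! term) from sum(y), sum(y*log E), sum(E).

    The node MLE rate is ``sum(y)/sum(E)``; the 0*log(0) convention makes a
    zero-event node contribute exactly 0.
    """
    y_sum = np.asarray(y_sum, dtype=float)
    E_sum = np.asarray(E_sum, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(E_sum > 0, y_sum / np.maximum(E_sum, _EPS), 0.0)
        loglam = np.where(lam > 0, np.log(np.maximum(lam, _EPS)), 0.0)
    return -2.0 * (y_sum * loglam + np.asarray(ylogE_sum, dtype=float) - y_sum)


def survival_loss_from_sums(d_sum, t_sum):
    """-2 log-likelihood of the exponential model from event and time totals."""
    d = np.asarray(d_sum, dtype=float)
    t = np.asarray(t_sum, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        logratio = np.where((d > 0) & (t > 0), np.log(np.maximum(d, _EPS) / np.maximum(t, _EPS)), 0.0)
    return np.where(d > 0, -2.0 * (d * logratio - d), 0.0)


# ---------------------------------------------------------------------------
# scalar node losses


def node_loss_continuous(values) -> NodeLoss:
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise LossDomainError("continuous loss of an empty sample")
    mean = float(y.mean())
    value = float(continuous_loss_from_sums(y.size, y.sum(), (y * y).sum()))
    return NodeLoss(
        value=value, n=int(y.size), stats={"mean": mean, "ss": value, "dev": value}
    )


def node_loss_categorical(labels, levels=None) -> NodeLoss:
    arr = np.asarray(labels, dtype=object)
    if arr.size == 0:
        raise LossDomainError("categorical loss of an empty sample")
    if levels is None:
        levels = list(dict.fromkeys(arr.tolist()))
    counts = np.array([int((arr == lv).sum()) for lv in levels], dtype=float)
    value = float(categorical_loss_from_counts(counts))
    return NodeLoss(
        value=value,
        n=int(arr.size),
        stats={"counts": {lv: int(c) for lv, c in zip(levels, counts)}, "dev": value},
    )


def node_loss_count(counts, exposure=None) -> NodeLoss:
    y = np.asarray(counts, dtype=float)
    if y.size == 0:
        raise LossDomainError("count loss of an empty sample")
    if exposure is None:
        E = np.ones_like(y)
    else:
        E = np.asarray(exposure, dtype=float)
    if E.shape != y.shape:
        raise LossDomainError("counts and exposure lengths differ")
    if (E <= 0).any():
        raise LossDomainError("exposure must be strictly positive")
    value = float(count_loss_from_sums(y.sum(), (y * np.log(E)).sum(), E.sum()))
    # saturated constant: 2*sum(y log y - y); dev = value + const >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, _EPS)), 0.0)
    dev = max(value + 2.0 * float((ylogy - y).sum()), 0.0)
    return NodeLoss(
        value=value,
        n=int(y.size),
        stats={"events": float(y.sum()), "exposure": float(E.sum()), "dev": dev},
    )


def node_loss_survival(times, events) -> NodeLoss:
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if t.size == 0:
        raise LossDomainError("survival loss of an empty sample")
    if t.shape != d.shape:
        raise LossDomainError("times and events lengths differ")
    D, T = float(d.sum()), float(t.sum())
    if D > 0 and T <= 0:
        raise LossDomainError("total observation time is zero with events present")
    value = float(survival_loss_from_sums(D, T))
    # saturated constant: -2*sum_{events}(log t + 1); dev = value + const >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dlogt = np.where(
            (d > 0) & (t > 0), d * (np.log(np.maximum(t, _EPS)) + 1.0), 0.0
        )
    dev = max(value - 2.0 * float(dlogt.sum()), 0.0) if D > 0 else 0.0
    return NodeLoss(
        value=value, n=int(t.size), stats={"events": D, "time": T, "dev": dev}
    )


# ---------------------------------------------------------------------------
# gains and p-values


def _p_continuous(ig: float, within: float, n: int) -> tuple[float, float]:
    df2 = n - 2
    if df2 <= 0 or ig <= 0:
        return (1.0, float(max(df2, 1)))
    if within <= _EPS * max(1.0, ig):
        return (_TINY_P, float(df2))
    F = ig / (within / df2)
    return (float(max(stats.f.sf(F, 1, df2), _TINY_P)), float(df2))


def _p_categorical(parent: NodeLoss, left: NodeLoss, right: NodeLoss) -> tuple[float, float]:
    levels = [lv for lv, c in parent.stats["counts"].items() if c > 0]
    K = len(levels)
    if K <= 1:
        return (1.0, 1.0)
    lc = np.array([left.stats["counts"].get(lv, 0) for lv in levels], dtype=float)
    rc = np.array([right.stats["counts"].get(lv, 0) for lv in levels], dtype=float)
    stat = chi2_independence_stat(lc[None, :], rc[None, :])[0]
    p = float(max(stats.chi2.sf(stat, K - 1), _TINY_P))
    return (p, float(K - 1))


def chi2_independence_stat(left_counts, right_counts):
    """Pearson chi-square of 2xK split-by-class tables (vectorized over rows)."""
    L = np.asarray(left_counts, dtype=float)
    R = np.asarray(right_counts, dtype=float)
    col = L + R
    ln = L.sum(axis=-1, keepdims=True)
    rn = R.sum(axis=-1, keepdims=True)
    n = ln + rn
    with np.errstate(invalid="ignore", divide="ignore"):
        eL = ln * col / np.maximum(n, 1)
        eR = rn * col / np.maximum(n, 1)
        termL = np.where(eL > 0, (L - eL) ** 2 / np.maximum(eL, _EPS), 0.0)
        termR = np.where(eR > 0, (R - eR) ** 2 / np.maximum(eR, _EPS), 0.0)
    return (termL + termR).sum(axis=-1)


def _p_lr(ig: float) -> tuple[float, float]:
    stat = max(ig, 0.0)
    return (float(max(stats.chi2.sf(stat, 1), _TINY_P)), 1.0)


def target_gain(parent: NodeLoss, left: NodeLoss, right: NodeLoss, ttype) -> TargetGain:
    """Raw IG, proportion IG, and p-value for one binary split of one target."""
    from .datamodel import TargetType  # local import to avoid cycle at module load

    ttype = TargetType(ttype)
    if parent.n != left.n + right.n:
        raise MTTreeError(
            f"inconsistent split: parent n={parent.n}, children {left.n}+{right.n}"
        )
    ig = parent.value - (left.value + right.value)
    if parent.deviance <= _EPS:
        prop_ig = 0.0
    else:
        prop_ig = float(np.clip(ig / parent.deviance, 0.0, 1.0))
    if ttype is TargetType.CONTINUOUS:
        p, df = _p_continuous(ig, left.value + right.value, parent.n)
    elif ttype is TargetType.CATEGORICAL:
        p, df = _p_categorical(parent, left, right)
    else:
        p, df = _p_lr(ig)
    return TargetGain(ig=float(ig), prop_ig=prop_ig, p_value=p, df=df)


# ---------------------------------------------------------------------------
# survival time rescaling


@dataclass(frozen=True)
class HazardScaler:
    """Step-function map from raw survival times to cumulative hazard.

    Fitted once at the root with the Nelson–Aalen estimator; replacing each
    time by its estimated cumulative hazard makes the constant-hazard
    (exponential) model exact at the root, so exponential LR split tests are
    well calibrated throughout the tree. Stored with the model so held-out
    survival losses are computed on the training scale.
    """

    times: np.ndarray  # ascending knots
    cumhaz: np.ndarray  # H(t) at each knot (right-continuous step function)

    @classmethod
    def fit(cls, times, events) -> "HazardScaler":
        from lifelines import NelsonAalenFitter

        t = np.asarray(times, dtype=float)
        d = np.asarray(events, dtype=float)
        if d.sum() == 0:
            # no events: hazard identically 0; keep a degenerate positive
            # slope so transformed times stay ordered and non-zero
            tmax = max(float(t.max()), 1.0)
            return cls(times=np.array([0.0, tmax]), cumhaz=np.array([0.0, 1.0]))
        naf = NelsonAalenFitter()
        naf.fit(t, event_observed=d)
        ch = naf.cumulative_hazard_
        knots = ch.index.to_numpy(dtype=float)
        vals = ch.iloc[:, 0].to_numpy(dtype=float)
        return cls(times=knots, cumhaz=vals)

    def transform(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, len(self.cumhaz) - 1)], 0.0)
        return out

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(), "cumhaz": self.cumhaz.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "HazardScaler":
        return cls(
            times=np.asarray(d["times"], dtype=float),
            cumhaz=np.asarray(d["cumhaz"], dtype=float),
        )
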