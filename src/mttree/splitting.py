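"""Candidate split enumeration, multi-target scoring, and split selection.

Features are binarized: numeric features into threshold splits at midpoints
between consecutive distinct values (capped per node), and categorical
features into one level-vs-rest split per level. Every candidate is scored
against all targets at once; the configured ``evalmethod`` turns the
per-target gains/p-values into a single ranking.

Two scoring paths share the same arithmetic helpers: the public
``enumerate_candidates``/``score_candidates`` pair materializes row sets per
candidate (convenient for inspection and for the lookahead recursion on
small nodes), while ``select_split`` scans numeric features with sorted
prefix sums so thousand-row nodes stay fast and only the winning candidate
is materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datamodel import Hyperparameters, MTDataset, TargetSpec, TargetType
from .errors import ConfigurationError
from . import losses
from .losses import HazardScaler, NodeLoss, TargetGain

_EPS = 1e-12
_TINY_P = float(np.finfo(float).tiny)

MAX_NUMERIC_THRESHOLDS = 1024


@dataclass(frozen=True)
class SplitCandidate:
    """One binarized cut: rows go left when value <= threshold (numeric) or
    value == threshold level (categorical); missing values follow the
    recorded majority side."""

    feature: str
    kind: str  # "numeric_threshold" | "level_vs_rest"
    threshold: object
    left_rows: np.ndarray  # global row positions, sorted
    right_rows: np.ndarray
    missing_side: str  # "left" | "right"
    order: tuple = (0, 0)  # (feature index, threshold index) for determinism


@dataclass(frozen=True)
class SplitScore:
    per_target: tuple  # TargetGain per TargetSpec, in spec order
    aggregate: float
    n_significant: int
    n_meaningful: int
    wmean_prop_ig: float
    mean_p_significant: float  # 1.0 when no significant target


@dataclass
class TargetData:
    """Per-target arrays aligned to the full dataset, precomputed once."""

    spec: TargetSpec
    y: np.ndarray
    aux: np.ndarray | None = None  # events (survival) / exposure (count)
    levels: list = field(default_factory=list)
    onehot: np.ndarray | None = None  # n x K indicator (categorical)
    ylogE: np.ndarray | None = None  # y * log(exposure) (count)


def prepare_target_data(
    data: MTDataset, targets: list[TargetSpec], scalers: dict[str, HazardScaler]
) -> list[TargetData]:
    out = []
    for spec in targets:
        col = data.frame[spec.name]
        if spec.ttype is TargetType.CONTINUOUS:
            out.append(TargetData(spec, y=col.to_numpy(dtype=float)))
        elif spec.ttype is TargetType.CATEGORICAL:
            vals = col.to_numpy(dtype=object)
            levels = list(dict.fromkeys(vals.tolist()))
            onehot = np.column_stack([(vals == lv).astype(float) for lv in levels])
            out.append(TargetData(spec, y=vals, levels=levels, onehot=onehot))
        elif spec.ttype is TargetType.COUNT:
            y = col.to_numpy(dtype=float)
            if spec.exposure_col:
                E = data.frame[spec.exposure_col].to_numpy(dtype=float)
            else:
                E = np.ones_like(y)
            out.append(TargetData(spec, y=y, aux=E, ylogE=y * np.log(E)))
        else:  # survival
            t = col.to_numpy(dtype=float)
            scaler = scalers.get(spec.name)
            if scaler is not None:
                t = scaler.transform(t)
            d = data.frame[spec.event_col].to_numpy(dtype=float)
            out.append(TargetData(spec, y=t, aux=d))
    return out


def node_losses(tdatas: list[TargetData], rows: np.ndarray) -> list[NodeLoss]:
    """Per-target NodeLoss for the node made of the given row positions."""
    out = []
    for td in tdatas:
        t = td.spec.ttype
        if t is TargetType.CONTINUOUS:
            out.append(losses.node_loss_continuous(td.y[rows]))
        elif t is TargetType.CATEGORICAL:
            out.append(losses.node_loss_categorical(td.y[rows], levels=td.levels))
        elif t is TargetType.COUNT:
            out.append(losses.node_loss_count(td.y[rows], td.aux[rows]))
        else:
            out.append(losses.node_loss_survival(td.y[rows], td.aux[rows]))
    return out


def _stat_matrix(td: TargetData, rows: np.ndarray) -> np.ndarray:
    """Per-row sufficient-statistic columns whose sums give child losses."""
    t = td.spec.ttype
    if t is TargetType.CONTINUOUS:
        y = td.y[rows]
        return np.column_stack([y, y * y])
    if t is TargetType.CATEGORICAL:
        return td.onehot[rows]
    if t is TargetType.COUNT:
        return np.column_stack([td.y[rows], td.aux[rows], td.ylogE[rows]])
    return np.column_stack([td.aux[rows], td.y[rows]])  # events, scaled times


def _p_value_arrays(ttype: TargetType, ig, within, extra: dict):
    """Vectorized split p-values; returns (p array, df)."""
    ig_pos = np.maximum(np.asarray(ig, dtype=float), 0.0)
    if ttype is TargetType.CONTINUOUS:
        n = extra["n"]
        df2 = n - 2
        if df2 <= 0:
            return np.ones_like(ig_pos), float(max(df2, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(within > _EPS, ig_pos / np.maximum(within, _EPS) * df2, np.inf)
        p = np.where(
            ig_pos <= 0,
            1.0,
            np.where(
                np.isinf(F), _TINY_P, sps.f.sf(np.where(np.isfinite(F), F, 0.0), 1, df2)
            ),
        )
        return np.maximum(p, _TINY_P), float(df2)
    if ttype is TargetType.CATEGORICAL:
        K = extra["K"]
        if K <= 1:
            return np.ones_like(ig_pos), 1.0
        stat = losses.chi2_independence_stat(extra["LC"], extra["RC"])
        return np.maximum(sps.chi2.sf(stat, K - 1), _TINY_P), float(K - 1)
    return np.maximum(sps.chi2.sf(ig_pos, 1), _TINY_P), 1.0


def _aggregate_arrays(prop, pvals, tdatas, node_loss_list, hp):
    """Per-candidate aggregate statistics from T x C gain/p matrices."""
    C = prop.shape[1]
    weights = np.array([td.spec.weight for td in tdatas])
    weighted = weights > 0
    pure = np.array([nl.deviance <= _EPS for nl in node_loss_list])
    agg_mask = weighted & ~pure  # pure-parent targets excluded from IG mixing
    wsum = weights[agg_mask].sum()
    if wsum > 0:
        wmean = (weights[agg_mask, None] * prop[agg_mask]).sum(axis=0) / wsum
    else:
        wmean = np.zeros(C)
    sig = (pvals <= hp.alpha) & weighted[:, None]
    meaningful = (prop >= hp.IGcutoff) & agg_mask[:, None]
    n_sig = sig.sum(axis=0)
    n_mean = meaningful.sum(axis=0)
    mean_p_sig = np.where(n_sig > 0, (pvals * sig).sum(axis=0) / np.maximum(n_sig, 1), 1.0)

    method = hp.evalmethod
    if method in ("avgIG", "splitError"):
        agg = wmean
    elif method == "maxIG":
        agg = prop[weighted].max(axis=0) if weighted.any() else np.zeros(C)
    elif method == "mostIG":
        agg = n_mean.astype(float)
    elif method == "avgPVal":
        agg = np.where(n_sig > 0, mean_p_sig, np.inf)
    elif method == "minPVal":
        pw = np.where(weighted[:, None], pvals, np.inf)
        agg = pw.min(axis=0) / np.maximum(1, n_sig)
    elif method == "mostPVal":
        agg = n_sig.astype(float)
    else:
        raise ConfigurationError(f"unknown evalmethod {method!r}")
    return {
        "agg": agg,
        "wmean": wmean,
        "n_sig": n_sig,
        "n_mean": n_mean,
        "mean_p_sig": mean_p_sig,
    }


def _head_key(method: str, aggs: dict, i: int) -> tuple:
    if method in ("avgIG", "splitError", "maxIG"):
        return (aggs["agg"][i],)
    if method == "mostIG":
        return (aggs["n_mean"][i], aggs["wmean"][i])
    if method == "avgPVal" or method == "minPVal":
        return (-aggs["agg"][i],)
    return (aggs["n_sig"][i], -aggs["mean_p_sig"][i])  # mostPVal


# ---------------------------------------------------------------------------
# enumeration (materialized candidates)


def _numeric_thresholds(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values[~np.isnan(values)])
    if uniq.size < 2:
        return np.empty(0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if mids.size > MAX_NUMERIC_THRESHOLDS:
        idx = np.unique(
            np.linspace(0, mids.size - 1, MAX_NUMERIC_THRESHOLDS).round().astype(int)
        )
        mids = mids[idx]
    return mids


def enumerate_candidates(
    data: MTDataset,
    rows: np.ndarray,
    used_features: frozenset | set = frozenset(),
    hp: Hyperparameters = Hyperparameters(),
) -> list[SplitCandidate]:
    """All admissible binarized splits of the node, in deterministic order.

    Candidates whose either side (missing rows included) would fall below
    ``hp.splitmin`` are removed. When ``hp.reuse`` is false, features already
    used on the path are skipped.
    """
    rows = np.asarray(rows)
    out: list[SplitCandidate] = []
    for f_idx, col in enumerate(data.feature_cols):
        if not hp.reuse and col in used_features:
            continue
        kind = data.feature_kinds[col]
        vals = data.feature_values(col)[rows]
        if kind == "numeric":
            for t_idx, thr in enumerate(_numeric_thresholds(vals)):
                cand = _materialize(data, rows, col, "numeric_threshold", float(thr), (f_idx, t_idx), hp.splitmin)
                if cand is not None:
                    out.append(cand)
        else:
            node_levels = [lv for lv in data.level_orders.get(col, []) if (vals == lv).any()]
            for t_idx, lv in enumerate(node_levels):
                cand = _materialize(data, rows, col, "level_vs_rest", lv, (f_idx, t_idx), hp.splitmin)
                if cand is not None:
                    out.append(cand)
    return out


def _materialize(data, rows, col, kind, thr, order, splitmin) -> SplitCandidate | None:
    """Build the row sets of one candidate (missing rows to the larger side)."""
    vals = data.feature_values(col)[rows]
    if kind == "numeric_threshold":
        miss = np.isnan(vals)
        left = ~miss & (vals <= thr)
        right = ~miss & (vals > thr)
    else:
        miss = np.array([v is None for v in vals], dtype=bool)
        left = ~miss & (vals == thr)
        right = ~miss & ~left
    side = "left"
    if miss.any():
        if left.sum() >= right.sum():
            left = left | miss
        else:
            right = right | miss
            side = "right"
    nl, nr = int(left.sum()), int(right.sum())
    if nl < splitmin or nr < splitmin or nl == 0 or nr == 0:
        return None
    return SplitCandidate(
        feature=col,
        kind=kind,
        threshold=thr,
        left_rows=rows[left],
        right_rows=rows[right],
        missing_side=side,
        order=order,
    )


# ---------------------------------------------------------------------------
# scoring of materialized candidates


def score_candidates(
    cands: list[SplitCandidate],
    tdatas: list[TargetData],
    node_loss_list: list[NodeLoss],
    hp: Hyperparameters,
    rows: np.ndarray,
) -> list[SplitScore]:
    """SplitScore for every candidate, vectorized across candidates."""
    if not cands:
        return []
    rows = np.asarray(rows)
    sorter = np.argsort(rows, kind="stable")
    rows_sorted = rows[sorter]
    n = len(rows)
    C = len(cands)
    M = np.zeros((C, n))
    for i, c in enumerate(cands):
        M[i, sorter[np.searchsorted(rows_sorted, c.left_rows)]] = 1.0
    nL = M.sum(axis=1)

    T = len(tdatas)
    prop = np.zeros((T, C))
    igs = np.zeros((T, C))
    pvals = np.ones((T, C))
    dfs = np.ones(T)
    for ti, (td, parent) in enumerate(zip(tdatas, node_loss_list)):
        S = _stat_matrix(td, rows)
        L = M @ S
        ig, pr, p, df = _gain_arrays_with_totals(td, parent, S, L, nL)
        igs[ti], prop[ti], pvals[ti], dfs[ti] = ig, pr, p, df

    aggs = _aggregate_arrays(prop, pvals, tdatas, node_loss_list, hp)
    scores = []
    for i in range(C):
        per_target = tuple(
            TargetGain(
                ig=float(igs[ti, i]),
                prop_ig=float(prop[ti, i]),
                p_value=float(pvals[ti, i]),
                df=float(dfs[ti]),
            )
            for ti in range(T)
        )
        scores.append(
            SplitScore(
                per_target=per_target,
                aggregate=float(aggs["agg"][i]),
                n_significant=int(aggs["n_sig"][i]),
                n_meaningful=int(aggs["n_mean"][i]),
                wmean_prop_ig=float(aggs["wmean"][i]),
                mean_p_significant=float(aggs["mean_p_sig"][i]),
            )
        )
    return scores


def _gain_arrays_with_totals(td, parent, S, L, nL):
    """Gain arrays using explicit per-node stat totals (robust to parents
    deserialized without sufficient statistics)."""
    total = S.sum(axis=0)
    R = total[None, :] - L
    nR = parent.n - nL
    t = td.spec.ttype
    if t is TargetType.CONTINUOUS:
        ll = losses.continuous_loss_from_sums(nL, L[:, 0], L[:, 1])
        rl = losses.continuous_loss_from_sums(nR, R[:, 0], R[:, 1])
        extra = {"n": parent.n}
    elif t is TargetType.CATEGORICAL:
        ll = losses.categorical_loss_from_counts(L)
        rl = losses.categorical_loss_from_counts(R)
        present = total > 0
        extra = {"LC": L[:, present], "RC": R[:, present], "K": int(present.sum())}
    elif t is TargetType.COUNT:
        ll = losses.count_loss_from_sums(L[:, 0], L[:, 2], L[:, 1])
        rl = losses.count_loss_from_sums(R[:, 0], R[:, 2], R[:, 1])
        extra = {}
    else:
        ll = losses.survival_loss_from_sums(L[:, 0], L[:, 1])
        rl = losses.survival_loss_from_sums(R[:, 0], R[:, 1])
        extra = {}
    ig = parent.value - (ll + rl)
    dev = parent.deviance
    prop = np.clip(ig / dev, 0.0, 1.0) if dev > _EPS else np.zeros_like(ig)
    p, df = _p_value_arrays(t, ig, ll + rl, extra)
    return ig, prop, p, df


def score_candidate(
    cand: SplitCandidate,
    tdatas: list[TargetData],
    node_loss_list: list[NodeLoss],
    hp: Hyperparameters,
    rows: np.ndarray,
) -> SplitScore:
    return score_candidates([cand], tdatas, node_loss_list, hp, rows)[0]


def ranking_key(cand: SplitCandidate, score: SplitScore, method: str) -> tuple:
    """Comparison key under which larger is better; embeds all tie-breaks."""
    aggs = {
        "agg": [score.aggregate],
        "wmean": [score.wmean_prop_ig],
        "n_sig": [score.n_significant],
        "n_mean": [score.n_meaningful],
        "mean_p_sig": [score.mean_p_significant],
    }
    return _head_key(method, aggs, 0) + (
        score.wmean_prop_ig,
        -cand.order[0],
        -cand.order[1],
    )


# ---------------------------------------------------------------------------
# fast whole-node scan (selection path)


@dataclass
class _LightCandidate:
    feature: str
    kind: str
    threshold: object
    order: tuple
    index: int  # column in the concatenated score arrays


def _scan_node(data, rows, tdatas, node_loss_list, hp, used_features):
    """Score every admissible split without materializing row sets.

    Returns (light candidates, aggregate arrays dict, prop/p matrices).
    """
    rows = np.asarray(rows)
    n = len(rows)
    stats = [_stat_matrix(td, rows) for td in tdatas]
    totals = [S.sum(axis=0) for S in stats]

    lights: list[_LightCandidate] = []
    L_blocks = [[] for _ in tdatas]  # per target, list of (C_f x m) blocks
    nL_blocks: list[np.ndarray] = []

    for f_idx, col in enumerate(data.feature_cols):
        if not hp.reuse and col in used_features:
            continue
        kind = data.feature_kinds[col]
        vals = data.feature_values(col)[rows]
        if kind == "numeric":
            miss = np.isnan(vals)
            thresholds = _numeric_thresholds(vals)
            if thresholds.size == 0:
                continue
            nonmiss_idx = np.flatnonzero(~miss)
            order = nonmiss_idx[np.argsort(vals[nonmiss_idx], kind="stable")]
            sv = vals[order]
            ks = np.searchsorted(sv, thresholds, side="right")
            n_miss = int(miss.sum())
            n_nonmiss = len(order)
            nl0 = ks.astype(float)
            nr0 = n_nonmiss - nl0
            left_gets_miss = nl0 >= nr0
            nL = nl0 + n_miss * left_gets_miss
            nR = n - nL
            valid = (nL >= hp.splitmin) & (nR >= hp.splitmin) & (nL > 0) & (nR > 0)
            if not valid.any():
                continue
            sel = np.flatnonzero(valid)
            for t_idx in sel:
                lights.append(
                    _LightCandidate(col, "numeric_threshold", float(thresholds[t_idx]), (f_idx, int(t_idx)), -1)
                )
            for ti, S in enumerate(stats):
                Ssort = S[order]
                cum = np.vstack([np.zeros((1, S.shape[1])), np.cumsum(Ssort, axis=0)])
                Lmat = cum[ks[sel]]
                if n_miss:
                    miss_sum = S[miss].sum(axis=0)
                    Lmat = Lmat + np.outer(left_gets_miss[sel].astype(float), miss_sum)
                L_blocks[ti].append(Lmat)
            nL_blocks.append(nL[sel])
        else:
            miss = np.array([v is None for v in vals], dtype=bool)
            node_levels = [lv for lv in data.level_orders.get(col, []) if (vals == lv).any()]
            for t_idx, lv in enumerate(node_levels):
                left = ~miss & (vals == lv)
                right = ~miss & ~left
                gets_miss = left.sum() >= right.sum()
                nl = int(left.sum()) + (int(miss.sum()) if gets_miss else 0)
                nr = n - nl
                if nl < hp.splitmin or nr < hp.splitmin or nl == 0 or nr == 0:
                    continue
                if gets_miss:
                    left = left | miss
                lights.append(
                    _LightCandidate(col, "level_vs_rest", lv, (f_idx, t_idx), -1)
                )
                for ti, S in enumerate(stats):
                    L_blocks[ti].append(S[left].sum(axis=0)[None, :])
                nL_blocks.append(np.array([nl], dtype=float))

    if not lights:
        return [], None, None, None
    for i, lc in enumerate(lights):
        lc.index = i
    nL = np.concatenate(nL_blocks)
    T = len(tdatas)
    C = len(lights)
    prop = np.zeros((T, C))
    pvals = np.ones((T, C))
    for ti, (td, parent) in enumerate(zip(tdatas, node_loss_list)):
        L = np.vstack(L_blocks[ti])
        _, pr, p, _ = _gain_arrays_with_totals(td, parent, stats[ti], L, nL)
        prop[ti], pvals[ti] = pr, p
    aggs = _aggregate_arrays(prop, pvals, tdatas, node_loss_list, hp)
    return lights, aggs, prop, pvals


# ---------------------------------------------------------------------------
# selection


def lookahead_error(
    subtree_leaves: list[list[NodeLoss]],
    root_losses: list[NodeLoss],
    targets: list[TargetSpec],
) -> float:
    """Normalized multi-target error of a subtree partition of a node.

    ``sum_t w_t * (sum_leaf dev_t / root_dev_t) / sum_t w_t``; a target with
    zero root deviance contributes 0. Deviances (losses net of the per-node
    saturated constant) are used so each term lies in [0, 1].
    """
    num = 0.0
    den = 0.0
    for ti, spec in enumerate(targets):
        if spec.weight <= 0:
            continue
        den += spec.weight
        root = root_losses[ti].deviance
        if root <= _EPS:
            continue
        leaf_sum = sum(leaf[ti].deviance for leaf in subtree_leaves)
        num += spec.weight * min(leaf_sum / root, 1.0)
    return num / den if den > 0 else 0.0


def _select_stepwise(cands, scores, hp, method=None):
    method = method or hp.evalmethod
    best = None
    for cand, score in zip(cands, scores):
        if score.wmean_prop_ig < hp.cp:  # cp acceptance gate
            continue
        key = ranking_key(cand, score, method)
        if best is None or key > best[0]:
            best = (key, cand, score)
    if best is None:
        return None
    return best[1], best[2]


def _lookahead_leaves(data, rows, tdatas, used, hp_avg, depth_left) -> list[list[NodeLoss]]:
    nl = node_losses(tdatas, rows)
    if depth_left <= 0 or len(rows) < hp_avg.nodesize:
        return [nl]
    cands = enumerate_candidates(data, rows, used, hp_avg)
    if not cands:
        return [nl]
    scores = score_candidates(cands, tdatas, nl, hp_avg, rows)
    sel = _select_stepwise(cands, scores, hp_avg, method="avgIG")
    if sel is None:
        return [nl]
    cand, _ = sel
    used2 = used | {cand.feature}
    left = _lookahead_leaves(data, cand.left_rows, tdatas, used2, hp_avg, depth_left - 1)
    right = _lookahead_leaves(data, cand.right_rows, tdatas, used2, hp_avg, depth_left - 1)
    return left + right


def select_split(
    data: MTDataset,
    rows: np.ndarray,
    tdatas: list[TargetData],
    node_loss_list: list[NodeLoss],
    used_features: frozenset | set,
    hp: Hyperparameters,
) -> tuple[SplitCandidate, SplitScore] | None:
    """Best split of the node under the configured evalmethod, or None (leaf).

    For ``splitError`` the top ``parallelsplit`` candidates by immediate
    average proportion IG are each expanded into an avgIG subtree of depth
    ``paralleldepth``; the candidate whose subtree has the smallest
    multi-target error wins, provided its immediate average proportion IG
    passes the cp gate.
    """
    rows = np.asarray(rows)
    lights, aggs, prop, pvals = _scan_node(
        data, rows, tdatas, node_loss_list, hp, used_features
    )
    if not lights:
        return None

    def full_key(i: int) -> tuple:
        lc = lights[i]
        return _head_key(hp.evalmethod, aggs, i) + (
            aggs["wmean"][i],
            -lc.order[0],
            -lc.order[1],
        )

    if hp.evalmethod != "splitError":
        best = None
        for i in range(len(lights)):
            if aggs["wmean"][i] < hp.cp:
                continue
            key = full_key(i)
            if best is None or key > best[0]:
                best = (key, i)
        if best is None:
            return None
        return _materialize_scored(data, rows, lights[best[1]], tdatas, node_loss_list, hp)

    # splitError: lookahead over the top-parallelsplit candidates by avgIG
    def avg_key(i: int) -> tuple:
        lc = lights[i]
        return (aggs["wmean"][i], -lc.order[0], -lc.order[1])

    ranked = sorted(range(len(lights)), key=avg_key, reverse=True)
    top = ranked[: hp.parallelsplit]
    hp_avg = hp.replace(evalmethod="avgIG")
    best = None
    for rank_pos, i in enumerate(top):
        cand = _materialize(
            data, rows, lights[i].feature, lights[i].kind, lights[i].threshold,
            lights[i].order, hp.splitmin,
        )
        leaves = _lookahead_leaves(
            data, cand.left_rows, tdatas, set(used_features) | {cand.feature},
            hp_avg, hp.paralleldepth - 1,
        ) + _lookahead_leaves(
            data, cand.right_rows, tdatas, set(used_features) | {cand.feature},
            hp_avg, hp.paralleldepth - 1,
        )
        err = lookahead_error(leaves, node_loss_list, [td.spec for td in tdatas])
        if best is None or err < best[0] - _EPS:
            best = (err, i, cand)
    _, i, cand = best
    if aggs["wmean"][i] < hp.cp:
        return None
    score = score_candidate(cand, tdatas, node_loss_list, hp, rows)
    return cand, score


def _materialize_scored(data, rows, light, tdatas, node_loss_list, hp):
    cand = _materialize(
        data, rows, light.feature, light.kind, light.threshold, light.order, hp.splitmin
    )
    score = score_candidate(cand, tdatas, node_loss_list, hp, rows)
    return cand, score
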