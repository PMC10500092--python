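"""Recursive multi-target tree growth, prediction, held-out evaluation, and
model (de)serialization.

A node becomes a leaf when the depth limit is reached, when it has fewer
rows than ``nodesize``, or when no candidate split passes the cp gate.
Survival times are rescaled once at the root (Nelson–Aalen cumulative
hazard) and the scaling map travels with the model so held-out survival
losses are computed on the training scale. There is no post-pruning: cp acts
only as a pre-pruning gate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd

from .datamodel import Hyperparameters, MTDataset, TargetSpec, TargetType
from .errors import ConfigurationError, DataParseError, SchemaError, UnsupportedVersionError
from . import losses as losses_mod
from . import splitting
from .losses import HazardScaler, NodeLoss
from .splitting import SplitCandidate, SplitScore, TargetData

logger = logging.getLogger(__name__)

_EPS = 1e-12

SCHEMA_VERSION = 1


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n: int
    per_target_loss: list[NodeLoss]
    summaries: list[dict]
    split: SplitCandidate | None = None
    score: SplitScore | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    rows: np.ndarray | None = None  # training row positions (not serialized)

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class TreeModel:
    root: TreeNode
    targets: list[TargetSpec]
    hp: Hyperparameters
    feature_cols: list[str]
    feature_kinds: dict[str, str]
    level_orders: dict[str, list]
    scalers: dict[str, HazardScaler] = field(default_factory=dict)

    def nodes(self) -> list[TreeNode]:
        """All nodes in level order (matches node_id assignment)."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            if node.children:
                queue.extend(node.children)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def max_depth(self) -> int:
        return max(n.depth for n in self.nodes())


@dataclass
class EvalReport:
    per_target: dict[str, dict]
    overall: float
    n_leaves: int
    leaf_assignment: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "per_target": self.per_target,
            "overall": self.overall,
            "n_leaves": self.n_leaves,
            "leaf_assignment": {str(k): v for k, v in self.leaf_assignment.items()},
        }


# ---------------------------------------------------------------------------
# summaries


def _leaf_summary(td: TargetData, rows: np.ndarray, loss: NodeLoss) -> dict:
    t = td.spec.ttype
    if t is TargetType.CONTINUOUS:
        return {"mean": float(np.mean(td.y[rows])), "n": int(len(rows))}
    if t is TargetType.CATEGORICAL:
        counts = loss.stats["counts"]
        total = sum(counts.values())
        props = {str(lv): c / total for lv, c in counts.items()}
        mode = max(counts.items(), key=lambda kv: (kv[1], -td.levels.index(kv[0])))[0]
        return {"mode": str(mode), "proportions": props}
    if t is TargetType.COUNT:
        events, exposure = loss.stats["events"], loss.stats["exposure"]
        return {"rate": events / exposure if exposure > 0 else 0.0, "exposure": exposure}
    events, time = loss.stats["events"], loss.stats["time"]
    return {"rate": events / time if time > 0 else 0.0, "events": events}


# ---------------------------------------------------------------------------
# growth


def grow(
    data: MTDataset,
    targets: list[TargetSpec] | None = None,
    hp: Hyperparameters | None = None,
) -> TreeModel:
    """Grow a multi-target tree on a validated dataset."""
    targets = list(targets) if targets is not None else list(data.targets)
    hp = hp if hp is not None else Hyperparameters()
    if not any(s.weight > 0 for s in targets):
        raise ConfigurationError("at least one target must have weight > 0")

    scalers: dict[str, HazardScaler] = {}
    for spec in targets:
        if spec.ttype is TargetType.SURVIVAL:
            scalers[spec.name] = HazardScaler.fit(
                data.frame[spec.name].to_numpy(dtype=float),
                data.frame[spec.event_col].to_numpy(dtype=float),
            )
    tdatas = splitting.prepare_target_data(data, targets, scalers)

    def build(rows: np.ndarray, depth: int, used: frozenset) -> TreeNode:
        nl = splitting.node_losses(tdatas, rows)
        node = TreeNode(
            node_id=-1,
            depth=depth,
            n=len(rows),
            per_target_loss=nl,
            summaries=[_leaf_summary(td, rows, l) for td, l in zip(tdatas, nl)],
            rows=rows,
        )
        if depth >= hp.d or len(rows) < hp.nodesize:
            return node
        sel = splitting.select_split(data, rows, tdatas, nl, used, hp)
        if sel is None:
            return node
        cand, score = sel
        node.split = cand
        node.score = score
        used2 = used | {cand.feature}
        node.children = (
            build(cand.left_rows, depth + 1, used2),
            build(cand.right_rows, depth + 1, used2),
        )
        return node

    root = build(np.asarray(data.row_ids), 0, frozenset())
    model = TreeModel(
        root=root,
        targets=targets,
        hp=hp,
        feature_cols=list(data.feature_cols),
        feature_kinds=dict(data.feature_kinds),
        level_orders={k: list(v) for k, v in data.level_orders.items()},
        scalers=scalers,
    )
    for i, node in enumerate(model.nodes()):
        node.node_id = i
    return model


# ---------------------------------------------------------------------------
# prediction


def _feature_arrays(model: TreeModel, frame: pd.DataFrame) -> dict[str, np.ndarray]:
    missing_cols = [c for c in model.feature_cols if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"input is missing required feature column(s): {missing_cols}")
    arrays = {}
    for col in model.feature_cols:
        if model.feature_kinds[col] == "numeric":
            arrays[col] = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        else:
            vals = frame[col].to_numpy(dtype=object)
            isna = pd.isna(frame[col]).to_numpy()
            vals = np.where(isna, None, vals)
            known = set(model.level_orders.get(col, []))
            unseen = sum(1 for v in vals if v is not None and v not in known)
            if unseen:
                logger.info(
                    "feature %r: %d value(s) with unseen level routed to 'rest' side",
                    col,
                    unseen,
                )
            arrays[col] = vals
    return arrays


def apply(model: TreeModel, frame: pd.DataFrame) -> np.ndarray:
    """Leaf node_id reached by every row of a feature table."""
    arrays = _feature_arrays(model, frame)
    n = len(frame)
    out = np.full(n, -1, dtype=int)

    def route(node: TreeNode, idx: np.ndarray):
        if node.is_leaf:
            out[idx] = node.node_id
            return
        cand = node.split
        vals = arrays[cand.feature][idx]
        if cand.kind == "numeric_threshold":
            miss = np.isnan(vals.astype(float))
            left = ~miss & (vals.astype(float) <= cand.threshold)
        else:
            miss = np.array([v is None for v in vals], dtype=bool)
            left = ~miss & (vals == cand.threshold)
        if cand.missing_side == "left":
            left = left | miss
        route(node.children[0], idx[left])
        route(node.children[1], idx[~left])

    route(model.root, np.arange(n))
    return out


def predict(model: TreeModel, frame: pd.DataFrame) -> pd.DataFrame:
    """Per-row per-target predictions from the leaf summaries.

    Continuous targets yield the leaf mean, categorical the modal level,
    count and survival the leaf rate.
    """
    leaf_ids = apply(model, frame)
    by_id = {n.node_id: n for n in model.leaves()}
    cols = {}
    for ti, spec in enumerate(model.targets):
        key = {
            TargetType.CONTINUOUS: "mean",
            TargetType.CATEGORICAL: "mode",
            TargetType.COUNT: "rate",
            TargetType.SURVIVAL: "rate",
        }[spec.ttype]
        cols[spec.name] = [by_id[i].summaries[ti][key] for i in leaf_ids]
    out = pd.DataFrame(cols, index=frame.index)
    out["leaf_id"] = leaf_ids
    return out


# ---------------------------------------------------------------------------
# evaluation


def _prediction_loss(td: TargetData, summaries: list[dict], leaf_of_row: np.ndarray) -> float:
    """Total predictive loss of per-row leaf summaries on one target.

    Uses the unit-deviance form of each loss family (squared error / Brier /
    Poisson deviance / exponential deviance), so on the fitting data this
    equals the partition loss, while on held-out data mis-fitted summaries
    are properly penalized.
    """
    t = td.spec.ttype
    if t is TargetType.CONTINUOUS:
        pred = np.array([summaries[i]["mean"] for i in leaf_of_row])
        return float(((td.y - pred) ** 2).sum())
    if t is TargetType.CATEGORICAL:
        # Brier score against leaf proportion vectors; equals size-weighted
        # Gini when the proportions were fitted on these same rows
        sumsq = np.array(
            [sum(p * p for p in summaries[i]["proportions"].values()) for i in leaf_of_row]
        )
        p_true = np.array(
            [
                summaries[i]["proportions"].get(str(yv), 0.0)
                for i, yv in zip(leaf_of_row, td.y)
            ]
        )
        return float((1.0 - 2.0 * p_true + sumsq).sum())
    if t is TargetType.COUNT:
        rate = np.array([summaries[i]["rate"] for i in leaf_of_row])
        mu = np.maximum(rate * td.aux, 1e-300)
        y = td.y
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        return float((2.0 * (term - (y - mu))).sum())
    rate = np.array([summaries[i]["rate"] for i in leaf_of_row])
    t_scaled, d = td.y, td.aux
    lam_t = np.maximum(rate * t_scaled, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(d > 0, d * np.log(np.maximum(d, 1e-300) / lam_t), 0.0)
    return float((2.0 * (term - (d - lam_t))).sum())


def evaluate(
    model: TreeModel, data: MTDataset, targets: list[TargetSpec] | None = None
) -> EvalReport:
    """Held-out evaluation: per-target predictive losses plus a normalized
    overall error (1.0 for a single-leaf model by construction).

    The overall error divides each target's predictive loss (training leaf
    summaries applied to this data) by the loss of the corresponding
    single-leaf predictor (training root summaries on this data), then takes
    the weight-normalized mean.
    """
    targets = list(targets) if targets is not None else list(model.targets)
    tdatas = splitting.prepare_target_data(data, targets, model.scalers)
    leaf_ids = apply(model, data.frame)
    preds = predict(model, data.frame)
    all_rows = np.arange(data.n_rows)
    groups = [all_rows[leaf_ids == n.node_id] for n in model.leaves()]
    leaf_index = {n.node_id: i for i, n in enumerate(model.leaves())}
    leaf_of_row = np.array([leaf_index[i] for i in leaf_ids])

    per_target: dict[str, dict] = {}
    num = 0.0
    den = 0.0
    for ti, spec in enumerate(targets):
        td = tdatas[ti]
        p = preds[spec.name].to_numpy()
        metrics: dict = {}
        if spec.ttype is TargetType.CONTINUOUS:
            y = td.y
            sse = float(((y - p.astype(float)) ** 2).sum())
            metrics["rmse"] = float(np.sqrt(sse / len(y)))
            sst = float(((y - y.mean()) ** 2).sum())
            metrics["r2"] = (1.0 - sse / sst) if sst > _EPS else None
        elif spec.ttype is TargetType.CATEGORICAL:
            y = td.y
            metrics["accuracy"] = float(np.mean(y == p))
            metrics["gini"] = float(
                sum(
                    losses_mod.node_loss_categorical(y[g], levels=td.levels).value
                    for g in groups
                    if len(g) > 0
                )
            )
        elif spec.ttype is TargetType.COUNT:
            y, E = td.y, td.aux
            mu = np.maximum(p.astype(float) * E, 1e-300)
            with np.errstate(invalid="ignore", divide="ignore"):
                term = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
            dev = 2.0 * (term - (y - mu))
            metrics["mean_poisson_deviance"] = float(dev.mean())
        else:
            t, d = td.y, td.aux
            lam_t = np.maximum(p.astype(float) * t, 1e-300)
            with np.errstate(invalid="ignore", divide="ignore"):
                term = np.where(d > 0, d * np.log(np.maximum(d, 1e-300) / lam_t), 0.0)
            dev = 2.0 * (term - (d - np.minimum(lam_t, 1e300)))
            metrics["mean_exponential_deviance"] = float(dev.mean())
        per_target[spec.name] = metrics
        if spec.weight > 0:
            den += spec.weight
            leaf_summ = [n.summaries[ti] for n in model.leaves()]
            root_summ = [model.root.summaries[ti]]
            model_loss = _prediction_loss(td, leaf_summ, leaf_of_row)
            root_loss = _prediction_loss(td, root_summ, np.zeros(data.n_rows, dtype=int))
            if root_loss > _EPS:
                num += spec.weight * (model_loss / root_loss)

    overall = num / den if den > 0 else 0.0
    assignment = {int(r): int(l) for r, l in zip(data.row_ids, leaf_ids)}
    return EvalReport(
        per_target=per_target,
        overall=float(overall),
        n_leaves=model.n_leaves,
        leaf_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: TargetSpec) -> dict:
    return {
        "name": spec.name,
        "type": spec.ttype.value,
        "weight": spec.weight,
        "event": spec.event_col,
        "exposure": spec.exposure_col,
    }


def _spec_from_dict(d: dict) -> TargetSpec:
    return TargetSpec(
        name=d["name"],
        ttype=TargetType(d["type"]),
        weight=float(d["weight"]),
        event_col=d.get("event"),
        exposure_col=d.get("exposure"),
    )


def serialize(model: TreeModel) -> str:
    nodes = []
    for node in model.nodes():
        entry = {
            "id": node.node_id,
            "depth": node.depth,
            "n": node.n,
            "summaries": node.summaries,
            "losses": [
                {"value": l.value, "n": l.n} for l in node.per_target_loss
            ],
            "split": None,
            "children": None,
        }
        if not node.is_leaf:
            entry["split"] = {
                "feature": node.split.feature,
                "kind": node.split.kind,
                "threshold": node.split.threshold,
                "missing_side": node.split.missing_side,
            }
            entry["children"] = [c.node_id for c in node.children]
        nodes.append(entry)
    doc = {
        "format": "mttree-model",
        "schema_version": SCHEMA_VERSION,
        "hyperparameters": model.hp.to_dict(),
        "targets": [_spec_to_dict(s) for s in model.targets],
        "features": {
            "columns": model.feature_cols,
            "kinds": model.feature_kinds,
            "levels": {k: list(v) for k, v in model.level_orders.items()},
        },
        "scalers": {k: v.to_dict() for k, v in model.scalers.items()},
        "nodes": nodes,
    }
    return json.dumps(doc, indent=1)


def deserialize(document: str) -> TreeModel:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise DataParseError(f"invalid or truncated model document: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "mttree-model":
        raise DataParseError("not a model document")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise UnsupportedVersionError(
            f"unsupported model schema version {doc.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    hp = Hyperparameters(**doc["hyperparameters"])
    targets = [_spec_from_dict(d) for d in doc["targets"]]
    by_id: dict[int, TreeNode] = {}
    for entry in doc["nodes"]:
        by_id[entry["id"]] = TreeNode(
            node_id=entry["id"],
            depth=entry["depth"],
            n=entry["n"],
            per_target_loss=[
                NodeLoss(value=l["value"], n=l["n"], stats={}) for l in entry["losses"]
            ],
            summaries=entry["summaries"],
        )
    for entry in doc["nodes"]:
        node = by_id[entry["id"]]
        if entry["split"] is not None:
            s = entry["split"]
            node.split = SplitCandidate(
                feature=s["feature"],
                kind=s["kind"],
                threshold=s["threshold"],
                left_rows=np.empty(0, dtype=int),
                right_rows=np.empty(0, dtype=int),
                missing_side=s["missing_side"],
            )
            node.children = tuple(by_id[c] for c in entry["children"])
    if 0 not in by_id:
        raise DataParseError("model document has no root node")
    feats = doc["features"]
    return TreeModel(
        root=by_id[0],
        targets=targets,
        hp=hp,
        feature_cols=list(feats["columns"]),
        feature_kinds=dict(feats["kinds"]),
        level_orders={k: list(v) for k, v in feats["levels"].items()},
        scalers={k: HazardScaler.from_dict(v) for k, v in doc["scalers"].items()},
    )
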