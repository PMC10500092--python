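"""Grid-search hyperparameter tuning with k-fold cross-validation.

Folds are drawn once per tuning call and shared by every grid combination,
so per-combination errors are paired. The objective is the weight-normalized
overall error of :func:`mttree.tree.evaluate`; the best combination is the
one minimizing mean error, with ties broken toward simpler models (smaller
``d``, then larger ``cp``, then first in grid order).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .datamodel import Hyperparameters, MTDataset, TargetSpec, TargetType
from .errors import ConfigurationError
from . import tree as tree_mod


@dataclass
class Grid:
    values: dict[str, list]  # hyperparameter name -> candidate values
    k: int = 5
    seed: int = 42
    base: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError(f"k must be >= 2, got {self.k}")
        valid = set(Hyperparameters().to_dict())
        unknown = set(self.values) - valid
        if unknown:
            raise ConfigurationError(f"unknown grid hyperparameter(s): {sorted(unknown)}")
        if any(len(v) == 0 for v in self.values.values()):
            raise ConfigurationError("every grid axis needs at least one value")

    def combinations(self) -> list[Hyperparameters]:
        keys = list(self.values)
        out = []
        for combo in itertools.product(*(self.values[k] for k in keys)):
            out.append(self.base.replace(**dict(zip(keys, combo))))
        return out


@dataclass
class TuneResult:
    combinations: list[Hyperparameters]
    fold_errors: np.ndarray  # combinations x folds
    mean: np.ndarray
    sd: np.ndarray
    best_index: int

    @property
    def best(self) -> Hyperparameters:
        return self.combinations[self.best_index]

    def to_dict(self) -> dict:
        rows = []
        for i, hp in enumerate(self.combinations):
            rows.append(
                {
                    "params": hp.to_dict(),
                    "fold_errors": [float(e) for e in self.fold_errors[i]],
                    "mean": float(self.mean[i]),
                    "sd": float(self.sd[i]),
                }
            )
        return {"table": rows, "best": self.best.to_dict(), "best_index": self.best_index}


def make_folds(
    data: MTDataset, k: int, targets: list[TargetSpec] | None = None, seed: int = 42
) -> list[np.ndarray]:
    """k disjoint row-position sets covering the data, sizes differing by <= 1.

    Stratified on the first weighted categorical target when one exists,
    otherwise uniform at random; deterministic given the seed.
    """
    targets = list(targets) if targets is not None else list(data.targets)
    n = data.n_rows
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the number of rows ({n})")
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    strat = next(
        (s for s in targets if s.weight > 0 and s.ttype is TargetType.CATEGORICAL), None
    )
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    if strat is not None:
        labels = data.frame[strat.name].to_numpy(dtype=object)
        for lv in dict.fromkeys(labels.tolist()):
            members = np.flatnonzero(labels == lv)
            members = members[rng.permutation(len(members))]
            for m in members:  # continue dealing round-robin across classes
                folds[cursor % k].append(int(m))
                cursor += 1
    else:
        order = rng.permutation(n)
        for m in order:
            folds[cursor % k].append(int(m))
            cursor += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _subset(data: MTDataset, rows: np.ndarray) -> MTDataset:
    frame = data.frame.iloc[rows].reset_index(drop=True)
    return MTDataset(
        frame=frame,
        feature_cols=list(data.feature_cols),
        feature_kinds=dict(data.feature_kinds),
        targets=list(data.targets),
        row_ids=np.arange(len(frame)),
        level_orders={k: list(v) for k, v in data.level_orders.items()},
    )


def cv_tune(data: MTDataset, targets: list[TargetSpec], grid: Grid) -> TuneResult:
    """Evaluate every grid combination with k-fold CV; pick the best."""
    combos = grid.combinations()
    if not combos:
        raise ConfigurationError("empty hyperparameter grid")
    folds = make_folds(data, grid.k, targets, seed=grid.seed)
    all_rows = np.arange(data.n_rows)
    errors = np.zeros((len(combos), grid.k))
    for fi, heldout in enumerate(folds):
        train_rows = np.setdiff1d(all_rows, heldout)
        train = _subset(data, train_rows)
        test = _subset(data, heldout)
        for ci, hp in enumerate(combos):
            model = tree_mod.grow(train, targets, hp)
            report = tree_mod.evaluate(model, test, targets)
            errors[ci, fi] = report.overall
    mean = errors.mean(axis=1)
    sd = errors.std(axis=1, ddof=1) if grid.k > 1 else np.zeros(len(combos))
    best = min(
        range(len(combos)),
        key=lambda i: (mean[i], combos[i].d, -combos[i].cp, i),
    )
    return TuneResult(
        combinations=combos, fold_errors=errors, mean=mean, sd=sd, best_index=best
    )


def read_grid(path, base: Hyperparameters | None = None) -> Grid:
    """Read a YAML grid document: {k, seed, grid: {param: [values]}}."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse grid file: {exc}") from exc
    if not isinstance(doc, Mapping) or "grid" not in doc:
        raise ConfigurationError("grid file must contain a 'grid' mapping")
    return Grid(
        values={k: list(v) for k, v in doc["grid"].items()},
        k=int(doc.get("k", 5)),
        seed=int(doc.get("seed", 42)),
        base=base if base is not None else Hyperparameters(),
    )
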