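"""Synthetic multi-target datasets with planted subgroup structure.

The generator plants a shallow true partition (depth-2 by default: two
uniform features, one cutpoint each, four subgroups) and draws one target of
each outcome type with clearly separated per-subgroup parameters, so split
and tree recovery can be checked by gap containment. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .datamodel import MTDataset, TargetSpec, TargetType, build_dataset
from .errors import ConfigurationError


def _default_planted() -> list[tuple[str, list[float]]]:
    return [("pf1", [0.5]), ("pf2", [0.5])]


@dataclass
class PlantSpec:
    """Parameters of the planted-subgroup generator.

    Per-subgroup parameter lists are indexed by the subgroup id, a mixed-radix
    code over the planted features' bins (first feature most significant).
    Continuous targets have unit residual sd, so adjacent subgroup means must
    differ by at least 2; count and survival rates must differ at least
    2-fold between adjacent subgroups, keeping the structure recoverable.
    """

    n_rows: int = 400
    n_noise_features: int = 10
    planted_features: list = field(default_factory=_default_planted)
    continuous_means: list = field(default_factory=lambda: [0.0, 5.0, 10.0, 15.0])
    categorical_levels: list = field(default_factory=lambda: ["L0", "L1", "L2", "L3"])
    categorical_dists: list | None = None  # rows: per-subgroup level probabilities
    count_rates: list = field(default_factory=lambda: [1.0, 5.0, 25.0, 125.0])
    survival_rates: list = field(default_factory=lambda: [0.2, 1.0, 5.0, 25.0])
    censoring_fraction: float = 0.2
    gap_width: float = 0.05  # empty band planted around each cutpoint
    seed: int = 1

    @property
    def n_subgroups(self) -> int:
        out = 1
        for _, cuts in self.planted_features:
            out *= len(cuts) + 1
        return out

    def __post_init__(self):
        g = self.n_subgroups
        if self.categorical_dists is None:
            # concentrate 0.9 on subgroup-specific modal level, spread the rest
            K = len(self.categorical_levels)
            dists = []
            for s in range(g):
                p = np.full(K, 0.1 / (K - 1)) if K > 1 else np.array([1.0])
                if K > 1:
                    p[s % K] = 0.9
                dists.append(p.tolist())
            self.categorical_dists = dists
        for name, values in (
            ("continuous_means", self.continuous_means),
            ("categorical_dists", self.categorical_dists),
            ("count_rates", self.count_rates),
            ("survival_rates", self.survival_rates),
        ):
            if len(values) != g:
                raise ConfigurationError(
                    f"{name} must have one entry per subgroup ({g}), got {len(values)}"
                )
        for a, b in zip(self.continuous_means[:-1], self.continuous_means[1:]):
            if abs(b - a) < 2.0:
                raise ConfigurationError(
                    "adjacent continuous subgroup means must differ by >= 2 sd"
                )
        for name, rates in (("count_rates", self.count_rates), ("survival_rates", self.survival_rates)):
            for a, b in zip(rates[:-1], rates[1:]):
                if min(a, b) <= 0 or max(a, b) / min(a, b) < 2.0:
                    raise ConfigurationError(
                        f"adjacent {name} must be positive and differ >= 2-fold"
                    )
        if not (0 <= self.censoring_fraction < 1):
            raise ConfigurationError(
                f"censoring fraction must be in [0, 1), got {self.censoring_fraction}"
            )
        if not (0 <= self.gap_width < 1):
            raise ConfigurationError(f"gap width must be in [0, 1), got {self.gap_width}")
        w = self.gap_width
        for name, cuts in self.planted_features:
            prev_hi = 0.0
            for c in sorted(cuts):
                if c - w / 2 <= prev_hi or c + w / 2 >= 1.0:
                    raise ConfigurationError(
                        f"gap bands around cutpoints of {name!r} must be disjoint "
                        "and inside (0, 1)"
                    )
                prev_hi = c + w / 2

    def gap_interval(self, feature: str, cut: float) -> tuple[float, float]:
        """The empty band planted around one cutpoint (recovery target)."""
        return (cut - self.gap_width / 2, cut + self.gap_width / 2)


def default_targets(weights: dict[str, float] | None = None) -> list[TargetSpec]:
    """Target specification matching the generated columns."""
    w = weights or {}
    return [
        TargetSpec("y_cont", TargetType.CONTINUOUS, weight=w.get("y_cont", 1.0)),
        TargetSpec("y_cat", TargetType.CATEGORICAL, weight=w.get("y_cat", 1.0)),
        TargetSpec("y_count", TargetType.COUNT, weight=w.get("y_count", 1.0)),
        TargetSpec(
            "time", TargetType.SURVIVAL, weight=w.get("time", 1.0), event_col="event"
        ),
    ]


def subgroup_labels(spec: PlantSpec, planted_values: dict[str, np.ndarray]) -> np.ndarray:
    """Deterministic subgroup id from planted feature values and cutpoints."""
    labels = np.zeros(len(next(iter(planted_values.values()))), dtype=int)
    for name, cuts in spec.planted_features:
        bins = np.searchsorted(np.asarray(cuts, dtype=float), planted_values[name], side="right")
        labels = labels * (len(cuts) + 1) + bins
    return labels


def _censoring_bound(lam: float, frac: float) -> float:
    """Upper bound c of Uniform(0, c) censoring achieving the target
    expected censored fraction under an Exponential(lam) event time."""

    def f(c):
        return (1.0 - np.exp(-lam * c)) / (lam * c) - frac

    hi = 1.0 / lam
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12 / lam:
            raise ConfigurationError(
                f"cannot achieve censoring fraction {frac} for rate {lam}"
            )
    return float(brentq(f, 1e-12 / lam, hi))


def generate(spec: PlantSpec) -> tuple[MTDataset, np.ndarray]:
    """Draw a dataset per the plant spec; returns (dataset, subgroup labels)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    cols: dict[str, np.ndarray] = {}
    planted_vals: dict[str, np.ndarray] = {}
    w = spec.gap_width
    for name, cuts in spec.planted_features:
        # uniform on [0, 1] minus an empty band of width w around each cut,
        # so threshold recovery is testable by band containment
        v = rng.uniform(0.0, 1.0 - w * len(cuts), size=n)
        for c in sorted(cuts):
            v = np.where(v >= c - w / 2, v + w, v)
        planted_vals[name] = v
        cols[name] = v
    for j in range(spec.n_noise_features):
        cols[f"nf{j + 1}"] = rng.uniform(0.0, 1.0, size=n)
    labels = subgroup_labels(spec, planted_vals)

    means = np.asarray(spec.continuous_means, dtype=float)
    cols["y_cont"] = rng.normal(means[labels], 1.0)

    levels = list(spec.categorical_levels)
    dists = np.asarray(spec.categorical_dists, dtype=float)
    cat = np.empty(n, dtype=object)
    for s in range(spec.n_subgroups):
        idx = np.flatnonzero(labels == s)
        if len(idx):
            cat[idx] = rng.choice(levels, size=len(idx), p=dists[s] / dists[s].sum())
    cols["y_cat"] = cat

    crates = np.asarray(spec.count_rates, dtype=float)
    cols["y_count"] = rng.poisson(crates[labels]).astype(float)

    srates = np.asarray(spec.survival_rates, dtype=float)
    T = rng.exponential(1.0 / srates[labels])
    if spec.censoring_fraction > 0:
        bounds = np.array(
            [_censoring_bound(r, spec.censoring_fraction) for r in srates]
        )
        C = rng.uniform(0.0, bounds[labels])
        cols["time"] = np.minimum(T, C)
        cols["event"] = (T <= C).astype(float)
    else:
        cols["time"] = T
        cols["event"] = np.ones(n)

    frame = pd.DataFrame(cols)
    data = build_dataset(frame, default_targets())
    return data, labels


def read_plant_spec(path) -> PlantSpec:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse plant spec: {exc}") from exc
    if "planted_features" in doc:
        doc["planted_features"] = [
            (e["name"], list(e["cutpoints"])) for e in doc["planted_features"]
        ]
    known = set(PlantSpec.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown plant spec key(s): {sorted(unknown)}")
    return PlantSpec(**doc)
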