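"""Typed representation of multi-target datasets, target specs, and hyperparameters.

Datasets are desk-scale delimited text tables with a header row. ``"NA"`` and
the empty string denote missing values. Rows with a missing value in any
target (or auxiliary event/exposure) column are dropped at load time with a
logged count; missing feature values are retained and handled at split time.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataParseError

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA")

EVAL_METHODS = (
    "avgIG",
    "maxIG",
    "mostIG",
    "avgPVal",
    "minPVal",
    "mostPVal",
    "splitError",
)


class TargetType(str, enum.Enum):
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"
    COUNT = "count"
    SURVIVAL = "survival"


@dataclass(frozen=True)
class TargetSpec:
    """Declaration of one endpoint: column, outcome type, weight, auxiliaries.

    ``event_col`` is required exactly for survival targets (0/1 indicator);
    ``exposure_col`` is optional and only allowed for count targets.
    """

    name: str
    ttype: TargetType
    weight: float = 1.0
    event_col: str | None = None
    exposure_col: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "ttype", TargetType(self.ttype))
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ConfigurationError(
                f"target {self.name!r}: weight must be a non-negative real, got {self.weight}"
            )
        if self.ttype is TargetType.SURVIVAL:
            if not self.event_col:
                raise ConfigurationError(
                    f"survival target {self.name!r} requires an event indicator column"
                )
        elif self.event_col is not None:
            raise ConfigurationError(
                f"target {self.name!r}: event column only allowed for survival targets"
            )
        if self.exposure_col is not None and self.ttype is not TargetType.COUNT:
            raise ConfigurationError(
                f"target {self.name!r}: exposure column only allowed for count targets"
            )

    @property
    def columns(self) -> list[str]:
        """All table columns this target reads."""
        cols = [self.name]
        if self.event_col:
            cols.append(self.event_col)
        if self.exposure_col:
            cols.append(self.exposure_col)
        return cols


@dataclass(frozen=True)
class Hyperparameters:
    """All tuning knobs of the engine.

    ``parallelsplit``/``paralleldepth`` are only consulted when
    ``evalmethod="splitError"``. ``d=0`` is allowed and yields a single-leaf
    tree.
    """

    evalmethod: str = "avgIG"
    d: int = 4
    nodesize: int = 20
    splitmin: int = 7
    cp: float = 0.01
    reuse: bool = True
    alpha: float = 0.05
    IGcutoff: float = 0.10
    parallelsplit: int = 5
    paralleldepth: int = 2
    seed: int = 42

    def __post_init__(self):
        if self.evalmethod not in EVAL_METHODS:
            raise ConfigurationError(
                f"unknown evalmethod {self.evalmethod!r}; valid options: "
                + ", ".join(EVAL_METHODS)
            )
        if int(self.d) != self.d or self.d < 0:
            raise ConfigurationError(f"d must be a non-negative integer, got {self.d}")
        for name in ("nodesize", "splitmin", "parallelsplit", "paralleldepth"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        if not (self.cp >= 0):
            raise ConfigurationError(f"cp must be >= 0, got {self.cp}")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0 <= self.IGcutoff <= 1):
            raise ConfigurationError(f"IGcutoff must be in [0, 1], got {self.IGcutoff}")

    def replace(self, **kwargs) -> "Hyperparameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MTDataset:
    """A validated multi-target dataset.

    ``frame`` holds feature and target columns; feature columns are tagged
    ``"numeric"`` or ``"categorical"`` in ``feature_kinds`` and categorical
    levels are recorded in first-appearance order for deterministic
    enumeration.
    """

    frame: pd.DataFrame
    feature_cols: list[str]
    feature_kinds: dict[str, str]
    targets: list[TargetSpec]
    row_ids: np.ndarray
    level_orders: dict[str, list] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def feature_frame(self) -> pd.DataFrame:
        return self.frame[self.feature_cols]

    def feature_values(self, col: str) -> np.ndarray:
        """Feature column as float array (numeric) or object array (categorical)."""
        if self.feature_kinds[col] == "numeric":
            return self.frame[col].to_numpy(dtype=float)
        return self.frame[col].to_numpy(dtype=object)


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.astype(str).str.strip().isin(MISSING_TOKENS)


def _to_float_exact(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Exact (correctly rounded) string-to-float conversion.

    pandas' fast to_numeric parser is not guaranteed round-trip faithful, so
    conversion goes through the platform strtod. Returns (values, bad_mask)
    with missing entries as NaN.
    """
    miss = _is_missing(series).to_numpy()
    out = np.full(len(series), np.nan)
    bad = np.zeros(len(series), dtype=bool)
    idx = np.flatnonzero(~miss)
    sub = series.iloc[idx].to_numpy(dtype=object)
    try:
        out[idx] = np.asarray(sub, dtype=float)
    except (ValueError, TypeError):
        for j, v in zip(idx, sub):
            try:
                out[j] = float(v)
            except (ValueError, TypeError):
                bad[j] = True
    return out, bad


def _parse_numeric(series: pd.Series, col: str, kind: str) -> np.ndarray:
    """Parse a string series to float, raising DataParseError with row index."""
    out, bad = _to_float_exact(series)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataParseError(
            f"non-numeric value {series.iloc[row]!r} in {kind} column", row=row, column=col
        )
    return out


def _validate_target_values(frame: pd.DataFrame, spec: TargetSpec) -> pd.DataFrame:
    """Parse/validate one target's columns in-place; returns the updated frame."""
    t = spec.ttype
    if t in (TargetType.CONTINUOUS, TargetType.COUNT, TargetType.SURVIVAL):
        vals = _parse_numeric(frame[spec.name], spec.name, t.value)
        if t is TargetType.COUNT:
            ok = np.isnan(vals) | ((vals >= 0) & (vals == np.floor(vals)))
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise DataParseError(
                    "count values must be non-negative integers", row=row, column=spec.name
                )
        if t is TargetType.SURVIVAL:
            ok = np.isnan(vals) | (vals >= 0)
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise DataParseError(
                    "survival times must be >= 0", row=row, column=spec.name
                )
        frame[spec.name] = vals
    if spec.event_col:
        ev = _parse_numeric(frame[spec.event_col], spec.event_col, "event indicator")
        ok = np.isnan(ev) | np.isin(ev, (0.0, 1.0))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise DataParseError(
                "event indicator must be 0 or 1", row=row, column=spec.event_col
            )
        frame[spec.event_col] = ev
    if spec.exposure_col:
        ex = _parse_numeric(frame[spec.exposure_col], spec.exposure_col, "exposure")
        ok = np.isnan(ex) | (ex > 0)
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise DataParseError(
                "exposure must be positive", row=row, column=spec.exposure_col
            )
        frame[spec.exposure_col] = ex
    return frame


def build_dataset(
    raw: pd.DataFrame,
    specs: list[TargetSpec],
    feature_cols: Iterable[str] | None = None,
    categorical_features: Iterable[str] = (),
) -> MTDataset:
    """Validate a raw (string- or value-typed) frame into an MTDataset.

    Feature columns default to every column not claimed by a target spec.
    Numeric-vs-categorical is detected from content unless a column is named
    in ``categorical_features``.
    """
    frame = raw.copy()
    target_cols: list[str] = []
    for spec in specs:
        for col in spec.columns:
            if col not in frame.columns:
                raise ConfigurationError(
                    f"target {spec.name!r} references missing column {col!r}"
                )
        target_cols.extend(spec.columns)
    if len(set(s.name for s in specs)) != len(specs):
        raise ConfigurationError("duplicate target names in specification")

    for spec in specs:
        frame = _validate_target_values(frame, spec)

    # drop rows incomplete on any target column
    miss = frame[target_cols].isna().any(axis=1)
    if miss.any():
        logger.info("dropping %d row(s) with missing target values", int(miss.sum()))
        frame = frame.loc[~miss].reset_index(drop=True)
    if len(frame) == 0:
        raise ConfigurationError("no rows remain after dropping incomplete targets")

    if feature_cols is None:
        feature_cols = [c for c in frame.columns if c not in set(target_cols)]
    else:
        feature_cols = list(feature_cols)
        for col in feature_cols:
            if col not in frame.columns:
                raise ConfigurationError(f"feature column {col!r} not found")

    feature_kinds: dict[str, str] = {}
    level_orders: dict[str, list] = {}
    cat_declared = set(categorical_features)
    for col in feature_cols:
        series = frame[col]
        missing = _is_missing(series)
        numeric, bad = _to_float_exact(series)
        if col not in cat_declared and not bad.any():
            feature_kinds[col] = "numeric"
            frame[col] = numeric
        else:
            feature_kinds[col] = "categorical"
            vals = series.astype(object).where(~missing, other=None)
            frame[col] = vals
            seen: list = []
            for v in vals:
                if v is not None and v not in seen:
                    seen.append(v)
            level_orders[col] = seen

    return MTDataset(
        frame=frame,
        feature_cols=feature_cols,
        feature_kinds=feature_kinds,
        targets=list(specs),
        row_ids=np.arange(len(frame)),
        level_orders=level_orders,
    )


def read_dataset(
    path,
    specs: list[TargetSpec],
    delimiter: str = ",",
    categorical_features: Iterable[str] = (),
) -> MTDataset:
    """Read a delimited text table with a header row into a validated dataset."""
    raw = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        na_values=list(MISSING_TOKENS),
        skipinitialspace=False,
    )
    return build_dataset(raw, specs, categorical_features=categorical_features)


def write_dataset(data: MTDataset, path, delimiter: str = ",") -> None:
    """Write the dataset back to delimited text; missing values become "NA"."""
    data.frame.to_csv(path, sep=delimiter, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# configuration documents


def _target_from_mapping(entry: Mapping) -> TargetSpec:
    if not isinstance(entry, Mapping) or "name" not in entry or "type" not in entry:
        raise ConfigurationError(
            f"each target entry needs at least 'name' and 'type': got {entry!r}"
        )
    known = {"name", "type", "weight", "event", "exposure"}
    unknown = set(entry) - known
    if unknown:
        raise ConfigurationError(f"unknown target keys: {sorted(unknown)}")
    try:
        ttype = TargetType(entry["type"])
    except ValueError:
        raise ConfigurationError(
            f"unknown target type {entry['type']!r}; valid: "
            + ", ".join(t.value for t in TargetType)
        ) from None
    return TargetSpec(
        name=str(entry["name"]),
        ttype=ttype,
        weight=float(entry.get("weight", 1.0)),
        event_col=entry.get("event"),
        exposure_col=entry.get("exposure"),
    )


def parse_config(doc: Mapping) -> tuple[list[TargetSpec], Hyperparameters]:
    if not isinstance(doc, Mapping) or "targets" not in doc:
        raise ConfigurationError("configuration must contain a 'targets' section")
    specs = [_target_from_mapping(e) for e in doc["targets"]]
    if not specs:
        raise ConfigurationError("at least one target must be declared")
    if not any(s.weight > 0 for s in specs):
        raise ConfigurationError("at least one target must have weight > 0")
    params = dict(doc.get("params") or {})
    unknown = set(params) - set(f.name for f in dataclasses.fields(Hyperparameters))
    if unknown:
        raise ConfigurationError(f"unknown hyperparameter(s): {sorted(unknown)}")
    hp = Hyperparameters(**params)
    return specs, hp


def read_config(path) -> tuple[list[TargetSpec], Hyperparameters]:
    """Read a YAML configuration with 'targets' and 'params' sections."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse configuration: {exc}") from exc
    return parse_config(doc)
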