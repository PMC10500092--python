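# mttree

Multi-target decision trees for mixed clinical endpoints.

`mttree` grows a single interpretable tree that explains several outcomes of
heterogeneous types **simultaneously** — continuous, categorical, count
(event rate, with optional exposure), and right-censored survival — from
numeric and/or categorical features. It supports per-target weights, seven
multi-target split-evaluation criteria (six stepwise plus a subtree
lookahead), constraint-based pre-pruning, grid-search k-fold
cross-validation for hyperparameter tuning, held-out evaluation, model
serialization, and text/DOT tree rendering.

## How it works

Features are binarized into candidate splits (numeric thresholds at
midpoints between distinct values; categorical level-vs-rest). Each
candidate is scored against every target with an information gain (IG) —
parent node loss minus summed child losses — using a type-specific loss:

| target type | node loss | split p-value |
|---|---|---|
| continuous | sum of squared deviations | one-way ANOVA F (1, n−2) |
| categorical | size-weighted Gini, `n(1 − Σ p²)` | chi-square independence, df K−1 |
| count | −2·Poisson log-likelihood at the node rate | chi-square(1) on the LR statistic |
| survival | −2·exponential log-likelihood on hazard-rescaled times | chi-square(1) on the LR statistic |

Survival times are rescaled once at the root by the Nelson–Aalen cumulative
hazard, which makes the constant-hazard model exact at the root; the scaling
map is stored with the model so held-out losses live on the training scale.
The *proportion IG* (IG divided by the parent deviance) standardizes gains
to [0, 1] so targets with different units are comparable.

The `evalmethod` hyperparameter picks the split ranking: `avgIG` (weighted
mean proportion IG), `maxIG` (best single-target proportion IG), `mostIG`
(meaningful IG ≥ `IGcutoff` in the most targets), `avgPVal` / `minPVal` /
`mostPVal` (p-value based), or `splitError` (a lookahead that expands the
top `parallelsplit` candidates into depth-`paralleldepth` subtrees and
keeps the one with the smallest multi-target subtree error).

Pre-pruning knobs: maximum depth `d`, minimum node size for splitting
`nodesize`, minimum leaf size `splitmin`, complexity gate `cp` (a split must
explain at least `cp` of the weighted parent deviance), feature-reuse flag
`reuse`, significance level `alpha`, and `IGcutoff`.

## CLI

The `mttree` command (or `python -m mttree.cli`) binds the whole workflow:

```sh
# 1. generate planted-subgroup synthetic data (optional --spec plant.yaml)
mttree --seed 7 simulate --out data.csv --truth truth.csv

# 2. tune hyperparameters by grid search + k-fold CV
mttree --seed 7 tune --data data.csv --config config.yaml --grid grid.yaml --out tune.json

# 3. train a model
mttree train --data data.csv --config config.yaml --out model.json

# 4. evaluate on (new) data
mttree test --model model.json --data test.csv --report report.json

# 5. render
mttree plot --model model.json --format text
mttree plot --model model.json --format dot --out tree.dot
```

`config.yaml` declares targets and parameters:

```yaml
targets:
  - {name: y_cont, type: continuous, weight: 1.0}
  - {name: y_cat, type: categorical}
  - {name: y_count, type: count}            # optional: exposure: <column>
  - {name: time, type: survival, event: event}
params:
  evalmethod: avgIG
  d: 3
  nodesize: 20
  splitmin: 7
  cp: 0.01
```

`grid.yaml` lists candidate values per hyperparameter:

```yaml
k: 5
grid:
  d: [1, 2, 3, 4]
  cp: [0.0, 0.01]
```

Exit codes: 0 success, 2 configuration/validation error, 1 unexpected
failure. Input tables are delimited text with a header; `NA` or an empty
field means missing. Rows missing any target value are dropped at load;
missing *feature* values are kept and routed to the majority side of each
split.

## Python API

```python
import mttree as mt

data, labels = mt.generate(mt.PlantSpec(seed=1))
model = mt.grow(data, hp=mt.Hyperparameters(d=2))
print(mt.render_text(model))
report = mt.evaluate(model, data)
preds = mt.predict(model, data.frame)
```

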