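"""Symbolic regression of NCP by genetic programming.

Net community production is modelled as an unknown, possibly non-linear
function of community structure (module eigenvalues) and physical drivers
(MLD, PAR, mixed-layer PAR, salinity, SST, freshwater fractions, grid
coordinates).  Rather than fixing a functional form, candidate formulas are
evolved as expression trees over the features with arithmetic operators and
ephemeral constants:

* the data are split into even training and validation halves with a seeded
  shuffle;
* a population of trees is evolved by tournament selection, subtree crossover
  and subtree/constant mutation, minimising training mean squared error;
* every evaluated tree may update a (complexity, MSE) Pareto archive, so the
  output is a front of solutions trading accuracy against size rather than a
  single formula;
* the front is then re-evaluated on the held-out validation half and ranked
  by validation MSE.

Each tree's raw output h(x) is mapped to predictions through a least-squares
linear scaling y_hat = a + b*h(x) fitted on the training half (a standard
device that removes the burden of evolving output offset and scale).
Division is protected: it returns 1 whenever |denominator| < 1e-9.
Complexity is the node count of the tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GpConfig",
    "GpSolution",
    "split_even",
    "evolve",
    "evaluate_tree",
    "tree_complexity",
    "tree_features",
    "tree_to_infix",
    "SymbolicRegression",
    "GpResults",
]

_OPS = ("+", "-", "*", "/")
_PROTECTED_EPS = 1e-9


@dataclass(frozen=True)
class GpConfig:
    """Hyperparameters of the evolutionary search."""

    population_size: int = 400
    generations: int = 50
    tournament_size: int = 3
    p_crossover: float = 0.7
    p_mutation: float = 0.25
    max_depth: int = 5
    const_range: tuple[float, float] = (-2.0, 2.0)
    operators: tuple[str, ...] = _OPS
    standardize: bool = True
    linear_scaling: bool = True
    split_seed: int = 0
    run_seed: int = 0

    def __post_init__(self):
        for p in (self.p_crossover, self.p_mutation):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.max_depth < 2:
            raise ValueError("max_depth must be >= 2")
        bad = set(self.operators) - set(_OPS)
        if bad:
            raise ValueError(f"unknown operators: {bad}")


# ---------------------------------------------------------------------------
# expression trees: ("c", value) | ("x", name) | (op, left, right)


def evaluate_tree(tree, data: dict) -> np.ndarray:
    """Evaluate an expression tree over a dict of feature arrays."""
    tag = tree[0]
    if tag == "c":
        n = len(next(iter(data.values())))
        return np.full(n, tree[1], dtype=float)
    if tag == "x":
        if tree[1] not in data:
            raise ValueError(f"feature {tree[1]!r} missing from data")
        return np.asarray(data[tree[1]], dtype=float)
    a = evaluate_tree(tree[1], data)
    b = evaluate_tree(tree[2], data)
    if tag == "+":
        return a + b
    if tag == "-":
        return a - b
    if tag == "*":
        return a * b
    if tag == "/":
        return np.where(np.abs(b) < _PROTECTED_EPS, 1.0, a / np.where(b == 0, 1.0, b))
    raise ValueError(f"unknown node {tag!r}")


def tree_complexity(tree) -> int:
    if tree[0] in ("c", "x"):
        return 1
    return 1 + tree_complexity(tree[1]) + tree_complexity(tree[2])


def tree_depth(tree) -> int:
    if tree[0] in ("c", "x"):
        return 1
    return 1 + max(tree_depth(tree[1]), tree_depth(tree[2]))


def tree_features(tree) -> set[str]:
    if tree[0] == "x":
        return {tree[1]}
    if tree[0] == "c":
        return set()
    return tree_features(tree[1]) | tree_features(tree[2])


def tree_to_infix(tree, ndigits: int = 4) -> str:
    if tree[0] == "c":
        return f"{tree[1]:.{ndigits}g}"
    if tree[0] == "x":
        return tree[1]
    return f"({tree_to_infix(tree[1], ndigits)} {tree[0]} {tree_to_infix(tree[2], ndigits)})"


def _subtree_count(tree) -> int:
    return tree_complexity(tree)


def _get_subtree(tree, idx):
    """Pre-order indexing; returns the subtree at position idx."""
    if idx == 0:
        return tree
    if tree[0] in ("c", "x"):
        raise IndexError(idx)
    left_n = tree_complexity(tree[1])
    if idx - 1 < left_n:
        return _get_subtree(tree[1], idx - 1)
    return _get_subtree(tree[2], idx - 1 - left_n)


def _set_subtree(tree, idx, new):
    if idx == 0:
        return new
    left_n = tree_complexity(tree[1])
    if idx - 1 < left_n:
        return (tree[0], _set_subtree(tree[1], idx - 1, new), tree[2])
    return (tree[0], tree[1], _set_subtree(tree[2], idx - 1 - left_n, new))


def _random_tree(rng, features, config, depth, method="grow"):
    if depth <= 1 or (method == "grow" and depth < config.max_depth and rng.random() < 0.3):
        if rng.random() < 0.7:
            return ("x", features[rng.integers(len(features))])
        lo, hi = config.const_range
        return ("c", float(rng.uniform(lo, hi)))
    op = config.operators[rng.integers(len(config.operators))]
    return (
        op,
        _random_tree(rng, features, config, depth - 1, method),
        _random_tree(rng, features, config, depth - 1, method),
    )


def _mutate(tree, rng, features, config):
    n = tree_complexity(tree)
    idx = int(rng.integers(n))
    node = _get_subtree(tree, idx)
    if node[0] == "c" and rng.random() < 0.5:
        new = ("c", float(node[1] + rng.normal(0.0, 0.5 * (abs(node[1]) + 1.0))))
    else:
        new = _random_tree(rng, features, config, depth=3, method="grow")
    out = _set_subtree(tree, idx, new)
    return out if tree_depth(out) <= config.max_depth else tree


def _crossover(t1, t2, rng, config):
    i1 = int(rng.integers(tree_complexity(t1)))
    i2 = int(rng.integers(tree_complexity(t2)))
    child = _set_subtree(t1, i1, _get_subtree(t2, i2))
    return child if tree_depth(child) <= config.max_depth else t1


# ---------------------------------------------------------------------------


def split_even(data: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle into disjoint halves (odd n: validation gets the extra)."""
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 rows to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = n // 2
    return data.iloc[order[:n_train]], data.iloc[order[n_train:]]


def _fit_scaling(h: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (a, b) for y ~ a + b*h; b = 0 for degenerate h."""
    if not np.all(np.isfinite(h)):
        return np.nan, np.nan
    vh = np.var(h)
    if vh < 1e-12:
        return float(np.mean(y)), 0.0
    b = float(np.cov(h, y, bias=True)[0, 1] / vh)
    a = float(np.mean(y) - b * np.mean(h))
    return a, b


@dataclass
class GpSolution:
    """One evolved formula with its metrics."""

    tree: tuple
    scale_a: float
    scale_b: float
    complexity: int
    train_mse: float
    val_mse: float | None = None
    val_r2: float | None = None

    @property
    def expression(self) -> str:
        core = tree_to_infix(self.tree)
        if self.scale_b == 1.0 and self.scale_a == 0.0:
            return core
        return f"{self.scale_a:.4g} + {self.scale_b:.4g} * {core}"

    @property
    def features(self) -> set[str]:
        return tree_features(self.tree)

    def predict(self, data: dict) -> np.ndarray:
        return self.scale_a + self.scale_b * evaluate_tree(self.tree, data)

    def score(self, data: dict, y: np.ndarray) -> tuple[float, float]:
        """(MSE, R^2) of this solution on the given feature dict/target."""
        pred = self.predict(data)
        resid = y - pred
        mse = float(np.mean(resid**2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
        return mse, r2

    def to_dict(self) -> dict:
        return {
            "expression": self.expression,
            "complexity": self.complexity,
            "features": sorted(self.features),
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "val_r2": self.val_r2,
        }


def _update_front(front: dict, tree, mse, a, b):
    """Keep, per complexity, the best MSE; then prune dominated members."""
    if not np.isfinite(mse):
        return
    c = tree_complexity(tree)
    cur = front.get(c)
    if cur is None or mse < cur[0]:
        front[c] = (mse, tree, a, b)
    # prune: higher complexity must have strictly lower mse
    best = np.inf
    for c in sorted(front):
        if front[c][0] >= best:
            del front[c]
        else:
            best = front[c][0]


def evolve(
    train: pd.DataFrame,
    target: str,
    config: GpConfig = GpConfig(),
    feature_columns: list[str] | None = None,
    scaler: tuple[pd.Series, pd.Series] | None = None,
) -> list[GpSolution]:
    """Run the evolutionary search on the training half.

    Returns the Pareto front as a list of :class:`GpSolution` ordered by
    complexity.  ``scaler`` is the (mean, sd) pair used to standardize the
    features; pass the one fitted on the training half so validation uses the
    same transform (handled by :class:`SymbolicRegression`).
    """
    feats = feature_columns or [c for c in train.columns if c != target]
    if not feats:
        raise ValueError("no feature columns")
    X = train[feats].to_numpy(dtype=float)
    y = train[target].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in features or target")
    if scaler is not None:
        mu, sd = scaler
        X = (X - mu[feats].to_numpy()) / sd[feats].to_numpy()
    data = {f: X[:, j] for j, f in enumerate(feats)}

    rng = np.random.default_rng(config.run_seed)
    pop = []
    depths = [2 + i % (config.max_depth - 1) for i in range(config.population_size)]
    for i in range(config.population_size):
        method = "grow" if i % 2 else "full"
        pop.append(_random_tree(rng, feats, config, depths[i], method))

    front: dict[int, tuple] = {}

    def fitness(tree):
        h = evaluate_tree(tree, data)
        if config.linear_scaling:
            a, b = _fit_scaling(h, y)
            if not np.isfinite(a):
                return np.inf, 1.0, 0.0
            mse = float(np.mean((y - a - b * h) ** 2))
            return mse, a, b
        if not np.all(np.isfinite(h)):
            return np.inf, 0.0, 1.0
        return float(np.mean((y - h) ** 2)), 0.0, 1.0

    fits = []
    for t in pop:
        mse, a, b = fitness(t)
        fits.append(mse)
        _update_front(front, t, mse, a, b)

    for _ in range(config.generations):
        new_pop = []
        # elitism: carry over the best individual
        best_i = int(np.argmin(fits))
        new_pop.append(pop[best_i])
        while len(new_pop) < config.population_size:
            def select():
                idx = rng.integers(len(pop), size=config.tournament_size)
                return pop[min(idx, key=lambda i: fits[i])]

            r = rng.random()
            if r < config.p_crossover:
                child = _crossover(select(), select(), rng, config)
            elif r < config.p_crossover + config.p_mutation:
                child = _mutate(select(), rng, feats, config)
            else:
                child = select()
            new_pop.append(child)
        pop = new_pop
        fits = []
        for t in pop:
            mse, a, b = fitness(t)
            fits.append(mse)
            _update_front(front, t, mse, a, b)

    solutions = [
        GpSolution(
            tree=tree,
            scale_a=a if config.linear_scaling else 0.0,
            scale_b=b if config.linear_scaling else 1.0,
            complexity=c,
            train_mse=mse,
        )
        for c, (mse, tree, a, b) in sorted(front.items())
    ]
    return solutions


class SymbolicRegression:
    """Model: evolve NCP formulas from a feature table.

    Parameters
    ----------
    data : DataFrame
        Feature columns plus the target column, one row per sample.
    target : str
        Name of the target column (e.g. volumetric NCP).
    config : GpConfig
    """

    def __init__(self, data: pd.DataFrame, target: str, config: GpConfig = GpConfig()):
        if target not in data.columns:
            raise ValueError(f"target column {target!r} missing")
        self.data = data
        self.target = target
        self.config = config
        self.feature_columns = [c for c in data.columns if c != target]

    @classmethod
    def from_tables(
        cls,
        eigenvalues: pd.DataFrame,
        physical: pd.DataFrame,
        target: pd.Series,
        config: GpConfig = GpConfig(),
    ) -> "SymbolicRegression":
        """Join module eigenvalues and physical drivers on the sample index."""
        data = eigenvalues.join(physical, how="inner")
        data[target.name or "ncp"] = target
        data = data.dropna()
        return cls(data, target.name or "ncp", config)

    def fit(self, seed: int | None = None) -> "GpResults":
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, split_seed=seed, run_seed=seed)
        values = self.data[self.feature_columns + [self.target]].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("features and target must be finite")
        train, val = split_even(self.data, cfg.split_seed)
        scaler = None
        if cfg.standardize:
            mu = train[self.feature_columns].mean()
            sd = train[self.feature_columns].std(ddof=0).replace(0.0, 1.0)
            scaler = (mu, sd)
        front = evolve(train, self.target, cfg, self.feature_columns, scaler)
        return GpResults(
            model=self, config=cfg, train=train, validation=val,
            scaler=scaler, front=front,
        ).rank()


@dataclass
class GpResults:
    """Pareto front of evolved NCP formulas plus validation ranking."""

    model: SymbolicRegression
    config: GpConfig
    train: pd.DataFrame
    validation: pd.DataFrame
    scaler: tuple[pd.Series, pd.Series] | None
    front: list[GpSolution]
    ranked: list[GpSolution] = field(default_factory=list)

    def _data_dict(self, frame: pd.DataFrame) -> dict:
        feats = self.model.feature_columns
        X = frame[feats].to_numpy(dtype=float)
        if self.scaler is not None:
            mu, sd = self.scaler
            X = (X - mu[feats].to_numpy()) / sd[feats].to_numpy()
        return {f: X[:, j] for j, f in enumerate(feats)}

    def evaluate(self, solution: GpSolution, frame: pd.DataFrame) -> tuple[float, float]:
        """(MSE, R^2) of one solution on an arbitrary data frame."""
        missing = solution.features - set(frame.columns)
        if missing:
            raise ValueError(f"missing feature column(s): {sorted(missing)}")
        y = frame[self.model.target].to_numpy(dtype=float)
        return solution.score(self._data_dict(frame), y)

    def rank(self) -> "GpResults":
        """Re-evaluate the front on the validation half; sort by val MSE."""
        if not self.front:
            raise ValueError("empty Pareto front")
        for sol in self.front:
            sol.val_mse, sol.val_r2 = self.evaluate(sol, self.validation)
        self.ranked = sorted(self.front, key=lambda s: s.val_mse)
        return self

    @property
    def best(self) -> GpSolution:
        return self.ranked[0]

    def feature_frequency(self, top_k: int | None = None) -> pd.Series:
        """Fraction of (top-k) ranked solutions in which each feature appears."""
        sols = self.ranked[:top_k] if top_k else self.ranked
        counts = pd.Series(0.0, index=self.model.feature_columns)
        for s in sols:
            for f in s.features:
                counts[f] += 1
        return counts / len(sols)

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "rank": i + 1,
                "expression": s.expression,
                "complexity": s.complexity,
                "train_mse": s.train_mse,
                "val_mse": s.val_mse,
                "val_r2": s.val_r2,
                "features": ",".join(sorted(s.features)),
            }
            for i, s in enumerate(self.ranked)
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.model.target,
                "n_train": len(self.train),
                "n_validation": len(self.validation),
                "solutions": [s.to_dict() for s in self.ranked],
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            "Symbolic regression of NCP (Pareto front, ranked by validation MSE)",
            f"  n train/validation: {len(self.train)}/{len(self.validation)}",
            f"  population {self.config.population_size}, "
            f"generations {self.config.generations}, "
            f"seed {self.config.run_seed}",
            "",
            f"  {'rank':<5}{'cplx':<6}{'val MSE':>10}{'val R2':>8}  expression",
        ]
        for i, s in enumerate(self.ranked[:10]):
            lines.append(
                f"  {i + 1:<5}{s.complexity:<6}{s.val_mse:>10.4g}{s.val_r2:>8.3f}  "
                f"{s.expression}"
            )
        return "\n".join(lines)
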