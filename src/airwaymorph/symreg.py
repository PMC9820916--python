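"""Genetic-programming symbolic regression with fitness-weighted importance.

Evolves closed-form expression models of a target (airway volume or
CSAmin) from a measurement table, using the building blocks addition,
subtraction, multiplication, division, exponential, natural logarithm,
power and square root, with mean absolute error as the fitness metric and
a random 80/20 train/validation split.  The search is a steady-state GP:
tournament selection, subtree crossover, point/subtree mutation, constant
jitter and elitism, maintaining a Pareto archive over (complexity,
training MAE).  Several independent experiments are aggregated into a
normalized fitness-weighted variable-importance ranking and a signed
sensitivity ("magnitude of effects") summary.

Two numerical choices matter for desk-scale budgets and are documented in
the methods note: model outputs are linearly scaled (slope/intercept fit
on the training split by least squares — the standard Keijzer scaling),
and the constants of archived models are locally optimised by least
squares at intervals and at the end of each run.  A model whose raw
prediction is non-finite on any row (division by zero, log of a
non-positive value, invalid power) is infeasible and gets MAE = +inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

# ----------------------------------------------------------------- trees
# node forms: ("var", j) | ("const", c) | ("u", op, child)
#           | ("b", op, left, right) | ("pow", child, exponent)
UNARY_OPS = ("exp", "ln", "sqrt")
BINARY_OPS = ("add", "sub", "mul", "div")
#: sampling weights: plain arithmetic dominates, transcendentals are rare
_OP_CHOICES = (("b", "add"), ("b", "sub"), ("b", "mul"), ("b", "div"),
               ("u", "sqrt"), ("u", "ln"), ("u", "exp"), ("pow", None))
_OP_WEIGHTS = np.array([4.0, 4.0, 4.0, 2.0, 1.0, 0.5, 0.5, 0.5])
_OP_WEIGHTS = _OP_WEIGHTS / _OP_WEIGHTS.sum()

MAX_POW = 10.0


def tree_size(t) -> int:
    if t[0] in ("var", "const"):
        return 1
    if t[0] == "u":
        return 1 + tree_size(t[2])
    if t[0] == "pow":
        return 2 + tree_size(t[1])  # operator + exponent constant
    return 1 + tree_size(t[2]) + tree_size(t[3])


def tree_variables(t) -> set[int]:
    if t[0] == "var":
        return {t[1]}
    if t[0] == "const":
        return set()
    if t[0] == "u":
        return tree_variables(t[2])
    if t[0] == "pow":
        return tree_variables(t[1])
    return tree_variables(t[2]) | tree_variables(t[3])


def eval_tree(t, X: np.ndarray) -> np.ndarray:
    """Evaluate a tree on the feature matrix ``X`` (rows × features)."""
    kind = t[0]
    if kind == "var":
        return X[:, t[1]]
    if kind == "const":
        return np.full(X.shape[0], t[1])
    with np.errstate(all="ignore"):
        if kind == "u":
            a = eval_tree(t[2], X)
            if t[1] == "exp":
                return np.exp(a)
            if t[1] == "ln":
                return np.log(a)
            return np.sqrt(a)
        if kind == "pow":
            return np.power(eval_tree(t[1], X), t[2])
        a = eval_tree(t[2], X)
        b = eval_tree(t[3], X)
        op = t[1]
        if op == "add":
            return a + b
        if op == "sub":
            return a - b
        if op == "mul":
            return a * b
        return a / b


def tree_infix(t, names: Sequence[str]) -> str:
    kind = t[0]
    if kind == "var":
        return names[t[1]]
    if kind == "const":
        return f"{t[1]:.6g}"
    if kind == "u":
        fn = {"exp": "exp", "ln": "ln", "sqrt": "sqrt"}[t[1]]
        return f"{fn}({tree_infix(t[2], names)})"
    if kind == "pow":
        return f"({tree_infix(t[1], names)})^{t[2]:.6g}"
    sym = {"add": " + ", "sub": " - ", "mul": "*", "div": "/"}[t[1]]
    return f"({tree_infix(t[2], names)}{sym}{tree_infix(t[3], names)})"


def _tree_to_jsonable(t):
    return list(t[:1]) + [(_tree_to_jsonable(x) if isinstance(x, tuple) else x)
                          for x in t[1:]]


def _tree_from_jsonable(t):
    return tuple(t[:1] + [(_tree_from_jsonable(x) if isinstance(x, list) else x)
                          for x in t[1:]])


# ---------------------------------------------------------------- models
@dataclass(frozen=True)
class ExpressionModel:
    """An evolved expression with its linear output scaling and errors.

    The prediction is ``scale_a * f(x) + scale_b`` where ``f`` is the
    expression tree; complexity is the node count of the tree.
    """

    tree: tuple
    feature_names: tuple[str, ...]
    scale_a: float = 1.0
    scale_b: float = 0.0
    train_mae: float = float("inf")
    val_mae: float = float("inf")

    @property
    def complexity(self) -> int:
        return tree_size(self.tree)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.feature_names[j] for j in sorted(tree_variables(self.tree)))

    @property
    def infix(self) -> str:
        core = tree_infix(self.tree, self.feature_names)
        if self.scale_a == 1.0 and self.scale_b == 0.0:
            return core
        return f"{self.scale_a:.6g}*{core} + {self.scale_b:.6g}"

    def predict(self, table) -> np.ndarray:
        X = _feature_matrix(table, self.feature_names)
        return self.scale_a * eval_tree(self.tree, X) + self.scale_b

    def to_dict(self) -> dict:
        return {"tree": _tree_to_jsonable(self.tree),
                "feature_names": list(self.feature_names),
                "scale_a": self.scale_a, "scale_b": self.scale_b,
                "train_mae": self.train_mae, "val_mae": self.val_mae,
                "complexity": self.complexity, "infix": self.infix}

    @classmethod
    def from_dict(cls, d: dict) -> "ExpressionModel":
        return cls(tree=_tree_from_jsonable(d["tree"]),
                   feature_names=tuple(d["feature_names"]),
                   scale_a=d["scale_a"], scale_b=d["scale_b"],
                   train_mae=d["train_mae"], val_mae=d["val_mae"])


def _feature_matrix(table, names: Sequence[str]) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        missing = [n for n in names if n not in table.columns]
        if missing:
            raise KeyError(f"unknown variable(s) in model: {missing}")
        return table.loc[:, list(names)].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def evaluate(model: ExpressionModel, table, target) -> float:
    """Mean absolute error of a model; +inf when any prediction is non-finite."""
    y = table[target].to_numpy(dtype=float) if isinstance(target, str) \
        else np.asarray(target, dtype=float)
    pred = model.predict(table)
    if not np.all(np.isfinite(pred)):
        return float("inf")
    return float(np.mean(np.abs(pred - y)))


# ---------------------------------------------------------------- config
@dataclass
class SRConfig:
    """Search configuration.  Defaults are desk-scale: population 500,
    200 generations, at most 10^6 model evaluations per run, k = 10
    independent runs with independent 80/20 splits."""

    target: str = "Vol"
    features: tuple[str, ...] | None = None  # None: all numeric non-target columns
    population_size: int = 500
    generations: int = 200
    max_evaluations: int = 1_000_000
    train_fraction: float = 0.8
    runs: int = 10
    seed: int = 0
    tournament_size: int = 5
    crossover_rate: float = 0.7
    mutation_rate: float = 0.9
    const_range: float = 5.0
    max_nodes: int = 40
    const_opt_every: int = 25    # generations between constant-optimisation passes

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")
        if min(self.population_size, self.generations, self.max_evaluations,
               self.runs) <= 0:
            raise ValueError("budgets must be positive")


# ------------------------------------------------------------ generation
def _random_leaf(rng, n_feat, const_range):
    if rng.uniform() < 0.75:
        return ("var", int(rng.integers(n_feat)))
    return ("const", float(np.round(rng.uniform(-const_range, const_range), 3)))


def _random_tree(rng, n_feat, const_range, depth):
    if depth <= 0 or (depth < 3 and rng.uniform() < 0.3):
        return _random_leaf(rng, n_feat, const_range)
    kind, op = _OP_CHOICES[rng.choice(len(_OP_CHOICES), p=_OP_WEIGHTS)]
    if kind == "u":
        return ("u", op, _random_tree(rng, n_feat, const_range, depth - 1))
    if kind == "pow":
        expo = float(np.round(rng.uniform(-3, 3), 2))
        return ("pow", _random_tree(rng, n_feat, const_range, depth - 1), expo)
    return ("b", op,
            _random_tree(rng, n_feat, const_range, depth - 1),
            _random_tree(rng, n_feat, const_range, depth - 1))


def _nodes_with_paths(t, path=()):
    yield path, t
    if t[0] == "u":
        yield from _nodes_with_paths(t[2], path + (2,))
    elif t[0] == "pow":
        yield from _nodes_with_paths(t[1], path + (1,))
    elif t[0] == "b":
        yield from _nodes_with_paths(t[2], path + (2,))
        yield from _nodes_with_paths(t[3], path + (3,))


def _replace_at(t, path, sub):
    if not path:
        return sub
    i = path[0]
    lst = list(t)
    lst[i] = _replace_at(t[i], path[1:], sub)
    return tuple(lst)


def _pick_node(rng, t):
    nodes = list(_nodes_with_paths(t))
    return nodes[int(rng.integers(len(nodes)))]


def crossover(rng, t1, t2, max_nodes):
    p1, _ = _pick_node(rng, t1)
    _, s2 = _pick_node(rng, t2)
    child = _replace_at(t1, p1, s2)
    return child if tree_size(child) <= max_nodes else t1


def mutate(rng, t, n_feat, const_range, max_nodes):
    r = rng.uniform()
    path, node = _pick_node(rng, t)
    if r < 0.3:  # subtree mutation
        sub = _random_tree(rng, n_feat, const_range, depth=int(rng.integers(1, 4)))
        child = _replace_at(t, path, sub)
        return child if tree_size(child) <= max_nodes else t
    if r < 0.6:  # point mutation
        if node[0] == "b":
            op = BINARY_OPS[int(rng.integers(len(BINARY_OPS)))]
            return _replace_at(t, path, ("b", op, node[2], node[3]))
        if node[0] == "u":
            op = UNARY_OPS[int(rng.integers(len(UNARY_OPS)))]
            return _replace_at(t, path, ("u", op, node[2]))
        return _replace_at(t, path, _random_leaf(rng, n_feat, const_range))
    # constant jitter (also perturbs pow exponents, clamped)
    consts = [(p, n) for p, n in _nodes_with_paths(t)
              if n[0] in ("const", "pow")]
    if not consts:
        return _replace_at(t, path, _random_leaf(rng, n_feat, const_range))
    p, n = consts[int(rng.integers(len(consts)))]
    if n[0] == "const":
        c = n[1] + rng.normal(0.0, 0.5 * abs(n[1]) + 0.1)
        return _replace_at(t, p, ("const", float(c)))
    e = float(np.clip(n[2] + rng.normal(0.0, 0.25), -MAX_POW, MAX_POW))
    return _replace_at(t, p, ("pow", n[1], e))


# ------------------------------------------------------------- evaluation
def _fit_scale(raw: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope/intercept of y on the raw tree output."""
    with np.errstate(all="ignore"):
        var = np.var(raw)
    if not np.isfinite(var) or var < 1e-30:
        return 0.0, float(np.mean(y))
    a = float(np.cov(raw, y, bias=True)[0, 1] / var)
    return a, float(np.mean(y) - a * np.mean(raw))


def _score(tree, Xtr, ytr) -> tuple[float, float, float]:
    """(train MAE, scale a, scale b); +inf MAE when infeasible on train."""
    raw = eval_tree(tree, Xtr)
    if not np.all(np.isfinite(raw)):
        return float("inf"), 1.0, 0.0
    a, b = _fit_scale(raw, ytr)
    return float(np.mean(np.abs(a * raw + b - ytr))), a, b


def _const_paths(t):
    out = []
    for p, n in _nodes_with_paths(t):
        if n[0] == "const":
            out.append((p, 1))
        elif n[0] == "pow":
            out.append((p, 2))
    return out


def _optimize_constants(tree, Xtr, ytr, max_consts: int = 6):
    """Refine the tree's constants by local least squares (scaling refit
    per step).  Returns the (possibly improved) tree."""
    paths = _const_paths(tree)
    if not paths or len(paths) > max_consts:
        return tree

    def build(theta):
        t = tree
        for (p, slot), v in zip(paths, theta):
            node = t
            for i in p:
                node = node[i]
            if slot == 2:
                v = float(np.clip(v, -MAX_POW, MAX_POW))
                t = _replace_at(t, p, ("pow", node[1], v))
            else:
                t = _replace_at(t, p, ("const", float(v)))
        return t

    theta0 = []
    t0 = tree
    for p, slot in paths:
        node = t0
        for i in p:
            node = node[i]
        theta0.append(node[slot])

    def residuals(theta):
        raw = eval_tree(build(theta), Xtr)
        if not np.all(np.isfinite(raw)):
            return np.full(ytr.size, 1e6)
        a, b = _fit_scale(raw, ytr)
        return a * raw + b - ytr

    try:
        sol = least_squares(residuals, np.asarray(theta0, dtype=float),
                            method="lm", max_nfev=60 * len(paths))
    except Exception:
        return tree
    cand = build(sol.x)
    return cand if _score(cand, Xtr, ytr)[0] <= _score(tree, Xtr, ytr)[0] else tree


# ----------------------------------------------------------------- search
@dataclass
class RunResult:
    """One GP run: its Pareto front and best (validation) model."""

    front: list[ExpressionModel]
    best: ExpressionModel
    seed: int
    train_index: np.ndarray
    val_index: np.ndarray
    evaluations: int


class _Archive:
    """Best training MAE per complexity level; yields the strict front."""

    def __init__(self):
        self.by_complexity: dict[int, tuple[float, tuple, float, float]] = {}

    def offer(self, tree, mae, a, b):
        if not np.isfinite(mae):
            return
        c = tree_size(tree)
        cur = self.by_complexity.get(c)
        if cur is None or mae < cur[0]:
            self.by_complexity[c] = (mae, tree, a, b)

    def front(self) -> list[tuple[int, float, tuple, float, float]]:
        out = []
        best = float("inf")
        for c in sorted(self.by_complexity):
            mae, tree, a, b = self.by_complexity[c]
            if mae < best:  # strictly improving in MAE as complexity grows
                out.append((c, mae, tree, a, b))
                best = mae
        return out


def evolve(table: pd.DataFrame, target: str, config: SRConfig,
           seed: int | None = None) -> RunResult:
    """One steady-state GP run; deterministic under a fixed seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    features = config.features
    if features is None:
        features = tuple(c for c in table.select_dtypes("number").columns
                         if c != target)
    if len(table) < 10:
        raise ValueError("need at least 10 rows for symbolic regression")
    used = list(features) + [target]
    if table[used].isna().any().any():
        raise ValueError("missing values in feature/target columns")
    y_all = table[target].to_numpy(dtype=float)
    if np.ptp(y_all) == 0:
        raise ValueError(f"target {target!r} has zero variance")
    X_all = _feature_matrix(table, features)

    n = len(table)
    perm = rng.permutation(n)
    n_tr = max(2, int(round(config.train_fraction * n)))
    n_tr = min(n_tr, n - 1)
    tr, va = np.sort(perm[:n_tr]), np.sort(perm[n_tr:])
    Xtr, ytr = X_all[tr], y_all[tr]
    Xva, yva = X_all[va], y_all[va]

    n_feat = len(features)
    evals = 0
    archive = _Archive()

    def scored(tree):
        nonlocal evals
        evals += 1
        mae, a, b = _score(tree, Xtr, ytr)
        archive.offer(tree, mae, a, b)
        return [tree, mae, a, b]

    pop = []
    depths = [2, 3, 4]
    for i in range(config.population_size):
        pop.append(scored(_random_tree(rng, n_feat, config.const_range,
                                       depths[i % len(depths)])))

    def tournament(best=True):
        idx = rng.integers(len(pop), size=config.tournament_size)
        key = min if best else max
        return int(key(idx, key=lambda i: (pop[i][1], tree_size(pop[i][0]))))

    best_idx = min(range(len(pop)), key=lambda i: pop[i][1])
    gen = 0
    while gen < config.generations and evals < config.max_evaluations:
        gen += 1
        for _ in range(config.population_size):
            if evals >= config.max_evaluations:
                break
            if rng.uniform() < config.crossover_rate:
                t = crossover(rng, pop[tournament()][0], pop[tournament()][0],
                              config.max_nodes)
            else:
                t = pop[tournament()][0]
            if rng.uniform() < config.mutation_rate:
                t = mutate(rng, t, n_feat, config.const_range, config.max_nodes)
            child = scored(t)
            victim = tournament(best=False)
            if victim == best_idx:  # elitism: the incumbent best survives
                continue
            pop[victim] = child
            if child[1] < pop[best_idx][1]:
                best_idx = victim
        if gen % config.const_opt_every == 0:
            for c, mae, tree, a, b in archive.front():
                scored(_optimize_constants(tree, Xtr, ytr))

    for c, mae, tree, a, b in archive.front():
        scored(_optimize_constants(tree, Xtr, ytr))

    front_models = []
    for c, mae, tree, a, b in archive.front():
        raw_va = eval_tree(tree, Xva)
        pred_va = a * raw_va + b
        val = float(np.mean(np.abs(pred_va - yva))) \
            if np.all(np.isfinite(pred_va)) else float("inf")
        front_models.append(ExpressionModel(
            tree=tree, feature_names=tuple(features), scale_a=a, scale_b=b,
            train_mae=mae, val_mae=val))

    best = min(front_models, key=lambda m: (m.val_mae, m.complexity))
    return RunResult(front=front_models, best=best, seed=seed,
                     train_index=tr, val_index=va, evaluations=evals)


# ------------------------------------------------------------ aggregation
@dataclass
class ExperimentResult:
    """k independent runs with pooled importance and sensitivity tables."""

    runs: list[RunResult]
    importance: pd.Series
    sensitivity: pd.DataFrame
    target: str

    @property
    def best_models(self) -> list[ExpressionModel]:
        return [r.best for r in self.runs]

    def save_models(self, path) -> None:
        payload = [{"seed": r.seed, "evaluations": r.evaluations,
                    "best": r.best.to_dict(),
                    "front": [m.to_dict() for m in r.front]} for r in self.runs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def variable_importance(models: Iterable[ExpressionModel]) -> pd.Series:
    """Normalized fitness-weighted variable importance over a model pool.

    importance(v) ∝ Σ_m w_m·1[v ∈ m] with w_m = 1/(ε + validation MAE of
    m), normalized so the importances sum to 1; ranked descending.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model set")
    eps = 1e-12
    weights: dict[str, float] = {}
    total_w = 0.0
    for m in models:
        w = 1.0 / (eps + m.val_mae) if np.isfinite(m.val_mae) else 0.0
        total_w += w
        for v in m.variables:
            weights[v] = weights.get(v, 0.0) + w
    if total_w == 0 or not weights:
        raise ValueError("no feasible model contains any variable")
    s = pd.Series(weights, dtype=float) / total_w
    s = s / s.sum()
    return s.sort_values(ascending=False).rename("importance")


def sensitivity(model: ExpressionModel, table: pd.DataFrame, target: str,
                rel_step: float = 1e-4) -> pd.DataFrame:
    """Signed standardized sensitivity of a model to each of its variables.

    For variable x_j: mean over rows of ∂f/∂x_j (central difference with
    step ``rel_step``·SD(x_j)) times SD(x_j)/SD(f).  Positive means the
    target increases when the variable increases.  Rows where the
    derivative is undefined are dropped; a variable is flagged when more
    than 10% of rows are undefined.
    """
    X = _feature_matrix(table, model.feature_names)
    base = model.scale_a * eval_tree(model.tree, X) + model.scale_b
    if not np.all(np.isfinite(base)):
        raise ValueError("model is infeasible on this table")
    sd_f = float(np.std(base))
    rows = []
    for name in model.variables:
        j = model.feature_names.index(name)
        sd_x = float(np.std(X[:, j]))
        if sd_x == 0 or sd_f == 0:
            rows.append({"variable": name, "signed_magnitude": 0.0,
                         "frac_undefined": 0.0, "flagged": sd_x == 0})
            continue
        h = rel_step * sd_x
        Xp, Xm = X.copy(), X.copy()
        Xp[:, j] += h
        Xm[:, j] -= h
        fp = model.scale_a * eval_tree(model.tree, Xp) + model.scale_b
        fm = model.scale_a * eval_tree(model.tree, Xm) + model.scale_b
        d = (fp - fm) / (2.0 * h)
        ok = np.isfinite(d)
        frac_bad = 1.0 - ok.mean()
        mag = float(np.mean(d[ok]) * sd_x / sd_f) if ok.any() else float("nan")
        rows.append({"variable": name, "signed_magnitude": mag,
                     "frac_undefined": float(frac_bad),
                     "flagged": frac_bad > 0.10})
    return pd.DataFrame(rows).set_index("variable")


def sensitivity_table(models: Iterable[ExpressionModel], table: pd.DataFrame,
                      target: str) -> pd.DataFrame:
    """Mean magnitude of effects over the best model of each run.

    Averages the signed sensitivity of each variable over the models that
    contain it and reports in how many best models it appears.
    """
    acc: dict[str, list[float]] = {}
    n_models = 0
    for m in models:
        n_models += 1
        try:
            s = sensitivity(m, table, target)
        except ValueError:
            continue
        for v, row in s.iterrows():
            if np.isfinite(row.signed_magnitude):
                acc.setdefault(v, []).append(row.signed_magnitude)
    rows = [{"variable": v, "mean_magnitude": float(np.mean(vals)),
             "n_models": len(vals)} for v, vals in acc.items()]
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["mean_magnitude", "n_models"])
    return out.set_index("variable").sort_values(
        "mean_magnitude", key=np.abs, ascending=False)


def run_experiments(table: pd.DataFrame, target: str,
                    config: SRConfig) -> ExperimentResult:
    """k independent GP runs with derived seeds and independent splits."""
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(config.seed).spawn(config.runs)]
    runs = [evolve(table, target, config, seed=s) for s in child_seeds]
    pooled = [m for r in runs for m in r.front]
    importance = variable_importance(pooled)
    sens = sensitivity_table([r.best for r in runs], table, target)
    return ExperimentResult(runs=runs, importance=importance,
                            sensitivity=sens, target=target)
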