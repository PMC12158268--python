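"""Multigene genetic-programming symbolic regression.

A model is a weighted sum of evolved expression trees ("genes") plus a bias:

    y_hat = b0 + w1 * g1(x1, x2) + ... + wG * gG(x1, x2)

The tree structures evolve by tournament selection, subtree/gene crossover
and subtree mutation; the output weights are not evolved but re-fit by
ordinary least squares at every fitness evaluation, so the search only has
to discover useful basis functions. Fitness is the training RMSE (seconds);
an occasional Pareto tournament on (RMSE, expression complexity) keeps the
population from bloating.

The function set is {+, -, *, natural log, square} plus ephemeral random
constants in [-10, 10]: log and square are the nonlinearities appearing in
the published response-time surface, so the published model is expressible.
Log is "protected" only in the sense that a gene whose log argument is
non-positive anywhere on the training inputs is assigned infinite fitness
and selected away — predictions never silently patch the domain error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIABLES = ("x1", "x2")
# name -> arity
FUNCTIONS = {"add": 2, "sub": 2, "mul": 2, "log": 1, "square": 1}
_CONST_RANGE = (-10.0, 10.0)


class EvalDomainError(ValueError):
    """A gene hit an invalid operation (log of a non-positive value)."""


# ---------------------------------------------------------------------------
# Expression trees (nested tuples: ("x1",), ("const", 3.2), ("add", l, r), ...)
# ---------------------------------------------------------------------------


def tree_depth(tree) -> int:
    if tree[0] in VARIABLES or tree[0] == "const":
        return 0
    return 1 + max(tree_depth(c) for c in tree[1:])


def tree_size(tree) -> int:
    if tree[0] in VARIABLES or tree[0] == "const":
        return 1
    return 1 + sum(tree_size(c) for c in tree[1:])


def eval_tree(tree, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Evaluate a tree elementwise over input arrays.

    Raises :class:`EvalDomainError` when log meets a non-positive argument.
    """
    op = tree[0]
    if op == "x1":
        return x1
    if op == "x2":
        return x2
    if op == "const":
        return np.full_like(np.asarray(x1, dtype=float), tree[1])
    if op == "add":
        return eval_tree(tree[1], x1, x2) + eval_tree(tree[2], x1, x2)
    if op == "sub":
        return eval_tree(tree[1], x1, x2) - eval_tree(tree[2], x1, x2)
    if op == "mul":
        return eval_tree(tree[1], x1, x2) * eval_tree(tree[2], x1, x2)
    if op == "log":
        arg = eval_tree(tree[1], x1, x2)
        if np.any(arg <= 0):
            raise EvalDomainError("log of non-positive value")
        return np.log(arg)
    if op == "square":
        child = eval_tree(tree[1], x1, x2)
        return child * child
    raise ValueError(f"unknown node {op!r}")


def tree_to_string(tree) -> str:
    op = tree[0]
    if op in VARIABLES:
        return op
    if op == "const":
        return repr(float(tree[1]))
    if op == "add":
        return f"({tree_to_string(tree[1])} + {tree_to_string(tree[2])})"
    if op == "sub":
        return f"({tree_to_string(tree[1])} - {tree_to_string(tree[2])})"
    if op == "mul":
        return f"({tree_to_string(tree[1])} * {tree_to_string(tree[2])})"
    if op == "log":
        return f"log({tree_to_string(tree[1])})"  # natural log
    if op == "square":
        return f"({tree_to_string(tree[1])})^2"
    raise ValueError(f"unknown node {op!r}")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class GPModel:
    genes: list
    weights: np.ndarray
    bias: float
    train_rmse: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "weights": np.asarray(self.weights).tolist(),
                "bias": float(self.bias),
                "train_rmse": float(self.train_rmse),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GPModel":
        def detuple(node):
            return tuple(detuple(n) if isinstance(n, list) else n for n in node)

        raw = json.loads(text)
        genes = [detuple(g) for g in raw["genes"]]
        return cls(
            genes=genes,
            weights=np.asarray(raw["weights"], dtype=float),
            bias=float(raw["bias"]),
            train_rmse=float(raw["train_rmse"]),
        )


def predict(model: GPModel, x1, x2):
    """Evaluate a model at (x1, x2); inputs may be scalars or arrays.

    Propagates log domain errors, naming the offending gene.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    out = np.full_like(x1, model.bias, dtype=float)
    for i, (gene, w) in enumerate(zip(model.genes, model.weights)):
        try:
            out = out + w * eval_tree(gene, x1, x2)
        except EvalDomainError as err:
            raise EvalDomainError(f"gene {i}: {err}") from err
    return float(out) if out.ndim == 0 else out


def model_to_expression(model: GPModel) -> str:
    """Render the model as a single human-readable infix expression.

    The string uses ``log(...)`` for the natural logarithm and ``(...)^2``
    for squaring, and parses back with :func:`parse_expression` to a
    function that agrees with :func:`predict`.
    """
    parts = [repr(float(model.bias))]
    for gene, w in zip(model.genes, model.weights):
        parts.append(f"{float(w)!r}*{tree_to_string(gene)}")
    return " + ".join(parts)


def parse_expression(text: str):
    """Parse an expression emitted by :func:`model_to_expression`.

    Grammar: numbers (including negative literals), ``x1``/``x2``, binary
    ``+ - *``, parentheses, ``log(expr)`` and ``(expr)^2``. Returns a
    callable ``f(x1, x2)``.
    """
    import re

    tokens = re.findall(r"log|x1|x2|\^2|[-+*()]|\d+\.?\d*(?:[eE][-+]?\d+)?", text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValueError(f"expected {expected!r}, got {tok!r}")
        pos += 1
        return tok

    def parse_sum():
        node = parse_term()
        while peek() in ("+", "-"):
            op = take()
            node = ("add" if op == "+" else "sub", node, parse_term())
        return node

    def parse_term():
        node = parse_factor()
        while peek() == "*":
            take("*")
            node = ("mul", node, parse_factor())
        return node

    def parse_factor():
        tok = peek()
        if tok == "-":
            take("-")
            return ("sub", ("const", 0.0), parse_factor())
        if tok == "+":
            take("+")
            return parse_factor()
        if tok == "log":
            take("log")
            take("(")
            inner = parse_sum()
            take(")")
            return postfix(("log", inner))
        if tok == "(":
            take("(")
            inner = parse_sum()
            take(")")
            return postfix(inner)
        if tok in VARIABLES:
            take()
            return postfix((tok,))
        take()
        return postfix(("const", float(tok)))

    def postfix(node):
        while peek() == "^2":
            take("^2")
            node = ("square", node)
        return node

    tree = parse_sum()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens at {pos}: {tokens[pos:]}")

    def f(x1, x2):
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        out = eval_tree(tree, x1, x2)
        return float(out) if np.ndim(out) == 0 else out

    return f


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


@dataclass
class GPHyperparams:
    """Evolution settings; defaults are the study configuration."""

    population_size: int = 100
    max_generations: int = 50
    tournament_size: int = 10
    elite_fraction: float = 0.1
    pareto_tournament_prob: float = 0.1
    max_genes: int = 20
    max_tree_depth: int = 10
    crossover_prob: float = 0.84
    mutation_prob: float = 0.14

    def validate(self) -> None:
        for name in ("elite_fraction", "pareto_tournament_prob", "crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.crossover_prob + self.mutation_prob > 1:
            raise ValueError("crossover_prob + mutation_prob must be <= 1")
        for name in ("population_size", "max_generations", "tournament_size", "max_genes", "max_tree_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class _Individual:
    genes: list
    weights: np.ndarray | None = None
    bias: float = 0.0
    rmse: float = np.inf
    complexity: int = 0


def _grow_tree(rng, depth_budget: int, full: bool):
    if depth_budget <= 0 or (not full and rng.random() < 0.3):
        r = rng.random()
        if r < 0.4:
            return ("x1",)
        if r < 0.8:
            return ("x2",)
        return ("const", float(rng.uniform(*_CONST_RANGE)))
    op = list(FUNCTIONS)[rng.integers(0, len(FUNCTIONS))]
    children = [_grow_tree(rng, depth_budget - 1, full) for _ in range(FUNCTIONS[op])]
    return (op, *children)


def _random_subtree_index(rng, tree) -> int:
    return int(rng.integers(0, tree_size(tree)))


def _get_subtree(tree, index: int):
    # preorder traversal
    stack = [tree]
    i = 0
    while stack:
        node = stack.pop(0)
        if i == index:
            return node
        i += 1
        if node[0] in FUNCTIONS:
            stack = list(node[1:]) + stack
    raise IndexError(index)


def _replace_subtree(tree, index: int, replacement):
    counter = [0]

    def rec(node):
        if counter[0] == index:
            counter[0] += 1
            return replacement
        counter[0] += 1
        if node[0] not in FUNCTIONS:
            return node
        return (node[0], *[rec(c) for c in node[1:]])

    return rec(tree)


def _fit_weights(genes, x1, x2, y):
    """Least-squares output weights for a gene set; returns (w, b, rmse).

    Returns None when any gene is invalid on the training inputs. Singular
    systems fall back to a small ridge penalty (logged).
    """
    cols = [np.ones_like(y)]
    for gene in genes:
        try:
            g = eval_tree(gene, x1, x2)
        except EvalDomainError:
            return None
        if not np.all(np.isfinite(g)):
            return None
        cols.append(np.broadcast_to(g, y.shape).astype(float))
    G = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(G, y, rcond=None)
    if not np.all(np.isfinite(coef)):
        logger.warning("singular least-squares system; falling back to ridge")
        lam = 1e-8
        coef = np.linalg.solve(G.T @ G + lam * np.eye(G.shape[1]), G.T @ y)
    resid = y - G @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return coef[1:], float(coef[0]), rmse


def _evaluate_individual(ind: _Individual, x1, x2, y) -> None:
    fit = _fit_weights(ind.genes, x1, x2, y)
    ind.complexity = sum(tree_size(g) for g in ind.genes)
    if fit is None:
        ind.weights, ind.bias, ind.rmse = None, 0.0, np.inf
    else:
        ind.weights, ind.bias, ind.rmse = fit


def _tournament(rng, population, params: GPHyperparams) -> _Individual:
    idx = rng.integers(0, len(population), size=params.tournament_size)
    entrants = [population[i] for i in idx]
    if rng.random() < params.pareto_tournament_prob:
        # Pareto tournament on (rmse, complexity): pick a non-dominated entrant.
        front = [
            e
            for e in entrants
            if not any(
                (o.rmse <= e.rmse and o.complexity <= e.complexity)
                and (o.rmse < e.rmse or o.complexity < e.complexity)
                for o in entrants
            )
        ]
        return front[rng.integers(0, len(front))]
    return min(entrants, key=lambda e: e.rmse)


def _crossover(rng, p1: _Individual, p2: _Individual, params) -> _Individual:
    if rng.random() < 0.5 and (len(p1.genes) > 1 or len(p2.genes) > 1):
        # High-level gene crossover: exchange random gene subsets.
        keep1 = [g for g in p1.genes if rng.random() < 0.5]
        give2 = [g for g in p2.genes if rng.random() < 0.5]
        genes = keep1 + give2
        if not genes:
            genes = [p1.genes[rng.integers(0, len(p1.genes))]]
        if len(genes) > params.max_genes:
            sel = rng.choice(len(genes), size=params.max_genes, replace=False)
            genes = [genes[i] for i in sorted(sel)]
        return _Individual(genes=genes)
    # Low-level subtree crossover within one gene of each parent.
    genes = list(p1.genes)
    gi = int(rng.integers(0, len(genes)))
    donor = p2.genes[int(rng.integers(0, len(p2.genes)))]
    for _ in range(10):
        sub = _get_subtree(donor, _random_subtree_index(rng, donor))
        child = _replace_subtree(genes[gi], _random_subtree_index(rng, genes[gi]), sub)
        if tree_depth(child) <= params.max_tree_depth:
            genes[gi] = child
            break
    return _Individual(genes=genes)


def _mutate(rng, parent: _Individual, params) -> _Individual:
    genes = list(parent.genes)
    gi = int(rng.integers(0, len(genes)))
    for _ in range(10):
        target = _random_subtree_index(rng, genes[gi])
        depth_budget = int(rng.integers(0, 4))
        child = _replace_subtree(genes[gi], target, _grow_tree(rng, depth_budget, full=False))
        if tree_depth(child) <= params.max_tree_depth:
            genes[gi] = child
            break
    return _Individual(genes=genes)


def evolve(
    dataset: pd.DataFrame,
    params: GPHyperparams | None = None,
    seed: int = 0,
    return_history: bool = False,
):
    """Evolve a multigene model of response time on (PEG, BTB).

    ``dataset`` uses the formulation-dataset schema (columns ``peg_pct``,
    ``btb_pct``, ``response_time_s``). Runs ``max_generations`` generations
    of tournament selection, crossover, mutation and elitism, tracking the
    best-ever individual, whose model is returned. The run is fully
    determined by ``seed``. With ``return_history=True`` also returns the
    best-ever RMSE after each generation.

    Raises ``ValueError`` for too few records or a constant input column.
    """
    if params is None:
        params = GPHyperparams()
    params.validate()
    for col in ("peg_pct", "btb_pct", "response_time_s"):
        if col not in dataset.columns:
            raise ValueError(f"dataset missing column {col!r}")
    x1 = dataset["peg_pct"].to_numpy(dtype=float)
    x2 = dataset["btb_pct"].to_numpy(dtype=float)
    y = dataset["response_time_s"].to_numpy(dtype=float)
    if len(y) < params.max_genes + 2:
        raise ValueError(f"need at least max_genes + 2 = {params.max_genes + 2} records")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("degenerate dataset: an input column is constant")

    rng = np.random.default_rng(seed)
    population = []
    for i in range(params.population_size):
        n_genes = int(rng.integers(1, 4))
        depth = 1 + i % 5  # ramped initial depths
        genes = [_grow_tree(rng, depth, full=bool(i % 2)) for _ in range(n_genes)]
        population.append(_Individual(genes=genes))
    for ind in population:
        _evaluate_individual(ind, x1, x2, y)

    def best_of(pop):
        return min(pop, key=lambda e: (e.rmse, e.complexity))

    best = best_of(population)
    history = []
    n_elite = max(1, int(round(params.elite_fraction * params.population_size)))
    for _gen in range(params.max_generations):
        ranked = sorted(population, key=lambda e: (e.rmse, e.complexity))
        next_pop = [
            _Individual(genes=list(e.genes), weights=e.weights, bias=e.bias,
                        rmse=e.rmse, complexity=e.complexity)
            for e in ranked[:n_elite]
        ]
        while len(next_pop) < params.population_size:
            r = rng.random()
            p1 = _tournament(rng, population, params)
            if r < params.crossover_prob:
                child = _crossover(rng, p1, _tournament(rng, population, params), params)
            elif r < params.crossover_prob + params.mutation_prob:
                child = _mutate(rng, p1, params)
            else:
                child = _Individual(genes=list(p1.genes))
            _evaluate_individual(child, x1, x2, y)
            next_pop.append(child)
        population = next_pop
        gen_best = best_of(population)
        if (gen_best.rmse, gen_best.complexity) < (best.rmse, best.complexity):
            best = gen_best
        history.append(best.rmse)

    if best.weights is None:
        raise RuntimeError("no valid individual evolved")
    model = GPModel(
        genes=list(best.genes),
        weights=np.asarray(best.weights, dtype=float),
        bias=float(best.bias),
        train_rmse=float(best.rmse),
    )
    if return_history:
        return model, np.asarray(history)
    return model
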