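"""Genetic-programming binary classifiers with feature selection.

Classifiers are expression trees over the 11 RoI descriptors: an RoI is
labelled positive when the expression evaluates to a value > 0.  The raw
fitness of a tree is its training error rate (0 = perfect), populations
evolve by roulette-wheel selection on linearly scaled fitness, subtree
crossover (rate 0.9), rare subtree mutation (rate 2e-4) and elitism, with
depth capped at 4 to keep the classifiers small enough to run onboard a
low-power imaging device.

Feature selection: the best-of-run trees collected across all CV runs form
a population pool; a feature is deemed relevant when its occurrence count
among pool members exceeds the upper-tail threshold of a Bernoulli trial
under the equal-probability null (two-tailed alpha, upper tail used).  The
deployed recognizer is a sign-vote ensemble of the pool members that use
only relevant features and the fewest of them.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .dataset import CVPlan, Dataset, make_cv_runs
from .features import FEATURE_ALIASES, FEATURE_NAMES

_CLAMP = 1e12
_DIV_EPS = 1e-12

BINARY_OPS = ("add", "sub", "mul", "div")
UNARY_OPS = ("sqrt", "log", "sin", "cos", "tan", "atan")
_OP_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


class GPError(ValueError):
    pass


class ParseError(GPError):
    pass


# ----------------------------------------------------------------------
# expression trees
# ----------------------------------------------------------------------

class Node:
    """One tree node: an operator, a variable, or a constant."""

    __slots__ = ("op", "value", "children")

    def __init__(self, op: str, children: tuple = (), value=None):
        self.op = op
        self.children = children
        self.value = value

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({serialize_expression(self)!r})"


def variable(name: str) -> Node:
    return Node("var", value=name)


def constant(v: float) -> Node:
    return Node("const", value=float(v))


def depth(node: Node) -> int:
    """Tree depth; a lone leaf has depth 0."""
    if not node.children:
        return 0
    return 1 + max(depth(c) for c in node.children)


def subtree_list(node: Node) -> list[Node]:
    """Preorder list of all subtrees."""
    out = [node]
    for c in node.children:
        out.extend(subtree_list(c))
    return out


def replace_subtree(node: Node, index: int, sub: Node) -> Node:
    """Copy of `node` with the preorder `index`-th subtree replaced."""

    def rec(n: Node, i: int) -> tuple[Node, int]:
        if i == index:
            return sub, i + 1
        if not n.children:
            return n, i + 1
        i += 1
        new_children = []
        changed = False
        for c in n.children:
            nc, i = rec(c, i)
            changed = changed or nc is not c
            new_children.append(nc)
        if not changed:
            return n, i
        return Node(n.op, tuple(new_children), n.value), i

    new, _ = rec(node, 0)
    return new


def variables_used(node: Node) -> frozenset[str]:
    return frozenset(n.value for n in subtree_list(node) if n.op == "var")


# ----------------------------------------------------------------------
# protected evaluation (Eq.-style total semantics)
# ----------------------------------------------------------------------

def _clamp(v):
    return np.clip(v, -_CLAMP, _CLAMP)


def _eval(node: Node, env: dict[str, np.ndarray]):
    op = node.op
    if op == "const":
        return node.value
    if op == "var":
        try:
            return env[node.value]
        except KeyError:
            raise GPError(f"unbound variable {node.value!r}") from None
    if op in BINARY_OPS:
        a = _eval(node.children[0], env)
        b = _eval(node.children[1], env)
        if op == "add":
            return _clamp(a + b)
        if op == "sub":
            return _clamp(a - b)
        if op == "mul":
            return _clamp(a * b)
        # protected division: a/b -> 1 where |b| ~ 0
        b_arr = np.asarray(b, dtype=float)
        safe = np.where(np.abs(b_arr) < _DIV_EPS, 1.0, b_arr)
        out = np.where(np.abs(b_arr) < _DIV_EPS, 1.0, np.asarray(a) / safe)
        return _clamp(out)
    a = _eval(node.children[0], env)
    if op == "sqrt":
        return np.sqrt(np.abs(a))
    if op == "log":
        a_arr = np.abs(np.asarray(a, dtype=float))
        with np.errstate(divide="ignore"):
            out = np.where(a_arr == 0.0, 0.0, np.log(np.where(a_arr == 0, 1.0, a_arr)))
        return _clamp(out)
    if op == "sin":
        return np.sin(a)
    if op == "cos":
        return np.cos(a)
    if op == "tan":
        return _clamp(np.tan(a))
    if op == "atan":
        return np.arctan(a)
    raise GPError(f"unknown operator {op!r}")  # pragma: no cover


def protected_eval(tree: Node, x: dict[str, float] | np.ndarray,
                   feature_names=FEATURE_NAMES) -> float:
    """Evaluate a tree at a single feature vector; always finite."""
    if isinstance(x, dict):
        env = {k: float(v) for k, v in x.items()}
    else:
        env = {n: float(v) for n, v in zip(feature_names, np.asarray(x, float))}
    return float(np.asarray(_eval(tree, env), dtype=float))


def eval_batch(tree: Node, X: np.ndarray, feature_names=FEATURE_NAMES) -> np.ndarray:
    """Vectorized evaluation over the rows of X (n x p)."""
    env = {n: X[:, j] for j, n in enumerate(feature_names)}
    out = _eval(tree, env)
    return np.broadcast_to(np.asarray(out, dtype=float), (len(X),)).copy()


def classify(tree: Node, x, feature_names=FEATURE_NAMES) -> int:
    """Binary decision: 1 iff the evaluation is strictly positive."""
    return int(protected_eval(tree, x, feature_names) > 0)


def classify_batch(tree: Node, X: np.ndarray, feature_names=FEATURE_NAMES) -> np.ndarray:
    return (eval_batch(tree, X, feature_names) > 0).astype(int)


def raw_fitness(tree: Node, E: Dataset) -> float:
    """Mean |J_c(x) - y| over the example set: the training error rate."""
    if E.n == 0:
        raise GPError("raw fitness needs a non-empty dataset")
    preds = classify_batch(tree, E.X, E.feature_names)
    return float(np.abs(preds - E.y).mean())


# ----------------------------------------------------------------------
# primitive set and initialization
# ----------------------------------------------------------------------

@dataclass
class PrimitiveSet:
    """Operators, variables, and the run's ephemeral constants.

    Constants are k reals drawn uniformly from [-10, 10] with k itself a
    uniform integer in [0, 10]; they are drawn once when the set is created
    and stay fixed through the evolution.
    """

    variables: tuple[str, ...] = FEATURE_NAMES
    constants: tuple[float, ...] = ()

    @classmethod
    def create(cls, rng: np.random.Generator,
               variables: tuple[str, ...] = FEATURE_NAMES) -> "PrimitiveSet":
        k = int(rng.integers(0, 11))
        return cls(variables=tuple(variables),
                   constants=tuple(rng.uniform(-10.0, 10.0, size=k)))

    def random_leaf(self, rng: np.random.Generator) -> Node:
        pool_size = len(self.variables) + len(self.constants)
        i = int(rng.integers(0, pool_size))
        if i < len(self.variables):
            return variable(self.variables[i])
        return constant(self.constants[i - len(self.variables)])

    def random_op(self, rng: np.random.Generator) -> str:
        ops = BINARY_OPS + UNARY_OPS
        return ops[int(rng.integers(0, len(ops)))]


@dataclass
class GPParams:
    population_size: int = 1000
    max_generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 2e-4
    max_depth: int = 4
    elitism: bool = True
    seed: int = 0


@dataclass
class Individual:
    tree: Node
    raw_fitness: float | None = None

    @property
    def variables_used(self) -> frozenset[str]:
        return variables_used(self.tree)


def _gen_tree(rng: np.random.Generator, pset: PrimitiveSet, budget: int,
              method: str) -> Node:
    if budget == 0:
        return pset.random_leaf(rng)
    if method == "grow":
        # uniform over all primitives and terminals
        n_term = len(pset.variables) + len(pset.constants)
        n_ops = len(BINARY_OPS) + len(UNARY_OPS)
        if rng.integers(0, n_term + n_ops) < n_term:
            return pset.random_leaf(rng)
    op = pset.random_op(rng)
    arity = 2 if op in BINARY_OPS else 1
    children = tuple(_gen_tree(rng, pset, budget - 1, method) for _ in range(arity))
    return Node(op, children)


def ramped_half_and_half(params: GPParams, pset: PrimitiveSet,
                         rng: np.random.Generator | None = None) -> list[Node]:
    """Initial population: depths ramped over 2..max_depth, half full/grow."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    depths = list(range(2, params.max_depth + 1))
    trees: list[Node] = []
    for i in range(params.population_size):
        d = depths[i % len(depths)]
        method = "full" if (i // len(depths)) % 2 == 0 else "grow"
        trees.append(_gen_tree(rng, pset, d, method))
    return trees


# ----------------------------------------------------------------------
# evolution
# ----------------------------------------------------------------------

def _roulette_pick(cum_scaled: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional selection via the cumulative scaled fitness."""
    u = rng.random() * cum_scaled[-1]
    return int(np.searchsorted(cum_scaled, u, side="right"))


def scaled_fitness(raw: np.ndarray) -> np.ndarray:
    """Linear scaling for roulette selection: (worst - raw) + 1e-6.

    Selection maximizes the scaled value; the epsilon keeps the wheel
    well-defined when every individual has the same raw fitness.
    """
    return (raw.max() - raw) + 1e-6


def reproduce(population: list[Node], cum_scaled: np.ndarray,
              params: GPParams, pset: PrimitiveSet,
              rng: np.random.Generator) -> tuple[Node, bool, bool, int]:
    """One reproduction event.

    Two parents are roulette-selected; with probability crossover_rate a
    subtree crossover produces the offspring, otherwise the first parent is
    cloned.  The offspring is then subtree-mutated with probability
    mutation_rate.  Offspring exceeding max_depth are discarded and the
    first parent cloned instead.  Returns (child, crossover_applied,
    mutation_applied, first_parent_index).
    """
    i = _roulette_pick(cum_scaled, rng)
    j = _roulette_pick(cum_scaled, rng)
    p1, p2 = population[i], population[j]
    crossed = rng.random() < params.crossover_rate
    if crossed:
        nodes1 = subtree_list(p1)
        nodes2 = subtree_list(p2)
        at = int(rng.integers(0, len(nodes1)))
        frm = int(rng.integers(0, len(nodes2)))
        child = replace_subtree(p1, at, nodes2[frm])
    else:
        child = p1
    mutated = rng.random() < params.mutation_rate
    if mutated:
        nodes = subtree_list(child)
        at = int(rng.integers(0, len(nodes)))
        sub = _gen_tree(rng, pset, int(rng.integers(0, params.max_depth + 1)), "grow")
        child = replace_subtree(child, at, sub)
    if depth(child) > params.max_depth:
        child = p1
    return child, crossed, mutated, i


@dataclass
class EvolutionLog:
    """Optional per-generation bookkeeping filled in by `evolve`."""

    pop_sizes: list[int] = field(default_factory=list)
    best_raw: list[float] = field(default_factory=list)
    n_reproductions: int = 0
    n_crossovers: int = 0


def evolve(E: Dataset, params: GPParams,
           pset: PrimitiveSet | None = None,
           rng: np.random.Generator | None = None,
           log: EvolutionLog | None = None) -> Individual:
    """Evolve a binary classifier on E; returns the best individual.

    Generational loop with roulette selection on scaled fitness, elitism,
    and early stop when a tree reaches raw fitness 0 (zero training
    errors) or max_generations is attained.
    """
    if E.n == 0:
        raise GPError("cannot evolve on an empty dataset")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pset = pset if pset is not None else PrimitiveSet.create(rng, E.feature_names)

    population = ramped_half_and_half(params, pset, rng)
    fitness = np.array([raw_fitness(t, E) for t in population])

    for _gen in range(params.max_generations):
        best_i = int(fitness.argmin())
        if log is not None:
            log.pop_sizes.append(len(population))
            log.best_raw.append(float(fitness[best_i]))
        if fitness[best_i] == 0.0:
            return Individual(population[best_i], 0.0)

        cum = np.cumsum(scaled_fitness(fitness))
        new_pop: list[Node] = []
        new_fit: list[float | None] = []
        if params.elitism:
            new_pop.append(population[best_i])
            new_fit.append(float(fitness[best_i]))
        while len(new_pop) < params.population_size:
            child, crossed, mutated, i = reproduce(population, cum, params, pset, rng)
            if log is not None:
                log.n_reproductions += 1
                log.n_crossovers += crossed
            new_pop.append(child)
            # an unchanged child (clone, or rejected-depth offspring that
            # fell back to the parent) keeps the parent's cached fitness
            new_fit.append(float(fitness[i]) if child is population[i] else None)
        population = new_pop
        fitness = np.array(
            [raw_fitness(t, E) if f is None else f for t, f in zip(population, new_fit)]
        )

    best_i = int(fitness.argmin())
    if log is not None:
        log.pop_sizes.append(len(population))
        log.best_raw.append(float(fitness[best_i]))
    return Individual(population[best_i], float(fitness[best_i]))


# ----------------------------------------------------------------------
# population pool, relevance test, ensemble
# ----------------------------------------------------------------------

@dataclass
class PopulationPool:
    """Best-of-run classifiers across the CV framework."""

    individuals: list[Individual]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def occurrence_counts(self) -> dict[str, int]:
        counts = {n: 0 for n in self.feature_names}
        for ind in self.individuals:
            for v in ind.variables_used:
                counts[v] += 1
        return counts


@dataclass
class RelevanceResult:
    p_value: float
    p0: float
    threshold_occurrences: int
    relevant_features: frozenset[str]


def build_population_pool(ds: Dataset, plan: CVPlan, params: GPParams) -> PopulationPool:
    """One best-of-run individual per CV run (fresh primitives per run)."""
    runs = make_cv_runs(ds, plan)
    individuals: list[Individual] = []
    for r, (train_idx, _val_idx) in enumerate(runs):
        rng = np.random.default_rng((params.seed, r))
        pset = PrimitiveSet.create(rng, ds.feature_names)
        individuals.append(evolve(ds.subset(train_idx), params, pset, rng))
    return PopulationPool(individuals, ds.feature_names)


def relevance_test(pool: PopulationPool, p_value: float = 0.001) -> RelevanceResult:
    """Bernoulli-trial test for feature relevance.

    Under the null every feature appears in a pool classifier with the same
    probability p0, estimated as the mean number of distinct variables per
    classifier divided by the number of features.  The occurrence threshold
    th is the smallest integer whose upper binomial tail P(X > th) with
    X ~ Bin(pool size, p0) is <= p_value / 2 (two-tailed test, upper tail
    deciding relevance); features occurring more than th times are
    relevant.
    """
    if not pool.individuals:
        raise GPError("relevance test needs a non-empty pool")
    n = len(pool.individuals)
    p = len(pool.feature_names)
    mean_vars = float(np.mean([len(ind.variables_used) for ind in pool.individuals]))
    p0 = mean_vars / p
    th = n
    for t in range(n + 1):
        if binom.sf(t, n, p0) <= p_value / 2.0:
            th = t
            break
    counts = pool.occurrence_counts
    relevant = frozenset(f for f, c in counts.items() if c > th)
    return RelevanceResult(p_value, p0, th, relevant)


@dataclass
class Ensemble:
    """Sign-vote ensemble of minimal-variable pool classifiers."""

    members: list[Individual]
    relevant_features: frozenset[str]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def classify(self, x) -> int:
        return ensemble_classify(self, x)

    def classify_batch(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(X))
        for m in self.members:
            votes += np.where(eval_batch(m.tree, X, self.feature_names) > 0, 1, -1)
        return (votes > 0).astype(int)


def build_ensemble(pool: PopulationPool, rel: RelevanceResult) -> Ensemble:
    """Members: pool individuals using only relevant features, and the
    smallest number of them (at least one)."""
    qualifying = [
        ind for ind in pool.individuals
        if ind.variables_used and ind.variables_used <= rel.relevant_features
    ]
    if not qualifying:
        raise GPError("no pool individual uses only relevant features")
    min_count = min(len(ind.variables_used) for ind in qualifying)
    members = [ind for ind in qualifying if len(ind.variables_used) == min_count]
    return Ensemble(members, rel.relevant_features, pool.feature_names)


def ensemble_classify(ens: Ensemble, x) -> int:
    """Each member votes +1/-1 by the sign of its evaluation; the ensemble
    answers 1 iff the vote sum is strictly positive (ties -> 0)."""
    if not ens.members:
        raise GPError("empty ensemble")
    vote = 0
    for m in ens.members:
        vote += 1 if protected_eval(m.tree, x, ens.feature_names) > 0 else -1
    return int(vote > 0)


# ----------------------------------------------------------------------
# expression text round trip
# ----------------------------------------------------------------------

_FUNC_NAMES = set(UNARY_OPS)


def parse_expression(text: str, feature_names=FEATURE_NAMES) -> Node:
    """Parse an infix expression into a tree.

    Accepts + - * /, the unary functions sqrt/log/sin/cos/tan/atan, numeric
    constants, the canonical feature names and their short codes (sAxm,
    sol, per, hstI, ctrs).  Raises ParseError with a position on unknown
    symbols or arity mismatches.
    """
    try:
        mod = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ParseError(f"syntax error at offset {exc.offset}: {exc.msg}") from None

    names = set(feature_names)

    def conv(node: ast.AST) -> Node:
        if isinstance(node, ast.Expression):
            return conv(node.body)
        if isinstance(node, ast.BinOp):
            ops = {ast.Add: "add", ast.Sub: "sub", ast.Mult: "mul", ast.Div: "div"}
            op = ops.get(type(node.op))
            if op is None:
                raise ParseError(
                    f"unsupported operator at col {node.col_offset}"
                )
            return Node(op, (conv(node.left), conv(node.right)))
        if isinstance(node, ast.UnaryOp):
            if isinstance(node.op, ast.USub):
                inner = conv(node.operand)
                if inner.op == "const":
                    return constant(-inner.value)
                return Node("sub", (constant(0.0), inner))
            raise ParseError(f"unsupported unary operator at col {node.col_offset}")
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNC_NAMES:
                fname = getattr(node.func, "id", "?")
                raise ParseError(
                    f"unknown function {fname!r} at col {node.col_offset}"
                )
            if len(node.args) != 1 or node.keywords:
                raise ParseError(
                    f"{node.func.id} takes exactly one argument "
                    f"(col {node.col_offset})"
                )
            return Node(node.func.id, (conv(node.args[0]),))
        if isinstance(node, ast.Name):
            name = FEATURE_ALIASES.get(node.id, node.id)
            if name not in names:
                raise ParseError(
                    f"unknown symbol {node.id!r} at col {node.col_offset}"
                )
            return variable(name)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return constant(node.value)
        raise ParseError(
            f"unsupported syntax at col {getattr(node, 'col_offset', 0)}"
        )

    return conv(mod)


def serialize_expression(tree: Node) -> str:
    """Infix text; parse(serialize(t)) evaluates identically to t."""
    if tree.op == "var":
        return tree.value
    if tree.op == "const":
        return repr(tree.value)
    if tree.op in BINARY_OPS:
        a = serialize_expression(tree.children[0])
        b = serialize_expression(tree.children[1])
        return f"({a} {_OP_SYMBOL[tree.op]} {b})"
    return f"{tree.op}({serialize_expression(tree.children[0])})"
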