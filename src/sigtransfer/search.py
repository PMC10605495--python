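"""Evolutionary search with random sampling over small gene formulas.

The search explores the space of 1–3-gene add/multiply expression trees for
one (dataset, cell type) training slice: an initial population is drawn
uniformly at random, every structure is fitted by maximum likelihood
(:func:`~sigtransfer.formula.fit_parameters`), the better half survives each
generation, and the population is refilled with mutants of survivors plus a
fixed fraction of fresh random immigrants. Fitted structures are cached by
canonical structure key, so the cost is governed by the number of *distinct*
structures visited rather than population × generations.

The run returns the ``n_models`` best distinct structures (by training loss,
then complexity, then expression string), mirroring the convention of keeping
a shortlist of ten candidate signatures per run for downstream transfer
evaluation and dominant-feature tallies.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import CellTypeSlice
from .formula import FormulaModel, FitResult, Leaf, Node, fit_parameters, complexity
from .metrics import MetricsReport, compute_metrics

__all__ = ["SearchConfig", "ModelCandidate", "SearchError", "sample_structure", "mutate", "search"]

logger = logging.getLogger(__name__)

_DEFAULT_RATES = {"swap_gene": 0.4, "swap_operator": 0.2, "grow": 0.2, "shrink": 0.2}


class SearchError(RuntimeError):
    pass


@dataclass
class SearchConfig:
    population_size: int = 64
    generations: int = 30
    max_features: int = 3
    n_models: int = 10
    mutation_rates: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    candidate_gene_pool: "list[str] | None" = None
    pool_size_cap: int = 500  # top-variance genes when no explicit pool is given
    seed: int = 0
    n_restarts_fit: int = 3

    def __post_init__(self) -> None:
        if self.n_models > self.population_size:
            raise ValueError("n_models cannot exceed population_size")
        if not 1 <= self.max_features <= 3:
            raise ValueError("max_features must be in [1, 3]")
        if sum(self.mutation_rates.values()) > 1 + 1e-9:
            raise ValueError("mutation rates must sum to at most 1")


@dataclass
class ModelCandidate:
    """A fitted structure with its training-slice metrics."""

    model: FormulaModel
    fit: FitResult
    train_metrics: MetricsReport


# ---------------------------------------------------------------------------
# structure sampling and mutation


def _left_deep(genes: list[str], ops: list[str]) -> FormulaModel:
    tree = Leaf(genes[0])
    for g, op in zip(genes[1:], ops):
        tree = Node(op=op, left=tree, right=Leaf(g))
    return FormulaModel(tree=tree)


def sample_structure(
    genes: list[str],
    config: SearchConfig,
    rng: np.random.Generator,
    gene_weights: "np.ndarray | None" = None,
) -> FormulaModel:
    """Draw a feature count uniformly, distinct genes, and a random operator
    assignment. ``gene_weights`` (aligned to ``genes``) optionally biases the
    gene draw — the search uses this to reinforce genes that recur in elite
    structures; without it the draw is uniform."""
    if not genes:
        raise ValueError("gene pool is empty")
    k = int(rng.integers(1, config.max_features + 1))
    k = min(k, len(genes))
    p = None
    if gene_weights is not None:
        p = np.asarray(gene_weights, dtype=float)
        p = p / p.sum()
    chosen = [genes[i] for i in rng.choice(len(genes), size=k, replace=False, p=p)]
    ops = [str(rng.choice(["add", "multiply"])) for _ in range(k - 1)]
    return _left_deep(chosen, ops)


def mutate(
    model: FormulaModel,
    pool: list[str],
    rates: dict,
    rng: np.random.Generator,
    max_features: int = 3,
    gene_weights: "np.ndarray | None" = None,
) -> FormulaModel:
    """Apply exactly one structural move; an illegal draw redraws the move kind
    (i.e. the draw is over the *legal* moves, with rates renormalized)."""
    n_feat = len(model.features)
    has_node = n_feat > 1
    has_unused = len(set(pool) - set(model.features)) > 0
    legal = {
        "swap_gene": has_unused,
        "swap_operator": has_node,
        "grow": n_feat < max_features and has_unused,
        "shrink": n_feat > 1,
    }
    moves = [m for m in rates if legal.get(m, False) and rates[m] > 0]
    if not moves:
        return sample_structure(pool, SearchConfig(max_features=max_features), rng, gene_weights)
    probs = np.asarray([rates[m] for m in moves], dtype=float)
    probs = probs / probs.sum()
    move = moves[int(rng.choice(len(moves), p=probs))]
    out = _try_move(model, move, pool, rng, max_features, gene_weights)
    assert out is not None
    return out


def _pick_unused(
    pool: list[str],
    unused: list[str],
    rng: np.random.Generator,
    gene_weights: "np.ndarray | None",
) -> str:
    if gene_weights is None:
        return unused[int(rng.integers(len(unused)))]
    w = {g: gene_weights[j] for j, g in enumerate(pool)}
    p = np.asarray([w[g] for g in unused], dtype=float)
    p = p / p.sum()
    return unused[int(rng.choice(len(unused), p=p))]


def _try_move(
    model: FormulaModel,
    move: str,
    pool: list[str],
    rng: np.random.Generator,
    max_features: int,
    gene_weights: "np.ndarray | None" = None,
) -> "FormulaModel | None":
    m = model.copy()
    used = set(m.features)
    unused = [g for g in pool if g not in used]
    leaves = m.leaves
    nodes = list(_internal_nodes(m))
    if move == "swap_gene":
        if not unused:
            return None
        leaf = leaves[int(rng.integers(len(leaves)))]
        leaf.gene = _pick_unused(pool, unused, rng, gene_weights)
        return m
    if move == "swap_operator":
        if not nodes:
            return None
        node = nodes[int(rng.integers(len(nodes)))]
        node.op = "multiply" if node.op == "add" else "add"
        return m
    if move == "grow":
        if len(m.features) >= max_features or not unused:
            return None
        new_leaf = Leaf(_pick_unused(pool, unused, rng, gene_weights))
        op = str(rng.choice(["add", "multiply"]))
        return FormulaModel(tree=Node(op=op, left=m.tree, right=new_leaf))
    if move == "shrink":
        if len(leaves) <= 1:
            return None
        victim = leaves[int(rng.integers(len(leaves)))]
        return FormulaModel(tree=_remove_leaf(m.tree, victim))
    raise ValueError(f"unknown move {move!r}")


def _internal_nodes(model: FormulaModel):
    def rec(t):
        if isinstance(t, Node):
            yield t
            yield from rec(t.left)
            yield from rec(t.right)

    yield from rec(model.tree)


def _remove_leaf(tree, victim: Leaf):
    """Drop one leaf, replacing its parent node with the sibling subtree."""
    if tree is victim:
        return None
    if isinstance(tree, Leaf):
        return tree
    left = _remove_leaf(tree.left, victim)
    right = _remove_leaf(tree.right, victim)
    if left is None:
        return right
    if right is None:
        return left
    return Node(op=tree.op, left=left, right=right)


# ---------------------------------------------------------------------------
# the generational loop


def _fit_seed(config_seed: int, key: str) -> int:
    digest = hashlib.sha256(f"{config_seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def default_gene_pool(slice_: CellTypeSlice, cap: int) -> list[str]:
    """The ``cap`` highest-variance genes of the training slice (tie: gene id)."""
    X = slice_.X
    if hasattr(X, "toarray") and X.shape[1] > 0:
        mean = np.asarray(X.mean(axis=0)).ravel()
        meansq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = meansq - mean**2
    else:
        var = np.asarray(X).var(axis=0)
    order = sorted(range(len(var)), key=lambda j: (-var[j], str(slice_.gene_ids[j])))
    return [str(slice_.gene_ids[j]) for j in order[: min(cap, len(var))]]


def search(slice_: CellTypeSlice, config: SearchConfig) -> list[ModelCandidate]:
    """Top ``n_models`` distinct fitted structures for one training slice."""
    if not slice_.has_both_classes():
        raise SearchError(
            f"slice {slice_.dataset_id}/{slice_.cell_type} has a single class"
        )
    pool = list(config.candidate_gene_pool or default_gene_pool(slice_, config.pool_size_cap))
    missing = [g for g in pool if g not in set(map(str, slice_.gene_ids))]
    if missing:
        raise ValueError(f"pool gene(s) absent from slice: {missing[:5]}")
    if not pool:
        raise ValueError("candidate gene pool is empty")

    rng = np.random.default_rng(config.seed)
    cache: dict[str, tuple[FormulaModel, FitResult]] = {}

    def fitted(structure: FormulaModel) -> tuple[str, float]:
        key = structure.structure_key()
        if key not in cache:
            m = structure.copy()
            fr = fit_parameters(
                m, slice_, n_restarts=config.n_restarts_fit,
                seed=_fit_seed(config.seed, key),
            )
            cache[key] = (m, fr)
        return key, cache[key][1].loss

    population = [sample_structure(pool, config, rng) for _ in range(config.population_size)]
    weights: "np.ndarray | None" = None  # gen 0 samples uniformly
    for gen in range(config.generations):
        scored = sorted((fitted(s) for s in population), key=lambda kv: kv[1])
        best = scored[0][1]
        logger.info("generation %d: best loss %.5f (%d structures cached)",
                    gen, best, len(cache))
        n_elite = config.population_size // 2
        elite_keys: list[str] = []
        for key, _ in scored:
            if key not in elite_keys:
                elite_keys.append(key)
            if len(elite_keys) == n_elite:
                break
        elites = [cache[k][0] for k in elite_keys]
        # reinforce genes that recur among elites: immigrants and gene swaps
        # draw from a 50/50 mixture of uniform and elite-feature frequency,
        # so well-performing genes meet in one structure while full support
        # over the pool is kept
        freq = np.zeros(len(pool))
        pool_idx = {g: j for j, g in enumerate(pool)}
        for e in elites:
            for g in e.features:
                freq[pool_idx[g]] += 1.0
        uniform = np.full(len(pool), 1.0 / len(pool))
        weights = 0.5 * uniform + 0.5 * freq / freq.sum() if freq.sum() else uniform
        n_fresh = max(1, round(0.2 * config.population_size))
        n_mut = config.population_size - len(elites) - n_fresh
        population = (
            elites
            + [
                mutate(elites[int(rng.integers(len(elites)))], pool,
                       config.mutation_rates, rng, config.max_features, weights)
                for _ in range(max(0, n_mut))
            ]
            + [sample_structure(pool, config, rng, weights) for _ in range(n_fresh)]
        )
    for s in population:  # fit the final generation too
        fitted(s)

    ranked = sorted(
        cache.items(),
        key=lambda kv: (kv[1][1].loss, complexity(kv[1][0]), kv[0]),
    )
    out: list[ModelCandidate] = []
    y = slice_.labels
    for key, (model, fr) in ranked[: config.n_models]:
        # polish the shortlist: more restarts and a full-precision optimizer run
        fr2 = fit_parameters(
            model, slice_, n_restarts=config.n_restarts_fit + 3,
            seed=_fit_seed(config.seed, "polish:" + key), maxiter=300,
        )
        scores = _predict(model, slice_)
        out.append(
            ModelCandidate(model=model, fit=fr2, train_metrics=compute_metrics(y, scores))
        )
    out.sort(key=lambda c: (c.fit.loss, complexity(c.model), c.model.structure_key()))
    return out


def _predict(model: FormulaModel, slice_: CellTypeSlice) -> np.ndarray:
    from .formula import evaluate

    X = slice_.feature_matrix(model.features) if model.features else np.zeros((slice_.n_cells, 0))
    return evaluate(model, X)
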