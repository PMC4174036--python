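"""Linear Gaussian Bayesian networks: representation, scoring, and search.

A linear Gaussian Bayesian network over nodes X1..Xn factorizes the joint
density as a product of per-node conditionals

    P(X1..Xn) = prod_i P(Xi | Pa(Xi)),
    Xi | Pa(Xi) ~ Normal(mu_i + sum_p b_p (x_p - mu_p), sigma_i^2),

so each node is a linear regression on its parents and the joint distribution
is multivariate normal.  Structures are selected by maximizing the BIC

    BIC(G | D) = log P(D | G, Theta*) - (d/2) log m

with Theta* the maximum-likelihood parameters, d = 2n + #edges the number of
free parameters (mean and residual variance per node plus one weight per
edge), and m the number of samples.  The search is greedy hill-climbing over
edge additions, deletions and reversals, restricted to candidate parents
proposed by L1-regularization paths, with random restarts; an exhaustive
enumerator over all labeled DAGs serves as the optimality oracle at small n.

Because the Gaussian family score depends on the data only through the
cross-product matrix Z'Z (Z = [1 | X]), scores are computed from cached
sufficient statistics, making each candidate evaluation independent of the
sample count.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lasso_path

from .roi_io import RoiTimeSeriesMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DagStructure",
    "GaussianNodeParams",
    "GaussianBnParameters",
    "BicScore",
    "BnModel",
    "LearnConfig",
    "fit_node_ml",
    "node_log_likelihood",
    "bic_score",
    "l1_parent_path",
    "learn_structure",
    "exhaustive_search",
    "enumerate_dags",
    "implied_covariance",
    "joint_log_likelihood",
    "cpdag",
]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DagStructure:
    """Directed acyclic graph: ordered node labels and per-node parent sets."""

    nodes: tuple[str, ...]
    parents: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        parents = {n: frozenset(self.parents.get(n, frozenset())) for n in self.nodes}
        object.__setattr__(self, "parents", parents)
        for child, pset in parents.items():
            if child in pset:
                raise ValueError(f"self-loop on {child!r}")
            if not pset <= node_set:
                raise ValueError(f"unknown parents {pset - node_set} of {child!r}")
        if self.topological_order() is None:
            raise ValueError("graph contains a cycle")

    @classmethod
    def from_edges(cls, nodes, edges) -> "DagStructure":
        parents: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v in edges:
            parents[v].add(u)
        return cls(tuple(nodes), {n: frozenset(p) for n, p in parents.items()})

    def edges(self) -> list[tuple[str, str]]:
        """Edge list (parent, child) in deterministic lexicographic order."""
        return sorted(
            (p, c) for c in self.nodes for p in self.parents[c]
        )

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self.parents.values())

    def topological_order(self) -> list[str] | None:
        """Kahn's algorithm; None if cyclic. Ties broken by node order."""
        indeg = {n: len(self.parents[n]) for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c in self.nodes:
            for p in self.parents[c]:
                children[p].append(c)
        ready = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        return order if len(order) == len(self.nodes) else None

    def with_edge(self, u: str, v: str) -> "DagStructure":
        parents = dict(self.parents)
        parents[v] = self.parents[v] | {u}
        return DagStructure(self.nodes, parents)

    def without_edge(self, u: str, v: str) -> "DagStructure":
        parents = dict(self.parents)
        parents[v] = self.parents[v] - {u}
        return DagStructure(self.nodes, parents)

    def creates_cycle(self, u: str, v: str) -> bool:
        """Would adding u->v create a cycle (i.e. is u reachable from v)?"""
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c in self.nodes:
            for p in self.parents[c]:
                children[p].append(c)
        stack, seen = [v], {v}
        while stack:
            n = stack.pop()
            if n == u:
                return True
            for c in children[n]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False


@dataclass(frozen=True)
class GaussianNodeParams:
    """Linear Gaussian conditional of one node given its parents."""

    mean: float
    weights: dict[str, float]
    residual_variance: float

    def __post_init__(self) -> None:
        if self.residual_variance <= 0:
            raise ValueError("residual variance must be > 0")


@dataclass(frozen=True)
class GaussianBnParameters:
    """Per-node parameter map covering every node of the companion structure."""

    node_params: dict[str, GaussianNodeParams]

    def __getitem__(self, node: str) -> GaussianNodeParams:
        return self.node_params[node]


@dataclass(frozen=True)
class BicScore:
    per_node_loglik: dict[str, float]
    d: int
    m: int

    @property
    def total_loglik(self) -> float:
        return float(sum(self.per_node_loglik.values()))

    @property
    def total(self) -> float:
        return self.total_loglik - 0.5 * self.d * np.log(self.m)


@dataclass(frozen=True)
class BnModel:
    structure: DagStructure
    params: GaussianBnParameters
    score: BicScore

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (p, c): self.params[c].weights[p]
            for p, c in self.structure.edges()
        }


@dataclass
class LearnConfig:
    """Knobs of the structure search.

    ``restarts`` counts random restarts in addition to the empty-graph start;
    ``n_lambdas``/``lambda_min_ratio`` shape the L1 path grid (log-spaced from
    the data-derived lambda_max); ``restrict_to_l1`` gates edge additions on
    lasso-path candidate membership.
    """

    restarts: int = 10
    seed: int = 0
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    restrict_to_l1: bool = True
    max_iter: int = 200
    min_gain: float = 1e-9
    restart_edge_prob: float = 0.25
    plateau_moves: int = 20


# ---------------------------------------------------------------------------
# ML fitting and likelihoods
# ---------------------------------------------------------------------------

def fit_node_ml(
    ts: RoiTimeSeriesMatrix, node: str, parent_set
) -> GaussianNodeParams:
    """ML fit of one node's linear Gaussian conditional.

    Weights are the OLS coefficients of the node on its parents (with
    intercept); the residual variance is the ML estimate RSS/m.  With no
    parents the fit reduces to the sample mean and ML variance.
    """
    parents = sorted(parent_set)
    idx = {lab: j for j, lab in enumerate(ts.node_labels)}
    y = ts.values[:, idx[node]]
    m = y.shape[0]
    if m <= len(parents) + 1:
        raise ValueError(f"{node!r}: m={m} too small for {len(parents)} parents")
    if not parents:
        mu = float(y.mean())
        var = float(np.mean((y - mu) ** 2))
        return GaussianNodeParams(mean=mu, weights={}, residual_variance=max(var, 1e-300))
    X = np.column_stack([np.ones(m)] + [ts.values[:, idx[p]] for p in parents])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"{node!r}: singular design; collinear parents among {parents}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    var = float(np.mean(resid**2))
    # express the intercept in centred form: u_i = mu_i + sum b_p (x_p - mu_p)
    parent_means = {p: float(ts.values[:, idx[p]].mean()) for p in parents}
    weights = {p: float(b) for p, b in zip(parents, beta[1:])}
    mu = float(beta[0] + sum(weights[p] * parent_means[p] for p in parents))
    return GaussianNodeParams(
        mean=mu, weights=weights, residual_variance=max(var, 1e-300)
    )


def node_log_likelihood(
    ts: RoiTimeSeriesMatrix,
    node: str,
    params: GaussianNodeParams,
    parent_means: dict[str, float] | None = None,
) -> float:
    """Sum over samples of the log Gaussian conditional density of ``node``.

    The conditional mean is mu_i + sum_p b_p (x_p - mu_p); parent means
    default to the sample means of the parent columns.
    """
    idx = {lab: j for j, lab in enumerate(ts.node_labels)}
    y = ts.values[:, idx[node]]
    mu = params.mean
    cond = np.full(y.shape, mu)
    for p, b in params.weights.items():
        xp = ts.values[:, idx[p]]
        mp = parent_means[p] if parent_means is not None else float(xp.mean())
        cond = cond + b * (xp - mp)
    var = params.residual_variance
    return float(
        -0.5 * np.sum((y - cond) ** 2) / var
        - 0.5 * y.shape[0] * np.log(2 * np.pi * var)
    )


# ---------------------------------------------------------------------------
# Gram-matrix score engine
# ---------------------------------------------------------------------------

class _ScoreEngine:
    """Family log-likelihoods from the cross-product matrix Z'Z, Z = [1 | X].

    For a child j with parent column set S, the OLS solution and residual sum
    of squares are functions of sub-blocks of C = Z'Z alone, so every family
    score costs O(|S|^3) regardless of m.  Scores are cached per
    (child, parent-set).
    """

    def __init__(self, values: np.ndarray):
        self.m = values.shape[0]
        self.n = values.shape[1]
        Z = np.column_stack([np.ones(self.m), values])
        self.C = Z.T @ Z
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def family_rss(self, j: int, parent_idx: frozenset[int]) -> float:
        cols = [0] + sorted(i + 1 for i in parent_idx)
        A = self.C[np.ix_(cols, cols)]
        b = self.C[cols, j + 1]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        rss = float(self.C[j + 1, j + 1] - beta @ b)
        return max(rss, 1e-300)

    def family_loglik(self, j: int, parent_idx: frozenset[int]) -> float:
        """Maximized conditional log-likelihood: -(m/2)(log(2 pi RSS/m) + 1)."""
        key = (j, parent_idx)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        rss = self.family_rss(j, parent_idx)
        ll = -0.5 * self.m * (np.log(2 * np.pi * rss / self.m) + 1.0)
        self._cache[key] = ll
        return ll

    def structure_loglik(self, parent_idx_map: dict[int, frozenset[int]]) -> float:
        return sum(self.family_loglik(j, ps) for j, ps in parent_idx_map.items())


def bic_score(structure: DagStructure, ts: RoiTimeSeriesMatrix) -> BicScore:
    """BIC of a structure: per-node ML log-likelihoods minus (d/2) log m."""
    if tuple(ts.node_labels) != structure.nodes:
        if set(ts.node_labels) != set(structure.nodes):
            raise ValueError("structure nodes do not match time-series labels")
    engine = _ScoreEngine(ts.values)
    idx = {lab: j for j, lab in enumerate(ts.node_labels)}
    per_node = {
        node: engine.family_loglik(
            idx[node], frozenset(idx[p] for p in structure.parents[node])
        )
        for node in structure.nodes
    }
    d = 2 * len(structure.nodes) + structure.n_edges
    return BicScore(per_node_loglik=per_node, d=d, m=ts.n_samples)


def _fit_all_params(structure: DagStructure, ts: RoiTimeSeriesMatrix) -> GaussianBnParameters:
    return GaussianBnParameters(
        {n: fit_node_ml(ts, n, structure.parents[n]) for n in structure.nodes}
    )


def _model_from_structure(structure: DagStructure, ts: RoiTimeSeriesMatrix) -> BnModel:
    return BnModel(
        structure=structure, params=_fit_all_params(structure, ts),
        score=bic_score(structure, ts),
    )


# ---------------------------------------------------------------------------
# L1 candidate parents
# ---------------------------------------------------------------------------

def l1_parent_path(
    ts: RoiTimeSeriesMatrix,
    node: str,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> list[frozenset[str]]:
    """Candidate parent sets along the lasso path of ``node`` on all others.

    The penalty grid is log-spaced over ``n_lambdas`` points from the
    data-derived lambda_max (smallest penalty with empty support) down to
    ``lambda_min_ratio * lambda_max``; supports are deduplicated in order of
    appearance, starting from the empty set.
    """
    idx = {lab: j for j, lab in enumerate(ts.node_labels)}
    if node not in idx:
        raise ValueError(f"unknown node {node!r}")
    others = [lab for lab in ts.node_labels if lab != node]
    y = ts.values[:, idx[node]]
    X = ts.values[:, [idx[p] for p in others]]
    yc = np.ascontiguousarray(y - y.mean())
    Xc = np.asfortranarray(X - X.mean(axis=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # centred float64 Fortran-ordered inputs let us skip per-alpha checks
        alphas, coefs, _ = lasso_path(
            Xc, yc, n_alphas=n_lambdas, eps=lambda_min_ratio, check_input=False
        )
    candidates: list[frozenset[str]] = [frozenset()]
    for k in range(coefs.shape[1]):
        support = frozenset(
            others[i] for i in np.flatnonzero(np.abs(coefs[:, k]) > 0)
        )
        if support not in candidates:
            candidates.append(support)
    return candidates


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def _random_start(
    nodes: tuple[str, ...],
    allowed: dict[str, set[str]],
    rng: np.random.Generator,
    edge_prob: float,
) -> DagStructure:
    """Random DAG over allowed edges: permutation order + Bernoulli edges."""
    order = list(rng.permutation(len(nodes)))
    rank = {nodes[n]: r for r, n in enumerate(order)}
    parents: dict[str, set[str]] = {n: set() for n in nodes}
    for v in nodes:
        for u in sorted(allowed[v]):
            if rank[u] < rank[v] and rng.random() < edge_prob:
                parents[v].add(u)
    return DagStructure(tuple(nodes), {n: frozenset(p) for n, p in parents.items()})


def _hill_climb(
    start: DagStructure,
    engine: _ScoreEngine,
    allowed: dict[str, set[str]],
    idx: dict[str, int],
    log_m: float,
    max_iter: int,
    min_gain: float,
    rng: np.random.Generator | None = None,
    plateau_moves: int = 20,
) -> tuple[DagStructure, float]:
    """Greedy BIC ascent over add/delete/reverse moves with plateau walks.

    Score decomposability: a move touching children {v} (or {u, v} for a
    reversal) changes only those nodes' family terms, so move gains are
    evaluated from at most two cached family scores.  Each edge parameter
    costs log(m)/2 in penalty.  Ties among equal-gain moves go to the first
    in iteration order; ``rng`` shuffles that order (used by random restarts
    so different restarts explore different equally-scoring orientations).

    When no strictly improving move exists, the climber walks the score
    plateau by reversing covered edges (u -> v with Pa(v) = Pa(u) + {u}) —
    score-neutral moves that traverse the Markov equivalence class and can
    open strictly improving moves misorientation traps hide; the walk is
    bounded by ``plateau_moves`` reversals per climb.
    """
    nodes = start.nodes
    struct = start
    fam = {v: engine.family_loglik(idx[v], frozenset(idx[p] for p in struct.parents[v]))
           for v in nodes}
    penalty_per_edge = 0.5 * log_m
    pairs = list(itertools.permutations(nodes, 2))
    plateau_budget = plateau_moves

    for _ in range(max_iter):
        best_gain = min_gain
        best_move = None
        if rng is not None:
            rng.shuffle(pairs)
        for u, v in pairs:
            pv = struct.parents[v]
            if u not in pv:
                # addition
                if u not in allowed[v] or struct.creates_cycle(u, v):
                    continue
                new = engine.family_loglik(idx[v], frozenset(idx[p] for p in pv | {u}))
                gain = new - fam[v] - penalty_per_edge
                if gain > best_gain:
                    best_gain, best_move = gain, ("add", u, v)
            else:
                # deletion
                new = engine.family_loglik(idx[v], frozenset(idx[p] for p in pv - {u}))
                gain = new - fam[v] + penalty_per_edge
                if gain > best_gain:
                    best_gain, best_move = gain, ("del", u, v)
                # reversal u->v  =>  v->u
                if v in allowed[u]:
                    tmp = struct.without_edge(u, v)
                    if not tmp.creates_cycle(v, u):
                        new_v = engine.family_loglik(
                            idx[v], frozenset(idx[p] for p in pv - {u})
                        )
                        new_u = engine.family_loglik(
                            idx[u],
                            frozenset(idx[p] for p in struct.parents[u] | {v}),
                        )
                        gain = (new_v - fam[v]) + (new_u - fam[u])
                        if gain > best_gain:
                            best_gain, best_move = gain, ("rev", u, v)
        if best_move is None:
            # plateau walk: reverse one covered edge (score-neutral) and retry
            if plateau_budget <= 0:
                break
            covered = [
                (u, v)
                for u, v in struct.edges()
                if struct.parents[v] == struct.parents[u] | {u} and v in allowed[u]
            ]
            if not covered:
                break
            pick = (
                covered[int(rng.integers(len(covered)))] if rng is not None
                else covered[0]
            )
            plateau_budget -= 1
            best_move = ("rev", *pick)
        else:
            plateau_budget = plateau_moves
        kind, u, v = best_move
        if kind == "add":
            struct = struct.with_edge(u, v)
        elif kind == "del":
            struct = struct.without_edge(u, v)
        else:
            struct = struct.without_edge(u, v).with_edge(v, u)
            fam[u] = engine.family_loglik(
                idx[u], frozenset(idx[p] for p in struct.parents[u])
            )
        fam[v] = engine.family_loglik(
            idx[v], frozenset(idx[p] for p in struct.parents[v])
        )
    total = sum(fam.values()) - (2 * len(nodes) + struct.n_edges) * penalty_per_edge
    return struct, total


def learn_structure(
    ts: RoiTimeSeriesMatrix, config: LearnConfig | None = None
) -> BnModel:
    """BIC-maximizing structure search seeded by L1-regularization paths.

    Greedy hill-climbing over additions/deletions/reversals, with additions
    u->v restricted to parents u appearing in some lasso-path candidate set
    for v; one deterministic empty-graph start plus ``config.restarts``
    seeded random restarts; the best-BIC local optimum wins (ties broken by
    fewer edges, then lexicographic edge list).
    """
    config = config or LearnConfig()
    nodes = tuple(ts.node_labels)
    n = len(nodes)
    if ts.n_samples <= 3 * n:
        log.warning(
            "only m=%d samples for n=%d nodes; m > 3n recommended", ts.n_samples, n
        )
    idx = {lab: j for j, lab in enumerate(nodes)}
    if config.restrict_to_l1:
        allowed = {
            v: set().union(
                *l1_parent_path(ts, v, config.n_lambdas, config.lambda_min_ratio)
            )
            for v in nodes
        }
    else:
        allowed = {v: set(nodes) - {v} for v in nodes}

    engine = _ScoreEngine(ts.values)
    log_m = float(np.log(ts.n_samples))
    rng = np.random.default_rng(config.seed)

    starts: list[tuple[DagStructure, np.random.Generator]] = [
        (
            DagStructure(nodes, {v: frozenset() for v in nodes}),
            np.random.default_rng(rng.integers(2**31)),
        )
    ]
    starts += [
        (
            _random_start(nodes, allowed, rng, config.restart_edge_prob),
            np.random.default_rng(rng.integers(2**31)),
        )
        for _ in range(config.restarts)
    ]
    best: tuple[float, int, list, DagStructure] | None = None
    for start, move_rng in starts:
        struct, score = _hill_climb(
            start, engine, allowed, idx, log_m, config.max_iter, config.min_gain,
            rng=move_rng, plateau_moves=config.plateau_moves,
        )
        key = (-score, struct.n_edges, struct.edges())
        if best is None or key < (best[0], best[1], best[2]):
            best = (-score, struct.n_edges, struct.edges(), struct)
    assert best is not None
    return _model_from_structure(best[3], ts)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def _all_parent_maps(n: int):
    """Yield every acyclic assignment of parent index sets on n labeled nodes."""
    per_node = []
    for j in range(n):
        others = [i for i in range(n) if i != j]
        per_node.append(
            [frozenset(c) for k in range(n) for c in itertools.combinations(others, k)]
        )
    for combo in itertools.product(*per_node):
        if _is_acyclic_idx(combo):
            yield combo


def _is_acyclic_idx(parent_sets) -> bool:
    n = len(parent_sets)
    indeg = [len(p) for p in parent_sets]
    children = [[] for _ in range(n)]
    for c, ps in enumerate(parent_sets):
        for p in ps:
            children[p].append(c)
    ready = [i for i in range(n) if indeg[i] == 0]
    count = 0
    while ready:
        i = ready.pop()
        count += 1
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    return count == n


def enumerate_dags(n: int) -> int:
    """Number of labeled DAGs on n nodes by brute-force enumeration."""
    return sum(1 for _ in _all_parent_maps(n))


def exhaustive_search(ts: RoiTimeSeriesMatrix, max_nodes: int = 4) -> BnModel:
    """Globally BIC-optimal DAG by enumerating every labeled DAG (n <= max_nodes).

    Ties are broken by fewest edges, then by lexicographic edge list.
    """
    n = ts.n_nodes
    if n > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} nodes; got {n}")
    nodes = tuple(ts.node_labels)
    engine = _ScoreEngine(ts.values)
    log_m = float(np.log(ts.n_samples))
    best = None
    for combo in _all_parent_maps(n):
        n_edges = sum(len(p) for p in combo)
        ll = sum(engine.family_loglik(j, ps) for j, ps in enumerate(combo))
        score = ll - 0.5 * (2 * n + n_edges) * log_m
        edges = sorted((nodes[p], nodes[c]) for c, ps in enumerate(combo) for p in ps)
        key = (-score, n_edges, edges)
        if best is None or key < best[0]:
            best = (key, combo)
    assert best is not None
    structure = DagStructure(
        nodes,
        {nodes[j]: frozenset(nodes[p] for p in best[1][j]) for j in range(n)},
    )
    return _model_from_structure(structure, ts)


# ---------------------------------------------------------------------------
# joint density and equivalence classes
# ---------------------------------------------------------------------------

def implied_covariance(
    structure: DagStructure, params: GaussianBnParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance of the joint Gaussian the network implies.

    With W[i, p] = b_{p->i}, the centred system is x - mu = W (x - mu) + eps,
    hence Cov = (I - W)^-1 Sigma_eps (I - W)^-T.
    """
    nodes = structure.nodes
    n = len(nodes)
    idx = {lab: j for j, lab in enumerate(nodes)}
    W = np.zeros((n, n))
    mu = np.zeros(n)
    sig = np.zeros(n)
    for v in nodes:
        i = idx[v]
        mu[i] = params[v].mean
        sig[i] = params[v].residual_variance
        for p, b in params[v].weights.items():
            W[i, idx[p]] = b
    A = np.linalg.inv(np.eye(n) - W)
    cov = A @ np.diag(sig) @ A.T
    return mu, cov


def joint_log_likelihood(
    ts: RoiTimeSeriesMatrix, structure: DagStructure, params: GaussianBnParameters
) -> float:
    """Joint log density of the data under the implied multivariate normal."""
    from scipy.stats import multivariate_normal

    mu, cov = implied_covariance(structure, params)
    col = {lab: j for j, lab in enumerate(ts.node_labels)}
    X = ts.values[:, [col[lab] for lab in structure.nodes]]
    return float(multivariate_normal(mean=mu, cov=cov, allow_singular=False).logpdf(X).sum())


def cpdag(structure: DagStructure) -> frozenset[tuple]:
    """Completed PDAG (Markov equivalence class) of a DAG.

    Returns a canonical frozenset of ``("->", u, v)`` directed and
    ``("--", a, b)`` (a < b) undirected edge records.  Built from the
    skeleton and v-structures, closed under Meek's orientation rules R1-R3
    (sufficient for patterns derived from a DAG).
    """
    nodes = structure.nodes
    adj: set[frozenset[str]] = set()
    for p, c in structure.edges():
        adj.add(frozenset((p, c)))

    def adjacent(a, b):
        return frozenset((a, b)) in adj

    directed: set[tuple[str, str]] = set()
    for v in nodes:
        for u, w in itertools.combinations(sorted(structure.parents[v]), 2):
            if not adjacent(u, w):  # v-structure u -> v <- w
                directed.add((u, v))
                directed.add((w, v))
    undirected = {
        (p, c) for p, c in structure.edges() if (p, c) not in directed
    }

    changed = True
    while changed:
        changed = False
        for p, c in sorted(undirected):
            # R1: a -> p, p -- c, a and c non-adjacent  =>  p -> c
            r1 = any(
                (a, p) in directed and not adjacent(a, c)
                for a in nodes
                if a not in (p, c)
            )
            # R2: p -> b -> c with p -- c  =>  p -> c
            r2 = any(
                (p, b) in directed and (b, c) in directed
                for b in nodes
                if b not in (p, c)
            )
            # R3: p -- c with two non-adjacent b1, b2, p -- b_i (undirected),
            # b_i -> c
            r3 = False
            bs = [
                b for b in nodes
                if b not in (p, c)
                and ((p, b) in undirected or (b, p) in undirected)
                and (b, c) in directed
            ]
            for b1, b2 in itertools.combinations(bs, 2):
                if not adjacent(b1, b2):
                    r3 = True
                    break
            if r1 or r2 or r3:
                undirected.discard((p, c))
                directed.add((p, c))
                changed = True

    records: set[tuple] = set()
    for u, v in directed:
        records.add(("->", u, v))
    for u, v in undirected:
        a, b = sorted((u, v))
        records.add(("--", a, b))
    return frozenset(records)
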