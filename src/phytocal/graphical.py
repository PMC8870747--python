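"""Gaussian graphical models and discrete Bayesian networks on
posterior samples.

The GGM side performs covariance selection: zero entries of the
partial-correlation matrix (equivalently, of the precision matrix)
define missing edges; iterative proportional fitting (IPF) finds the
maximum-likelihood correlation matrix V consistent with a prescribed
edge set, and the deviance

    dev_S(G) = N * ln(|V| / |S|)

measures the information in the data against the hypothesized graph.
Edge relevance is scored by the deviance increment of excluding one
more edge (EED) or re-establishing a removed one (EID), and a greedy
backward elimination prunes the graph.

The BN side orients the undirected edges along a node ordering,
discretizes each parameter into equal-range bins, fits smoothed
conditional probability tables, and answers evidence queries by exact
variable elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import chi2

from .posterior_analysis import SampleSet

__all__ = [
    "GraphModel",
    "BNModel",
    "all_edges",
    "partial_corr",
    "ipf_fit",
    "deviance",
    "edge_scores",
    "prune_graph",
    "explained_variance",
    "orient_dag",
    "moralize",
    "fit_cpts",
    "bn_query",
]

#: EEDs below the 99.9% quantile of chi2(1) count as "not clearly relevant"
DEFAULT_EED_FLOOR = float(chi2.ppf(0.999, df=1))


def _check_corr(S: np.ndarray, name: str = "S") -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} must be positive definite") from err
    return S


def _norm_edges(edges, p: int) -> set:
    out = set()
    for i, j in edges:
        i, j = int(i), int(j)
        if i == j or not (0 <= i < p and 0 <= j < p):
            raise ValueError(f"invalid edge ({i}, {j})")
        out.add((min(i, j), max(i, j)))
    return out


def all_edges(p: int) -> set:
    return {(i, j) for i in range(p) for j in range(i + 1, p)}


def partial_corr(S) -> np.ndarray:
    """Partial correlations from a correlation/covariance matrix.

    Sp_ij = -P_ij / sqrt(P_ii P_jj) with P = S^-1; unit diagonal by
    convention.  Zeros of Sp and of the precision matrix coincide.
    """
    S = _check_corr(S)
    P = np.linalg.inv(S)
    d = np.sqrt(np.diag(P))
    Sp = -P / np.outer(d, d)
    np.fill_diagonal(Sp, 1.0)
    return Sp


def ipf_fit(S, edges, tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
    """Maximum-likelihood matrix V for the graph by iterative
    proportional fitting.

    Cycles over the maximal cliques of the graph, adjusting the
    precision matrix so the fitted marginal on each clique matches the
    sample matrix (clique-marginal matching characterizes the MLE).
    Off-clique precision entries are never touched, so the fitted
    partial correlations vanish exactly on missing edges, and on edges
    (cliques) V reproduces S unchanged.
    """
    S = _check_corr(S)
    p = S.shape[0]
    edges = _norm_edges(edges, p)
    if edges == all_edges(p):
        return S.copy()
    G = nx.Graph()
    G.add_nodes_from(range(p))
    G.add_edges_from(edges)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(G)]
    K = np.diag(1.0 / np.diag(S))  # independence model start
    V = np.linalg.inv(K)
    for _ in range(max_iter):
        V_old = V
        for c in cliques:
            idx = np.ix_(c, c)
            K[idx] += np.linalg.inv(S[idx]) - np.linalg.inv(V[idx])
            K = (K + K.T) / 2.0
            V = np.linalg.inv(K)
        if np.max(np.abs(V - V_old)) < tol:
            return (V + V.T) / 2.0
    raise RuntimeError(f"IPF did not converge within {max_iter} sweeps")


def deviance(S, V, N: int) -> float:
    """dev = N * ln(|V| / |S|); >= 0 when V is the IPF fit of a submodel."""
    S = _check_corr(S, "S")
    V = _check_corr(V, "V")
    sign_v, logdet_v = np.linalg.slogdet(V)
    sign_s, logdet_s = np.linalg.slogdet(S)
    return float(N) * (logdet_v - logdet_s)


def edge_scores(S, edges, removed_edges, N: int, tol: float = 1e-10):
    """Deviance increments for single-edge changes to the current graph.

    EED(e) = dev(graph without e) - dev(graph), for each retained e;
    EID(e) = dev(graph) - dev(graph with e re-added), for each removed
    e.  Both are non-negative up to IPF tolerance.
    """
    S = _check_corr(S)
    p = S.shape[0]
    edges = _norm_edges(edges, p)
    removed = _norm_edges(removed_edges, p)
    if edges & removed:
        raise ValueError("an edge cannot be both retained and removed")
    dev_now = deviance(S, ipf_fit(S, edges, tol), N)
    eed = {
        e: deviance(S, ipf_fit(S, edges - {e}, tol), N) - dev_now for e in edges
    }
    eid = {
        e: dev_now - deviance(S, ipf_fit(S, edges | {e}, tol), N) for e in removed
    }
    return eed, eid


@dataclass
class GraphModel:
    """A fitted Gaussian graphical model with its audit trail."""

    names: Sequence[str]
    S: np.ndarray
    V: np.ndarray
    Sp: np.ndarray
    Vp: np.ndarray
    edges: set
    N: int
    deviance: float
    trail: list = field(default_factory=list)  # (edge, eed_at_removal) in order

    @property
    def removed_edges(self) -> set:
        return all_edges(self.S.shape[0]) - self.edges


def prune_graph(
    S,
    N: int,
    margin: float = 2.0,
    eed_floor: float = DEFAULT_EED_FLOOR,
    names: Sequence[str] | None = None,
    tol: float = 1e-10,
) -> GraphModel:
    """Greedy backward elimination of GGM edges.

    Starting from the saturated graph, repeatedly removes the retained
    edge with the smallest exclusion deviance while that deviance is
    not "clearly larger" than the evidence for the edges already
    removed: a candidate is removed when its EED is strictly below
    max(eed_floor, margin * max EID of the removed edges).  The floor
    (default: 99.9% quantile of chi2 with 1 degree of freedom) encodes
    statistical irrelevance of a single-edge restriction; the margin
    encodes the required separation between kept and dropped edges.
    ``margin=0`` with ``eed_floor=0`` keeps the saturated graph.

    Returns the fitted model with the full removal audit trail.
    """
    S = _check_corr(S)
    p = S.shape[0]
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    edges = all_edges(p)
    removed: set = set()
    trail: list = []
    while edges:
        eed, eid = edge_scores(S, edges, removed, N, tol)
        candidate = min(eed, key=eed.get)
        max_eid = max(eid.values()) if eid else 0.0
        threshold = max(eed_floor, margin * max_eid)
        if not eed[candidate] < threshold:
            break
        edges = edges - {candidate}
        removed = removed | {candidate}
        trail.append((candidate, float(eed[candidate])))
    V = ipf_fit(S, edges, tol)
    return GraphModel(
        names=tuple(names),
        S=S,
        V=V,
        Sp=partial_corr(S),
        Vp=partial_corr(V),
        edges=edges,
        N=N,
        deviance=deviance(S, V, N),
        trail=trail,
    )


def explained_variance(R) -> np.ndarray:
    """Squared multiple correlation of each variable on all others.

    For a correlation matrix R this is 1 - 1/(R^-1)_ii: the fraction
    of a parameter's variance explainable as a linear function of the
    remaining parameters.
    """
    R = _check_corr(R, "R")
    prec_diag = np.diag(np.linalg.inv(R))
    return 1.0 - 1.0 / (prec_diag * np.diag(R))


# --------------------------------------------------------------------------
# Bayesian network


def orient_dag(edges, ordering: Sequence) -> nx.DiGraph:
    """Orient undirected edges from earlier to later in ``ordering``.

    Any total ordering yields an acyclic result; reversing the
    ordering reverses every edge.
    """
    order_pos = {v: k for k, v in enumerate(ordering)}
    dag = nx.DiGraph()
    dag.add_nodes_from(ordering)
    for u, v in edges:
        if u not in order_pos or v not in order_pos:
            raise ValueError(f"ordering does not cover edge ({u}, {v})")
        if order_pos[u] < order_pos[v]:
            dag.add_edge(u, v)
        else:
            dag.add_edge(v, u)
    if not nx.is_directed_acyclic_graph(dag):  # pragma: no cover - by construction
        raise RuntimeError("orientation produced a cycle")
    return dag


def moralize(dag: nx.DiGraph) -> nx.Graph:
    """Moral graph: undirected skeleton plus edges marrying co-parents."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("input must be a DAG")
    return nx.moral_graph(dag)


@dataclass
class BNModel:
    """Discrete Bayesian network fitted to posterior samples."""

    dag: nx.DiGraph
    bin_edges: dict                 # node -> (nbins+1,) equal-range edges
    cpts: dict                      # node -> array, axes (parents..., node)
    parents: dict                   # node -> tuple of parent nodes (axis order)
    nbins: int
    pseudo_count: float


def _digitize(col: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, col, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def fit_cpts(
    samples: SampleSet,
    dag: nx.DiGraph,
    nbins: int = 10,
    pseudo_count: float = 1.0,
    max_parents: int = 3,
) -> BNModel:
    """Equal-range discretization and smoothed conditional probability
    tables for every node of the DAG.

    CPT entries are (count + pseudo) / (row total + pseudo * nbins) per
    parent-state combination; the pseudo-count keeps sparsely populated
    parent configurations proper.  A root node's CPT is its marginal
    histogram (up to smoothing).
    """
    cols = {name: samples.values[:, samples.column(name)] for name in dag.nodes}
    bin_edges = {}
    codes = {}
    for name, col in cols.items():
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            raise ValueError(f"degenerate column {name!r}")
        edges = np.linspace(lo, hi, nbins + 1)
        bin_edges[name] = edges
        codes[name] = _digitize(col, edges)
    cpts = {}
    parents = {}
    for node in dag.nodes:
        pa = tuple(sorted(dag.predecessors(node), key=list(dag.nodes).index))
        if len(pa) > max_parents:
            raise ValueError(
                f"node {node!r} has {len(pa)} parents; CPT would hold "
                f"{nbins ** (len(pa) + 1)} entries (max_parents={max_parents})"
            )
        parents[node] = pa
        shape = (nbins,) * len(pa) + (nbins,)
        counts = np.zeros(shape)
        idx = tuple(codes[q] for q in pa) + (codes[node],)
        np.add.at(counts, idx, 1.0)
        row_tot = counts.sum(axis=-1, keepdims=True)
        cpts[node] = (counts + pseudo_count) / (row_tot + pseudo_count * nbins)
    return BNModel(
        dag=dag, bin_edges=bin_edges, cpts=cpts, parents=parents,
        nbins=nbins, pseudo_count=pseudo_count,
    )


def _factor_product(f1, f2):
    """Factors are (vars tuple, ndarray with one axis per var)."""
    v1, a1 = f1
    v2, a2 = f2
    out_vars = tuple(v1) + tuple(v for v in v2 if v not in v1)
    sl1 = [slice(None) if v in v1 else None for v in out_vars]
    a1b = a1.transpose([v1.index(v) for v in out_vars if v in v1])[tuple(sl1)]
    sl2 = [slice(None) if v in v2 else None for v in out_vars]
    a2b = a2.transpose([v2.index(v) for v in out_vars if v in v2])[tuple(sl2)]
    return out_vars, a1b * a2b


def _sum_out(factor, var):
    vars_, arr = factor
    ax = vars_.index(var)
    return tuple(v for v in vars_ if v != var), arr.sum(axis=ax)


def bn_query(bn: BNModel, evidence: Mapping | None = None) -> dict:
    """Exact node marginals given evidence, by variable elimination.

    ``evidence`` maps node -> bin index (0-based).  Without evidence
    the result reproduces each node's fitted marginal.  Raises on an
    evidence combination of probability zero.
    """
    evidence = dict(evidence or {})
    for node, b in evidence.items():
        if node not in bn.dag.nodes:
            raise ValueError(f"unknown evidence node {node!r}")
        if not 0 <= int(b) < bn.nbins:
            raise ValueError(f"evidence bin {b} out of range for {node!r}")
    base_factors = []
    for node in bn.dag.nodes:
        vars_ = bn.parents[node] + (node,)
        arr = bn.cpts[node]
        # apply evidence by slicing the corresponding axes
        keep_vars, sl = [], []
        for v in vars_:
            if v in evidence:
                sl.append(int(evidence[v]))
            else:
                sl.append(slice(None))
                keep_vars.append(v)
        arr = arr[tuple(sl)]
        base_factors.append((tuple(keep_vars), np.asarray(arr)))
    out = {}
    for query in bn.dag.nodes:
        if query in evidence:
            probs = np.zeros(bn.nbins)
            probs[int(evidence[query])] = 1.0
            out[query] = probs
            continue
        factors = list(base_factors)
        for var in [v for v in bn.dag.nodes if v != query and v not in evidence]:
            involved = [f for f in factors if var in f[0]]
            rest = [f for f in factors if var not in f[0]]
            prod = involved[0]
            for f in involved[1:]:
                prod = _factor_product(prod, f)
            factors = rest + [_sum_out(prod, var)]
        result = factors[0]
        for f in factors[1:]:
            result = _factor_product(result, f)
        vars_, arr = result
        arr = np.asarray(arr, dtype=float).reshape(bn.nbins)
        total = arr.sum()
        if total <= 0:
            raise ValueError("evidence configuration has probability zero")
        out[query] = arr / total
    return out
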