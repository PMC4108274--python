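"""Markov Cluster Algorithm over the thresholded HRR network.

MCL simulates stochastic flow on the graph: the column-normalized adjacency
matrix is alternately squared (expansion — flow spreads along walks) and
raised entrywise to the inflation power I with renormalization (inflation —
strong flows are favoured over weak ones).  Flow evaporates across sparse
boundaries and pools inside dense regions; at convergence the nonzero
pattern reads off the clusters.  The inflation parameter controls
granularity: higher I gives more, smaller clusters.

Clusters with fewer than ``min_size`` members (default 3) are moved to the
unassigned set — tiny clusters carry no usable enrichment signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class MCLParams:
    """MCL flow-simulation parameters.

    ``self_loop_weight=None`` adds, per node, a loop equal to the maximum
    edge weight incident to it (1.0 for isolated nodes), so loop and edge
    flow stay on the same scale whatever the weighting of the input graph;
    a float forces a constant loop weight.
    """

    inflation: float = 1.2
    expansion: int = 2
    pruning_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8
    self_loop_weight: float | None = None

    def __post_init__(self) -> None:
        if self.inflation < 1:
            raise ValueError("inflation must be >= 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


#: default inflation sweep grid: 1.1 to 2.0 in steps of 0.1
DEFAULT_INFLATION_GRID = tuple(round(1.1 + 0.1 * i, 1) for i in range(10))


@dataclass
class Clustering:
    """A disjoint partition of (part of) the network's nodes.

    ``clusters`` maps a stable integer id (1-based, assigned by descending
    size then lexicographically smallest member) to its member list;
    ``unassigned`` holds nodes dropped by the size filter.
    """

    clusters: dict[int, list[str]]
    unassigned: list[str]
    params: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {m: cid for cid, members in self.clusters.items() for m in members}


@dataclass
class ConnectivityReport:
    pairs: pd.DataFrame  # cluster_a, cluster_b, n_edges, score, connected
    threshold: float


def _column_normalize(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return m @ sp.diags(1.0 / sums, format="csc")


def _build_matrix(edges: pd.DataFrame, nodes: list[str], self_loop: float | None) -> sp.csc_matrix:
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = edges["weight"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("edge weights must be strictly positive")
    ai = edges["probeset_a"].map(index).to_numpy()
    bi = edges["probeset_b"].map(index).to_numpy()
    m = sp.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([ai, bi]), np.concatenate([bi, ai]))),
        shape=(n, n),
    ).tocsc()
    if self_loop is None:
        col_max = np.zeros(n)
        if m.nnz:
            col_max = m.max(axis=0).toarray().ravel()
        loops = np.where(col_max > 0, col_max, 1.0)
    else:
        loops = np.full(n, float(self_loop))
    return (m + sp.diags(loops, format="csc")).tocsc()


def mcl(
    edges: pd.DataFrame,
    params: MCLParams | None = None,
    min_size: int = 3,
    on_iteration=None,
) -> Clustering:
    """Cluster an undirected weighted edge list by MCL flow simulation.

    ``edges`` needs columns (probeset_a, probeset_b, weight) with strictly
    positive weights.  ``on_iteration(iteration, matrix)`` is called with the
    column-stochastic flow matrix after every iteration (used to audit
    stochasticity).  MCL is fully deterministic.
    """
    params = params or MCLParams()
    nodes = sorted(set(edges["probeset_a"]) | set(edges["probeset_b"]))
    if not nodes:
        return Clustering({}, [], params=_params_dict(params, min_size))
    m = _column_normalize(_build_matrix(edges, nodes, params.self_loop_weight))
    if on_iteration is not None:
        on_iteration(0, m)
    converged = False
    for it in range(1, params.max_iterations + 1):
        prev = m
        # expansion: e-th matrix power
        mexp = m
        for _ in range(params.expansion - 1):
            mexp = mexp @ m
        m = mexp
        # inflation: entrywise power, then column renormalization
        m = m.copy()
        m.data **= params.inflation
        m = _column_normalize(m)
        # pruning of negligible flow, then renormalization
        m.data[m.data < params.pruning_threshold] = 0.0
        m.eliminate_zeros()
        m = _column_normalize(m)
        if on_iteration is not None:
            on_iteration(it, m)
        diff = abs(m - prev).max() if (m - prev).nnz else 0.0
        if diff < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations; "
            "clusters read from the last iterate",
            stacklevel=2,
        )
    clusters = _interpret(m.tocsr(), nodes)
    return _finalize(clusters, nodes, min_size, _params_dict(params, min_size), converged)


def _params_dict(params: MCLParams, min_size: int) -> dict:
    return {
        "method": "mcl",
        "inflation": params.inflation,
        "expansion": params.expansion,
        "pruning_threshold": params.pruning_threshold,
        "max_iterations": params.max_iterations,
        "convergence_tol": params.convergence_tol,
        "self_loop_weight": params.self_loop_weight,
        "min_size": min_size,
    }


def _interpret(m: sp.csr_matrix, nodes: list[str]) -> list[list[int]]:
    """Read clusters off the converged flow matrix.

    Attractors are the nodes whose row still carries flow.  Attractor systems
    (weakly connected components among attractors) define the clusters; every
    node joins the system of the attractors it flows to, ties resolved to the
    lowest cluster id.
    """
    n = len(nodes)
    row_nnz = np.diff(m.indptr)
    attractors = np.flatnonzero(row_nnz > 0)
    if attractors.size == 0:  # degenerate: uniform flow died out entirely
        return [[i] for i in range(n)]
    sub = m[attractors][:, attractors]
    n_comp, labels = connected_components(sub, directed=False)
    systems: list[list[int]] = [[] for _ in range(n_comp)]
    # order systems deterministically by their smallest attractor index
    order = np.argsort(
        [attractors[np.flatnonzero(labels == c)[0]] for c in range(n_comp)]
    )
    relabel = np.empty(n_comp, dtype=int)
    relabel[order] = np.arange(n_comp)
    labels = relabel[labels]
    attractor_system = dict(zip(attractors.tolist(), labels.tolist()))
    assignment = np.full(n, -1, dtype=int)
    mc = m.tocsc()
    for j in range(n):
        rows = mc.indices[mc.indptr[j] : mc.indptr[j + 1]]
        cands = [attractor_system[i] for i in rows if i in attractor_system]
        if cands:
            assignment[j] = min(cands)  # overlapping systems: lowest cluster id
    # nodes with no surviving inflow become singletons (filtered later)
    systems = [[] for _ in range(n_comp)]
    singletons: list[list[int]] = []
    for j in range(n):
        if assignment[j] >= 0:
            systems[assignment[j]].append(j)
        else:
            singletons.append([j])
    return [s for s in systems if s] + singletons


def _finalize(
    raw_clusters: list[list[int]],
    nodes: list[str],
    min_size: int,
    params: dict,
    converged: bool = True,
) -> Clustering:
    named = [sorted(nodes[i] for i in members) for members in raw_clusters]
    named.sort(key=lambda ms: (-len(ms), ms[0]))
    clusters: dict[int, list[str]] = {}
    unassigned: list[str] = []
    cid = 0
    for members in named:
        if len(members) >= min_size:
            cid += 1
            clusters[cid] = members
        else:
            unassigned.extend(members)
    return Clustering(clusters, sorted(unassigned), params=params, converged=converged)


def sweep_inflation(
    edges: pd.DataFrame,
    grid=DEFAULT_INFLATION_GRID,
    annotations=None,
    background: set[str] | None = None,
    params: MCLParams | None = None,
    min_size: int = 3,
    dataset: str = "dataset",
    universe: str = "annotated",
) -> tuple[pd.DataFrame, dict[float, Clustering]]:
    """Run MCL across an inflation grid and score each solution by F-measure.

    Returns the performance table (one row per inflation, ranked by
    descending F) and the per-inflation clusterings.  Scoring delegates to
    the enrichment module; with ``annotations=None`` only cluster counts are
    reported.
    """
    from .enrichment import clustering_performance

    grid = list(grid)
    if not grid:
        raise ValueError("inflation grid is empty")
    base = params or MCLParams()
    rows = []
    solutions: dict[float, Clustering] = {}
    for inflation in grid:
        clustering = mcl(edges, replace(base, inflation=inflation), min_size=min_size)
        solutions[inflation] = clustering
        row = {
            "dataset": dataset,
            "inflation": inflation,
            "n_clusters": clustering.n_clusters,
        }
        if annotations is not None:
            perf = clustering_performance(
                clustering, annotations, background=background, universe=universe
            )
            row.update(
                specificity=perf.specificity,
                sensitivity=perf.sensitivity,
                f_measure=perf.f_measure,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if "f_measure" in table.columns:
        table = table.sort_values("f_measure", ascending=False, ignore_index=True)
    return table, solutions


def cluster_connectivity(
    clustering: Clustering, edges: pd.DataFrame, threshold: float = 0.03
) -> ConnectivityReport:
    """Inter-cluster edge density: score(A,B) = #edges between A and B / (|A| |B|).

    Pairs with score strictly above ``threshold`` are flagged connected.
    Only cluster pairs joined by at least one edge are listed (all others
    score 0 by definition).
    """
    member = clustering.membership()
    sizes = {cid: len(ms) for cid, ms in clustering.clusters.items()}
    empty = [cid for cid, s in sizes.items() if s == 0]
    if empty:
        warnings.warn(f"excluding empty clusters {empty}", stacklevel=2)
    ca = edges["probeset_a"].map(member)
    cb = edges["probeset_b"].map(member)
    mask = ca.notna() & cb.notna() & (ca != cb)
    lo = np.minimum(ca[mask].astype(int), cb[mask].astype(int))
    hi = np.maximum(ca[mask].astype(int), cb[mask].astype(int))
    counts = pd.DataFrame({"cluster_a": lo, "cluster_b": hi}).value_counts().sort_index()
    rows = []
    for (a, b), n_edges in counts.items():
        if sizes.get(a, 0) == 0 or sizes.get(b, 0) == 0:
            continue
        score = n_edges / (sizes[a] * sizes[b])
        rows.append(
            {
                "cluster_a": a,
                "cluster_b": b,
                "n_edges": int(n_edges),
                "score": score,
                "connected": score > threshold,
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "n_edges", "score", "connected"]
    )
    return ConnectivityReport(pairs, threshold)


def write_clusters(clustering: Clustering, path) -> None:
    rows = [(cid, m) for cid, members in clustering.clusters.items() for m in members]
    pd.DataFrame(rows, columns=["cluster_id", "probeset_id"]).to_csv(
        path, sep="\t", index=False
    )


def load_clusters(path) -> Clustering:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str})
    clusters = {
        int(cid): sorted(g["probeset_id"]) for cid, g in df.groupby("cluster_id")
    }
    return Clustering(clusters, [], params={"method": "loaded"})


def write_connectivity(report: ConnectivityReport, path) -> None:
    report.pairs.to_csv(path, sep="\t", index=False)
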