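"""Pearson correlation, co-expression ranks, the HRR index and thresholded networks.

The highest reciprocal rank (HRR) between genes A and B is

    HRR(A, B) = max(rank(A, B), rank(B, A))

where rank(A, B) is the position of B in A's co-expression list ordered from
the strongest Pearson correlation down (rank 1 = A's closest partner).  Low
HRR therefore means a mutually strong co-expression relationship; taking the
maximum of the two directional ranks retains weak but reciprocal links while
discarding one-sided ones.

All heavy operations accept a ``block_size`` so that compendium-scale inputs
(tens of thousands of probesets) are processed in fixed-size row blocks
without materializing the dense float correlation matrix; block size never
changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix

#: cutoff -> uniform edge weight used when thresholding an HRR network.
#: The five table values follow w = 1/(cutoff - 5), which is applied for
#: any other cutoff; the table values themselves are returned verbatim.
WEIGHT_TABLE = {10: 0.2, 20: 0.067, 30: 0.04, 40: 0.028, 50: 0.022}


def cutoff_weight(cutoff: int) -> float:
    """Edge weight attached to every edge retained at ``HRR <= cutoff``."""
    if cutoff in WEIGHT_TABLE:
        return WEIGHT_TABLE[cutoff]
    if cutoff <= 5:
        # the hyperbolic map has its pole at 5; tiny cutoffs get unit weight
        return 1.0
    return 1.0 / (cutoff - 5)


@dataclass
class CorrelationMatrix:
    probeset_ids: list[str]
    r: np.ndarray  # symmetric, diagonal = 1 by convention (self excluded downstream)


@dataclass
class RankMatrix:
    """rank[i, j] = position of gene j in gene i's co-expression ordering.

    Rank 1 is the strongest partner; the diagonal holds 0 (self excluded).
    Each off-diagonal row is a permutation of 1..n-1.  Ties in r are broken
    by ascending probeset identifier so results are deterministic across
    platforms and block boundaries.
    """

    probeset_ids: list[str]
    rank: np.ndarray


@dataclass
class HRRNetwork:
    probeset_ids: list[str]
    hrr: np.ndarray  # symmetric int, diagonal 0
    rank: np.ndarray | None = None  # directional ranks, kept for tie-breaking

    @property
    def n(self) -> int:
        return len(self.probeset_ids)


@dataclass
class GuideCluster:
    """A guide (seed) gene and its top-k co-expressed partners.

    Members are sorted by ascending HRR (ties by the guide's directional
    rank, which is unique within a guide); the guide itself is not a member.
    """

    guide: str
    member_ids: list[str]
    hrr_values: np.ndarray

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class EdgeList:
    """Thresholded HRR network: all unordered pairs with hrr <= cutoff.

    ``edges`` has columns (probeset_a, probeset_b, hrr, weight) with each
    pair ordered lexicographically; every edge carries the single uniform
    weight for the cutoff.  Nodes that lost all their edges are reported in
    ``isolated`` but excluded from the edge list.
    """

    edges: pd.DataFrame
    cutoff: int
    weight: float
    nodes: list[str]
    isolated: list[str]


def _min_int_dtype(n: int):
    return np.int16 if n <= np.iinfo(np.int16).max else np.int32


def _standardize_rows(values: np.ndarray, probeset_ids) -> np.ndarray:
    """Center rows and scale to unit L2 norm so X @ X.T is the Pearson matrix."""
    X = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((X**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        bad = [probeset_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValueError(
            f"zero-variance probesets (undefined correlation): {bad}"
            + (" ..." if zero.sum() > 10 else "")
        )
    return X / norms[:, None]


def pearson_correlation(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """Textbook Pearson r between every probeset pair over all arrays.

    Zero-variance probesets are an error (their correlation is undefined);
    callers may drop them first.  Symmetry is enforced exactly.
    """
    if matrix.n_arrays < 3:
        raise ValueError("need at least 3 arrays")
    X = _standardize_rows(matrix.values, matrix.probeset_ids)
    r = X @ X.T
    r = (r + r.T) / 2.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(matrix.probeset_ids), r)


def _rank_rows(
    r_block: np.ndarray,
    row_offset: int,
    lex_perm: np.ndarray,
    inv_lex_perm: np.ndarray,
    out_dtype,
) -> np.ndarray:
    """Rank each row of a correlation block (1 = highest r, 0 = self).

    Columns are permuted into lexicographic identifier order before a stable
    descending sort, which realizes the ascending-identifier tie rule.
    """
    b, n = r_block.shape
    work = r_block[:, lex_perm]
    # self gets +inf so it lands at position 0 and receives rank 0
    self_cols = inv_lex_perm[row_offset : row_offset + b]
    work[np.arange(b), self_cols] = np.inf
    order = np.argsort(-work, axis=1, kind="stable")
    pos = np.empty((b, n), dtype=out_dtype)
    np.put_along_axis(pos, order, np.arange(n, dtype=out_dtype)[None, :], axis=1)
    return pos[:, inv_lex_perm]


def correlation_to_ranks(corr: CorrelationMatrix, block_size: int | None = None) -> RankMatrix:
    """Transform correlations into per-gene co-expression ranks (rank 1 = top partner)."""
    n = len(corr.probeset_ids)
    lex_perm = np.argsort(np.asarray(corr.probeset_ids, dtype=object))
    inv_lex_perm = np.empty(n, dtype=np.intp)
    inv_lex_perm[lex_perm] = np.arange(n)
    dtype = _min_int_dtype(n)
    block = block_size or n
    rank = np.empty((n, n), dtype=dtype)
    for s in range(0, n, block):
        e = min(s + block, n)
        rank[s:e] = _rank_rows(
            np.array(corr.r[s:e], dtype=float), s, lex_perm, inv_lex_perm, dtype
        )
    return RankMatrix(list(corr.probeset_ids), rank)


def hrr_matrix(ranks: RankMatrix, keep_ranks: bool = True) -> HRRNetwork:
    """HRR(A,B) = max(rank(A,B), rank(B,A)) for every unordered pair."""
    hrr = np.maximum(ranks.rank, ranks.rank.T)
    return HRRNetwork(list(ranks.probeset_ids), hrr, ranks.rank if keep_ranks else None)


def hrr_network(
    matrix: ExpressionMatrix,
    block_size: int | None = None,
    keep_ranks: bool = True,
) -> HRRNetwork:
    """Compendium -> HRR network in one pass, block by block.

    Equivalent to ``hrr_matrix(correlation_to_ranks(pearson_correlation(m)))``
    but never materializes the dense float correlation matrix: each row block
    of correlations is consumed immediately into integer ranks.  Results are
    identical for every block size.
    """
    n = matrix.n_probesets
    ids = list(matrix.probeset_ids)
    X = _standardize_rows(matrix.values, ids)
    lex_perm = np.argsort(np.asarray(ids, dtype=object))
    inv_lex_perm = np.empty(n, dtype=np.intp)
    inv_lex_perm[lex_perm] = np.arange(n)
    dtype = _min_int_dtype(n)
    block = block_size or n
    rank = np.empty((n, n), dtype=dtype)
    for s in range(0, n, block):
        e = min(s + block, n)
        r_block = X[s:e] @ X.T
        rank[s:e] = _rank_rows(r_block, s, lex_perm, inv_lex_perm, dtype)
    if keep_ranks:
        hrr = np.empty_like(rank)
        rk = rank
    else:
        hrr = rank  # symmetrized in place; directional ranks discarded
        rk = None
    for s in range(0, n, block):
        e = min(s + block, n)
        for s2 in range(s, n, block):
            e2 = min(s2 + block, n)
            m = np.maximum(rank[s:e, s2:e2], rank[s2:e2, s:e].T)
            hrr[s:e, s2:e2] = m
            hrr[s2:e2, s:e] = m.T
    return HRRNetwork(ids, hrr, rk)


def guide_clusters(
    net: HRRNetwork, k: int = 100, block_size: int | None = None
) -> list[GuideCluster]:
    """One cluster per gene: the k partners with the smallest HRR to it.

    Ties are broken by ascending HRR, then the guide's directional rank, then
    ascending identifier (the directional rank is already unique within a
    guide, so the identifier rule is only needed when ranks were discarded).
    When fewer than k partners exist the cluster holds all n-1 of them.
    Clusters overlap freely and need not be symmetric: B appearing in A's
    cluster does not imply A appears in B's.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = net.n
    ids = np.asarray(net.probeset_ids, dtype=object)
    kk = min(k, n - 1)
    if net.rank is not None:
        tiebreak = net.rank
    else:
        # fall back to lexicographic identifier order as the secondary key
        lex_rank = np.empty(n, dtype=np.int64)
        lex_rank[np.argsort(ids)] = np.arange(n)
        tiebreak = np.broadcast_to(lex_rank, (n, n))
    block = block_size or min(n, 2048)
    out: list[GuideCluster] = []
    sentinel = np.int64(n) * n + n  # larger than any real key
    for s in range(0, n, block):
        e = min(s + block, n)
        key = net.hrr[s:e].astype(np.int64) * n + tiebreak[s:e]
        key[np.arange(e - s), np.arange(s, e)] = sentinel
        part = np.argpartition(key, kk - 1, axis=1)[:, :kk]
        part_keys = np.take_along_axis(key, part, axis=1)
        order = np.argsort(part_keys, axis=1, kind="stable")
        sel = np.take_along_axis(part, order, axis=1)
        for i in range(e - s):
            g = s + i
            members = sel[i]
            out.append(
                GuideCluster(
                    guide=str(ids[g]),
                    member_ids=[str(x) for x in ids[members]],
                    hrr_values=np.asarray(net.hrr[g, members], dtype=int),
                )
            )
    return out


def threshold_network(net: HRRNetwork, cutoff: int) -> EdgeList:
    """Keep all unordered pairs with hrr <= cutoff, each at the uniform weight."""
    n = net.n
    if not 2 <= cutoff <= n - 1:
        raise ValueError(f"cutoff must be in [2, {n - 1}], got {cutoff}")
    w = cutoff_weight(cutoff)
    ids = np.asarray(net.probeset_ids, dtype=object)
    ii, jj = np.nonzero(np.triu(net.hrr <= cutoff, k=1))
    a_ids, b_ids = ids[ii], ids[jj]
    swap = a_ids > b_ids  # lexicographic pair ordering
    a_ids, b_ids = np.where(swap, b_ids, a_ids), np.where(swap, a_ids, b_ids)
    edges = pd.DataFrame(
        {
            "probeset_a": a_ids,
            "probeset_b": b_ids,
            "hrr": net.hrr[ii, jj].astype(int),
            "weight": w,
        }
    ).sort_values(["probeset_a", "probeset_b"], ignore_index=True)
    connected = set(a_ids) | set(b_ids)
    isolated = [str(p) for p in net.probeset_ids if p not in connected]
    return EdgeList(edges, cutoff, w, [str(p) for p in net.probeset_ids], isolated)


def write_edges(edge_list: EdgeList, path: str | Path) -> None:
    edge_list.edges.to_csv(path, sep="\t", index=False)


def load_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_a": str, "probeset_b": str})
    required = {"probeset_a", "probeset_b", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    return df


def write_graphml(edge_list: EdgeList, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(edge_list.nodes)
    for row in edge_list.edges.itertuples(index=False):
        g.add_edge(row.probeset_a, row.probeset_b, hrr=int(row.hrr), weight=float(row.weight))
    nx.write_graphml(g, path)


def write_guide_clusters(clusters: list[GuideCluster], path: str | Path) -> None:
    rows = [
        (c.guide, m, int(h))
        for c in clusters
        for m, h in zip(c.member_ids, c.hrr_values)
    ]
    pd.DataFrame(rows, columns=["guide", "member", "hrr"]).to_csv(
        path, sep="\t", index=False
    )
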