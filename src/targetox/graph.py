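"""Protein association network and node-node distance matrices.

The network is an undirected graph of proteins read from a STRING-style
scored edge list.  All downstream features are defined on distances between
nodes of its main connected component, under one of three metrics:

* ``dsd`` — diffusion state distance: the L1 distance between two nodes'
  expected random-walk visit-count profiles,
  ``DSD(u, v) = || (b_u - b_v)^T (I - D^{-1}A + P)^{-1} ||_1``,
  where ``A`` is the binary adjacency matrix, ``D`` the diagonal degree
  matrix and ``P`` the constant matrix whose rows all equal the walk's
  stationary distribution ``pi_i = deg(i) / (2|E|)``.
* ``shortest_path`` — unweighted hop counts.
* ``discretized_sp`` — 1 when the hop count is below 3, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import shortest_path as _csgraph_sp
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DisconnectedGraphError,
    EmptyNetworkError,
    NumericalError,
    ParseError,
    UnknownIdError,
)

EDGE_COLUMNS = ("protein1", "protein2", "combined_score")


@dataclass(frozen=True)
class ProteinNetwork:
    """Undirected scored protein graph.

    Nodes are kept in lexicographic order; edges are unordered pairs with an
    integer confidence score on the STRING 0-1000 scale.  Self-loops and
    duplicate edges are excluded at construction.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass
class DistanceMatrix:
    """Dense symmetric node x node distance matrix under a named metric."""

    metric: str
    ids: tuple[str, ...]
    values: np.ndarray
    index: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.ids = tuple(self.ids)
        self.index = {p: i for i, p in enumerate(self.ids)}
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match the id list")

    def locate(self, node: str) -> int:
        try:
            return self.index[node]
        except KeyError:
            raise UnknownIdError(f"protein '{node}' is not indexed in this matrix")

    def distance(self, u: str, v: str) -> float:
        return float(self.values[self.locate(u), self.locate(v)])

    def row(self, node: str) -> np.ndarray:
        return self.values[self.locate(node)]

    def quantile(self, q: float) -> float:
        """Quantile of the off-diagonal distance distribution."""
        iu = np.triu_indices(len(self.ids), k=1)
        return float(np.quantile(self.values[iu], q))

    # -- serialization --------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npy`` (matrix) and ``<prefix>.ids`` (one id/line)."""
        prefix = Path(prefix)
        np.save(str(prefix) + ".npy", self.values)
        Path(str(prefix) + ".ids").write_text(
            "\n".join(self.ids) + "\n", encoding="utf-8"
        )
        Path(str(prefix) + ".metric").write_text(self.metric + "\n", encoding="utf-8")

    @classmethod
    def load(cls, prefix: str | Path) -> "DistanceMatrix":
        prefix = Path(prefix)
        values = np.load(str(prefix) + ".npy")
        ids = Path(str(prefix) + ".ids").read_text(encoding="utf-8").split()
        metric_file = Path(str(prefix) + ".metric")
        metric = metric_file.read_text().strip() if metric_file.exists() else "dsd"
        return cls(metric=metric, ids=tuple(ids), values=values)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (node_a, node_b, distance) table, upper triangle."""
        iu, ju = np.triu_indices(len(self.ids), k=1)
        ids = np.asarray(self.ids)
        return pd.DataFrame(
            {
                "node_a": ids[iu],
                "node_b": ids[ju],
                "distance": self.values[iu, ju],
            }
        )


# ---------------------------------------------------------------------------
# network construction


def load_network(
    edge_table: pd.DataFrame | str | Path | Iterable[tuple],
    min_score: int = 200,
) -> ProteinNetwork:
    """Build the protein network from a scored edge list.

    ``edge_table`` may be a path to a (optionally gzipped) TSV with header
    columns ``protein1, protein2, combined_score``, a DataFrame with those
    columns, or an iterable of ``(a, b, score)`` tuples.  Edges below
    ``min_score`` and self-loops are dropped; duplicate pairs collapse to the
    maximum score.
    """
    if isinstance(edge_table, (str, Path)):
        frame = pd.read_csv(edge_table, sep="\t", dtype=str)
        missing = [c for c in EDGE_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(
                f"edge table is missing required column(s): {', '.join(missing)}"
            )
    elif isinstance(edge_table, pd.DataFrame):
        frame = edge_table.copy()
        missing = [c for c in EDGE_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(
                f"edge table is missing required column(s): {', '.join(missing)}"
            )
    else:
        frame = pd.DataFrame(list(edge_table), columns=list(EDGE_COLUMNS))

    scores = pd.to_numeric(frame["combined_score"], errors="coerce")
    bad = scores.index[scores.isna()]
    if len(bad):
        # +2: one for the header row, one for 1-based numbering
        raise ParseError(
            f"non-numeric combined_score at line {int(bad[0]) + 2} of the edge table"
        )
    if frame["protein1"].isna().any() or frame["protein2"].isna().any():
        bad = frame.index[frame["protein1"].isna() | frame["protein2"].isna()][0]
        raise ParseError(f"missing protein id at line {int(bad) + 2} of the edge table")

    g = nx.Graph()
    kept = frame.loc[scores >= min_score]
    kept_scores = scores.loc[kept.index]
    for a, b, s in zip(kept["protein1"], kept["protein2"], kept_scores):
        a, b = str(a), str(b)
        if a == b:
            g.add_node(a)  # self-loop dropped, node retained
            continue
        s = int(s)
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=s)
    if g.number_of_nodes() == 0:
        raise EmptyNetworkError(
            f"no record passes the score filter (min_score={min_score})"
        )
    return ProteinNetwork(graph=g)


def main_component(net: ProteinNetwork) -> ProteinNetwork:
    """Largest connected component; size ties go to the component whose
    lexicographically smallest member is smallest."""
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot take the main component of an empty network")
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    return ProteinNetwork(graph=net.graph.subgraph(comps[0]).copy())


# ---------------------------------------------------------------------------
# distances


def _adjacency(net: ProteinNetwork) -> tuple[list[str], np.ndarray]:
    nodes = sorted(net.graph.nodes)
    A = nx.to_numpy_array(net.graph, nodelist=nodes, weight=None)  # binary
    return nodes, A


def _require_connected(net: ProteinNetwork, op: str) -> None:
    if not net.is_connected():
        raise DisconnectedGraphError(
            f"{op} requires a connected graph; extract it with main_component() first"
        )


def dsd_matrix(net: ProteinNetwork) -> DistanceMatrix:
    """Diffusion state distance via the closed form.

    Solves ``X = (I - D^{-1}A + P)^{-1}`` once by dense LU and returns the
    pairwise L1 distances between rows of ``X``.  Confidence scores are used
    only as the upstream edge filter: the walk runs on binary adjacency.
    """
    _require_connected(net, "dsd_matrix")
    nodes, A = _adjacency(net)
    n = len(nodes)
    if n < 2:
        raise ValueError("DSD needs at least two nodes")
    deg = A.sum(axis=1)
    T = A / deg[:, None]
    pi = deg / deg.sum()
    M = np.eye(n) - T + np.tile(pi, (n, 1))
    try:
        lu, piv = scipy.linalg.lu_factor(M)
        X = scipy.linalg.lu_solve((lu, piv), np.eye(n))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
        raise NumericalError(
            f"(I - D^-1 A + P) is singular (cond ~ {np.linalg.cond(M):.3e}): {exc}"
        ) from exc
    values = squareform(pdist(X, metric="cityblock"))
    return DistanceMatrix(metric="dsd", ids=tuple(nodes), values=values)


def dsd_iterative(net: ProteinNetwork, k: int) -> DistanceMatrix:
    """Truncated random-walk oracle for the DSD closed form.

    ``He^k(u) = sum_{i=0..k} b_u^T (D^{-1}A)^i`` — the expected visit counts
    of a k-step walk.  Pairwise L1 distances between these profiles converge
    to :func:`dsd_matrix` as k grows (pairwise convergence requires the walk
    to be aperiodic for node pairs on opposite sides of a bipartition).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    _require_connected(net, "dsd_iterative")
    nodes, A = _adjacency(net)
    T = A / A.sum(axis=1)[:, None]
    He = np.eye(len(nodes))
    power = np.eye(len(nodes))
    for _ in range(k):
        power = power @ T
        He += power
    values = squareform(pdist(He, metric="cityblock"))
    return DistanceMatrix(metric="dsd_iterative", ids=tuple(nodes), values=values)


def shortest_path_matrix(net: ProteinNetwork, discretize: bool = False) -> DistanceMatrix:
    """Unweighted hop counts; with ``discretize``, 1 when hops < 3 else 0.

    Under discretization the diagonal is 1 (a self-distance of 0 hops is
    below 3); self-distances are never used downstream.
    """
    _require_connected(net, "shortest_path_matrix")
    nodes = sorted(net.graph.nodes)
    adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight=None, format="csr")
    hops = _csgraph_sp(adj, method="D", unweighted=True, directed=False)
    if discretize:
        return DistanceMatrix(
            metric="discretized_sp",
            ids=tuple(nodes),
            values=(hops < 3).astype(float),
        )
    return DistanceMatrix(metric="shortest_path", ids=tuple(nodes), values=hops)


def build_distance_matrix(net: ProteinNetwork, metric: str = "dsd") -> DistanceMatrix:
    """Dispatch on metric name: ``dsd`` | ``shortest_path``/``sp`` |
    ``discretized_sp``/``dsp``."""
    metric = metric.lower()
    if metric == "dsd":
        return dsd_matrix(net)
    if metric in ("shortest_path", "sp"):
        return shortest_path_matrix(net, discretize=False)
    if metric in ("discretized_sp", "dsp"):
        return shortest_path_matrix(net, discretize=True)
    raise ValueError(f"unknown distance metric '{metric}'")


def medoid(dm: DistanceMatrix, node_set: Sequence[str]) -> str:
    """Member of ``node_set`` minimizing the summed distance to the other
    members; ties broken by lexicographic id."""
    members = sorted(set(node_set))
    if not members:
        raise ValueError("node_set must be nonempty")
    idx = np.array([dm.locate(m) for m in members])
    sub = dm.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    return members[int(np.argmin(sums))]  # argmin takes first -> lexicographic


def mean_pairwise_distance(dm: DistanceMatrix, node_set: Sequence[str]) -> float:
    """Mean over all unordered pairs of distinct members; needs >= 2 members."""
    members = sorted(set(node_set))
    if len(members) < 2:
        raise ValueError("need at least two distinct members")
    idx = np.array([dm.locate(m) for m in members])
    sub = dm.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())
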