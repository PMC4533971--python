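"""Observed statistics of the regime shift-driver network.

One-mode projections (drivers linked by the shifts they jointly cause,
shifts linked by the drivers they share), projection mean degree,
co-occurrence (open-triangle) index, the bipartite clustering coefficient
(four-cycles over three-paths), NODF nestedness with per-node
contributions, and generalist/idiosyncratic driver summaries.

Conventions, fixed because the source statistics are cited without
formulas: the co-occurrence index is normalized per node pair (the raw
open-triangle count is also returned); the clustering coefficient is
4*squares / three_paths, counting unlabeled subgraphs, so a complete
bipartite graph has coefficient 1; projection mean degree is computed on
the binarized projection; printed "~%" figures use integer truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .rsdb import BipartiteNetwork, _check_side


@dataclass
class Projection:
    """Weighted one-mode graph; weight(u,v) = shared opposite-side neighbours."""

    node_names: list[str]
    weights: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("projection weights must be symmetric")
        if np.diagonal(self.weights).any():
            raise ValueError("projection diagonal must be zero")

    def binary_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_names, columns=self.node_names)


@dataclass
class NodfResult:
    total: float
    rows: float
    cols: float
    row_contributions: pd.Series = field(repr=False)
    col_contributions: pd.Series = field(repr=False)


@dataclass
class NetworkSummary:
    """The statistics compared against fixed-margin null ensembles."""

    mean_degree_drivers: float
    mean_degree_shifts: float
    co_occurrence_drivers: float
    co_occurrence_shifts: float
    co_occurrence_connected_drivers: float
    co_occurrence_connected_shifts: float
    open_triangles_drivers: int
    open_triangles_shifts: int
    clustering_coefficient: float
    squares: int
    three_paths: int
    nodf_total: float
    nodf_rows: float
    nodf_cols: float

    # Note: the per-pair co-occurrence index is determined by the degree
    # sequences alone (sum of C(deg, 2) over the opposite side), so it is
    # constant across a fixed-margin null ensemble and its comparison is
    # degenerate by construction; the per-connected-pair version varies and
    # carries the actual signal.
    COMPARED = (
        "mean_degree_drivers",
        "mean_degree_shifts",
        "co_occurrence_drivers",
        "co_occurrence_shifts",
        "co_occurrence_connected_drivers",
        "co_occurrence_connected_shifts",
        "clustering_coefficient",
        "nodf_total",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.COMPARED}


@dataclass
class DriverSummary:
    n_shifts: int
    n_drivers: int
    n_links: int
    idiosyncratic_drivers: list[str]
    idiosyncratic_pct: int
    half_coverage_drivers: list[str]
    half_coverage_pct: int
    driver_degrees: pd.Series = field(repr=False)
    shift_degree_min: tuple[str, int] = ("", 0)
    shift_degree_max: tuple[str, int] = ("", 0)


def project_one_mode(network: BipartiteNetwork, side: str) -> Projection:
    """One-mode projection with shared-neighbour-count weights."""
    _check_side(side)
    A = network.incidence.astype(np.int64)
    if side == "driver":
        W, names = A.T @ A, network.driver_names
    else:
        W, names = A @ A.T, network.shift_names
    np.fill_diagonal(W, 0)
    return Projection(list(names), W, side)


def mean_degree(projection: Projection) -> float:
    """Average binary degree of the projection (count of co-occurring partners)."""
    if len(projection.node_names) == 0:
        return 0.0
    return float(projection.binary_degrees().mean())


def co_occurrence_index(network: BipartiteNetwork, side: str) -> tuple[float, int]:
    """Mean open-triangle count per pair of ``side`` nodes.

    An open triangle is two same-side nodes attached to a common node of the
    other side; the count sums C(degree, 2) over opposite-side nodes and the
    index divides by the number of node pairs on ``side``.
    """
    _check_side(side)
    n_side = network.n_drivers if side == "driver" else network.n_shifts
    if n_side < 2:
        raise UndefinedStatisticError(
            f"co-occurrence index needs >=2 {side} nodes, have {n_side}"
        )
    opp_deg = network.shift_degrees if side == "driver" else network.driver_degrees
    opp_deg = opp_deg.astype(np.int64)
    count = int((opp_deg * (opp_deg - 1) // 2).sum())
    return count / math.comb(n_side, 2), count


def co_occurrence_per_connected_pair(network: BipartiteNetwork, side: str) -> float:
    """Mean shared-neighbour count among pairs that co-occur at all.

    Unlike the per-pair index, this is not fixed by the degree sequences:
    concentrating the (margin-conserved) total co-occurrence on fewer pairs
    raises it, which is exactly the observed co-occurrence signature of the
    empirical network relative to randomized ones.
    """
    proj = project_one_mode(network, side)
    iu = np.triu_indices(len(proj.node_names), k=1)
    w = proj.weights[iu]
    connected = w > 0
    if not connected.any():
        return 0.0
    return float(w[connected].mean())


def bipartite_clustering_coefficient(
    network: BipartiteNetwork,
) -> tuple[float, int, int]:
    """Ratio of closed four-cycles (squares) to open three-link paths.

    Both are counted as unlabeled subgraphs; each square contains four of
    the counted three-paths, so the coefficient is ``4*squares/three_paths``
    and equals 1 on complete bipartite graphs.  NaN when no three-path
    exists.
    """
    A = network.incidence.astype(np.int64)
    S = A @ A.T  # shared drivers per shift pair
    iu = np.triu_indices_from(S, k=1)
    shared = S[iu]
    squares = int((shared * (shared - 1) // 2).sum())
    r = A.sum(axis=1)  # shift degrees
    c = A.sum(axis=0)  # driver degrees
    three_paths = int((A * np.outer(r - 1, c - 1)).sum())
    cc = 4.0 * squares / three_paths if three_paths > 0 else float("nan")
    return cc, squares, three_paths


def _nodf_one_side(mat: np.ndarray) -> tuple[float, np.ndarray, float]:
    """NODF over row pairs of ``mat``: (sum of paired overlaps, per-row mean, mean)."""
    m = mat.shape[0]
    if m < 2:
        return 0.0, np.zeros(m), 0.0
    k = mat.sum(axis=1).astype(np.float64)
    O = (mat @ mat.T).astype(np.float64)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(kmin > 0, 100.0 * O / kmin, 0.0)
    V[np.equal.outer(k, k)] = 0.0  # decreasing-fill condition: equal degrees score 0
    np.fill_diagonal(V, 0.0)
    iu = np.triu_indices(m, k=1)
    total = float(V[iu].sum())
    contrib = V.sum(axis=1) / (m - 1)
    return total, contrib, total / len(iu[0])


def nodf_nestedness(network: BipartiteNetwork) -> NodfResult:
    """NODF nestedness (0-100) from paired overlap with decreasing fill.

    For each pair of rows (and of columns) whose degrees strictly differ,
    the paired overlap is the share of the smaller-degree node's links also
    held by the larger-degree node, as a percentage; equal-degree pairs
    score 0.  Row, column and total scores average these paired values; the
    per-node contribution is the mean overlap of the pairs involving that
    node, which is also a useful node ordering for display.
    """
    A = network.incidence.astype(np.int64)
    m, n = A.shape
    row_sum, row_contrib, nodf_rows = _nodf_one_side(A)
    col_sum, col_contrib, nodf_cols = _nodf_one_side(A.T)
    n_pairs = (math.comb(m, 2) if m > 1 else 0) + (math.comb(n, 2) if n > 1 else 0)
    total = (row_sum + col_sum) / n_pairs if n_pairs else 0.0
    return NodfResult(
        total=total,
        rows=nodf_rows,
        cols=nodf_cols,
        row_contributions=pd.Series(row_contrib, index=network.shift_names),
        col_contributions=pd.Series(col_contrib, index=network.driver_names),
    )


def network_summary(network: BipartiteNetwork) -> NetworkSummary:
    """All null-comparable statistics of the network in one pass."""
    cc, squares, three_paths = bipartite_clustering_coefficient(network)
    cooc_d, tri_d = co_occurrence_index(network, "driver")
    cooc_s, tri_s = co_occurrence_index(network, "shift")
    nodf = nodf_nestedness(network)
    return NetworkSummary(
        mean_degree_drivers=mean_degree(project_one_mode(network, "driver")),
        mean_degree_shifts=mean_degree(project_one_mode(network, "shift")),
        co_occurrence_drivers=cooc_d,
        co_occurrence_shifts=cooc_s,
        co_occurrence_connected_drivers=co_occurrence_per_connected_pair(network, "driver"),
        co_occurrence_connected_shifts=co_occurrence_per_connected_pair(network, "shift"),
        open_triangles_drivers=tri_d,
        open_triangles_shifts=tri_s,
        clustering_coefficient=cc,
        squares=squares,
        three_paths=three_paths,
        nodf_total=nodf.total,
        nodf_rows=nodf.rows,
        nodf_cols=nodf.cols,
    )


def truncated_pct(part: int, whole: int) -> int:
    """Integer-truncated percentage, the convention behind printed "~%" figures."""
    return int(100 * part // whole) if whole else 0


def driver_summary(network: BipartiteNetwork) -> DriverSummary:
    """Idiosyncratic (degree-1) and half-coverage driver sets with shares."""
    if network.n_links == 0:
        raise UndefinedStatisticError("driver summary of an empty network")
    deg = pd.Series(network.driver_degrees, index=network.driver_names, dtype=int)
    idio = sorted(deg.index[deg == 1])
    # smallest prefix of drivers (by descending degree, ties alphabetical)
    # whose links exceed half of all links
    ordered = deg.sort_index().sort_values(ascending=False, kind="stable")
    cum = ordered.cumsum()
    half = network.n_links / 2
    n_half = int((cum <= half).sum()) + 1
    half_set = list(ordered.index[:n_half])
    sdeg = pd.Series(network.shift_degrees, index=network.shift_names, dtype=int)
    smin, smax = sdeg.idxmin(), sdeg.idxmax()
    return DriverSummary(
        n_shifts=network.n_shifts,
        n_drivers=network.n_drivers,
        n_links=network.n_links,
        idiosyncratic_drivers=idio,
        idiosyncratic_pct=truncated_pct(len(idio), network.n_drivers),
        half_coverage_drivers=half_set,
        half_coverage_pct=truncated_pct(len(half_set), network.n_drivers),
        driver_degrees=ordered,
        shift_degree_min=(str(smin), int(sdeg[smin])),
        shift_degree_max=(str(smax), int(sdeg[smax])),
    )


def shared_driver_pairs(
    network: BipartiteNetwork, side: str, threshold: int
) -> pd.DataFrame:
    """Unordered same-side pairs sharing >= ``threshold`` opposite neighbours.

    Sorted by shared count descending, then lexically, mirroring statements
    like "each pair occurs together in 10 or more regime shifts".
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    proj = project_one_mode(network, side)
    names = np.asarray(proj.node_names, dtype=object)
    iu = np.triu_indices(len(names), k=1)
    w = proj.weights[iu]
    keep = w >= threshold
    df = pd.DataFrame(
        {
            "node_a": names[iu[0][keep]],
            "node_b": names[iu[1][keep]],
            "shared": w[keep].astype(int),
        }
    )
    pairs_sorted = np.sort(df[["node_a", "node_b"]].to_numpy(dtype=object), axis=1)
    df[["node_a", "node_b"]] = pairs_sorted
    return df.sort_values(
        ["shared", "node_a", "node_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
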