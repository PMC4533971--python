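"""Distance-based clustering and ordination of regime shifts and drivers.

Regime shifts are compared through the drivers they share (Sorensen-Dice
distance, which rewards shared presences rather than shared absences) and
drivers through the shifts they cause (Jaccard).  Average-linkage (UPGMA)
clustering organizes either side into a dendrogram; classical (metric)
multidimensional scaling embeds the distance matrix by double-centering
and eigendecomposition; external variables are fitted onto the ordination
as vectors (regression of the variable on the coordinates) with
permutation p-values, and binary variable blocks from the database yield
per-block distance matrices.

UPGMA is implemented here rather than delegated so that ties break
deterministically (lexically smallest cluster pair); it is cross-checked
against an independent implementation in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import FormatError, UndefinedStatisticError
from .rsdb import AttributeTable, BipartiteNetwork, _check_side

METRICS = ("sorensen_dice", "jaccard")


@dataclass
class DistanceMatrix:
    node_names: list[str]
    distances: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        D = np.asarray(self.distances, dtype=float)
        if D.shape != (len(self.node_names),) * 2:
            raise FormatError("distance matrix shape does not match node names")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
            raise FormatError("distances must be symmetric with zero diagonal")
        self.distances = D

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.node_names, columns=self.node_names)

    def condensed(self) -> np.ndarray:
        return squareform(self.distances, checks=False)


@dataclass
class Dendrogram:
    """UPGMA merge tree in the standard linkage encoding.

    Row k of ``linkage`` merges clusters ``linkage[k,0]`` and
    ``linkage[k,1]`` (ids >= n_leaves refer to earlier merges) at height
    ``linkage[k,2]`` into cluster ``n_leaves+k`` of size ``linkage[k,3]``.
    """

    leaf_names: list[str]
    linkage: np.ndarray = field(repr=False)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> DistanceMatrix:
        from scipy.cluster.hierarchy import cophenet

        return DistanceMatrix(
            list(self.leaf_names),
            squareform(cophenet(self.linkage)),
            "cophenetic",
        )

    def to_newick(self) -> str:
        n = len(self.leaf_names)

        def label(name: str) -> str:
            if any(ch in name for ch in " ()[]:;,'"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def node(idx: int) -> tuple[str, float]:
            if idx < n:
                return label(self.leaf_names[idx]), 0.0
            a, b, h, _ = self.linkage[idx - n]
            sa, ha = node(int(a))
            sb, hb = node(int(b))
            return f"({sa}:{h/2 - ha/2:.10g},{sb}:{h/2 - hb/2:.10g})", h

        s, _ = node(n + len(self.linkage) - 1)
        return s + ";"


@dataclass
class Ordination:
    node_names: list[str]
    coordinates: np.ndarray  # node x axis, centered
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # per retained axis

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{k+1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.node_names, columns=cols)


@dataclass
class FittedVariable:
    variable_name: str
    direction: np.ndarray  # unit vector in ordination space
    r_squared: float
    permutation_p: float
    skipped: bool = False


def pairwise_distance(
    network: BipartiteNetwork, side: str, metric: str = "sorensen_dice"
) -> DistanceMatrix:
    """Binary Sorensen-Dice or Jaccard distances between same-side nodes.

    For neighbour sets A, B: jaccard = 1 - |A&B|/|A|B|union|;
    sorensen_dice = 1 - 2|A&B|/(|A|+|B|).  Every node must have at least
    one neighbour.
    """
    _check_side(side)
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    mat = network.incidence if side == "shift" else network.incidence.T
    names = network.names(side)
    deg = mat.sum(axis=1)
    if (deg == 0).any():
        empty = [n for n, d in zip(names, deg) if d == 0]
        raise UndefinedStatisticError(
            f"{side} nodes with empty neighbour sets: {empty}"
        )
    scipy_metric = "dice" if metric == "sorensen_dice" else "jaccard"
    D = squareform(pdist(mat.astype(bool), metric=scipy_metric))
    return DistanceMatrix(list(names), D, metric)


def upgma_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering with lexical tie-breaking.

    Among all minimum-distance cluster pairs, the pair whose (sorted)
    representative leaf names are lexically smallest merges first, making
    the dendrogram deterministic even under exact ties.
    """
    D0 = dist.distances
    n = len(dist.node_names)
    if n < 2:
        raise UndefinedStatisticError("clustering needs >= 2 nodes")
    if np.isnan(D0).any():
        raise FormatError("NaN distances")
    active: dict[int, dict] = {
        i: {"size": 1, "rep": dist.node_names[i]} for i in range(n)
    }
    d: dict[frozenset[int], float] = {
        frozenset((i, j)): float(D0[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best_key, best_val, best_reps = None, np.inf, None
        for key, val in d.items():
            i, j = sorted(key)
            reps = tuple(sorted((active[i]["rep"], active[j]["rep"])))
            if val < best_val - 1e-12 or (
                abs(val - best_val) <= 1e-12 and (best_reps is None or reps < best_reps)
            ):
                best_key, best_val, best_reps = key, val, reps
        i, j = sorted(best_key)
        si, sj = active[i]["size"], active[j]["size"]
        linkage[step] = (i, j, best_val, si + sj)
        new = {"size": si + sj, "rep": min(active[i]["rep"], active[j]["rep"])}
        del d[best_key]
        for k in list(active):
            if k in (i, j):
                continue
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[next_id] = new
        next_id += 1
    return Dendrogram(list(dist.node_names), linkage)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical (metric) scaling: double-center squared distances, eigendecompose.

    Retains the top ``k`` positive-eigenvalue axes (fewer, with a warning,
    if the distance matrix does not support k positive axes).  Negative
    eigenvalues are reported but never used for coordinates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dist.distances
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(abs(w).max(), 1.0) * 1e-10
    n_pos = int((w > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating requested {k} axes",
            stacklevel=2,
        )
    k_eff = min(k, n_pos)
    coords = V[:, :k_eff] * np.sqrt(w[:k_eff])
    coords -= coords.mean(axis=0, keepdims=True)  # numerically exact centering
    pos_sum = w[:n_pos].sum() if n_pos else 1.0
    return Ordination(
        node_names=list(dist.node_names),
        coordinates=coords,
        eigenvalues=w,
        proportion_explained=w[:k_eff] / pos_sum,
    )


def fit_variables(
    ordn: Ordination,
    variables: pd.DataFrame,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> list[FittedVariable]:
    """Fit explanatory variables onto the ordination as vectors.

    Each (centered, scaled) variable is regressed on the ordination
    coordinates; r-squared comes from that fit, the direction is the
    normalized coefficient vector, and the p-value permutes the variable's
    values (add-one convention).  Constant variables are flagged and
    skipped.  Use :func:`significant_variables` for the p < alpha view.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng() if rng is None else rng
    vars_df = variables.reindex(ordn.node_names)
    if vars_df.isna().any().any():
        missing = list(vars_df.index[vars_df.isna().any(axis=1)])
        raise FormatError(f"variables not aligned to ordination nodes: {missing}")
    X = ordn.coordinates
    Q, _ = np.linalg.qr(X - X.mean(axis=0, keepdims=True))
    results: list[FittedVariable] = []
    for name in vars_df.columns:
        y = vars_df[name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            results.append(
                FittedVariable(name, np.zeros(X.shape[1]), float("nan"),
                               float("nan"), skipped=True)
            )
            continue
        yc = (y - y.mean()) / y.std()
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        proj = Q.T @ yc
        r2 = float(proj @ proj) / float(yc @ yc)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        perms = np.column_stack(
            [rng.permutation(yc) for _ in range(n_perm)]
        )
        perm_proj = Q.T @ perms
        perm_r2 = (perm_proj**2).sum(axis=0) / (perms**2).sum(axis=0)
        p = (1 + int((perm_r2 >= r2).sum())) / (n_perm + 1)
        results.append(FittedVariable(name, direction, r2, p))
    return results


def significant_variables(
    fitted: Sequence[FittedVariable], alpha: float = 0.05
) -> list[FittedVariable]:
    return [f for f in fitted if not f.skipped and f.permutation_p < alpha]


def fitted_table(fitted: Sequence[FittedVariable]) -> pd.DataFrame:
    rows = []
    for f in fitted:
        row = {
            "variable": f.variable_name,
            "r_squared": f.r_squared,
            "permutation_p": f.permutation_p,
            "skipped": f.skipped,
        }
        for k, v in enumerate(f.direction):
            row[f"direction_{k+1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def categorical_block_distance(
    attrs: AttributeTable,
    blocks: Mapping[str, Sequence[str]],
    side: str = "shift",
) -> dict[str, DistanceMatrix]:
    """Sorensen-Dice distances over each named block of binary variables.

    All-zero variables are dropped from a block before computing (they
    carry no information); a node whose profile is all-zero after cleaning
    makes the distance undefined and raises.
    """
    df = attrs.for_side(side)
    out: dict[str, DistanceMatrix] = {}
    for block, cols in blocks.items():
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"block {block!r} references unknown variables {missing}")
        sub = df[list(cols)].astype(float)
        sub = sub.loc[:, sub.sum(axis=0) > 0]  # delete zero columns
        if sub.shape[1] == 0:
            raise UndefinedStatisticError(f"block {block!r} empty after cleaning")
        zero_rows = list(sub.index[sub.sum(axis=1) == 0])
        if zero_rows:
            raise UndefinedStatisticError(
                f"block {block!r}: all-zero profiles for {zero_rows}"
            )
        D = squareform(pdist(sub.to_numpy(dtype=bool), metric="dice"))
        out[block] = DistanceMatrix(list(sub.index), D, f"sorensen_dice[{block}]")
    return out
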