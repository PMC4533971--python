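"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as directly as possible from definitions
(explicit loops over node subsets / neighbour sets) and deliberately shares
no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def cooccurrence_count_naive(A: np.ndarray, side: str) -> int:
    """Open triangles by exhaustive enumeration of same-side pairs."""
    mat = A if side == "shift" else A.T
    n = mat.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(mat[i] * mat[j]))
    return total


def squares_and_three_paths_naive(A: np.ndarray) -> tuple[int, int]:
    """Count 4-cycles and 3-link paths by enumerating 2x2 node subsets."""
    m, n = A.shape
    squares = 0
    paths = 0
    for i, j in itertools.combinations(range(m), 2):
        for k, l in itertools.combinations(range(n), 2):
            cells = (A[i, k], A[i, l], A[j, k], A[j, l])
            if all(cells):
                squares += 1
            # a 3-path on these four nodes: one of the four cells absent,
            # the other three present
            if sum(cells) == 3:
                paths += 1
            elif sum(cells) == 4:
                paths += 4  # each square contains four 3-paths
    return squares, paths


def nodf_naive(A: np.ndarray) -> float:
    """NODF by double loop over row pairs and column pairs."""

    def side_sum(mat):
        rows = [set(np.flatnonzero(r)) for r in mat]
        degs = [len(r) for r in rows]
        total = 0.0
        n_pairs = 0
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                n_pairs += 1
                if degs[i] == degs[j] or min(degs[i], degs[j]) == 0:
                    continue
                small, large = (i, j) if degs[i] < degs[j] else (j, i)
                total += 100.0 * len(rows[small] & rows[large]) / degs[small]
        return total, n_pairs

    rsum, rpairs = side_sum(A)
    csum, cpairs = side_sum(A.T)
    if rpairs + cpairs == 0:
        return 0.0
    return (rsum + csum) / (rpairs + cpairs)


def enumerate_margin_class(row_margins, col_margins) -> list[bytes]:
    """All binary matrices with the given margins (small sizes only)."""
    r = list(row_margins)
    c = list(col_margins)
    m, n = len(r), len(c)
    out: list[bytes] = []

    def rec(i: int, remaining_cols: tuple[int, ...], rows_acc: list[tuple[int, ...]]):
        if i == m:
            if all(x == 0 for x in remaining_cols):
                out.append(np.array(rows_acc, dtype=np.int8).tobytes())
            return
        for cols in itertools.combinations(range(n), r[i]):
            if any(remaining_cols[j] == 0 for j in cols):
                continue
            row = tuple(1 if j in cols else 0 for j in range(n))
            nxt = tuple(
                remaining_cols[j] - (1 if j in cols else 0) for j in range(n)
            )
            rec(i + 1, nxt, rows_acc + [row])

    rec(0, tuple(c), [])
    return out


def total_variation_to_uniform(counts: dict[bytes, int], n_states: int) -> float:
    total = sum(counts.values())
    tv = 0.0
    seen = 0
    for k, v in counts.items():
        tv += abs(v / total - 1.0 / n_states)
        seen += 1
    tv += (n_states - seen) * (1.0 / n_states)
    return 0.5 * tv


def mean_shared_per_connected_pair_naive(A: np.ndarray, side: str) -> float:
    mat = A if side == "shift" else A.T
    vals = []
    for i in range(mat.shape[0]):
        for j in range(i + 1, mat.shape[0]):
            s = int(np.sum(mat[i] * mat[j]))
            if s > 0:
                vals.append(s)
    return float(np.mean(vals)) if vals else 0.0


def random_binary_matrix(rng: np.random.Generator, m: int, n: int, fill: float) -> np.ndarray:
    """Random matrix with no empty rows/columns (resampled until valid)."""
    while True:
        A = (rng.random((m, n)) < fill).astype(np.int8)
        if A.sum(0).min() > 0 and A.sum(1).min() > 0:
            return A
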