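"""Fixed-margin null models for the bipartite network.

Null networks share both degree sequences with the observed matrix, i.e.
they randomly reshuffle which driver causes which regime shift while
keeping every node's number of links unchanged.  Two samplers are
provided:

* ``curveball`` (default): trade-based MCMC whose stationary distribution
  is uniform over all binary matrices with the observed margins.  Each
  sample restarts from the observed matrix and applies a configurable
  number of trades (default ``5 * min(n_shifts, n_drivers)``).
* ``sis``: sequential importance sampling that builds the matrix column by
  column and returns an importance weight.  Weights are approximate
  (sequential-selection probabilities with dead-end restarts) and unweighted
  summaries are used by default; the sampler exists for parity with
  constructive samplers used elsewhere in the field.

Observed statistics are compared against the ensemble with a standardized
effect size, an add-one empirical p-value (never exactly zero) and a
one-sample t-test of the null draws against the observed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleMarginsError
from . import netstats
from .rsdb import BipartiteNetwork


@dataclass
class NullEnsemble:
    """Per-sample statistics of fixed-margin null networks."""

    statistics: pd.DataFrame
    sampler: str
    n_trades: int | None = None
    importance_weights: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.statistics)


@dataclass
class StatComparison:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    ses_z: float  # NaN when null_sd == 0
    empirical_p: float
    t_p: float
    direction: str  # "greater" | "less"


def gale_ryser_feasible(row_margins, col_margins) -> bool:
    """Whether a 0/1 matrix with the given margins exists."""
    r = np.sort(np.asarray(row_margins, dtype=int))[::-1]
    c = np.asarray(col_margins, dtype=int)
    n = len(c)
    if r.sum() != c.sum() or (r < 0).any() or (c < 0).any():
        return False
    if len(r) and r[0] > n:
        return False
    for k in range(1, len(r) + 1):
        lhs = r[:k].sum()
        rhs = np.minimum(c, k).sum()
        if lhs > rhs:
            return False
    return True


# ---------------------------------------------------------------------------
# curveball
# ---------------------------------------------------------------------------

def _rows_to_sets(incidence: np.ndarray) -> list[set[int]]:
    return [set(np.flatnonzero(row)) for row in incidence]


def _sets_to_matrix(row_sets: list[set[int]], n_cols: int) -> np.ndarray:
    A = np.zeros((len(row_sets), n_cols), dtype=np.int8)
    for i, s in enumerate(row_sets):
        A[i, list(s)] = 1
    return A


def curveball_trades(
    row_sets: list[set[int]], n_trades: int, rng: np.random.Generator
) -> None:
    """Apply ``n_trades`` curveball trades in place.

    A trade picks two rows and re-deals the columns held by exactly one of
    them uniformly at random, preserving both row sizes and all column sums.
    """
    m = len(row_sets)
    if m < 2:
        return
    pairs = rng.integers(0, m, size=(n_trades, 2))
    for i, j in pairs:
        if i == j:
            continue
        a, b = row_sets[i], row_sets[j]
        only_a = a - b
        only_b = b - a
        if not only_a or not only_b:
            continue
        pool = list(only_a | only_b)
        perm = rng.permutation(len(pool))
        cut = len(only_a)
        new_a = {pool[k] for k in perm[:cut]}
        new_b = {pool[k] for k in perm[cut:]}
        common = a & b
        row_sets[i] = common | new_a
        row_sets[j] = common | new_b


def default_n_trades(network: BipartiteNetwork) -> int:
    return 5 * min(network.n_shifts, network.n_drivers)


def sample_fixed_margins(
    network: BipartiteNetwork,
    method: str = "curveball",
    rng: np.random.Generator | None = None,
    n_trades: int | None = None,
) -> tuple[BipartiteNetwork, float]:
    """One null network with the observed margins, plus an importance weight.

    The weight is 1.0 for curveball (uniform sampler); for SIS it is the
    (approximate, unnormalized) inverse proposal probability.
    """
    rng = np.random.default_rng() if rng is None else rng
    if network.n_links == 0:
        raise InfeasibleMarginsError("cannot resample an empty network")
    if method == "curveball":
        n_trades = default_n_trades(network) if n_trades is None else n_trades
        row_sets = _rows_to_sets(network.incidence)
        curveball_trades(row_sets, n_trades, rng)
        A = _sets_to_matrix(row_sets, network.n_drivers)
        weight = 1.0
    elif method == "sis":
        A, weight = _sis_sample(
            network.shift_degrees.astype(int), network.driver_degrees.astype(int), rng
        )
    else:
        raise ValueError(f"unknown sampler {method!r}")
    return (
        BipartiteNetwork(list(network.shift_names), list(network.driver_names), A),
        weight,
    )


# ---------------------------------------------------------------------------
# sequential importance sampling
# ---------------------------------------------------------------------------

def _sis_sample(
    row_margins: np.ndarray, col_margins: np.ndarray, rng: np.random.Generator,
    max_restarts: int = 1000,
) -> tuple[np.ndarray, float]:
    r = np.asarray(row_margins, dtype=int)
    c = np.asarray(col_margins, dtype=int)
    if not gale_ryser_feasible(r, c):
        raise InfeasibleMarginsError(
            f"no binary matrix has row margins {r.tolist()} and column margins {c.tolist()}"
        )
    m, n = len(r), len(c)
    col_order = np.argsort(-c, kind="stable")
    for _ in range(max_restarts):
        A = np.zeros((m, n), dtype=np.int8)
        remaining = r.copy()
        logq = 0.0
        ok = True
        for pos, j in enumerate(col_order):
            cj = int(c[j])
            if cj == 0:
                continue
            rows, logp = _draw_column(remaining, cj, rng)
            if rows is None:
                ok = False
                break
            A[rows, j] = 1
            remaining[rows] -= 1
            rest_cols = c[col_order[pos + 1:]]
            if not gale_ryser_feasible(rest_cols, remaining):
                ok = False
                break
            logq += logp
        if ok:
            return A, math.exp(-logq) if logq < 700 else float("inf")
    raise InfeasibleMarginsError("SIS failed to complete a matrix (too many restarts)")


def _draw_column(remaining: np.ndarray, cj: int, rng: np.random.Generator):
    """Pick ``cj`` distinct rows with probability proportional to remaining capacity."""
    avail = np.flatnonzero(remaining > 0)
    if len(avail) < cj:
        return None, 0.0
    w = remaining[avail].astype(float)
    chosen = []
    logp = 0.0
    for _ in range(cj):
        p = w / w.sum()
        k = rng.choice(len(avail), p=p)
        logp += math.log(p[k])
        chosen.append(avail[k])
        w[k] = 0.0
    return np.array(chosen), logp


# ---------------------------------------------------------------------------
# ensembles and comparison
# ---------------------------------------------------------------------------

def build_null_ensemble(
    network: BipartiteNetwork,
    n_samples: int,
    rng: np.random.Generator | None = None,
    sampler: str = "curveball",
    n_trades: int | None = None,
    mode: str = "restart",
    thin: int | None = None,
    stats_fn: Callable[[BipartiteNetwork], Mapping[str, float]] | None = None,
) -> NullEnsemble:
    """Statistics of ``n_samples`` fixed-margin null networks.

    ``mode="restart"`` (default) starts every sample from the observed
    matrix with ``n_trades`` curveball trades; ``mode="chain"`` runs a
    single chain recording a sample every ``thin`` trades after an
    ``n_trades`` burn-in.  ``stats_fn`` defaults to the full network
    summary.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    stats_fn = stats_fn or (lambda net: netstats.network_summary(net).as_dict())
    n_trades = default_n_trades(network) if n_trades is None else n_trades
    rows: list[dict[str, float]] = []
    weights = np.ones(n_samples)
    if sampler == "curveball" and mode == "chain":
        thin = n_trades if thin is None else thin
        row_sets = _rows_to_sets(network.incidence)
        curveball_trades(row_sets, n_trades, rng)  # burn-in
        for _ in range(n_samples):
            curveball_trades(row_sets, thin, rng)
            A = _sets_to_matrix(row_sets, network.n_drivers)
            rows.append(dict(stats_fn(BipartiteNetwork(
                list(network.shift_names), list(network.driver_names), A))))
    else:
        for k in range(n_samples):
            sampled, w = sample_fixed_margins(network, sampler, rng, n_trades)
            weights[k] = w
            rows.append(dict(stats_fn(sampled)))
    return NullEnsemble(
        statistics=pd.DataFrame(rows),
        sampler=sampler,
        n_trades=n_trades,
        importance_weights=weights if sampler == "sis" else None,
    )


def empirical_p(null_values: np.ndarray, observed: float, direction: str) -> float:
    """Add-one empirical p-value for a fixed tail (never exactly zero)."""
    null_values = np.asarray(null_values, dtype=float)
    if direction == "greater":
        extreme = int((null_values >= observed).sum())
    elif direction == "less":
        extreme = int((null_values <= observed).sum())
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return (1 + extreme) / (len(null_values) + 1)


def compare_to_null(
    observed: netstats.NetworkSummary | Mapping[str, float],
    ensemble: NullEnsemble,
) -> list[StatComparison]:
    """Observed vs null: SES, add-one empirical p, one-sample t-test p.

    The empirical p counts null draws at least as extreme as the observation
    in the observed direction, with the add-one (never-zero) convention:
    ``(1 + #extreme) / (n_samples + 1)``.
    """
    obs = observed.as_dict() if isinstance(observed, netstats.NetworkSummary) else dict(observed)
    out: list[StatComparison] = []
    n = ensemble.n_samples
    for name, value in obs.items():
        if name not in ensemble.statistics.columns:
            continue
        null = ensemble.statistics[name].to_numpy(dtype=float)
        null = null[~np.isnan(null)]
        if len(null) == 0:
            continue
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd <= 1e-12 * max(1.0, abs(mu)):  # margin-determined statistic
            sd = 0.0
        direction = "greater" if value >= mu else "less"
        if sd == 0.0:
            emp_p = 1.0 if np.isclose(value, mu) else 1 / (len(null) + 1)
        else:
            emp_p = empirical_p(null, value, direction)
        ses = (value - mu) / sd if sd > 0 else float("nan")
        if sd > 0:
            t_p = float(stats.ttest_1samp(null, popmean=value).pvalue)
        else:
            t_p = 1.0 if np.isclose(value, mu) else 0.0
        out.append(
            StatComparison(
                statistic_name=name,
                observed=float(value),
                null_mean=mu,
                null_sd=sd,
                ses_z=ses,
                empirical_p=emp_p,
                t_p=t_p,
                direction=direction,
            )
        )
    return out


def comparisons_table(comparisons: list[StatComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])
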