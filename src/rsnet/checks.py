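"""Study procedures validating the machinery on controlled inputs.

These are the computations behind the package's own quality claims:
exactness of the fixed-margin samplers (margin conservation and total
variation distance to the uniform distribution on enumerable margin
classes), calibration of the permutation and null-ensemble p-values under
their null hypotheses, and recovery of planted structure (nestedness,
clustering, projection thinning, attribute homophily) at database scale.
They are exposed as library functions so the test suite, the analysis
scripts and the acceptance script all run the identical procedure.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from . import attributes, netstats, nulls, ordination, synth
from .rsdb import MANAGEMENT_SCALES, BipartiteNetwork


def _net(A: np.ndarray) -> BipartiteNetwork:
    A = np.asarray(A, dtype=np.int8)
    return BipartiteNetwork(
        [f"s{i}" for i in range(A.shape[0])],
        [f"d{j}" for j in range(A.shape[1])],
        A,
    )


def enumerate_matrices(row_margins, col_margins) -> list[bytes]:
    """All binary matrices with the given margins (tiny sizes only)."""
    r = list(row_margins)
    c = tuple(col_margins)
    n = len(c)
    out: list[bytes] = []

    def rec(i, remaining, acc):
        if i == len(r):
            if not any(remaining):
                out.append(np.array(acc, dtype=np.int8).tobytes())
            return
        for cols in itertools.combinations(range(n), r[i]):
            if any(remaining[j] == 0 for j in cols):
                continue
            rec(
                i + 1,
                tuple(remaining[j] - (j in cols) for j in range(n)),
                acc + [[1 if j in cols else 0 for j in range(n)]],
            )

    rec(0, c, [])
    return out


def sampler_margin_violations(
    network: BipartiteNetwork,
    n_samples: int,
    rng: np.random.Generator,
    sampler: str = "curveball",
) -> int:
    """Number of samples whose margins differ from the observed ones."""
    bad = 0
    for _ in range(n_samples):
        s, _ = nulls.sample_fixed_margins(network, sampler, rng)
        if not (
            np.array_equal(s.shift_degrees, network.shift_degrees)
            and np.array_equal(s.driver_degrees, network.driver_degrees)
        ):
            bad += 1
    return bad


def sampler_tv_to_uniform(
    seed_matrix: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    n_trades: int | None = None,
) -> tuple[float, int]:
    """Total variation distance of curveball samples to the uniform
    distribution over the seed matrix's margin class, by enumeration."""
    seed_matrix = np.asarray(seed_matrix, dtype=np.int8)
    states = set(enumerate_matrices(seed_matrix.sum(axis=1), seed_matrix.sum(axis=0)))
    net = _net(seed_matrix)
    counts: Counter[bytes] = Counter()
    for _ in range(n_samples):
        s, _ = nulls.sample_fixed_margins(net, "curveball", rng, n_trades)
        counts[s.incidence.tobytes()] += 1
    assert set(counts) <= states, "sampler left the margin class"
    k = len(states)
    tv = 0.5 * sum(abs(counts.get(st, 0) / n_samples - 1 / k) for st in states)
    return tv, k


def null_p_calibration(
    rng: np.random.Generator,
    n_replicates: int = 200,
    ensemble_size: int = 99,
    shape: tuple[int, int] = (8, 10),
    fill: float = 0.35,
) -> np.ndarray:
    """Fixed-direction empirical p of NODF when the observation is itself a
    null draw; uniform on {1/(n+1), ..., 1} when the sampler is exact."""
    while True:
        base = (rng.random(shape) < fill).astype(np.int8)
        if base.sum(0).min() > 0 and base.sum(1).min() > 0:
            break
    base_net = _net(base)
    nodf = lambda net: {"nodf": netstats.nodf_nestedness(net).total}
    ps = np.empty(n_replicates)
    for b in range(n_replicates):
        observed, _ = nulls.sample_fixed_margins(base_net, "curveball", rng)
        ens = nulls.build_null_ensemble(observed, ensemble_size, rng, stats_fn=nodf)
        ps[b] = nulls.empirical_p(
            ens.statistics["nodf"].to_numpy(),
            netstats.nodf_nestedness(observed).total,
            "greater",
        )
    return ps


def homophily_p_calibration(
    rng: np.random.Generator,
    n_replicates: int = 200,
    n_perm: int = 99,
) -> np.ndarray:
    """Homophily permutation p under random labels (one projection, many
    independent labelings)."""
    net, _, _ = synth.generate_rsdb_like(int(rng.integers(2**31)))
    proj = netstats.project_one_mode(net, "driver")
    ps = np.empty(n_replicates)
    for b in range(n_replicates):
        labels = pd.Series(
            rng.choice(MANAGEMENT_SCALES, size=net.n_drivers),
            index=net.driver_names,
        )
        ps[b] = attributes.attribute_homophily_test(
            proj, labels, n_perm=n_perm, rng=rng
        ).permutation_p
    return ps


def vector_fit_p_calibration(
    rng: np.random.Generator,
    n_replicates: int = 200,
    n_perm: int = 99,
    n_points: int = 25,
) -> np.ndarray:
    """Vector-fitting permutation p for variables independent of the
    ordination."""
    pts = rng.normal(size=(n_points, 2))
    pts -= pts.mean(axis=0)
    names = [f"p{i}" for i in range(n_points)]
    ordn = ordination.Ordination(
        names, pts, np.array([2.0, 1.0]), np.array([0.6, 0.3])
    )
    ps = np.empty(n_replicates)
    for b in range(n_replicates):
        y = pd.DataFrame({"v": rng.normal(size=n_points)}, index=names)
        ps[b] = ordination.fit_variables(ordn, y, n_perm=n_perm, rng=rng)[0].permutation_p
    return ps


def planted_structure_recovery(
    n_seeds: int = 100,
    n_null: int = 40,
    n_perm: int = 199,
    seed: int = 0,
    config: synth.SyntheticConfig | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of seeds reproducing the empirical network's signature.

    For each seed a database-scale synthetic network (nested + guild
    structure, planted scale homophily) is compared against a fixed-margin
    null ensemble: nestedness, bipartite clustering and driver-projection
    co-occurrence per connected pair should exceed the null mean, the
    driver-projection mean degree should fall below it, and the scale-
    homophily permutation test should reject at ``alpha``.
    """
    wins = Counter()
    for k in range(n_seeds):
        cfg = config or synth.SyntheticConfig(seed=seed + k)
        cfg = synth.SyntheticConfig(**{**vars(cfg), "seed": seed + k})
        net, attrs, _ = synth.generate_rsdb_like(cfg.seed, cfg)
        obs = netstats.network_summary(net).as_dict()
        ens = nulls.build_null_ensemble(
            net, n_null, np.random.default_rng([seed + k, 1])
        )
        mu = ens.statistics.mean()
        wins["nodf_above_null"] += obs["nodf_total"] > mu["nodf_total"]
        wins["clustering_above_null"] += (
            obs["clustering_coefficient"] > mu["clustering_coefficient"]
        )
        wins["driver_mean_degree_below_null"] += (
            obs["mean_degree_drivers"] < mu["mean_degree_drivers"]
        )
        wins["co_occurrence_above_null"] += (
            obs["co_occurrence_connected_drivers"]
            > mu["co_occurrence_connected_drivers"]
        )
        res = attributes.attribute_homophily_test(
            netstats.project_one_mode(net, "driver"),
            attrs.attribute("management_scale", "driver"),
            n_perm=n_perm,
            rng=np.random.default_rng([seed + k, 2]),
        )
        wins["homophily_rejected"] += res.permutation_p < alpha
    return {k: v / n_seeds for k, v in wins.items()}
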