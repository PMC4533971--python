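"""Synthetic regime shift-driver data with planted structure.

The generator emulates the statistical shape of the full regime-shifts
database so every downstream stage is testable without a download: ~25
shifts by ~57 drivers, mean shift degree ~11.2, an exact number of
idiosyncratic (degree-1) drivers, a nested incidence matrix, and
management-scale labels with tunable homophily on the driver projection.

Nestedness is planted constructively.  A deterministic template splits
both sides into two latent guilds (think aquatic vs terrestrial systems
and their driver pools) and fills each guild with a nested staircase of
driver columns: degrees decay geometrically and each column occupies the
top-ranked shifts of its guild, with equal-degree columns tiled over
successive disjoint segments.  ``nestedness_strength`` sets the fraction
of links that keep their template position (``1 - exp(-strength/2)``);
the remainder relocate uniformly, so strength 0 is a margin-matched
random network and large strength approaches the pure template.  This
within-guild containment plus between-guild separation is what
simultaneously raises nestedness and clustering above degree-preserving
nulls while keeping the driver projection sparser than them, the
co-occurrence signature of the real database; a global rank surface
cannot do both at once because fixed margins conserve total pairwise
overlap.  The heavy-tailed driver degree distribution is an assumption,
not an observed property of the database.

Planted homophily anchors each driver's management scale to the network
structure: the generalist tier (top third by degree) leans international,
and the two specialist co-occurrence communities (recovered spectrally
from the driver projection) lean local and regional/national; the anchor
is kept with probability ``homophily_strength``, otherwise drawn
uniformly.  Anchoring to structure, rather than label copying along the
(nearly complete) projection, is what leaves a signal that a
label-permutation test can detect; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleMarginsError
from .rsdb import (
    MANAGEMENT_SCALES,
    AttributeTable,
    BipartiteNetwork,
    CategoryScheme,
)

#: broad category -> its three detailed categories (15 detailed, 5 broad,
#: mutually exclusive memberships)
CATEGORY_TREE: dict[str, list[str]] = {
    "habitat modification": [
        "deforestation & land conversion",
        "urbanization",
        "infrastructure & engineering",
    ],
    "food production": [
        "agriculture & cropping",
        "livestock & ranching",
        "aquaculture",
    ],
    "nutrients & pollutants": [
        "nutrient inputs",
        "pollutants & toxins",
        "greenhouse emissions",
    ],
    "resource extraction": [
        "fishing & harvest",
        "logging & fuelwood",
        "water extraction",
    ],
    "spill-over effects": [
        "climatic spillovers",
        "oceanic spillovers",
        "ecological spillovers",
    ],
}

#: categorical-variable blocks recorded for each regime shift (name -> size)
SHIFT_BLOCK_SIZES: dict[str, int] = {
    "ecosystem_processes": 5,
    "provisioning_services": 8,
    "regulating_services": 8,
    "cultural_services": 4,
    "drivers": 10,
    "land_use": 11,
    "scales": 8,
    "reversibility": 3,
}

ECOSYSTEM_CLASSES = ("aquatic", "terrestrial", "subcontinental")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults emulate the database)."""

    n_shifts: int = 25
    n_drivers: int = 57
    target_mean_shift_degree: float = 11.2
    nestedness_strength: float = 5.0
    homophily_strength: float = 0.8
    n_idiosyncratic: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shifts < 2 or self.n_drivers < 2:
            raise ValueError("need at least 2 nodes on each side")
        if not 0 <= self.n_idiosyncratic <= self.n_drivers:
            raise ValueError("n_idiosyncratic must be in [0, n_drivers]")
        if not 0.0 <= self.homophily_strength <= 1.0:
            raise ValueError("homophily_strength must be in [0, 1]")
        if self.nestedness_strength < 0:
            raise ValueError("nestedness_strength must be >= 0")
        L = self.n_links
        if L > self.n_shifts * self.n_drivers:
            raise InfeasibleMarginsError("target mean degree exceeds matrix capacity")
        # idiosyncratic columns hold exactly one link each; the rest at most n_shifts
        if L > self.n_idiosyncratic + (self.n_drivers - self.n_idiosyncratic) * self.n_shifts:
            raise InfeasibleMarginsError("target fill incompatible with idiosyncratic count")
        if L < max(self.n_shifts, self.n_drivers):
            raise InfeasibleMarginsError("too few links to avoid empty nodes")

    @property
    def n_links(self) -> int:
        return int(round(self.target_mean_shift_degree * self.n_shifts))


def _rng(config: SyntheticConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return np.random.default_rng(config.seed) if rng is None else rng


def _split_sizes(total: int, proportions: np.ndarray) -> np.ndarray:
    sizes = np.floor(proportions * total).astype(int)
    while sizes.sum() < total:
        sizes[int(np.argmax(proportions * total - sizes))] += 1
    return sizes


def _staircase_degrees(n_cols: int, max_deg: int, budget: int) -> np.ndarray:
    """Decreasing column degrees, geometric profile, summing to ``budget``."""
    t = np.linspace(0.0, 1.0, n_cols) if n_cols > 1 else np.zeros(1)
    raw = max_deg ** (1.0 - t)
    k = np.clip(np.round(raw * budget / raw.sum()).astype(int), 1, max_deg)
    while k.sum() != budget:
        if k.sum() < budget:
            k[int(np.argmax((k < max_deg) * (max_deg - k)))] += 1
        else:
            j = len(k) - 1 - int(np.argmax(k[::-1] > 1))
            k[j] -= 1
    return np.sort(k)[::-1]


def _nested_template(m: int, n: int, n_links: int) -> np.ndarray:
    """Deterministic two-guild nested incidence template with ``n_links`` links.

    Each guild holds a staircase: driver degrees decay geometrically and
    each column covers top-ranked shifts of its guild; equal-degree columns
    tile successive segments instead of stacking (identical tied columns
    would concentrate overlap on pairs that a paired-overlap nestedness
    score ignores).
    """
    props = np.array([0.52, 0.48])
    ms = _split_sizes(m, props)
    ns = _split_sizes(n, props)
    budgets = _split_sizes(n_links, (ms * ns) / (ms * ns).sum())
    # guild budgets must be feasible: 1..ms[g] per column
    for g in range(2):
        budgets[g] = min(max(budgets[g], ns[g]), ns[g] * ms[g])
    budgets[0] = n_links - budgets[1]
    A = np.zeros((m, n), dtype=np.int8)
    row_start = np.concatenate([[0], np.cumsum(ms)[:-1]])
    col = 0
    for g in range(2):
        rows = np.arange(row_start[g], row_start[g] + ms[g])
        degs = _staircase_degrees(ns[g], ms[g], int(budgets[g]))
        prev, offset = None, 0
        for k in degs:
            if k != prev:
                prev, offset = k, 0
            if offset + k <= ms[g]:
                sel = rows[offset:offset + k]
            else:
                sel = np.concatenate([rows[offset:], rows[:offset + k - ms[g]]])
            A[sel, col] = 1
            col += 1
            offset = (offset + k) % ms[g]
    return A


def generate_nested_bipartite(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> BipartiteNetwork:
    """Sample a nested binary incidence matrix matching the configuration.

    Guarantees: no empty rows or columns, exactly ``n_idiosyncratic``
    columns of degree 1, total links equal to
    ``round(target_mean_shift_degree * n_shifts)`` (so the realized mean
    shift degree equals the target up to rounding).
    """
    rng = _rng(config, rng)
    m, n = config.n_shifts, config.n_drivers
    T = _nested_template(m, n, config.n_links)
    keep_prob = 1.0 - np.exp(-config.nestedness_strength / 2.0)
    A = T.copy()
    links = np.argwhere(A == 1)
    moved = links[rng.random(len(links)) >= keep_prob]
    for i, j in moved:
        A[i, j] = 0
    for _ in range(len(moved)):  # relocate uniformly among empty cells
        empty = np.flatnonzero(A.ravel() == 0)
        A.ravel()[rng.choice(empty)] = 1
    # template cells weight the repairs below so fixes respect the structure
    P = np.clip(keep_prob * T + (1.0 - keep_prob) * (config.n_links / A.size), 1e-6, 1.0)

    _fill_empty(A, P, rng)
    idio = _plant_idiosyncratic(A, P, config.n_idiosyncratic, rng)
    _fill_empty(A, P, rng, forbidden_cols=idio)
    _fix_stray_degree_one(A, P, idio, rng)
    _balance_links(A, P, config.n_links, idio, rng)

    assert not (A.sum(0) == 0).any() and not (A.sum(1) == 0).any()
    assert int((A.sum(0) == 1).sum()) == config.n_idiosyncratic
    assert int(A.sum()) == config.n_links
    shift_names = [f"RS{i+1:02d}" for i in range(m)]
    driver_names = [f"D{j+1:02d}" for j in range(n)]
    return BipartiteNetwork(shift_names, driver_names, A)


def _fill_empty(A, P, rng, forbidden_cols: set[int] | None = None) -> None:
    forbidden = forbidden_cols or set()
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        w = P[i].copy()
        w[list(forbidden)] = 0.0
        A[i, rng.choice(len(w), p=w / w.sum())] = 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        if j in forbidden:
            continue
        w = P[:, j]
        A[rng.choice(len(w), p=w / w.sum()), j] = 1


def _plant_idiosyncratic(A, P, n_idio: int, rng) -> set[int]:
    """Prune the lowest-degree columns to exactly one link each."""
    if n_idio == 0:
        return set()
    deg = A.sum(axis=0)
    order = np.lexsort((rng.random(len(deg)), deg))  # ascending degree, random ties
    chosen = set(int(j) for j in order[:n_idio])
    free = np.ones(A.shape[1], dtype=bool)
    free[list(chosen)] = False
    for j in chosen:
        rows = np.flatnonzero(A[:, j])
        if len(rows) == 0:
            A[int(rng.choice(len(P), p=P[:, j] / P[:, j].sum())), j] = 1
            continue
        # keep the link whose shift is best connected (nested: idiosyncratic
        # drivers attach to generalist shifts)
        row_deg = A.sum(axis=1)
        keep = rows[int(np.argmax(row_deg[rows] + 0.1 * rng.random(len(rows))))]
        for r in rows:
            if r == keep:
                continue
            if A[r].sum() == 1:  # would empty the shift: relink it first
                w = P[r] * (1 - A[r]) * free
                if w.sum() > 0:
                    A[r, rng.choice(len(w), p=w / w.sum())] = 1
                else:  # nowhere to relink; keep this link instead
                    if A[keep].sum() > 1:
                        A[keep, j] = 0
                        keep = r
                    continue
            A[r, j] = 0
    return chosen


def _fix_stray_degree_one(A, P, idio: set[int], rng) -> None:
    """Lift non-planted degree-1 columns to degree >= 2."""
    for j in np.flatnonzero(A.sum(axis=0) == 1):
        if int(j) in idio:
            continue
        w = P[:, j] * (1 - A[:, j])
        if w.sum() == 0:
            continue
        A[rng.choice(len(w), p=w / w.sum()), j] = 1


def _balance_links(A, P, target: int, idio: set[int], rng) -> None:
    """Add/remove links in non-idiosyncratic columns to hit the exact total."""
    free = np.ones(A.shape[1], dtype=bool)
    free[list(idio)] = False
    guard = 10 * A.size
    while int(A.sum()) != target and guard > 0:
        guard -= 1
        if int(A.sum()) < target:
            w = (P * (1 - A)) * free[None, :]
            flat = w.ravel()
            if flat.sum() == 0:
                raise InfeasibleMarginsError("no room to add links outside idiosyncratic columns")
            k = rng.choice(A.size, p=flat / flat.sum())
            A[np.unravel_index(k, A.shape)] = 1
        else:
            col_deg, row_deg = A.sum(axis=0), A.sum(axis=1)
            removable = (
                (A == 1)
                & free[None, :]
                & (col_deg >= 3)[None, :]
                & (row_deg >= 2)[:, None]
            )
            flat = ((1 - P) + 1e-9) * removable
            flat = flat.ravel()
            if flat.sum() == 0:
                raise InfeasibleMarginsError("cannot remove links without violating constraints")
            k = rng.choice(A.size, p=flat / flat.sum())
            A[np.unravel_index(k, A.shape)] = 0
    if guard == 0:
        raise InfeasibleMarginsError("link balancing did not converge")


def structural_scale_anchors(network: BipartiteNetwork) -> np.ndarray:
    """Deterministic scale anchors aligned with co-occurrence structure.

    The top third of drivers by degree anchor to ``international``
    (globally shared pressures are generalists); the remaining specialists
    split into two co-occurrence communities by the sign of the second
    eigenvector of the degree-normalized driver projection, anchoring to
    ``local`` and ``regional_national``.  Orientation is fixed so the
    community containing the lexically smallest specialist is ``local``.
    """
    from .netstats import project_one_mode

    n = network.n_drivers
    names = np.asarray(network.driver_names, dtype=object)
    deg = network.driver_degrees
    order = np.lexsort((names, -deg))
    generalists = set(order[: int(np.ceil(n / 3))].tolist())
    specialists = [j for j in range(n) if j not in generalists]
    anchor = np.empty(n, dtype=object)
    for j in generalists:
        anchor[j] = "international"
    if len(specialists) < 2:
        for j in specialists:
            anchor[j] = "local"
        return anchor
    W = project_one_mode(network, "driver").weights.astype(float)
    W = W[np.ix_(specialists, specialists)]
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    scale = 1.0 / np.sqrt(d)
    vals, vecs = np.linalg.eigh(scale[:, None] * W * scale[None, :])
    v = vecs[:, -2] if W.shape[0] > 1 else np.ones(len(specialists))
    side = v >= 0
    if not side[int(np.argmin(names[specialists]))]:
        side = ~side
    for t, j in enumerate(specialists):
        anchor[j] = "local" if side[t] else "regional_national"
    return anchor


def plant_attribute_homophily(
    network: BipartiteNetwork,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> AttributeTable:
    """Assign management-scale labels with tunable projection homophily.

    Each driver's anchor label comes from
    :func:`structural_scale_anchors`; the anchor is kept with probability
    ``homophily_strength`` and replaced by a uniform draw otherwise.  At
    strength 0 labels are independent of the network; at strength 1 they
    are a deterministic function of the network alone.
    """
    rng = _rng(config, rng)
    n = network.n_drivers
    anchor = structural_scale_anchors(network)
    keep = rng.random(n) < config.homophily_strength
    uniform = rng.choice(MANAGEMENT_SCALES, size=n)
    labels = np.where(keep, anchor, uniform)
    df = pd.DataFrame(
        {
            "node": network.driver_names,
            "side": "driver",
            "management_scale": labels,
        }
    )
    return AttributeTable(df)


def _category_scheme(driver_names: list[str], rng: np.random.Generator) -> CategoryScheme:
    detailed = [d for group in CATEGORY_TREE.values() for d in group]
    broad = list(CATEGORY_TREE)
    det_to_broad = {d: b for b, group in CATEGORY_TREE.items() for d in group}
    assignment = rng.choice(len(detailed), size=len(driver_names))
    membership = pd.DataFrame(
        np.eye(len(detailed), dtype=int)[assignment],
        index=driver_names,
        columns=detailed,
    )
    return CategoryScheme(detailed, broad, det_to_broad, membership)


def _shift_attributes(
    shift_names: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    n = len(shift_names)
    # ecosystem classes in database proportions (13 aquatic / 7 terrestrial /
    # 5 subcontinental out of 25), scaled to n and shuffled
    counts = np.array([13, 7, 5])
    alloc = np.floor(counts / 25 * n).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmax(counts / 25 * n - alloc))] += 1
    eco = np.repeat(ECOSYSTEM_CLASSES, alloc)
    rng.shuffle(eco)
    df = pd.DataFrame({"node": shift_names, "side": "shift", "ecosystem_type": eco})
    for block, size in SHIFT_BLOCK_SIZES.items():
        B = (rng.random((n, size)) < 0.4).astype(int)
        for col in range(size):  # keep every variable informative
            if B[:, col].sum() == 0:
                B[rng.integers(n), col] = 1
        for row in range(n):  # every shift records something in each block
            if B[row].sum() == 0:
                B[row, rng.integers(size)] = 1
        for col in range(size):
            df[f"{block}_{col+1:02d}"] = B[:, col]
    return df


def shift_block_columns() -> dict[str, list[str]]:
    """Column names of each categorical-variable block, keyed by block."""
    return {
        block: [f"{block}_{k+1:02d}" for k in range(size)]
        for block, size in SHIFT_BLOCK_SIZES.items()
    }


def generate_rsdb_like(
    seed: int, config: SyntheticConfig | None = None
) -> tuple[BipartiteNetwork, AttributeTable, CategoryScheme]:
    """A full synthetic dataset at database scale.

    25 shifts x 57 drivers, mean shift degree 11.2, 14 idiosyncratic
    drivers, nested structure, management scales with planted homophily,
    directedness, 15 mutually exclusive detailed categories in 5 broad
    ones, shift ecosystem types and binary variable blocks.
    """
    config = SyntheticConfig(seed=seed) if config is None else config
    rng = np.random.default_rng(seed)
    net = generate_nested_bipartite(config, rng)
    scales = plant_attribute_homophily(net, config, rng)
    scheme = _category_scheme(net.driver_names, rng)
    steps = rng.choice([0, 1, 2], size=net.n_drivers, p=[0.45, 0.35, 0.2])
    drivers = scales.df.assign(
        steps_to_feedback=steps,
        directedness=np.where(steps == 0, "direct", "indirect"),
        detailed_category=scheme.membership.idxmax(axis=1).to_numpy(),
    )
    drivers["broad_category"] = drivers["detailed_category"].map(scheme.detailed_to_broad)
    shifts = _shift_attributes(net.shift_names, rng)
    attrs = AttributeTable(pd.concat([drivers, shifts], ignore_index=True))
    return net, attrs, scheme
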