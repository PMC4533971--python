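"""Driver categorization, management-scale aggregation, and homophily tests.

Drivers belong to one of 15 mutually exclusive detailed global-change
categories grouped into 5 broad ones; multiplying the incidence matrix by
the membership matrix yields the number of drivers of each category behind
each regime shift.  Every driver is also classified by the broadest scale
at which management action can counteract it (local, regional/national,
international); per-shift proportions of those scales summarize where
action is possible.  Whether drivers sharing an attribute co-occur more
than chance is assessed with a label-permutation test on the weighted
one-mode projection, a verifiably calibrated stand-in for model-based
homophily terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingAttributeError, UndefinedStatisticError
from .netstats import Projection, truncated_pct
from .rsdb import (
    MANAGEMENT_SCALES,
    AttributeTable,
    BipartiteNetwork,
    CategoryScheme,
)


@dataclass
class HomophilyResult:
    label_name: str
    observed_within_share: float
    permutation_p: float
    n_perm: int
    direction: str = "greater"
    null_mean: float = float("nan")


def category_counts(
    network: BipartiteNetwork, scheme: CategoryScheme, level: str = "detailed"
) -> pd.DataFrame:
    """Drivers per regime shift in each category (incidence x membership).

    Row sums equal the bipartite degree of each shift because every driver
    belongs to exactly one detailed category.
    """
    if level not in ("detailed", "broad"):
        raise ValueError("level must be 'detailed' or 'broad'")
    missing = [d for d in network.driver_names if d not in scheme.membership.index]
    if missing:
        raise MissingAttributeError(
            f"drivers missing from category scheme: {missing}"
        )
    membership = (
        scheme.membership if level == "detailed" else scheme.broad_membership()
    ).loc[network.driver_names]
    counts = network.incidence @ membership.to_numpy()
    return pd.DataFrame(
        counts, index=pd.Index(network.shift_names, name="shift"),
        columns=membership.columns,
    )


def management_scale_proportions(
    network: BipartiteNetwork, attrs: AttributeTable
) -> pd.DataFrame:
    """Per-shift proportion of drivers manageable at each scale.

    Rows sum to 1; shifts are ordered by ecosystem type (when present) and
    then by name, the ordering used for the managerial-opportunities
    display.
    """
    scales = attrs.attribute("management_scale", "driver")
    missing = [d for d in network.driver_names if d not in scales.index or pd.isna(scales[d])]
    if missing:
        raise MissingAttributeError(f"drivers without management scale: {missing}")
    bad = set(scales.dropna()) - set(MANAGEMENT_SCALES)
    if bad:
        raise MissingAttributeError(f"unknown management scales: {sorted(bad)}")
    onehot = pd.get_dummies(scales.loc[network.driver_names]).reindex(
        columns=list(MANAGEMENT_SCALES), fill_value=0
    )
    counts = network.incidence @ onehot.to_numpy()
    props = counts / counts.sum(axis=1, keepdims=True)
    out = pd.DataFrame(
        props, index=pd.Index(network.shift_names, name="shift"),
        columns=list(MANAGEMENT_SCALES),
    )
    shift_attrs = attrs.for_side("shift")
    for eco_col in ("ecosystem_class", "ecosystem_type"):
        if eco_col in shift_attrs.columns:
            eco = shift_attrs.reindex(out.index)[eco_col].to_numpy(dtype=object)
            names = out.index.to_numpy(dtype=object)
            return out.iloc[np.lexsort((names, eco))]
    return out.sort_index()


def global_scale_shares(attrs: AttributeTable) -> pd.DataFrame:
    """Share of all classified drivers per management scale.

    Returns exact fractions and integer-truncated percentages, plus the
    combined sub-international (local + regional/national) share.
    """
    scales = attrs.attribute("management_scale", "driver").dropna()
    if len(scales) == 0:
        raise MissingAttributeError("no scale-classified drivers")
    counts = scales.value_counts().reindex(list(MANAGEMENT_SCALES), fill_value=0)
    n = int(counts.sum())
    rows = [
        {
            "scale": scale,
            "n_drivers": int(k),
            "fraction": k / n,
            "pct_truncated": truncated_pct(int(k), n),
        }
        for scale, k in counts.items()
    ]
    sub = int(counts["local"] + counts["regional_national"])
    rows.append(
        {
            "scale": "local_or_regional_national",
            "n_drivers": sub,
            "fraction": sub / n,
            "pct_truncated": truncated_pct(sub, n),
        }
    )
    return pd.DataFrame(rows)


def attribute_homophily_test(
    projection: Projection,
    labels: pd.Series | dict,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    label_name: str = "label",
) -> HomophilyResult:
    """Label-permutation test for attribute homophily on a weighted projection.

    The statistic is the share of total projection weight on same-label
    pairs; the null permutes labels across nodes.  One-sided (greater),
    add-one p-value convention.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng() if rng is None else rng
    labels = pd.Series(labels)
    missing = [n for n in projection.node_names if n not in labels.index]
    if missing:
        raise MissingAttributeError(f"nodes without labels: {missing}")
    lab = labels.loc[projection.node_names].to_numpy()
    uniq, codes = np.unique(lab, return_inverse=True)
    if len(uniq) < 2:
        raise UndefinedStatisticError(
            "homophily needs >= 2 distinct labels (within-share is trivially 1)"
        )
    W = projection.weights.astype(float)
    total = W.sum()
    if total == 0:
        raise UndefinedStatisticError("projection has no positive weights")

    def within_share(c: np.ndarray) -> float:
        onehot = np.eye(len(uniq))[c]
        return float(np.einsum("ig,ij,jg->", onehot, W, onehot) - 0.0) / total

    obs = within_share(codes)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        perm_stats[b] = within_share(rng.permutation(codes))
    p = (1 + int((perm_stats >= obs).sum())) / (n_perm + 1)
    return HomophilyResult(
        label_name=label_name,
        observed_within_share=obs,
        permutation_p=p,
        n_perm=n_perm,
        null_mean=float(perm_stats.mean()),
    )
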