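"""One-command orchestration of the full comparative network analysis.

Stages run in order: load/canonicalize -> observed network statistics ->
fixed-margin null comparison -> attribute aggregation and homophily ->
distance-based clustering and ordination.  Every stochastic stage draws
its generator from the master seed and the stage name, so toggling one
stage never shifts another stage's randomness, and identical
configurations produce byte-identical result bundles.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import attributes as attr_mod
from . import netstats, nulls, ordination, rsdb, synth
from .errors import StageError

log = logging.getLogger("rsnet")

STAGES = ("stats", "null", "attributes", "ordination")


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``source`` is one of ``fixture`` (the packaged 25x3 worked example),
    ``synthetic`` (database-scale generated data) or ``files`` (user edge
    list / attribute tables).  Defaults mirror the reference analysis:
    10,000 null networks, 999 permutations, significance filter at 0.05,
    shared-pair threshold 10.
    """

    seed: int
    source: str = "fixture"
    edge_list: str | None = None
    attribute_table: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    apply_synonyms: bool = True
    n_null_samples: int = 10_000
    n_perm: int = 999
    sampler: str = "curveball"
    shared_pair_threshold: int = 10
    mds_axes: int = 2
    alpha: float = 0.05
    stages: tuple[str, ...] = STAGES
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("fixture", "synthetic", "files"):
            raise ValueError(f"unknown source {self.source!r}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.source == "files" and not self.edge_list:
            raise ValueError("source='files' requires edge_list")

    def as_manifest_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream per stage: master seed + stable hash of the name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def _load(config: RunConfig):
    scheme = None
    attrs = None
    if config.source == "fixture":
        net, attrs = rsdb.load_table1_fixture()
        if config.apply_synonyms:
            net, merge_log = rsdb.canonicalize_driver_names(net, rsdb.table1_synonym_map())
        else:
            merge_log = pd.DataFrame()
    elif config.source == "synthetic":
        cfg = config.synthetic or synth.SyntheticConfig(seed=config.seed)
        net, attrs, scheme = synth.generate_rsdb_like(cfg.seed, cfg)
        merge_log = pd.DataFrame()
    else:
        net = rsdb.read_bipartite_edge_list(config.edge_list)
        if config.attribute_table:
            attrs = rsdb.AttributeTable(pd.read_csv(config.attribute_table))
        merge_log = pd.DataFrame()
    return net, attrs, scheme, merge_log


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the configured stages and (optionally) write a results bundle.

    Returns the in-memory results dictionary; whatever completed before a
    stage failure is still written to ``config.output_dir``.
    """
    results: dict[str, object] = {}
    notes: dict[str, str] = {}
    completed: list[str] = []
    try:
        net, attrs, scheme, merge_log = _load(config)
        results["edge_list"] = net.to_edge_list()
        if len(merge_log):
            results["synonym_merge_log"] = merge_log
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s", stage)
            try:
                if stage == "stats":
                    _stage_stats(net, config, results)
                elif stage == "null":
                    _stage_null(net, config, results)
                elif stage == "attributes":
                    _stage_attributes(net, attrs, scheme, config, results, notes)
                elif stage == "ordination":
                    _stage_ordination(net, attrs, config, results, notes)
            except Exception as exc:  # annotate with the stage name
                raise StageError(f"stage '{stage}' failed: {exc}") from exc
            completed.append(stage)
    finally:
        if config.output_dir is not None:
            notes["completed_stages"] = ",".join(completed)
            rsdb.write_results_bundle(
                results,
                config.output_dir,
                seed=config.seed,
                config=config.as_manifest_dict(),
                notes=notes,
            )
    return results


def _stage_stats(net, config, results) -> None:
    summary = netstats.network_summary(net)
    results["network_summary"] = pd.DataFrame([vars(summary)]).drop(
        columns=[], errors="ignore"
    )
    ds = netstats.driver_summary(net)
    results["driver_degrees"] = ds.driver_degrees.rename("degree").rename_axis(
        "driver"
    ).reset_index()
    results["driver_summary"] = {
        "n_shifts": ds.n_shifts,
        "n_drivers": ds.n_drivers,
        "n_links": ds.n_links,
        "idiosyncratic_drivers": ds.idiosyncratic_drivers,
        "idiosyncratic_pct": ds.idiosyncratic_pct,
        "half_coverage_drivers": ds.half_coverage_drivers,
        "half_coverage_pct": ds.half_coverage_pct,
        "shift_degree_min": list(ds.shift_degree_min),
        "shift_degree_max": list(ds.shift_degree_max),
    }
    results["shared_driver_pairs"] = netstats.shared_driver_pairs(
        net, "driver", config.shared_pair_threshold
    )
    nodf = netstats.nodf_nestedness(net)
    results["nodf_contributions"] = pd.concat(
        [
            nodf.row_contributions.rename("contribution").rename_axis("node").reset_index().assign(side="shift"),
            nodf.col_contributions.rename("contribution").rename_axis("node").reset_index().assign(side="driver"),
        ],
        ignore_index=True,
    ).sort_values(["side", "node"]).reset_index(drop=True)


def _stage_null(net, config, results) -> None:
    rng = stage_rng(config.seed, "null")
    ensemble = nulls.build_null_ensemble(
        net, config.n_null_samples, rng, sampler=config.sampler
    )
    comparisons = nulls.compare_to_null(netstats.network_summary(net), ensemble)
    results["null_statistics"] = ensemble.statistics
    results["null_comparisons"] = nulls.comparisons_table(comparisons)


def _stage_attributes(net, attrs, scheme, config, results, notes) -> None:
    if attrs is None:
        notes["attributes"] = "no attribute table available; stage skipped"
        return
    driver_attrs = attrs.for_side("driver") if (attrs.df["side"] == "driver").any() else pd.DataFrame()
    if scheme is not None:
        results["category_counts_detailed"] = category = attr_mod.category_counts(
            net, scheme, "detailed"
        )
        results["category_counts_broad"] = attr_mod.category_counts(net, scheme, "broad")
    if "management_scale" in driver_attrs.columns:
        results["scale_proportions"] = attr_mod.management_scale_proportions(net, attrs)
        results["global_scale_shares"] = attr_mod.global_scale_shares(attrs)
        rng = stage_rng(config.seed, "attributes")
        proj = netstats.project_one_mode(net, "driver")
        res = attr_mod.attribute_homophily_test(
            proj,
            driver_attrs["management_scale"],
            n_perm=config.n_perm,
            rng=rng,
            label_name="management_scale",
        )
        results["homophily"] = pd.DataFrame([
            {k: (v if not isinstance(v, np.ndarray) else list(v)) for k, v in vars(res).items()}
        ])
    else:
        notes["attributes"] = "management_scale unavailable; scale analyses skipped"


def _stage_ordination(net, attrs, config, results, notes) -> None:
    rng = stage_rng(config.seed, "ordination")
    d_shift = ordination.pairwise_distance(net, "shift", "sorensen_dice")
    d_driver = ordination.pairwise_distance(net, "driver", "jaccard")
    results["shift_distances"] = d_shift.to_dataframe().rename_axis("shift")
    results["driver_distances"] = d_driver.to_dataframe().rename_axis("driver")
    results["shift_dendrogram"] = ordination.upgma_cluster(d_shift).to_newick()
    results["driver_dendrogram"] = ordination.upgma_cluster(d_driver).to_newick()
    ordn = ordination.classical_mds(d_shift, k=config.mds_axes)
    results["mds_coordinates"] = ordn.to_dataframe().rename_axis("shift")
    variables = _ordination_variables(attrs)
    if variables is not None and variables.shape[1] > 0:
        fitted = ordination.fit_variables(ordn, variables, n_perm=config.n_perm, rng=rng)
        results["fitted_variables"] = ordination.fitted_table(fitted)
        results["fitted_variables_significant"] = ordination.fitted_table(
            ordination.significant_variables(fitted, config.alpha)
        )
    else:
        notes["ordination"] = "no shift variables to fit onto the ordination"


def _ordination_variables(attrs) -> pd.DataFrame | None:
    """One-hot ecosystem class plus any binary block variables, for fitting."""
    if attrs is None:
        return None
    shift_attrs = attrs.for_side("shift")
    pieces = []
    for eco_col in ("ecosystem_class", "ecosystem_type"):
        if eco_col in shift_attrs.columns:
            pieces.append(pd.get_dummies(shift_attrs[eco_col], prefix=eco_col).astype(float))
            break
    block_cols = [
        c for cols in synth.shift_block_columns().values() for c in cols
        if c in shift_attrs.columns
    ]
    if block_cols:
        pieces.append(shift_attrs[block_cols].astype(float))
    if not pieces:
        return None
    return pd.concat(pieces, axis=1)


def write_synthetic_dataset(seed: int, outdir: str | Path,
                            config: synth.SyntheticConfig | None = None) -> dict:
    """Generate a database-scale synthetic dataset and write it as CSVs."""
    net, attrs, scheme = synth.generate_rsdb_like(
        seed, config or synth.SyntheticConfig(seed=seed)
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rsdb.write_edge_list(net, outdir / "edges.csv")
    attrs.df.to_csv(outdir / "attributes.csv", index=False)
    scheme.membership.rename_axis("driver").to_csv(outdir / "category_membership.csv")
    pd.Series(scheme.detailed_to_broad, name="broad").rename_axis("detailed").to_csv(
        outdir / "category_tree.csv"
    )
    return {"outdir": str(outdir), "n_shifts": net.n_shifts, "n_drivers": net.n_drivers,
            "n_links": net.n_links}
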