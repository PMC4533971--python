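"""Reading, writing and canonicalizing regime shift-driver network data.

The central object is :class:`BipartiteNetwork`, a binary incidence matrix
whose rows are regime shifts and whose columns are drivers, with a link
wherever the literature reports a causal influence of the driver on the
shift.  Edge lists arrive as CSV/TSV with ``shift`` and ``driver`` columns
(an optional ``reference`` column carries per-link citations).  A packaged
fixture transcribes the summary table of 25 generic regime shifts with three
selected drivers each, together with a curated synonym map (case folding,
spelling variants, ENSO/NSO) that is applied only on request so the raw
transcription stays auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, SynonymMapError

MANAGEMENT_SCALES = ("local", "regional_national", "international")


@dataclass
class BipartiteNetwork:
    """Binary regime shift x driver incidence matrix with node labels.

    Rows are regime shifts, columns are drivers.  Entries are 0/1; duplicate
    reports of the same (shift, driver) pair collapse to a single link.
    """

    shift_names: list[str]
    driver_names: list[str]
    incidence: np.ndarray
    provenance: dict[tuple[str, str], str] | None = None

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.int8)
        if self.incidence.ndim != 2:
            raise FormatError("incidence must be a 2-D matrix")
        m, n = self.incidence.shape
        if m != len(self.shift_names) or n != len(self.driver_names):
            raise FormatError(
                f"label counts ({len(self.shift_names)}, {len(self.driver_names)}) "
                f"do not match matrix shape {self.incidence.shape}"
            )
        if len(set(self.shift_names)) != m or len(set(self.driver_names)) != n:
            raise FormatError("node names must be unique within each side")
        vals = np.unique(self.incidence)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("incidence entries must be 0 or 1")

    # -- basic accessors -------------------------------------------------
    @property
    def n_shifts(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_drivers(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_links(self) -> int:
        return int(self.incidence.sum())

    @property
    def shift_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    @property
    def driver_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    def names(self, side: str) -> list[str]:
        _check_side(side)
        return self.driver_names if side == "driver" else self.shift_names

    def neighbor_sets(self, side: str) -> dict[str, frozenset[str]]:
        """Neighbour sets of each node on ``side`` (labels of the other side)."""
        _check_side(side)
        if side == "driver":
            mat, names, other = self.incidence.T, self.driver_names, self.shift_names
        else:
            mat, names, other = self.incidence, self.shift_names, self.driver_names
        other = np.asarray(other, dtype=object)
        return {
            name: frozenset(other[row.astype(bool)]) for name, row in zip(names, mat)
        }

    def empty_nodes(self) -> dict[str, list[str]]:
        """All-zero rows/columns, reported rather than silently accepted."""
        return {
            "shift": [s for s, d in zip(self.shift_names, self.shift_degrees) if d == 0],
            "driver": [t for t, d in zip(self.driver_names, self.driver_degrees) if d == 0],
        }

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.shift_names):
            for j, t in enumerate(self.driver_names):
                if self.incidence[i, j]:
                    ref = (self.provenance or {}).get((s, t), "")
                    rows.append((s, t, ref))
        return pd.DataFrame(rows, columns=["shift", "driver", "reference"])

    def copy(self) -> "BipartiteNetwork":
        return BipartiteNetwork(
            list(self.shift_names),
            list(self.driver_names),
            self.incidence.copy(),
            dict(self.provenance) if self.provenance else None,
        )


@dataclass
class AttributeTable:
    """Per-node categorical/numeric covariates for both sides of the network.

    Backed by a DataFrame with ``node`` and ``side`` columns plus one column
    per attribute; attributes that do not apply to a side are NaN there.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("node", "side"):
            if col not in self.df.columns:
                raise FormatError(f"attribute table lacks required column '{col}'")
        bad = set(self.df["side"]) - {"driver", "shift"}
        if bad:
            raise FormatError(f"unknown side values: {sorted(bad)}")
        if self.df.duplicated(subset=["node", "side"]).any():
            raise FormatError("duplicate (node, side) rows in attribute table")

    def for_side(self, side: str) -> pd.DataFrame:
        _check_side(side)
        sub = self.df[self.df["side"] == side].set_index("node")
        return sub.drop(columns=["side"]).dropna(axis=1, how="all")

    def attribute(self, name: str, side: str) -> pd.Series:
        sub = self.for_side(side)
        if name not in sub.columns:
            raise KeyError(f"attribute '{name}' absent for side '{side}'")
        return sub[name]

    def missing_nodes(self, network: BipartiteNetwork) -> dict[str, list[str]]:
        """Network nodes without an attribute row, per side."""
        out = {}
        for side, names in (("shift", network.shift_names), ("driver", network.driver_names)):
            have = set(self.df.loc[self.df["side"] == side, "node"])
            out[side] = [n for n in names if n not in have]
        return out


@dataclass
class CategoryScheme:
    """Mutually exclusive detailed driver categories nested in broad ones."""

    detailed_names: list[str]
    broad_names: list[str]
    detailed_to_broad: dict[str, str]
    membership: pd.DataFrame = field(repr=False)  # drivers x detailed, 0/1

    def __post_init__(self) -> None:
        if set(self.detailed_to_broad) != set(self.detailed_names):
            raise FormatError("detailed_to_broad must cover every detailed category")
        if not set(self.detailed_to_broad.values()) <= set(self.broad_names):
            raise FormatError("detailed_to_broad maps to unknown broad categories")
        if list(self.membership.columns) != list(self.detailed_names):
            raise FormatError("membership columns must equal detailed_names")
        sums = self.membership.sum(axis=1)
        if not (sums == 1).all():
            bad = list(self.membership.index[sums != 1])
            raise FormatError(f"membership rows must sum to 1; offending drivers: {bad}")

    def broad_membership(self) -> pd.DataFrame:
        agg = pd.DataFrame(
            0, index=self.detailed_names, columns=self.broad_names, dtype=int
        )
        for det, broad in self.detailed_to_broad.items():
            agg.loc[det, broad] = 1
        return self.membership @ agg


def _check_side(side: str) -> None:
    if side not in ("driver", "shift"):
        raise ValueError(f"side must be 'driver' or 'shift', got {side!r}")


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_bipartite_edge_list(path: str | Path) -> BipartiteNetwork:
    """Read a (shift, driver[, reference]) record file into a network.

    Duplicate records collapse to a single link.  Node order is the order of
    first appearance in the file, which makes loading deterministic.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"shift", "driver"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no edge records")
    return network_from_edges(
        df["shift"], df["driver"],
        df["reference"] if "reference" in df.columns else None,
    )


def network_from_edges(
    shifts: Iterable[str],
    drivers: Iterable[str],
    references: Iterable[str] | None = None,
) -> BipartiteNetwork:
    shifts = list(shifts)
    drivers = list(drivers)
    shift_names = list(pd.unique(pd.array(shifts)))
    driver_names = list(pd.unique(pd.array(drivers)))
    si = {s: i for i, s in enumerate(shift_names)}
    dj = {d: j for j, d in enumerate(driver_names)}
    inc = np.zeros((len(shift_names), len(driver_names)), dtype=np.int8)
    prov: dict[tuple[str, str], str] = {}
    refs = list(references) if references is not None else None
    for k, (s, d) in enumerate(zip(shifts, drivers)):
        inc[si[s], dj[d]] = 1
        if refs is not None and refs[k]:
            prov[(s, d)] = refs[k]
    return BipartiteNetwork(shift_names, driver_names, inc, prov or None)


def write_edge_list(network: BipartiteNetwork, path: str | Path) -> None:
    df = network.to_edge_list()
    if network.provenance is None:
        df = df.drop(columns=["reference"])
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# driver-name canonicalization
# ---------------------------------------------------------------------------

def canonicalize_driver_names(
    network: BipartiteNetwork, synonym_map: Mapping[str, str]
) -> tuple[BipartiteNetwork, pd.DataFrame]:
    """Merge driver columns that share a canonical name (logical OR).

    ``synonym_map`` maps raw labels to canonical ones; unmapped labels pass
    through unchanged.  Chained maps (a value that is itself remapped to a
    different target) are rejected.  Returns the merged network and a merge
    log with one row per canonical driver that absorbed at least two columns.
    """
    for raw, canon in synonym_map.items():
        if canon in synonym_map and synonym_map[canon] != canon:
            raise SynonymMapError(
                f"chained/cyclic synonym map: {raw!r} -> {canon!r} -> {synonym_map[canon]!r}"
            )
    canonical = [synonym_map.get(d, d) for d in network.driver_names]
    order: list[str] = list(pd.unique(pd.array(canonical)))
    cols = {name: np.zeros(network.n_shifts, dtype=np.int8) for name in order}
    members: dict[str, list[str]] = {name: [] for name in order}
    for j, (raw, canon) in enumerate(zip(network.driver_names, canonical)):
        cols[canon] |= network.incidence[:, j].astype(np.int8)
        members[canon].append(raw)
    inc = np.column_stack([cols[name] for name in order]).astype(np.int8)
    merged = BipartiteNetwork(list(network.shift_names), order, inc)
    log_rows = [
        {
            "canonical": name,
            "merged_from": "|".join(members[name]),
            "n_merged": len(members[name]),
            "links_after": int(inc[:, k].sum()),
        }
        for k, name in enumerate(order)
        if len(members[name]) > 1
    ]
    log = pd.DataFrame(log_rows, columns=["canonical", "merged_from", "n_merged", "links_after"])
    return merged, log


# ---------------------------------------------------------------------------
# packaged fixture (25 regime shifts x 3 selected drivers each)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("rsnet.data").joinpath(name)


def load_table1_fixture() -> tuple[BipartiteNetwork, AttributeTable]:
    """The packaged worked example: 25 regime shifts, 3 selected drivers each.

    Driver labels are kept exactly as transcribed (including case and
    spelling variants); apply :func:`table1_synonym_map` via
    :func:`canonicalize_driver_names` to merge them.  The attribute table
    carries the ecosystem type of each shift plus a coarse
    aquatic/terrestrial/subcontinental class.  This is a strict subnetwork of
    the full database (which has ~57 drivers and mean degree ~11.2), so it is
    a worked example, not the full dataset.
    """
    with _data_path("table1_edges.csv").open("r", encoding="utf-8") as fh:
        edges = pd.read_csv(fh, dtype=str)
    net = network_from_edges(edges["shift"], edges["driver"])
    with _data_path("table1_shifts.csv").open("r", encoding="utf-8") as fh:
        shifts = pd.read_csv(fh, dtype=str)
    attrs = AttributeTable(
        shifts.rename(columns={"shift": "node"}).assign(side="shift")[
            ["node", "side", "ecosystem_type", "ecosystem_class"]
        ]
    )
    return net, attrs


def table1_synonym_map() -> dict[str, str]:
    """Curated synonym map for the fixture (case folding, spelling, ENSO/NSO)."""
    with _data_path("table1_synonyms.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    return dict(zip(df["raw"], df["canonical"]))


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

def write_results_bundle(
    results: Mapping[str, object],
    outdir: str | Path,
    *,
    seed: int | None = None,
    config: Mapping[str, object] | None = None,
    notes: Mapping[str, str] | None = None,
) -> dict:
    """Write analysis outputs under ``outdir`` and return the manifest.

    DataFrames become TSV, strings ending in ';' become newick files, dicts
    become JSON.  The manifest records the seed, the configuration and the
    package version but no timestamps, so identical runs produce
    byte-identical bundles.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(outdir / fname, sep="\t", index=bool(obj.index.name),
                       float_format="%.12g")
        elif isinstance(obj, str) and obj.rstrip().endswith(";"):
            fname = f"{name}.nwk"
            (outdir / fname).write_text(obj, encoding="utf-8")
        elif isinstance(obj, (dict, list)):
            fname = f"{name}.json"
            (outdir / fname).write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=_jsonable),
                encoding="utf-8",
            )
        elif isinstance(obj, str):
            fname = f"{name}.txt"
            (outdir / fname).write_text(obj, encoding="utf-8")
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(obj)}")
        files[name] = fname
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config else {},
        "notes": dict(notes) if notes else {},
        "files": files,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable),
        encoding="utf-8",
    )
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_bundle`."""
    return pd.read_csv(path, sep="\t")
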