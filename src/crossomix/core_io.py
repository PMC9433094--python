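"""Domain types and I/O for count matrices, designs, gene sets, networks and config.

All readers validate and reject invalid input rather than coercing it; every
writer/reader pair round-trips losslessly. Networks are persisted as GraphML
(primary) or as a node-table + edge-list TSV pair (alternative). Node identity
in persisted networks is ``layer::feature_id`` so the same gene may appear in
both omic layers.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

DESIGN_COLUMNS = ("sample_id", "cell_line", "treatment", "time", "replicate")
LAYERS = ("rna", "atac")

NAMESPACE_SEP = "::"


class CrossomixError(ValueError):
    """Raised for invalid inputs or violated invariants."""


def namespaced(layer: str, feature: str) -> str:
    return f"{layer}{NAMESPACE_SEP}{feature}"


def split_namespace(node: str) -> tuple[str, str]:
    """Split a ``layer::feature`` node id into its layer and feature name."""
    layer, sep, feat = node.partition(NAMESPACE_SEP)
    if not sep:
        raise CrossomixError(f"node {node!r} is not layer-namespaced")
    return layer, feat


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Sample sheet: one row per sequencing sample.

    Columns: ``sample_id``, ``cell_line``, ``treatment``, ``time``,
    ``replicate`` (integer >= 1). Condition groups are keyed as
    ``cell_line|treatment|time``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise CrossomixError(f"design missing columns: {missing}")
        tab = self.table.reset_index(drop=True).copy()
        tab["sample_id"] = tab["sample_id"].astype(str)
        if tab["sample_id"].duplicated().any():
            dups = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
            raise CrossomixError(f"duplicate sample_id: {dups}")
        rep = pd.to_numeric(tab["replicate"], errors="coerce")
        if rep.isna().any() or (rep != rep.astype(int)).any() or (rep < 1).any():
            raise CrossomixError("replicate must be an integer >= 1")
        tab["replicate"] = rep.astype(int)
        self.table = tab

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_labels(self) -> pd.Series:
        """Condition-group key per sample, indexed by sample_id."""
        t = self.table
        lab = (
            t["cell_line"].astype(str)
            + "|"
            + t["treatment"].astype(str)
            + "|"
            + t["time"].astype(str)
        )
        return pd.Series(lab.values, index=t["sample_id"].values, name="group")

    def groups(self) -> dict[str, list[str]]:
        """Mapping group key -> ordered list of member sample_ids."""
        lab = self.group_labels()
        out: dict[str, list[str]] = {}
        for sid, g in lab.items():
            out.setdefault(g, []).append(sid)
        return out

    def subset(self, **conditions: str | Iterable[str]) -> "SampleDesign":
        """Restrict to rows matching the given column values.

        ``design.subset(cell_line="BxPC-3", treatment=["ctrl", "M"])``
        """
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            if col not in self.table.columns:
                raise CrossomixError(f"unknown design column {col!r}")
            if isinstance(val, str):
                mask &= self.table[col].astype(str) == val
            else:
                mask &= self.table[col].astype(str).isin([str(v) for v in val])
        sub = self.table[mask]
        if sub.empty:
            raise CrossomixError(f"empty design subset for {conditions}")
        return SampleDesign(sub)

    def __len__(self) -> int:
        return len(self.table)


def read_design(path: str | Path) -> SampleDesign:
    path = Path(path)
    if not path.exists():
        raise CrossomixError(f"design file not found: {path}")
    table = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw integer counts, features x samples, tagged with its omic layer."""

    counts: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise CrossomixError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise CrossomixError(f"duplicate feature ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise CrossomixError("non-numeric entries in count matrix")
        if np.isnan(vals.astype(float)).any():
            raise CrossomixError("missing values in count matrix")
        if (vals < 0).any():
            raise CrossomixError("negative count in matrix")
        if not np.allclose(vals, np.round(vals)):
            raise CrossomixError("non-integer count in matrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def features(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.counts.columns.tolist()


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in (".tsv", ".txt"):
        return "\t"
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_count_matrix(path: str | Path, layer: str) -> CountMatrix:
    """Read a TSV/CSV count table (first column = feature ids, header =
    sample ids) or a MatrixMarket triplet with ``<path>.rows`` /
    ``<path>.cols`` sidecar files."""
    path = Path(path)
    if not path.exists():
        raise CrossomixError(f"count file not found: {path}")
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        mat = mmread(path)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(rows), len(cols)):
            raise CrossomixError("MTX shape does not match sidecar row/col files")
        df = pd.DataFrame(dense, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    return CountMatrix(df, layer=layer)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    cm.counts.to_csv(path, sep="," if path.suffix.lower() == ".csv" else "\t")


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

PEAK_ANNOTATION_COLUMNS = (
    "peak_id", "chrom", "start", "end", "gene",
    "region_class", "is_promoter", "is_protein_coding",
)


@dataclass
class PeakAnnotation:
    """Peak -> gene annotation (BED-convention 0-based half-open coordinates).

    Annotation is consumed as input, never computed here.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise CrossomixError(f"peak annotation missing columns: {missing}")
        tab = self.table.reset_index(drop=True).copy()
        if tab["peak_id"].duplicated().any():
            raise CrossomixError("duplicate peak_id in annotation")
        tab["start"] = tab["start"].astype(int)
        tab["end"] = tab["end"].astype(int)
        if (tab["start"] >= tab["end"]).any():
            raise CrossomixError("peak with start >= end")
        for col in ("is_promoter", "is_protein_coding"):
            tab[col] = tab[col].map(_as_bool)
        self.table = tab

    def promoter_protein_coding(self) -> pd.DataFrame:
        t = self.table
        return t[t["is_promoter"] & t["is_protein_coding"]]


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise CrossomixError(f"cannot interpret {v!r} as boolean")


def read_peak_annotation(path: str | Path) -> PeakAnnotation:
    return PeakAnnotation(pd.read_csv(path, sep=_sniff_sep(Path(path))))


def write_peak_annotation(ann: PeakAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions; member lists de-duplicated."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise CrossomixError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CrossomixError(f"malformed GMT line: {line[:60]!r}")
            name, d, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise CrossomixError(f"duplicate gene set name {name!r}")
            if not members:
                raise CrossomixError(f"gene set {name!r} is empty")
            sets[name] = set(members)
            desc[name] = d
    return GeneSetCollection(sets, desc)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            d = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, d, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Network persistence
# ---------------------------------------------------------------------------

def write_network(net: nx.Graph, path: str | Path) -> None:
    """Persist a co-expression network as GraphML (node attrs ``layer`` and
    ``module``, edge attr ``weight`` at full float precision)."""
    g = net.copy()
    for _, data in g.nodes(data=True):
        data.setdefault("layer", "")
        data.setdefault("module", "")
    nx.write_graphml(g, str(path))


def read_network(path: str | Path) -> nx.Graph:
    path = Path(path)
    if not path.exists():
        raise CrossomixError(f"network file not found: {path}")
    try:
        g = nx.read_graphml(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parse errors uniformly
        raise CrossomixError(f"cannot parse GraphML {path}: {exc}") from exc
    out = nx.Graph()
    out.graph.update(g.graph)
    for n, data in g.nodes(data=True):
        out.add_node(str(n), **data)
    for u, v, data in g.edges(data=True):
        if "weight" not in data:
            raise CrossomixError(f"edge ({u},{v}) missing weight")
        out.add_edge(str(u), str(v), weight=float(data["weight"]))
    return out


def write_network_tsv(net: nx.Graph, edge_path: str | Path, node_path: str | Path) -> None:
    """Edge-list + node-table TSV alternative to GraphML."""
    edges = pd.DataFrame(
        [(u, v, f"{d['weight']!r}") for u, v, d in net.edges(data=True)],
        columns=["source", "target", "weight"],
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [
            (n, d.get("layer", ""), d.get("module", ""))
            for n, d in net.nodes(data=True)
        ],
        columns=["node", "layer", "module"],
    )
    nodes.to_csv(node_path, sep="\t", index=False)


def read_network_tsv(edge_path: str | Path, node_path: str | Path) -> nx.Graph:
    nodes = pd.read_csv(node_path, sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(
        edge_path, sep="\t", dtype={"source": str, "target": str},
        float_precision="round_trip",
    )
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["node"], layer=row["layer"], module=row["module"])
    for _, row in edges.iterrows():
        if row["source"] not in g or row["target"] not in g:
            raise CrossomixError(
                f"edge references unknown node: {row['source']}-{row['target']}"
            )
        g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return g


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All tunables of the pipeline, validated at load time.

    Defaults follow the CoCena conventions used throughout this package:
    strict ``> min_total`` filtering for RNA, ``>= min_total`` for ATAC,
    GFC cap 2.0, minimum module size 15, GSVA-style scoring with Gaussian
    kernel CDF and tau = 1.
    """

    seed: int = 0
    # preprocessing
    rna_min_total: int = 100
    atac_min_total: int = 20
    pseudocount: float = 1.0
    gfc_cap: float | None = 2.0
    padj_de: float = 0.05
    p_dar: float = 0.05
    top_n_variable: int = 1000
    # network
    cutoff_rna: float | None = None
    cutoff_atac: float | None = None
    cutoff_grid: tuple[float, ...] = (0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)
    powerlaw_r2_min: float = 0.8
    cluster_algorithm_rna: str = "infomap"
    cluster_algorithm_atac: str = "walktrap"
    cluster_algorithm_integrated: str = "walktrap"
    walktrap_steps: int = 4
    min_module_size: int = 15
    # vertical integration
    cross_cutoff: float | None = None
    cross_cutoff_grid: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    # signature
    sensitive_cell_line: str = ""
    resistant_cell_line: str = ""
    treatment: str = ""
    control_treatment: str = "ctrl"
    signature_time: str = "6h"
    baseline_padj: float = 0.01
    baseline_lfc: float = 1.0
    # scoring
    score_method: str = "gsva"
    kcdf: str = "gaussian"
    tau: float = 1.0
    es_mode: str = "maxdiff"
    # predictor
    test_fraction: float = 0.2
    k_folds: int = 10
    lambda_rule: str = "min"

    def __post_init__(self) -> None:
        if self.rna_min_total < 0 or self.atac_min_total < 0:
            raise CrossomixError("min_total thresholds must be >= 0")
        if self.pseudocount <= 0:
            raise CrossomixError("pseudocount must be > 0")
        if self.gfc_cap is not None and self.gfc_cap <= 0:
            raise CrossomixError("gfc_cap must be > 0 or null")
        for name in ("padj_de", "p_dar", "baseline_padj"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise CrossomixError(f"{name} must be in (0, 1]")
        if self.top_n_variable <= 0:
            raise CrossomixError("top_n_variable must be > 0")
        for name in ("cutoff_rna", "cutoff_atac", "cross_cutoff"):
            v = getattr(self, name)
            if v is not None and not 0 < v <= 1:
                raise CrossomixError(f"{name} must be in (0, 1]")
        for grid_name in ("cutoff_grid", "cross_cutoff_grid"):
            grid = tuple(getattr(self, grid_name))
            if any(not 0 < c <= 1 for c in grid):
                raise CrossomixError(f"{grid_name} values must be in (0, 1]")
            setattr(self, grid_name, grid)
        for name in ("cluster_algorithm_rna", "cluster_algorithm_atac",
                     "cluster_algorithm_integrated"):
            if getattr(self, name) not in ("walktrap", "infomap", "leiden"):
                raise CrossomixError(f"{name} must be walktrap|infomap|leiden")
        if self.min_module_size < 1:
            raise CrossomixError("min_module_size must be >= 1")
        if self.walktrap_steps < 1:
            raise CrossomixError("walktrap_steps must be >= 1")
        if self.score_method not in ("gsva", "ssgsea"):
            raise CrossomixError("score_method must be gsva|ssgsea")
        if self.kcdf not in ("gaussian", "poisson", "none"):
            raise CrossomixError("kcdf must be gaussian|poisson|none")
        if self.es_mode not in ("maxdiff", "maxdev"):
            raise CrossomixError("es_mode must be maxdiff|maxdev")
        if not 0 < self.test_fraction < 1:
            raise CrossomixError("test_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise CrossomixError("k_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise CrossomixError("lambda_rule must be min|1se")
        if not math.isfinite(self.tau) or self.tau < 0:
            raise CrossomixError("tau must be finite and >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise CrossomixError("config YAML must map keys to values")
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CrossomixError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# JSON helpers for signatures / scores / models
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
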