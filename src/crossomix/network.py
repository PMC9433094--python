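"""Single-layer co-expression networks from GFC patterns.

Edges connect features whose GFC vectors across condition groups are
positively Pearson-correlated at or above a cutoff; communities are detected
with walktrap, infomap or Leiden on the weighted graph, and communities
smaller than a minimum size (default 15 nodes) are pooled into an
"unassigned" label. Two networks of the same omic layer (e.g. the two cell
lines) merge horizontally by node/edge union, averaging the weights of
shared edges.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CrossomixError, namespaced, split_namespace
from .preprocess import GFCMatrix

logger = logging.getLogger(__name__)

ALGORITHMS = ("walktrap", "infomap", "leiden")

# module naming follows the field's color-name convention, by decreasing size
MODULE_COLORS = (
    "maroon", "darkgreen", "steelblue", "indianred", "lightgreen", "pink",
    "sandybrown", "orchid", "gold", "khaki", "darkorange", "lightblue",
    "darkgray", "plum", "teal", "salmon", "olive", "navy", "turquoise",
    "sienna", "crimson", "lavender", "coral", "seagreen",
)

UNASSIGNED = "unassigned"


@dataclass
class ModuleTable:
    """Module membership of network nodes.

    ``assignments`` maps node -> module label (color name or UNASSIGNED);
    ``means`` optionally holds module x condition-group mean GFC vectors.
    """

    assignments: pd.Series
    means: pd.DataFrame | None = None
    min_size: int = 15

    def members(self, module_id: str) -> list[str]:
        return self.assignments.index[self.assignments == module_id].tolist()

    @property
    def module_ids(self) -> list[str]:
        return [m for m in self.assignments.unique() if m != UNASSIGNED]

    def sizes(self) -> pd.Series:
        counts = self.assignments[self.assignments != UNASSIGNED].value_counts()
        return counts.sort_values(ascending=False)


def correlation_matrix(gfc: GFCMatrix, features: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of GFC row vectors across condition groups.

    Zero-variance rows are dropped with a warning; requires >= 3 groups.
    """
    values = gfc.values
    if features is not None:
        missing = [f for f in features if f not in values.index]
        if missing:
            raise CrossomixError(f"features absent from GFC matrix: {missing[:5]}")
        values = values.loc[features]
    if values.shape[1] < 3:
        raise CrossomixError("correlation needs >= 3 condition groups")
    sds = values.std(axis=1, ddof=1)
    flat = sds[sds == 0].index.tolist()
    if flat:
        logger.warning("dropping %d zero-variance features from correlation", len(flat))
        values = values.drop(index=flat)
    if values.empty:
        raise CrossomixError("no features with variance; correlation undefined")
    corr = np.corrcoef(values.to_numpy(dtype=float))
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def _degree_powerlaw_r2(degrees: np.ndarray) -> float:
    """R^2 of a log-log linear fit to the degree distribution.

    Returns NaN when fewer than 3 distinct positive degrees exist.
    """
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        return float("nan")
    uniq, counts = np.unique(degrees, return_counts=True)
    if uniq.size < 3:
        return float("nan")
    x = np.log(uniq.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid**2).sum() / ss_tot)


def cutoff_scan(corr: pd.DataFrame, grid: list[float]) -> pd.DataFrame:
    """Evaluate candidate correlation cutoffs.

    For each cutoff: number of non-isolated nodes, edge count, and the R^2
    of a log-log linear fit to the degree distribution (scale-freeness aid).
    """
    if len(grid) == 0:
        raise CrossomixError("empty cutoff grid")
    if any(not 0 < c <= 1 for c in grid):
        raise CrossomixError("cutoffs must be in (0, 1]")
    c = corr.to_numpy(dtype=float)
    iu = np.triu_indices(c.shape[0], k=1)
    weights = c[iu]
    rows = []
    for cutoff in grid:
        mask = (weights >= cutoff) & (weights > 0)
        n_edges = int(mask.sum())
        deg = np.zeros(c.shape[0], dtype=int)
        np.add.at(deg, iu[0][mask], 1)
        np.add.at(deg, iu[1][mask], 1)
        rows.append(
            {
                "cutoff": cutoff,
                "n_nodes": int((deg > 0).sum()),
                "n_edges": n_edges,
                "powerlaw_r2": _degree_powerlaw_r2(deg),
            }
        )
    return pd.DataFrame(rows)


def choose_cutoff(scan: pd.DataFrame, r2_min: float = 0.8) -> float:
    """Heuristic default: smallest scanned cutoff whose degree distribution
    fits a power law with R^2 >= r2_min. When no cutoff reaches the fit
    criterion (e.g. block-structured networks, which are nothing like
    scale-free), fall back to the most stringent cutoff that still keeps
    the maximal node count, rather than sacrificing nodes to a fit that is
    poor everywhere. Cutoff choice remains fundamentally empirical — prefer
    passing an explicit value chosen from the scan table."""
    ordered = scan.sort_values("cutoff")
    good = ordered[ordered["powerlaw_r2"] >= r2_min]
    if not good.empty:
        return float(good.iloc[0]["cutoff"])
    full = ordered[ordered["n_nodes"] == ordered["n_nodes"].max()]
    return float(full.iloc[-1]["cutoff"])


def build_network(corr: pd.DataFrame, cutoff: float, layer: str) -> nx.Graph:
    """Undirected weighted graph: edge (i, j) iff corr_ij >= cutoff and
    corr_ij > 0; weight = corr_ij; isolated nodes dropped. Nodes are
    namespaced as ``layer::feature``."""
    if not 0 < cutoff <= 1:
        raise CrossomixError("cutoff must be in (0, 1]")
    c = corr.to_numpy(dtype=float)
    names = corr.index.tolist()
    iu = np.triu_indices(len(names), k=1)
    mask = (c[iu] >= cutoff) & (c[iu] > 0)
    g = nx.Graph(layer=layer, cutoff=cutoff)
    for i, j, w in zip(iu[0][mask], iu[1][mask], c[iu][mask]):
        u = namespaced(layer, names[i])
        v = namespaced(layer, names[j])
        g.add_edge(u, v, weight=float(w))
    for n in g.nodes:
        g.nodes[n]["layer"] = split_namespace(n)[0]
    return g


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    weights = [net.edges[u, v]["weight"] for u, v in net.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def detect_modules(
    net: nx.Graph,
    algorithm: str = "infomap",
    min_size: int = 15,
    seed: int = 0,
    gfc: GFCMatrix | dict[str, GFCMatrix] | None = None,
    walktrap_steps: int = 4,
) -> ModuleTable:
    """Weighted community detection with a minimum-module-size rule.

    Communities smaller than ``min_size`` are pooled into "unassigned".
    Surviving modules are named by size-ordered color names. Deterministic
    given the seed. When ``gfc`` is provided, per-module mean GFC vectors
    are attached (a dict keyed by layer serves multi-layer graphs).
    """
    if algorithm not in ALGORITHMS:
        raise CrossomixError(f"unknown algorithm {algorithm!r}")
    if net.number_of_nodes() == 0:
        raise CrossomixError("empty network")
    g, nodes = _to_igraph(net)
    if algorithm == "walktrap":
        clustering = g.community_walktrap(
            weights="weight", steps=walktrap_steps
        ).as_clustering()
        membership = clustering.membership
    elif algorithm == "infomap":
        state = _random.Random(int(seed))
        ig.set_random_number_generator(state)
        try:
            membership = g.community_infomap(edge_weights="weight").membership
        finally:
            ig.set_random_number_generator(_random)
    else:  # leiden
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights="weight",
            seed=int(seed),
        )
        membership = part.membership
    series = pd.Series(membership, index=nodes)
    sizes = series.value_counts()
    keep = sizes[sizes >= min_size].sort_values(ascending=False)
    names: dict[int, str] = {}
    for rank, comm in enumerate(keep.index):
        names[comm] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        )
    labels = series.map(lambda c: names.get(c, UNASSIGNED))
    table = ModuleTable(assignments=labels, min_size=min_size)
    if gfc is not None:
        table.means = module_gfc_means(table, gfc)
    return table


def module_gfc_means(
    modules: ModuleTable, gfc: GFCMatrix | dict[str, GFCMatrix]
) -> pd.DataFrame:
    """Arithmetic mean of member GFC vectors per module.

    ``gfc`` may be a single GFCMatrix or a dict keyed by layer for graphs
    whose nodes span several omic layers; node ids are layer-namespaced and
    looked up in the matching matrix.
    """
    per_layer = gfc if isinstance(gfc, dict) else None
    rows = {}
    for module_id in modules.module_ids:
        vectors = []
        for node in modules.members(module_id):
            layer, feat = split_namespace(node)
            source = per_layer[layer] if per_layer is not None else gfc
            if feat not in source.values.index:
                raise CrossomixError(f"module member {node!r} missing from GFC matrix")
            vectors.append(source.values.loc[feat])
        rows[module_id] = pd.concat(vectors, axis=1).mean(axis=1)
    if not rows:
        some = next(iter(per_layer.values())) if per_layer else gfc
        return pd.DataFrame(columns=some.values.columns)
    return pd.DataFrame(rows).T


def merge_horizontal(net_a: nx.Graph, net_b: nx.Graph) -> nx.Graph:
    """hCoCena merge of two same-layer networks: union of nodes and edges;
    an edge present in both parents takes the mean of the two weights."""
    layer_a = net_a.graph.get("layer")
    layer_b = net_b.graph.get("layer")
    if layer_a != layer_b:
        raise CrossomixError(f"layer mismatch: {layer_a!r} vs {layer_b!r}")
    merged = nx.Graph(layer=layer_a)
    for src in (net_a, net_b):
        for n, data in src.nodes(data=True):
            merged.add_node(n, **data)
    for u, v, data in net_a.edges(data=True):
        merged.add_edge(u, v, weight=float(data["weight"]))
    for u, v, data in net_b.edges(data=True):
        w = float(data["weight"])
        if merged.has_edge(u, v):
            merged.edges[u, v]["weight"] = (merged.edges[u, v]["weight"] + w) / 2.0
        else:
            merged.add_edge(u, v, weight=w)
    return merged
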