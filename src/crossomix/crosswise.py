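"""Vertical (RNA <-> ATAC) network integration and pairwise concordance.

Module pairs from the two omic layers are matched by the Pearson correlation
of their mean GFC patterns. Pairs at or above a cross-layer cutoff
contribute gene-level cross-layer edges (between members whose feature-level
GFC vectors also correlate at or above the cutoff, weighted by that
correlation); all intra-layer edges are retained and the union graph is
reclustered. The cutoff is chosen to maximize the mixture between layers in
the resulting modules, quantified as the mean normalized Shannon entropy of
each module's (RNA fraction, ATAC fraction) composition.

The pairwise concordance analysis intersects differential-expression and
promoter-DAR calls gene-by-gene, classifying shared hits as up-up,
down-down or discordant, optionally with a time lag (chromatin at 6 h vs
transcription at 12 h).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CrossomixError, split_namespace
from .network import UNASSIGNED, ModuleTable, detect_modules, module_gfc_means
from .preprocess import GFCMatrix

logger = logging.getLogger(__name__)

LAGS = ("same_time", "atac6h_rna12h")


@dataclass
class IntegratedModules:
    """Reclustered modules of the integrated network with layer composition."""

    table: ModuleTable
    composition: pd.DataFrame  # module x (n_rna, n_atac, frac_rna, frac_atac)
    means: pd.DataFrame  # module x condition-group mean GFC


def _pairwise_pearson(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Row-by-row Pearson correlation between two matrices sharing columns."""
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    av = av - av.mean(axis=1, keepdims=True)
    bv = bv - bv.mean(axis=1, keepdims=True)
    na = np.sqrt((av**2).sum(axis=1))
    nb = np.sqrt((bv**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (av @ bv.T) / np.outer(na, nb)
    return corr


def match_modules(means_rna: pd.DataFrame, means_atac: pd.DataFrame) -> pd.DataFrame:
    """Cross-layer Pearson correlation of module mean GFC patterns.

    Returns long-format rows (module_rna, module_atac, pattern_correlation).
    """
    if list(means_rna.columns) != list(means_atac.columns):
        raise CrossomixError("condition-group columns differ between layers")
    if means_rna.shape[1] < 3:
        raise CrossomixError("pattern correlation needs >= 3 condition groups")
    corr = _pairwise_pearson(means_rna, means_atac)
    rows = []
    for i, mr in enumerate(means_rna.index):
        for j, ma in enumerate(means_atac.index):
            rows.append(
                {"module_rna": mr, "module_atac": ma,
                 "pattern_correlation": float(corr[i, j])}
            )
    return pd.DataFrame(rows)


def integrate_vertical(
    net_rna: nx.Graph,
    net_atac: nx.Graph,
    gfc_rna: GFCMatrix,
    gfc_atac: GFCMatrix,
    modules_rna: ModuleTable,
    modules_atac: ModuleTable,
    matches: pd.DataFrame,
    cross_cutoff: float,
    algorithm: str = "walktrap",
    min_size: int = 15,
    seed: int = 0,
    walktrap_steps: int = 4,
) -> tuple[nx.Graph, IntegratedModules]:
    """vCoCena integration of the RNA and ATAC networks.

    The integrated node set is the (namespaced, hence disjoint) union of
    both layers' nodes; all intra-layer edges are kept. For every matched
    module pair (pattern correlation >= cross_cutoff), cross-layer edges
    are added between members whose feature-level GFC vectors correlate at
    or above the same cutoff, weighted by that correlation. The union graph
    is then reclustered, module mean GFCs are recomputed and each module's
    layer composition is reported.
    """
    if not 0 < cross_cutoff <= 1:
        raise CrossomixError("cross_cutoff must be in (0, 1]")
    shared = set(net_rna.nodes) & set(net_atac.nodes)
    if shared:
        raise CrossomixError(f"node namespace collision: {sorted(shared)[:3]}")
    integrated = nx.Graph(layer="integrated", cross_cutoff=cross_cutoff)
    for src in (net_rna, net_atac):
        for n, data in src.nodes(data=True):
            integrated.add_node(n, **data)
        for u, v, data in src.edges(data=True):
            integrated.add_edge(u, v, weight=float(data["weight"]))

    matched = matches[matches["pattern_correlation"] >= cross_cutoff]
    n_cross = 0
    for _, row in matched.iterrows():
        members_r = modules_rna.members(row["module_rna"])
        members_a = modules_atac.members(row["module_atac"])
        feats_r = [split_namespace(n)[1] for n in members_r]
        feats_a = [split_namespace(n)[1] for n in members_a]
        corr = _pairwise_pearson(
            gfc_rna.values.loc[feats_r], gfc_atac.values.loc[feats_a]
        )
        idx_r, idx_a = np.where(corr >= cross_cutoff)
        for i, j in zip(idx_r, idx_a):
            u, v = members_r[i], members_a[j]
            w = float(corr[i, j])
            if not integrated.has_edge(u, v):
                n_cross += 1
            integrated.add_edge(u, v, weight=w)
    logger.info(
        "vertical integration: %d matched pairs, %d cross-layer edges",
        len(matched), n_cross,
    )

    gfc_by_layer = {"rna": gfc_rna, "atac": gfc_atac}
    table = detect_modules(
        integrated,
        algorithm=algorithm,
        min_size=min_size,
        seed=seed,
        gfc=gfc_by_layer,
        walktrap_steps=walktrap_steps,
    )
    comp = layer_composition(table)
    means = module_gfc_means(table, gfc_by_layer)
    return integrated, IntegratedModules(table=table, composition=comp, means=means)


def layer_composition(modules: ModuleTable) -> pd.DataFrame:
    """Per-module RNA/ATAC node counts and fractions (fractions sum to 1)."""
    rows = {}
    for module_id in modules.module_ids:
        members = modules.members(module_id)
        n_rna = sum(1 for n in members if split_namespace(n)[0] == "rna")
        n_atac = len(members) - n_rna
        total = len(members)
        rows[module_id] = {
            "n_rna": n_rna,
            "n_atac": n_atac,
            "frac_rna": n_rna / total,
            "frac_atac": n_atac / total,
        }
    return pd.DataFrame(rows).T if rows else pd.DataFrame(
        columns=["n_rna", "n_atac", "frac_rna", "frac_atac"]
    )


def mixing_score(composition: pd.DataFrame) -> float:
    """Mean normalized Shannon entropy of per-module layer fractions.

    0 iff every module is layer-pure, 1 iff every module is a 50/50 mix.
    Empty module sets score 0.
    """
    if composition.empty:
        return 0.0
    entropies = []
    for _, row in composition.iterrows():
        h = 0.0
        for p in (row["frac_rna"], row["frac_atac"]):
            if p > 0:
                h -= p * np.log2(p)
        entropies.append(h)
    return float(np.mean(entropies))


def crosslayer_cutoff_scan(
    matches: pd.DataFrame,
    cutoffs: list[float],
    net_rna: nx.Graph,
    net_atac: nx.Graph,
    gfc_rna: GFCMatrix,
    gfc_atac: GFCMatrix,
    modules_rna: ModuleTable,
    modules_atac: ModuleTable,
    algorithm: str = "walktrap",
    min_size: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate candidate cross-layer cutoffs by re-running the integration.

    Reports matched pair count, mixing score and module count per cutoff;
    the recommended cutoff maximizes the mixing score (ties break to the
    higher cutoff) so the chosen integration maximizes layer mixture.
    """
    if len(cutoffs) == 0:
        raise CrossomixError("empty cross-layer cutoff list")
    rows = []
    for cutoff in cutoffs:
        _, integ = integrate_vertical(
            net_rna, net_atac, gfc_rna, gfc_atac,
            modules_rna, modules_atac, matches,
            cross_cutoff=cutoff, algorithm=algorithm,
            min_size=min_size, seed=seed,
        )
        rows.append(
            {
                "cutoff": cutoff,
                "n_matched_pairs": int(
                    (matches["pattern_correlation"] >= cutoff).sum()
                ),
                "mixing_score": mixing_score(integ.composition),
                "n_modules": len(integ.table.module_ids),
            }
        )
    scan = pd.DataFrame(rows)
    return scan


def recommend_cross_cutoff(scan: pd.DataFrame) -> float:
    """argmax of mixing_score; ties resolve to the higher cutoff."""
    ordered = scan.sort_values(["mixing_score", "cutoff"], ascending=[False, False])
    return float(ordered.iloc[0]["cutoff"])


def pairwise_concordance(
    de_rna: pd.DataFrame,
    dar_gene: pd.DataFrame,
    alpha_rna: float = 0.05,
    alpha_atac: float = 0.05,
    lag: str = "same_time",
) -> pd.DataFrame:
    """Gene-level concordance between DE and promoter-DAR calls.

    Includes genes significant in at least one layer (padj < alpha_rna on
    RNA or p < alpha_atac on ATAC). Quadrants: up-up if both log2fc > 0,
    down-down if both < 0, else discordant. ``lag`` is recorded as a label
    — the caller supplies the tables for the intended time points (e.g.
    ATAC at 6 h against RNA at 12 h).
    """
    if lag not in LAGS:
        raise CrossomixError(f"unknown lag {lag!r}")
    common = de_rna.index.intersection(dar_gene.index)
    if common.empty:
        logger.warning("no shared genes between DE and DAR tables")
        return pd.DataFrame(
            columns=["log2fc_rna", "padj_rna", "log2fc_atac", "p_atac",
                     "quadrant", "lag"]
        ).rename_axis("gene")
    common = common.sort_values()
    rna = de_rna.loc[common]
    atac = dar_gene.loc[common]
    sig = (rna["padj"] < alpha_rna) | (atac["p"] < alpha_atac)
    out = pd.DataFrame(
        {
            "log2fc_rna": rna["log2fc"],
            "padj_rna": rna["padj"],
            "log2fc_atac": atac["log2fc"],
            "p_atac": atac["p"],
        }
    ).loc[sig.to_numpy()]
    both_up = (out["log2fc_rna"] > 0) & (out["log2fc_atac"] > 0)
    both_down = (out["log2fc_rna"] < 0) & (out["log2fc_atac"] < 0)
    out["quadrant"] = np.select(
        [both_up, both_down], ["up-up", "down-down"], default="discordant"
    )
    out["lag"] = lag
    return out.rename_axis("gene")
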