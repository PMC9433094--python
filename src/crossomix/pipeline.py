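"""End-to-end orchestration: counts -> networks -> integration -> signature.

Each stage delegates to the corresponding module; this file only wires them
together in the order of the crosswise workflow:

1. filter and normalize both layers (strict > threshold for RNA, >= for ATAC);
2. treated-vs-control contrasts per cell line; ATAC peaks reduced to one
   reference promoter peak per protein-coding gene (highest variance);
3. per-layer network input = significant features ranked by variance;
4. per-cell-line GFC networks at a scanned (or configured) cutoff, merged
   horizontally per layer, clustered;
5. vertical integration at the cross-layer cutoff maximizing layer mixing;
6. module dGFC / thr_score / q50 selection at the early time point and
   intersection with the baseline contrast into the up/down signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import crosswise, network, preprocess, signature as sig
from .core_io import AnalysisConfig, CountMatrix, CrossomixError, PeakAnnotation, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class CrosswiseResult:
    """Everything the crosswise pipeline produces, stage by stage."""

    normalized: dict[str, preprocess.NormalizedMatrix]
    gfc_full: dict[str, preprocess.GFCMatrix]
    de_tables: dict[str, dict[str, pd.DataFrame]]
    network_input: dict[str, list[str]]
    layer_networks: dict[str, object]
    layer_modules: dict[str, network.ModuleTable]
    cutoffs: dict[str, float]
    matches: pd.DataFrame
    cross_cutoff: float
    integrated_network: object
    integrated: crosswise.IntegratedModules
    module_scores: pd.DataFrame
    baseline_de: pd.DataFrame
    signature: sig.Signature
    extras: dict = field(default_factory=dict)


def treated_contrasts(design: SampleDesign, control_treatment: str) -> list[tuple[str, str, str]]:
    """(name, treated group, control group) for every cell line, non-control
    treatment and time, against the same-time control group."""
    t = design.table
    out = []
    for cl in sorted(t["cell_line"].unique()):
        for tr in sorted(t["treatment"].unique()):
            if tr == control_treatment:
                continue
            for tm in sorted(t[t["cell_line"] == cl]["time"].unique()):
                treated = f"{cl}|{tr}|{tm}"
                control = f"{cl}|{control_treatment}|{tm}"
                out.append((f"{cl}:{tr}_vs_{control_treatment}:{tm}", treated, control))
    return out


def reduce_atac_to_genes(
    norm_atac: preprocess.NormalizedMatrix,
    annotation: PeakAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference promoter peak per protein-coding gene by highest variance
    across all samples; returns (gene-level matrix, peak-gene map)."""
    peak_stats = pd.DataFrame(
        {"variance": norm_atac.values.var(axis=1, ddof=1)}, index=norm_atac.values.index
    )
    peak_map = preprocess.map_peaks_to_genes(
        peak_stats, annotation, rule="max_variance"
    )
    gene_matrix = norm_atac.values.loc[peak_map["peak_id"]]
    gene_matrix.index = peak_map.index
    return gene_matrix, peak_map


def _layer_network(
    features: list[str],
    gfc_by_cell: dict[str, preprocess.GFCMatrix],
    layer: str,
    config: AnalysisConfig,
    fixed_cutoff: float | None,
):
    """Per-cell-line networks at a shared or per-line cutoff, merged
    horizontally."""
    nets = []
    cutoffs_used = {}
    for cl, gfc in gfc_by_cell.items():
        present = [f for f in features if f in gfc.values.index]
        corr = network.correlation_matrix(gfc, present)
        if fixed_cutoff is not None:
            cutoff = fixed_cutoff
        else:
            scan = network.cutoff_scan(corr, list(config.cutoff_grid))
            cutoff = network.choose_cutoff(scan, config.powerlaw_r2_min)
        cutoffs_used[cl] = cutoff
        nets.append(network.build_network(corr, cutoff, layer))
    merged = nets[0]
    for other in nets[1:]:
        merged = network.merge_horizontal(merged, other)
    return merged, cutoffs_used


def run_crosswise(
    rna: CountMatrix,
    atac: CountMatrix,
    annotation: PeakAnnotation,
    design: SampleDesign,
    config: AnalysisConfig,
) -> CrosswiseResult:
    """Run the full crosswise workflow and construct the drug-sensitivity
    signature. Requires ``sensitive_cell_line``, ``resistant_cell_line``
    and ``treatment`` in the config."""
    for key in ("sensitive_cell_line", "resistant_cell_line", "treatment"):
        if not getattr(config, key):
            raise CrossomixError(f"config.{key} must be set for the pipeline")
    sens, res = config.sensitive_cell_line, config.resistant_cell_line
    ctrl = config.control_treatment

    # 1. filter + normalize
    rna_f = preprocess.filter_low_counts(rna, config.rna_min_total, "strict_gt")
    atac_f = preprocess.filter_low_counts(atac, config.atac_min_total, "gte")
    norm = {}
    for layer, cm in (("rna", rna_f), ("atac", atac_f)):
        factors = preprocess.size_factors(cm)
        norm[layer] = preprocess.normalize_log(cm, factors, config.pseudocount)

    # 2. ATAC reduced to reference promoter peaks per gene (highest variance)
    atac_gene, peak_map = reduce_atac_to_genes(norm["atac"], annotation)

    # 3. treated-vs-control contrasts per layer
    contrasts = treated_contrasts(design, ctrl)
    de_rna = {
        name: preprocess.differential_test(norm["rna"], design, a, b)
        for name, a, b in contrasts
    }
    de_atac = {
        name: preprocess.differential_test(atac_gene, design, a, b)
        for name, a, b in contrasts
    }

    # 4. network input per layer
    input_rna = preprocess.select_network_input(
        de_rna, norm["rna"], config.top_n_variable, config.padj_de, "padj"
    )
    input_atac = preprocess.select_network_input(
        de_atac, atac_gene, config.top_n_variable, config.p_dar, "p"
    )
    if not input_rna or not input_atac:
        raise CrossomixError("no network input features in one of the layers")

    # 5. GFC: full design for module statistics, per cell line for networks
    layer_values = {"rna": norm["rna"].values, "atac": atac_gene}
    gfc_full = {
        layer: preprocess.group_fold_change(vals, design, config.gfc_cap)
        for layer, vals in layer_values.items()
    }
    cell_lines = sorted(design.table["cell_line"].unique())
    gfc_by_cell = {
        layer: {
            cl: preprocess.group_fold_change(
                vals[design.subset(cell_line=cl).sample_ids],
                design.subset(cell_line=cl),
                config.gfc_cap,
            )
            for cl in cell_lines
        }
        for layer, vals in layer_values.items()
    }

    # 6. per-layer horizontal networks + modules
    net_rna, cut_rna = _layer_network(
        input_rna, gfc_by_cell["rna"], "rna", config, config.cutoff_rna
    )
    net_atac, cut_atac = _layer_network(
        input_atac, gfc_by_cell["atac"], "atac", config, config.cutoff_atac
    )
    algo = {"rna": config.cluster_algorithm_rna, "atac": config.cluster_algorithm_atac}
    modules = {
        "rna": network.detect_modules(
            net_rna, algo["rna"], config.min_module_size, config.seed,
            gfc=gfc_full["rna"], walktrap_steps=config.walktrap_steps,
        ),
        "atac": network.detect_modules(
            net_atac, algo["atac"], config.min_module_size, config.seed,
            gfc=gfc_full["atac"], walktrap_steps=config.walktrap_steps,
        ),
    }
    if not modules["rna"].module_ids or not modules["atac"].module_ids:
        raise CrossomixError("no modules detected in one of the layers")

    # 7. vertical integration
    matches = crosswise.match_modules(modules["rna"].means, modules["atac"].means)
    if config.cross_cutoff is not None:
        cross_cutoff = config.cross_cutoff
    else:
        scan = crosswise.crosslayer_cutoff_scan(
            matches, list(config.cross_cutoff_grid),
            net_rna, net_atac, gfc_full["rna"], gfc_full["atac"],
            modules["rna"], modules["atac"],
            algorithm=config.cluster_algorithm_integrated,
            min_size=config.min_module_size, seed=config.seed,
        )
        cross_cutoff = crosswise.recommend_cross_cutoff(scan)
    integrated_net, integrated = crosswise.integrate_vertical(
        net_rna, net_atac, gfc_full["rna"], gfc_full["atac"],
        modules["rna"], modules["atac"], matches,
        cross_cutoff=cross_cutoff,
        algorithm=config.cluster_algorithm_integrated,
        min_size=config.min_module_size, seed=config.seed,
        walktrap_steps=config.walktrap_steps,
    )
    if not integrated.table.module_ids:
        raise CrossomixError("vertical integration produced no modules")

    # 8. module selection by thr_score / q50 at the early time point
    tm = config.signature_time
    dg_sens = sig.module_delta_gfc(
        integrated.means, f"{sens}|{config.treatment}|{tm}", f"{sens}|{ctrl}|{tm}"
    )
    dg_res = sig.module_delta_gfc(
        integrated.means, f"{res}|{config.treatment}|{tm}", f"{res}|{ctrl}|{tm}"
    )
    scores = sig.module_threshold_scores(dg_sens, dg_res)
    selected = scores.index[scores["selected"]].tolist()
    if not selected:
        raise CrossomixError("no module passed the q50 thr_score selection")

    # 9. baseline contrast (untreated controls, both times pooled) + signature
    ctrl_sens = design.subset(cell_line=sens, treatment=ctrl).sample_ids
    ctrl_res = design.subset(cell_line=res, treatment=ctrl).sample_ids
    baseline_de = preprocess.differential_test_samples(
        norm["rna"], ctrl_sens, ctrl_res
    )
    signature = sig.build_signature(
        integrated.table, selected, baseline_de,
        padj_max=config.baseline_padj, lfc_min=config.baseline_lfc,
        drug=config.treatment,
    )
    return CrosswiseResult(
        normalized=norm,
        gfc_full=gfc_full,
        de_tables={"rna": de_rna, "atac": de_atac},
        network_input={"rna": input_rna, "atac": input_atac},
        layer_networks={"rna": net_rna, "atac": net_atac},
        layer_modules=modules,
        cutoffs={"rna": cut_rna, "atac": cut_atac},
        matches=matches,
        cross_cutoff=cross_cutoff,
        integrated_network=integrated_net,
        integrated=integrated,
        module_scores=scores,
        baseline_de=baseline_de,
        signature=signature,
        extras={"peak_map": peak_map, "atac_gene_matrix": atac_gene},
    )
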