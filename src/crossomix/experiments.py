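"""Self-contained recovery experiments on synthetic data.

Each function simulates a dataset with planted ground truth, runs the
relevant stage(s) of the workflow, and returns the recovery metrics. They
are the package's reproducible benchmark suite: the problem sizes are
scaled to desk hardware (hundreds of features, the standard 36-sample
perturbation design, cohorts of 60-500 samples) while keeping the study's
structure — two cell lines, three treatments, two time points, three
replicates, two omic layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import crosswise, network, preprocess, scoring
from .core_io import AnalysisConfig, split_namespace
from .pipeline import run_crosswise
from .predictor import train_lasso
from .signature import Signature
from .synthetic import (
    crosslayer_recovery_specs,
    default_design,
    module_recovery_specs,
    signature_recovery_specs,
    simulate_cohort,
    simulate_perturbation_dataset,
    simulate_phenotype,
)


def module_recovery_experiment(seed: int = 1) -> dict:
    """Four planted 50-feature RNA modules over the 12-group design,
    negative-binomial noise; modules detected at the scanned cutoff and
    compared with the planted partition by adjusted Rand index."""
    specs = module_recovery_specs(n_modules=4, n_features=50)
    design = default_design()
    rna, _, _, truth = simulate_perturbation_dataset(
        specs, design, seed=seed, n_background_rna=100, n_background_atac=1,
    )
    filtered = preprocess.filter_low_counts(rna, 100, "strict_gt")
    norm = preprocess.normalize_log(filtered, preprocess.size_factors(filtered))
    gfc = preprocess.group_fold_change(norm, design, cap=None)
    planted_features = truth["features"].query("layer == 'rna' and module != ''")
    corr = network.correlation_matrix(gfc, planted_features["feature"].tolist())
    scan = network.cutoff_scan(corr, [0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
    cutoff = network.choose_cutoff(scan)
    net = network.build_network(corr, cutoff, "rna")
    modules = network.detect_modules(net, "infomap", min_size=15, seed=seed)
    truth_of = dict(zip(planted_features["feature"], planted_features["module"]))
    planted = [truth_of[split_namespace(n)[1]] for n in modules.assignments.index]
    ari = adjusted_rand_score(planted, modules.assignments.values)
    return {
        "ari": float(ari),
        "cutoff": cutoff,
        "n_modules_detected": len(modules.module_ids),
        "n_nodes": net.number_of_nodes(),
    }


def vertical_integration_experiment(seed: int = 1, cross_cutoff: float | None = None) -> dict:
    """A planted cross-layer module (30 RNA + 30 ATAC features, identical
    pattern) plus one unpaired module per layer. After vertical integration
    at the recommended (or given) cutoff, the paired module should merge
    into one mixed module and the unpaired modules should stay layer-pure."""
    specs = crosslayer_recovery_specs(n_paired=30, n_unpaired=30)
    design = default_design()
    rna, atac, ann, truth = simulate_perturbation_dataset(
        specs, design, seed=seed, dispersion=0.02,
        n_background_rna=30, n_background_atac=30,
    )
    feats = truth["features"]

    def _prep(cm, mode, thr):
        f = preprocess.filter_low_counts(cm, thr, mode)
        return preprocess.normalize_log(f, preprocess.size_factors(f))

    norm_r = _prep(rna, "strict_gt", 100)
    norm_a = _prep(atac, "gte", 20)
    gene_atac = norm_a.values.copy()
    gene_atac.index = [p.removeprefix("pk_") for p in gene_atac.index]
    gfc_r = preprocess.group_fold_change(norm_r.values, design, cap=None)
    gfc_a = preprocess.group_fold_change(gene_atac, design, cap=None)
    rna_feats = feats.query("layer == 'rna' and module != ''")["feature"].tolist()
    atac_genes = feats.query("layer == 'atac' and module != ''")["gene"].tolist()
    net_r = network.build_network(
        network.correlation_matrix(gfc_r, rna_feats), 0.7, "rna"
    )
    net_a = network.build_network(
        network.correlation_matrix(gfc_a, atac_genes), 0.7, "atac"
    )
    mod_r = network.detect_modules(net_r, "infomap", 15, seed, gfc=gfc_r)
    mod_a = network.detect_modules(net_a, "walktrap", 15, seed, gfc=gfc_a)
    matches = crosswise.match_modules(mod_r.means, mod_a.means)
    if cross_cutoff is None:
        scan = crosswise.crosslayer_cutoff_scan(
            matches, [0.5, 0.6, 0.7, 0.8, 0.9],
            net_r, net_a, gfc_r, gfc_a, mod_r, mod_a, seed=seed,
        )
        cross_cutoff = crosswise.recommend_cross_cutoff(scan)
    _, integ = crosswise.integrate_vertical(
        net_r, net_a, gfc_r, gfc_a, mod_r, mod_a, matches,
        cross_cutoff=cross_cutoff, algorithm="walktrap", min_size=15, seed=seed,
    )
    module_of = dict(zip(feats["gene"], feats["module"]))
    assignments = integ.table.assignments
    planted = [module_of[split_namespace(n)[1]] for n in assignments.index]
    ari = adjusted_rand_score(planted, assignments.values)

    # layer purity of the unpaired planted modules
    purity = {}
    for planted_module in ("rna_only", "atac_only"):
        nodes = [n for n, p in zip(assignments.index, planted) if p == planted_module]
        detected = assignments.loc[nodes].value_counts().idxmax()
        comp = integ.composition.loc[detected]
        purity[planted_module] = float(max(comp["frac_rna"], comp["frac_atac"]))
    mixed_nodes = [n for n, p in zip(assignments.index, planted) if p == "paired"]
    mixed_module = assignments.loc[mixed_nodes].value_counts().idxmax()
    mixed_comp = integ.composition.loc[mixed_module]
    return {
        "ari": float(ari),
        "cross_cutoff": float(cross_cutoff),
        "mixed_module_minor_layer_fraction": float(
            min(mixed_comp["frac_rna"], mixed_comp["frac_atac"])
        ),
        "unpaired_layer_purity": purity,
    }


def signature_recovery_experiment(seed: int = 1) -> dict:
    """End-to-end run on the two-cell-line perturbation scenario with a
    planted baseline+perturbation signature; reports Jaccard overlap of the
    recovered up/down sets with the planted ones."""
    specs = signature_recovery_specs()
    design = default_design()
    rna, atac, ann, truth = simulate_perturbation_dataset(
        specs, design, seed=seed, dispersion=0.02,
        n_background_rna=300, n_background_atac=300,
    )
    config = AnalysisConfig(
        seed=seed, sensitive_cell_line="BxPC-3", resistant_cell_line="HCT-15",
        treatment="M", gfc_cap=None, cutoff_rna=0.75, cutoff_atac=0.75,
    )
    result = run_crosswise(rna, atac, ann, design, config)
    feats = truth["features"]
    planted_up = set(feats.query("module == 'sigup'")["gene"])
    planted_down = set(feats.query("module == 'sigdown'")["gene"])

    def jaccard(a: set, b: set) -> float:
        return len(a & b) / len(a | b) if a | b else 0.0

    return {
        "jaccard_up": jaccard(result.signature.up, planted_up),
        "jaccard_down": jaccard(result.signature.down, planted_down),
        "n_up": len(result.signature.up),
        "n_down": len(result.signature.down),
        "result": result,
        "planted": Signature(planted_up, planted_down),
    }


def scoring_validity_experiment(
    seed: int = 1, n_seeds: int = 20, n_samples: int = 60
) -> dict:
    """Sensitivity scores on simulated cohorts (effect size 1, noise 0.3)
    vs the latent sensitivity factor; median Pearson r over seeds."""
    planted = Signature(
        {f"u{i}" for i in range(30)}, {f"d{i}" for i in range(20)}
    )
    rs = []
    for k in range(n_seeds):
        expr, truth = simulate_cohort(
            planted, n_samples, 200, effect_size=1.0, noise_sd=0.3,
            seed=seed * 1000 + k,
        )
        scores = scoring.sensitivity_score(expr, planted)
        r, _, _ = scoring.validate_scores(scores, truth["latent_sensitivity"])
        rs.append(r)
    return {"median_r": float(np.median(rs)), "min_r": float(min(rs)), "rs": rs}


def phenotype_correlation_experiment(seed: int = 1, n_samples: int = 60) -> dict:
    """Score vs noisy phenotype (viability-decrease analogue, linear link)."""
    planted = Signature(
        {f"u{i}" for i in range(30)}, {f"d{i}" for i in range(20)}
    )
    expr, truth = simulate_cohort(
        planted, n_samples, 200, effect_size=1.0, noise_sd=0.3, seed=seed
    )
    pheno = simulate_phenotype(truth, "linear", noise_sd=0.1, seed=seed)
    scores = scoring.sensitivity_score(expr, planted)
    r, p, n = scoring.validate_scores(scores, pheno)
    return {"pearson_r": r, "p": p, "n": n}


def predictor_closure_experiment(
    seed: int = 1, n_samples: int = 500, n_genes: int = 2000
) -> dict:
    """Scaled-down self-supervision closure: a LASSO trained on 80% of a
    synthetic cohort labeled by the sensitivity score, with and without the
    signature genes in the feature matrix (correlated background rho=0.9)."""
    planted = Signature(
        {f"u{i}" for i in range(30)}, {f"d{i}" for i in range(20)}
    )
    n_background = n_genes - len(planted.up) - len(planted.down)
    expr, truth = simulate_cohort(
        planted, n_samples, n_background, effect_size=1.0,
        rho_background=0.9, noise_sd=0.3, seed=seed,
    )
    labels = scoring.sensitivity_score(expr, planted).scores
    _, report_full = train_lasso(expr, labels, test_fraction=0.2, seed=seed)
    _, report_excl = train_lasso(
        expr, labels, test_fraction=0.2,
        exclude=planted.up | planted.down, seed=seed,
    )
    return {
        "heldout_r": report_full.pearson_r,
        "heldout_rmse": report_full.rmse,
        "heldout_r_excluded": report_excl.pearson_r,
        "heldout_rmse_excluded": report_excl.rmse,
        "n_train": report_full.n_train,
        "n_test": report_full.n_test,
    }
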