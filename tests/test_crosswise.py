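import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crossomix.core_io import CrossomixError
from crossomix.crosswise import (
    crosslayer_cutoff_scan,
    integrate_vertical,
    layer_composition,
    match_modules,
    mixing_score,
    pairwise_concordance,
    recommend_cross_cutoff,
)
from crossomix.network import (
    ModuleTable,
    build_network,
    correlation_matrix,
    detect_modules,
)
from crossomix.preprocess import GFCMatrix, group_fold_change
from crossomix.synthetic import (
    crosslayer_recovery_specs,
    default_design,
    simulate_perturbation_dataset,
)


class TestMatchModules:
    def test_identical_patterns_correlate_perfectly(self):
        m = pd.DataFrame([[1.0, 0.0, -1.0, 0.5]], index=["maroon"])
        out = match_modules(m, m.rename(index={"maroon": "gold"}))
        assert out.loc[0, "pattern_correlation"] == pytest.approx(1.0)

    def test_negated_pattern_anticorrelates(self):
        a = pd.DataFrame([[1.0, 0.0, -1.0, 0.5]], index=["maroon"])
        b = -a.rename(index={"maroon": "gold"})
        out = match_modules(a, b)
        assert out.loc[0, "pattern_correlation"] == pytest.approx(-1.0)

    def test_matches_bruteforce_pairwise_pearson(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (3, 5)), index=list("abc"))
        b = pd.DataFrame(rng.normal(0, 1, (4, 5)), index=list("wxyz"))
        out = match_modules(a, b).set_index(["module_rna", "module_atac"])
        for ra in a.index:
            for rb in b.index:
                expected = np.corrcoef(a.loc[ra], b.loc[rb])[0, 1]
                got = out.loc[(ra, rb), "pattern_correlation"]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_group_mismatch_rejected(self):
        a = pd.DataFrame([[1, 2, 3]], columns=["g1", "g2", "g3"])
        b = pd.DataFrame([[1, 2, 3]], columns=["g1", "g2", "g4"])
        with pytest.raises(CrossomixError, match="columns differ"):
            match_modules(a, b)


@pytest.fixture(scope="module")
def planted_crosslayer():
    """Planted cross-layer module plus one unpaired module per layer."""
    design = default_design()
    specs = crosslayer_recovery_specs()
    rna, atac, ann, truth = simulate_perturbation_dataset(
        specs, design, seed=2, dispersion=0.02,
        n_background_rna=0, n_background_atac=0,
    )
    log_r = np.log2(rna.counts + 1.0)
    gene_atac = np.log2(atac.counts + 1.0)
    gene_atac.index = [p.removeprefix("pk_") for p in gene_atac.index]
    gfc_r = group_fold_change(log_r, design, cap=None)
    gfc_a = GFCMatrix(
        group_fold_change(gene_atac, design, cap=None).values, cap=None
    )
    net_r = build_network(correlation_matrix(gfc_r), 0.7, "rna")
    net_a = build_network(correlation_matrix(gfc_a), 0.7, "atac")
    mod_r = detect_modules(net_r, "infomap", 15, 1, gfc=gfc_r)
    mod_a = detect_modules(net_a, "walktrap", 15, 1, gfc=gfc_a)
    matches = match_modules(mod_r.means, mod_a.means)
    truth_mod = dict(zip(truth["features"]["gene"], truth["features"]["module"]))
    return dict(
        net_r=net_r, net_a=net_a, gfc_r=gfc_r, gfc_a=gfc_a,
        mod_r=mod_r, mod_a=mod_a, matches=matches, truth_mod=truth_mod,
    )


class TestIntegrateVertical:
    def test_no_matched_pairs_keeps_layers_pure(self, planted_crosslayer):
        p = planted_crosslayer
        _, integ = integrate_vertical(
            p["net_r"], p["net_a"], p["gfc_r"], p["gfc_a"],
            p["mod_r"], p["mod_a"],
            p["matches"].assign(pattern_correlation=-1.0),
            cross_cutoff=1.0, algorithm="walktrap", min_size=15, seed=1,
        )
        comp = integ.composition
        assert ((comp["frac_rna"] == 1.0) | (comp["frac_atac"] == 1.0)).all()
        assert mixing_score(comp) == 0.0

    def test_namespaced_union_node_count(self, planted_crosslayer):
        p = planted_crosslayer
        net, _ = integrate_vertical(
            p["net_r"], p["net_a"], p["gfc_r"], p["gfc_a"],
            p["mod_r"], p["mod_a"], p["matches"],
            cross_cutoff=0.7, algorithm="walktrap", min_size=15, seed=1,
        )
        assert net.number_of_nodes() == (
            p["net_r"].number_of_nodes() + p["net_a"].number_of_nodes()
        )

    def test_intra_layer_edges_retained(self, planted_crosslayer):
        p = planted_crosslayer
        net, _ = integrate_vertical(
            p["net_r"], p["net_a"], p["gfc_r"], p["gfc_a"],
            p["mod_r"], p["mod_a"], p["matches"],
            cross_cutoff=0.7, algorithm="walktrap", min_size=15, seed=1,
        )
        for src in (p["net_r"], p["net_a"]):
            for u, v in src.edges:
                assert net.has_edge(u, v)

    def test_cross_edge_count_non_increasing_in_cutoff(self, planted_crosslayer):
        p = planted_crosslayer
        counts = []
        intra = p["net_r"].number_of_edges() + p["net_a"].number_of_edges()
        for cutoff in (0.5, 0.7, 0.9):
            net, _ = integrate_vertical(
                p["net_r"], p["net_a"], p["gfc_r"], p["gfc_a"],
                p["mod_r"], p["mod_a"], p["matches"],
                cross_cutoff=cutoff, algorithm="walktrap", min_size=15, seed=1,
            )
            counts.append(net.number_of_edges() - intra)
        assert counts == sorted(counts, reverse=True)

    def test_planted_pair_merges_into_mixed_module(self, planted_crosslayer):
        p = planted_crosslayer
        _, integ = integrate_vertical(
            p["net_r"], p["net_a"], p["gfc_r"], p["gfc_a"],
            p["mod_r"], p["mod_a"], p["matches"],
            cross_cutoff=0.7, algorithm="walktrap", min_size=15, seed=1,
        )
        assignments = integ.table.assignments
        planted = [
            p["truth_mod"][n.split("::", 1)[1]] for n in assignments.index
        ]
        assert adjusted_rand_score(planted, assignments.values) >= 0.8
        paired_nodes = assignments[[pl == "paired" for pl in planted]]
        top = paired_nodes.value_counts().idxmax()
        comp = integ.composition.loc[top]
        assert 0.2 <= comp["frac_rna"] <= 0.8  # genuinely mixed

    def test_namespace_collision_rejected(self, planted_crosslayer):
        p = planted_crosslayer
        with pytest.raises(CrossomixError, match="collision"):
            integrate_vertical(
                p["net_r"], p["net_r"], p["gfc_r"], p["gfc_a"],
                p["mod_r"], p["mod_a"], p["matches"], 0.7,
            )


class TestCutoffScanAndMixing:
    def test_scan_reports_bounded_mixing(self, planted_crosslayer):
        p = planted_crosslayer
        scan = crosslayer_cutoff_scan(
            p["matches"], [0.5, 0.7, 0.9, 0.99],
            p["net_r"], p["net_a"], p["gfc_r"], p["gfc_a"],
            p["mod_r"], p["mod_a"],
        )
        assert ((scan["mixing_score"] >= 0) & (scan["mixing_score"] <= 1)).all()
        assert (scan.loc[scan["cutoff"] <= 0.9, "n_matched_pairs"] >= 1).all()
        assert (scan.loc[scan["cutoff"] <= 0.9, "mixing_score"] > 0).all()

    def test_recommended_cutoff_breaks_ties_upward(self):
        scan = pd.DataFrame(
            {"cutoff": [0.5, 0.7, 0.9], "mixing_score": [0.4, 0.4, 0.1]}
        )
        assert recommend_cross_cutoff(scan) == 0.7

    def test_empty_cutoff_list_rejected(self, planted_crosslayer):
        p = planted_crosslayer
        with pytest.raises(CrossomixError, match="empty"):
            crosslayer_cutoff_scan(
                p["matches"], [], p["net_r"], p["net_a"],
                p["gfc_r"], p["gfc_a"], p["mod_r"], p["mod_a"],
            )

    def test_layer_fractions_sum_to_one(self):
        table = ModuleTable(pd.Series({
            "rna::a": "maroon", "rna::b": "maroon", "atac::c": "maroon",
            "atac::d": "gold", "atac::e": "gold",
        }))
        comp = layer_composition(table)
        assert np.allclose(comp["frac_rna"] + comp["frac_atac"], 1.0)
        assert mixing_score(comp.loc[["gold"]]) == 0.0


class TestPairwiseConcordance:
    def _tables(self):
        de_rna = pd.DataFrame(
            {"log2fc": [1.2, 1.2, -0.4, 2.0], "padj": [0.01, 0.01, 0.2, 0.5]},
            index=["gA", "gB", "gC", "gD"],
        )
        dar = pd.DataFrame(
            {"log2fc": [0.8, -0.8, -0.6, 1.0], "p": [0.03, 0.2, 0.01, 0.9]},
            index=["gA", "gB", "gC", "gD"],
        )
        return de_rna, dar

    def test_sign_quadrants(self):
        de_rna, dar = self._tables()
        out = pairwise_concordance(de_rna, dar)
        assert out.loc["gA", "quadrant"] == "up-up"
        assert out.loc["gB", "quadrant"] == "discordant"

    def test_atac_only_significance_included(self):
        de_rna, dar = self._tables()
        out = pairwise_concordance(de_rna, dar)
        # gC significant only in ATAC, both negative -> down-down
        assert out.loc["gC", "quadrant"] == "down-down"
        # gD significant nowhere -> excluded
        assert "gD" not in out.index

    def test_row_order_invariance(self):
        de_rna, dar = self._tables()
        out1 = pairwise_concordance(de_rna, dar)
        out2 = pairwise_concordance(de_rna.iloc[::-1], dar.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(out1, out2)

    def test_disjoint_gene_sets_give_empty_table(self):
        de_rna, dar = self._tables()
        dar2 = dar.rename(index=lambda g: g + "_x")
        out = pairwise_concordance(de_rna, dar2)
        assert out.empty

    def test_unknown_lag_rejected(self):
        de_rna, dar = self._tables()
        with pytest.raises(CrossomixError, match="lag"):
            pairwise_concordance(de_rna, dar, lag="rna_first")
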