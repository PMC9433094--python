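import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossomix.core_io import CountMatrix, CrossomixError, PeakAnnotation, SampleDesign
from crossomix.preprocess import (
    differential_test,
    filter_low_counts,
    group_fold_change,
    map_peaks_to_genes,
    normalize_log,
    select_network_input,
    size_factors,
)


def _cm(rows, index=None, columns=None, layer="rna"):
    arr = np.asarray(rows)
    index = index or [f"g{i}" for i in range(arr.shape[0])]
    columns = columns or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=index, columns=columns), layer)


class TestFilterLowCounts:
    def test_strict_gt_boundary(self):
        cm = _cm([[150], [100], [99]])
        kept = filter_low_counts(cm, 100, "strict_gt")
        assert kept.features == ["g0"]  # 100 is not > 100

    def test_gte_boundary_atac_rule(self):
        cm = _cm([[20], [19]], layer="atac")
        kept = filter_low_counts(cm, 20, "gte")
        assert kept.features == ["g0"]  # keep >= 20

    def test_zero_threshold_is_identity(self):
        cm = _cm([[0, 1], [5, 5]])
        kept = filter_low_counts(cm, 0, "gte")
        assert kept.features == cm.features

    def test_all_removed_is_error(self):
        with pytest.raises(CrossomixError, match="empty matrix"):
            filter_low_counts(_cm([[1], [2]]), 100, "strict_gt")


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        f = size_factors(_cm([[2, 2], [4, 4]]))
        assert np.allclose(f, [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        # rows [2,4],[4,8],[6,12]: geomeans sqrt(8), sqrt(32), sqrt(72);
        # every ratio column is (1/sqrt2, sqrt2)
        f = size_factors(_cm([[2, 4], [4, 8], [6, 12]]))
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_no_all_positive_feature_is_error(self):
        with pytest.raises(CrossomixError, match="all-positive"):
            size_factors(_cm([[0, 5], [5, 0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(1, 1000),
        st.integers(2, 7),
        st.integers(0, 2**31 - 1),
    )
    def test_scale_equivariance(self, base, c, seed):
        """Multiplying one column by c multiplies its factor by c (relative
        to the others' rescaling by the shared geometric-mean shift)."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(base, base + 50, (20, 3))
        f0 = size_factors(_cm(counts))
        scaled = counts.copy()
        scaled[:, 1] *= c
        f1 = size_factors(_cm(scaled))
        ratio = (f1.iloc[1] / f0.iloc[1]) / (f1.iloc[0] / f0.iloc[0])
        assert ratio == pytest.approx(c, rel=1e-9)


class TestNormalizeLog:
    def test_known_values(self):
        cm = _cm([[0], [7]])
        norm = normalize_log(cm, pd.Series([1.0], index=["s0"]), pseudocount=1.0)
        assert norm.values.loc["g0", "s0"] == 0.0
        assert norm.values.loc["g1", "s0"] == 3.0  # log2(8)

    def test_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 500, (5, 4))
        cm = _cm(counts)
        factors = pd.Series(rng.uniform(0.5, 2.0, 4), index=cm.samples)
        norm = normalize_log(cm, factors, pseudocount=0.5)
        for i in range(5):
            for j in range(4):
                expected = np.log2(counts[i, j] / factors.iloc[j] + 0.5)
                assert norm.values.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_non_positive_factor_rejected(self):
        with pytest.raises(CrossomixError):
            normalize_log(_cm([[1]]), pd.Series([0.0], index=["s0"]))


def _expr_with_groups(values_by_group, n_rep=1):
    """DataFrame of one feature per row built from per-group values."""
    rows = []
    cols = []
    for g, val in values_by_group.items():
        for r in range(n_rep):
            cols.append(f"{g}_r{r}")
    return cols


class TestGroupFoldChange:
    @pytest.fixture()
    def four_group_design(self):
        rows = [
            {"sample_id": f"s{i}", "cell_line": "L", "treatment": t, "time": "6h",
             "replicate": 1}
            for i, t in enumerate(["a", "b", "c", "d"])
        ]
        return SampleDesign(pd.DataFrame(rows))

    def test_centering_around_group_mean(self, four_group_design):
        expr = pd.DataFrame([[4.0, 6.0, 8.0, 6.0]], index=["g"],
                            columns=[f"s{i}" for i in range(4)])
        gfc = group_fold_change(expr, four_group_design, cap=None)
        assert gfc.values.loc["g"].tolist() == [-2.0, 0.0, 2.0, 0.0]

    def test_cap_clips_symmetrically(self):
        rows = [
            {"sample_id": "s0", "cell_line": "L", "treatment": "a", "time": "t",
             "replicate": 1},
            {"sample_id": "s1", "cell_line": "L", "treatment": "b", "time": "t",
             "replicate": 1},
        ]
        design = SampleDesign(pd.DataFrame(rows))
        expr = pd.DataFrame([[0.0, 10.0]], index=["g"], columns=["s0", "s1"])
        gfc = group_fold_change(expr, design, cap=2.0)
        assert gfc.values.loc["g"].tolist() == [-2.0, 2.0]

    def test_rows_sum_to_zero_and_match_bruteforce(self, rng):
        rows = []
        for i, (t, tm) in enumerate(
            [(t, tm) for t in ("a", "b", "c") for tm in ("6h", "12h")]
        ):
            for r in (1, 2):
                rows.append({"sample_id": f"s{i}_{r}", "cell_line": "L",
                             "treatment": t, "time": tm, "replicate": r})
        design = SampleDesign(pd.DataFrame(rows))
        expr = pd.DataFrame(
            rng.normal(8, 2, (20, len(rows))),
            index=[f"g{i}" for i in range(20)],
            columns=[r["sample_id"] for r in rows],
        )
        gfc = group_fold_change(expr, design, cap=None)
        assert np.abs(gfc.values.sum(axis=1)).max() < 1e-9
        # brute force: two-pass mean computation
        labels = design.group_labels()
        for feat in expr.index[:5]:
            means = {}
            for g, samples in design.groups().items():
                means[g] = np.mean([expr.loc[feat, s] for s in samples])
            overall = np.mean(list(means.values()))
            for g in means:
                assert gfc.values.loc[feat, g] == pytest.approx(
                    means[g] - overall, abs=1e-12
                )


class TestDifferentialTest:
    def test_identical_groups_give_null_result(self, two_group_design):
        expr = pd.DataFrame(
            [[5.0] * 8], index=["g"],
            columns=two_group_design.sample_ids,
        )
        table = differential_test(expr, two_group_design, "L1|ctrl|6h", "L2|ctrl|6h")
        assert table.loc["g", "log2fc"] == 0.0
        assert table.loc["g", "p"] == 1.0

    def test_mean_shift_recovered(self, two_group_design, rng):
        a = 5.0 + rng.normal(0, 1e-6, 4)
        b = 3.0 + rng.normal(0, 1e-6, 4)
        expr = pd.DataFrame([np.concatenate([a, b])], index=["g"],
                            columns=two_group_design.sample_ids)
        table = differential_test(expr, two_group_design, "L1|ctrl|6h", "L2|ctrl|6h")
        assert table.loc["g", "log2fc"] == pytest.approx(2.0, abs=1e-5)
        assert table.loc["g", "padj"] >= table.loc["g", "p"]

    def test_type_one_error_near_nominal(self, two_group_design):
        """Null simulation: fraction of raw p < 0.05 stays near 0.05."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(
                rng.normal(0, 1, (100, 8)),
                index=[f"g{i}" for i in range(100)],
                columns=two_group_design.sample_ids,
            )
            t = differential_test(expr, two_group_design, "L1|ctrl|6h", "L2|ctrl|6h")
            fracs.append((t["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) <= 0.03

    def test_small_group_rejected(self, two_group_design):
        design = SampleDesign(two_group_design.table.iloc[[0, 4, 5, 6]])
        expr = pd.DataFrame(np.ones((2, 4)), index=["g0", "g1"],
                            columns=design.sample_ids)
        with pytest.raises(CrossomixError, match=">= 2 samples"):
            differential_test(expr, design, "L1|ctrl|6h", "L2|ctrl|6h")


@pytest.fixture()
def annotation():
    return PeakAnnotation(pd.DataFrame(
        [
            ("p1", "chr1", 0, 100, "G1", "Promoter", True, True),
            ("p2", "chr1", 200, 300, "G1", "Promoter", True, True),
            ("p3", "chr1", 400, 500, "G2", "Intron", False, True),
            ("p4", "chr1", 600, 700, "G3", "Promoter", True, False),
            ("p5", "chr1", 800, 900, "G4", "Promoter", True, True),
            ("p6", "chr1", 950, 990, "G4", "Promoter", True, True),
        ],
        columns=["peak_id", "chrom", "start", "end", "gene", "region_class",
                 "is_promoter", "is_protein_coding"],
    ))


class TestMapPeaksToGenes:
    def test_min_pvalue_rule(self, annotation):
        table = pd.DataFrame({"p": [0.01, 0.04, 0.2, 0.001, 0.5, 0.5]},
                             index=[f"p{i}" for i in range(1, 7)])
        m = map_peaks_to_genes(table, annotation, "min_pvalue")
        assert m.loc["G1", "peak_id"] == "p1"

    def test_non_promoter_and_non_coding_excluded(self, annotation):
        table = pd.DataFrame({"p": [0.01] * 6}, index=[f"p{i}" for i in range(1, 7)])
        m = map_peaks_to_genes(table, annotation, "min_pvalue")
        assert "G2" not in m.index  # intron only
        assert "G3" not in m.index  # non-coding

    def test_tie_breaks_lexicographically(self, annotation):
        table = pd.DataFrame({"p": [0.1, 0.1, 0.1, 0.1, 0.03, 0.03]},
                             index=[f"p{i}" for i in range(1, 7)])
        m = map_peaks_to_genes(table, annotation, "min_pvalue")
        assert m.loc["G4", "peak_id"] == "p5"

    def test_max_variance_rule(self, annotation):
        table = pd.DataFrame({"variance": [1.0, 3.0, 0.1, 0.1, 2.0, 5.0]},
                             index=[f"p{i}" for i in range(1, 7)])
        m = map_peaks_to_genes(table, annotation, "max_variance")
        assert m.loc["G1", "peak_id"] == "p2"
        assert m.loc["G4", "peak_id"] == "p6"

    def test_unknown_rule_rejected(self, annotation):
        with pytest.raises(CrossomixError, match="rule"):
            map_peaks_to_genes(pd.DataFrame({"p": []}), annotation, "best")


class TestSelectNetworkInput:
    def test_returns_all_when_pool_smaller_than_top_n(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (10, 6)),
                            index=[f"g{i}" for i in range(10)])
        de = pd.DataFrame({"padj": [0.01] * 5 + [0.9] * 5}, index=expr.index)
        out = select_network_input({"c1": de}, expr, top_n=1000)
        assert set(out) == {f"g{i}" for i in range(5)}

    def test_order_matches_variance_sort(self, rng):
        # construct variances by design: g0 < g1 < ... < g7
        expr = pd.DataFrame(
            np.array([rng.normal(0, 0.1 * (i + 1), 12) for i in range(8)]),
            index=[f"g{i}" for i in range(8)],
        )
        de = pd.DataFrame({"padj": [0.001] * 8}, index=expr.index)
        out = select_network_input({"c1": de}, expr, top_n=4)
        expected = expr.var(axis=1, ddof=1).sort_values(ascending=False).index[:4]
        assert out == list(expected)

    def test_top_n_must_be_positive(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (3, 4)), index=["a", "b", "c"])
        de = pd.DataFrame({"padj": [0.01] * 3}, index=expr.index)
        with pytest.raises(CrossomixError):
            select_network_input({"c": de}, expr, top_n=0)
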