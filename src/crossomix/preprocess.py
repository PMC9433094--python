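"""Count filtering, normalization, group fold change, differential testing
and promoter-peak reduction.

The normalization follows the median-of-ratios scheme (size factor of a
sample = median over all-positive features of its count divided by the
feature's geometric mean), followed by a log2 transform with a pseudocount.
Differential testing is a per-feature Welch t-test on log-scale values with
Benjamini-Hochberg adjustment; a precomputed differential table (e.g. from a
negative-binomial pipeline) can be supplied anywhere a DETable is consumed.

The group fold change (GFC) of feature *i* in condition group *g* is the
group's mean log2 expression minus the mean over groups of the group means —
on log scale a difference of means is a fold change of the (geometric) mean.
Uncapped GFC rows therefore sum to zero across groups; an optional symmetric
cap clips extreme values (default 2.0 log2 units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, CrossomixError, PeakAnnotation, SampleDesign

logger = logging.getLogger(__name__)

DE_COLUMNS = ("log2fc", "p", "padj", "mean_expr")


@dataclass
class NormalizedMatrix:
    """Features x samples log2-scale values with normalization provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise CrossomixError("non-finite normalized values")


@dataclass
class GFCMatrix:
    """Features x condition-groups group fold changes."""

    values: pd.DataFrame
    cap: float | None

    @property
    def groups(self) -> list[str]:
        return self.values.columns.tolist()


def filter_low_counts(
    counts: CountMatrix, min_total: int, mode: str = "strict_gt"
) -> CountMatrix:
    """Drop features whose row total fails the threshold.

    ``strict_gt`` keeps rows with total > min_total (RNA convention);
    ``gte`` keeps rows with total >= min_total (ATAC convention).
    """
    if min_total < 0:
        raise CrossomixError("min_total must be >= 0")
    totals = counts.counts.sum(axis=1)
    if mode == "strict_gt":
        keep = totals > min_total
    elif mode == "gte":
        keep = totals >= min_total
    else:
        raise CrossomixError(f"unknown filter mode {mode!r}")
    if not keep.any():
        raise CrossomixError("empty matrix after filtering")
    return CountMatrix(counts.counts.loc[keep], layer=counts.layer)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over features with all-positive counts of
    count_ij / geometric_mean_i(counts).
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise CrossomixError("no feature with all-positive counts; cannot "
                             "compute median-of-ratios size factors")
    sub = mat[all_pos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise CrossomixError("non-positive size factor")
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def normalize_log(
    counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """log2(count / size_factor + pseudocount)."""
    if pseudocount <= 0:
        raise CrossomixError("pseudocount must be > 0")
    factors = factors.reindex(counts.counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise CrossomixError("missing or non-positive size factor")
    vals = np.log2(counts.counts.to_numpy(dtype=float) / factors.to_numpy() + pseudocount)
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return NormalizedMatrix(df, size_factors=factors, pseudocount=pseudocount)


def group_fold_change(
    expr: NormalizedMatrix | pd.DataFrame,
    design: SampleDesign,
    cap: float | None = 2.0,
) -> GFCMatrix:
    """Per-feature GFC across condition groups.

    GFC_{i,g} = mean_g(expr_i) - mean over groups of the group means; clipped
    to +/- cap when a cap is set.
    """
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    groups = design.groups()
    if len(groups) < 2:
        raise CrossomixError("need >= 2 condition groups for GFC")
    missing = [s for s in values.columns if s not in design.group_labels().index]
    if missing:
        raise CrossomixError(f"samples without group assignment: {missing[:5]}")
    group_means = {}
    for g, samples in groups.items():
        samples = [s for s in samples if s in values.columns]
        if not samples:
            raise CrossomixError(f"condition group {g!r} has no samples in matrix")
        group_means[g] = values[samples].mean(axis=1)
    gm = pd.DataFrame(group_means)
    gfc = gm.sub(gm.mean(axis=1), axis=0)
    if cap is not None:
        if cap <= 0:
            raise CrossomixError("cap must be > 0 or None")
        gfc = gfc.clip(lower=-cap, upper=cap)
    return GFCMatrix(gfc, cap=cap)


def differential_test(
    expr: NormalizedMatrix | pd.DataFrame,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-feature two-sided Welch t-test of group A vs group B on log-scale
    values, with BH adjustment. log2fc = mean(A) - mean(B).

    Returns a DETable: DataFrame indexed by feature with columns
    ``log2fc``, ``p``, ``padj``, ``mean_expr``.
    """
    if method != "welch":
        raise CrossomixError(f"unknown method {method!r}")
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    groups = design.groups()
    for g in (group_a, group_b):
        if g not in groups:
            raise CrossomixError(f"unknown condition group {g!r}")
    sa = [s for s in groups[group_a] if s in values.columns]
    sb = [s for s in groups[group_b] if s in values.columns]
    return differential_test_samples(values, sa, sb)


def differential_test_samples(
    values: NormalizedMatrix | pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
) -> pd.DataFrame:
    """Welch t-test contrast between two explicit sample lists (used e.g.
    for the baseline contrast pooling both control time points)."""
    if isinstance(values, NormalizedMatrix):
        values = values.values
    sa = [s for s in samples_a if s in values.columns]
    sb = [s for s in samples_b if s in values.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise CrossomixError("both groups need >= 2 samples")
    a = values[sa].to_numpy(dtype=float)
    b = values[sb].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate zero-variance rows: identical means -> no evidence (p = 1);
    # different means with zero variance -> overwhelming evidence (p -> 0)
    bad = ~np.isfinite(p)
    p = np.where(bad & np.isclose(lfc, 0.0), 1.0, p)
    p = np.where(bad & ~np.isclose(lfc, 0.0), np.finfo(float).tiny, p)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "padj": padj,
            "mean_expr": values[sa + sb].mean(axis=1).to_numpy(),
        },
        index=values.index,
    )


def map_peaks_to_genes(
    peak_table: pd.DataFrame,
    annotation: PeakAnnotation,
    rule: str = "min_pvalue",
) -> pd.DataFrame:
    """Reduce peaks to one reference promoter peak per protein-coding gene.

    ``peak_table`` is indexed by peak_id; for rule ``min_pvalue`` it must
    carry a ``p`` column, for ``max_variance`` a ``variance`` column. Ties
    break to the lexicographically smaller peak_id.

    Returns a DataFrame indexed by gene with a ``peak_id`` column plus the
    peak's row from ``peak_table``.
    """
    if rule not in ("min_pvalue", "max_variance"):
        raise CrossomixError(f"unknown peak selection rule {rule!r}")
    ann = annotation.promoter_protein_coding()
    known = set(annotation.table["peak_id"])
    missing = [p for p in peak_table.index if p not in known]
    if missing:
        raise CrossomixError(f"peaks absent from annotation: {missing[:5]}")
    merged = ann.merge(
        peak_table, left_on="peak_id", right_index=True, how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=["peak_id", *peak_table.columns]).rename_axis("gene")
    key = "p" if rule == "min_pvalue" else "variance"
    if key not in merged.columns:
        raise CrossomixError(f"peak table lacks required column {key!r} for rule {rule}")
    ascending = rule == "min_pvalue"
    merged = merged.sort_values([key, "peak_id"], ascending=[ascending, True])
    chosen = merged.drop_duplicates("gene", keep="first").set_index("gene")
    return chosen[["peak_id", *peak_table.columns]].sort_index()


def select_network_input(
    de_tables: dict[str, pd.DataFrame],
    expr: NormalizedMatrix | pd.DataFrame,
    top_n: int = 1000,
    alpha: float = 0.05,
    sig_column: str = "padj",
) -> list[str]:
    """Features significant in >= 1 treated-vs-control contrast, ranked by
    variance of normalized values and truncated to the top_n most variable.

    ``de_tables`` maps contrast name -> DETable for that layer's treated
    comparisons; significance is ``sig_column`` < alpha (padj for RNA DE,
    raw p for ATAC DARs).
    """
    if top_n <= 0:
        raise CrossomixError("top_n must be > 0")
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    significant: set[str] = set()
    for name, table in de_tables.items():
        if sig_column not in table.columns:
            raise CrossomixError(f"DE table {name!r} lacks column {sig_column!r}")
        significant |= set(table.index[table[sig_column] < alpha])
    pool = [f for f in values.index if f in significant]
    if not pool:
        logger.warning("no significant features for network input")
        return []
    variances = values.loc[pool].var(axis=1, ddof=1)
    ranked = variances.sort_values(ascending=False, kind="stable")
    return ranked.index[:top_n].tolist()
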