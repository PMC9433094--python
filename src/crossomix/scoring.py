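"""Single-sample gene-set enrichment and the sensitivity score.

The GSVA-style route first turns expression into per-gene cumulative
statistics with a kernel CDF across samples (Gaussian kernel with bandwidth
sd/4 on continuous data, Poisson kernel on counts), then, per sample, runs
a weighted Kolmogorov-Smirnov random walk down the gene ranking: in-set
genes step the walk up proportionally to |statistic|^tau, out-of-set genes
step it down uniformly. The enrichment score (ES) is either the largest
positive deviation plus the (negative) largest negative deviation
("maxdiff", the package default in the GSVA tradition) or the single
largest-magnitude deviation ("maxdev"). The lighter ssGSEA variant ranks
raw expression per sample (no kernel step) and integrates the walk.

The sensitivity score of a sample is ES(up signature) - ES(down signature);
higher predicts greater drug susceptibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import CrossomixError
from .signature import Signature

logger = logging.getLogger(__name__)

KCDFS = ("gaussian", "poisson", "none")
METHODS = ("gsva", "ssgsea")
ES_MODES = ("maxdiff", "maxdev")


@dataclass
class SensitivityScores:
    """Per-sample ES_up, ES_down and score = ES_up - ES_down."""

    table: pd.DataFrame  # index sample_id; columns es_up, es_down, score

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["score"], t["es_up"] - t["es_down"]):
            raise CrossomixError("score != es_up - es_down")

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


def expression_statistic(expr: pd.DataFrame, kcdf: str = "gaussian") -> pd.DataFrame:
    """Per-gene cumulative statistic across samples.

    ``expr`` is samples x genes. Gaussian: statistic_{j,i} =
    mean_k Phi((x_{j,i} - x_{k,i}) / h_i) with bandwidth h_i = sd_i / 4.
    Poisson: mean_k of the Poisson CDF at x_{j,i} with rate x_{k,i} + 0.5.
    ``none`` passes the values through. Zero-variance genes map to 0.5.
    """
    if kcdf not in KCDFS:
        raise CrossomixError(f"unknown kcdf {kcdf!r}")
    if kcdf == "none":
        return expr.copy()
    if expr.shape[0] < 3:
        raise CrossomixError("kernel CDF needs >= 3 samples")
    x = expr.to_numpy(dtype=float)
    n, m = x.shape
    out = np.empty_like(x)
    if kcdf == "gaussian":
        sds = x.std(axis=0, ddof=1)
        for i in range(m):
            h = sds[i] / 4.0
            if h == 0:
                logger.warning("zero-variance gene %s: statistic set to 0.5",
                               expr.columns[i])
                out[:, i] = 0.5
                continue
            diffs = (x[:, i][:, None] - x[:, i][None, :]) / h
            out[:, i] = special.ndtr(diffs).mean(axis=1)
    else:  # poisson
        for i in range(m):
            lam = x[:, i] + 0.5
            out[:, i] = stats.poisson.cdf(x[:, i][:, None], lam[None, :]).mean(axis=1)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _walk_es(
    stat_row: np.ndarray,
    in_set: np.ndarray,
    tau: float,
    es_mode: str,
    integrate: bool,
) -> float:
    """One sample's weighted KS walk over genes ranked by descending
    statistic; ties keep stable input order."""
    order = np.argsort(-stat_row, kind="stable")
    ranked_stat = stat_row[order]
    ranked_in = in_set[order]
    n = stat_row.size
    m = int(ranked_in.sum())
    weights = np.abs(ranked_stat) ** tau
    w_in = np.where(ranked_in, weights, 0.0)
    total_in = w_in.sum()
    if total_in == 0:
        # degenerate all-zero in-set weights: fall back to uniform steps
        w_in = ranked_in.astype(float)
        total_in = float(m)
    steps = w_in / total_in - (~ranked_in).astype(float) / (n - m)
    dev = np.cumsum(steps)
    if integrate:
        return float(dev.sum() / n)
    if es_mode == "maxdiff":
        return float(max(dev.max(), 0.0) + min(dev.min(), 0.0))
    return float(dev[np.argmax(np.abs(dev))])


def enrichment_score(
    stat_matrix: pd.DataFrame,
    gene_set: set[str],
    method: str = "gsva",
    tau: float = 1.0,
    es_mode: str = "maxdiff",
) -> pd.Series:
    """Per-sample enrichment score of one gene set.

    ``stat_matrix`` is samples x genes: kernel-CDF statistics for ``gsva``
    (see :func:`expression_statistic`), raw expression for ``ssgsea`` (which
    works on per-sample ranks and integrates the walk).
    """
    if method not in METHODS:
        raise CrossomixError(f"unknown method {method!r}")
    if es_mode not in ES_MODES:
        raise CrossomixError(f"unknown es_mode {es_mode!r}")
    in_set = np.asarray(stat_matrix.columns.isin(list(gene_set)))
    if not in_set.any():
        raise CrossomixError("gene set does not intersect the matrix genes")
    if in_set.all():
        raise CrossomixError("gene set covers every gene; ES undefined")
    x = stat_matrix.to_numpy(dtype=float)
    if method == "ssgsea":
        # per-sample ranks of raw expression (1 = lowest); ties stable
        x = stats.rankdata(x, axis=1, method="average")
    es = np.array(
        [
            _walk_es(x[j], in_set, tau, es_mode, integrate=(method == "ssgsea"))
            for j in range(x.shape[0])
        ]
    )
    return pd.Series(es, index=stat_matrix.index, name="es")


def sensitivity_score(
    expr: pd.DataFrame,
    signature: Signature,
    method: str = "gsva",
    kcdf: str = "gaussian",
    tau: float = 1.0,
    es_mode: str = "maxdiff",
) -> SensitivityScores:
    """score_j = ES_up(j) - ES_down(j) over samples x genes expression."""
    if not signature.up or not signature.down:
        raise CrossomixError("signature needs non-empty up and down sets")
    if method == "gsva":
        stat = expression_statistic(expr, kcdf=kcdf)
    else:
        stat = expr
    es_up = enrichment_score(stat, signature.up, method, tau, es_mode)
    es_down = enrichment_score(stat, signature.down, method, tau, es_mode)
    table = pd.DataFrame(
        {"es_up": es_up, "es_down": es_down, "score": es_up - es_down}
    )
    return SensitivityScores(table)


def validate_scores(
    scores: SensitivityScores | pd.Series, phenotype: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation between scores and a per-sample phenotype.

    Returns (r, two-sided p from the t distribution with n-2 df, n).
    """
    s = scores.scores if isinstance(scores, SensitivityScores) else scores
    common = s.index.intersection(phenotype.index)
    if len(common) < 3:
        raise CrossomixError("need >= 3 paired observations")
    a = s.loc[common].to_numpy(dtype=float)
    b = phenotype.loc[common].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise CrossomixError("zero variance in scores or phenotype")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), int(len(common))
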