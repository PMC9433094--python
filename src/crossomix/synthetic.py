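"""Synthetic perturbation datasets and basal cohorts with known ground truth.

The perturbation generator emulates the study conditions of the real
workflow: two cell lines x {control, two drugs} x {6 h, 12 h} with three
replicates, sequenced in two layers (RNA counts over genes; ATAC counts
over promoter peaks). Planted modules are blocks of features sharing a GFC
pattern — a per-condition-group log2 offset added to the feature's baseline
log2 mean — optionally with a baseline log2 shift in one cell line and
optionally present in both layers (cross-layer co-regulation). Counts are
negative-binomial with a (mean, dispersion) parameterization
(var = mu + dispersion * mu^2) and log-normal per-sample library-size
factors. Background features have flat means.

The cohort generator emulates basal transcriptomes carrying a latent
sensitivity factor s in [0, 1]: signature-up genes increase with s,
signature-down genes decrease, and the background contains both a block
correlated with s (to probe predictor robustness once signature genes are
removed) and independent noise genes. Values are Gaussian on log scale.

Everything is a pure function of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    CountMatrix,
    CrossomixError,
    PeakAnnotation,
    SampleDesign,
)
from .signature import Signature

DEFAULT_CELL_LINES = ("BxPC-3", "HCT-15")
DEFAULT_TREATMENTS = ("ctrl", "M", "B")
DEFAULT_TIMES = ("6h", "12h")
DEFAULT_REPLICATES = 3


@dataclass
class PlantedModuleSpec:
    """Ground-truth block of co-regulated features.

    ``gfc_pattern`` maps condition-group keys (``cell|treatment|time``) to
    planted log2 offsets; omitted groups are 0. ``baseline_shift`` is a
    signed log2 offset applied to ``shift_cell_line`` in every condition.
    ``layer`` 'both' plants the same pattern over paired RNA genes and ATAC
    promoter peaks of those genes.
    """

    module_id: str
    layer: str
    n_features: int
    gfc_pattern: Mapping[str, float]
    baseline_shift: float = 0.0
    shift_cell_line: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in ("rna", "atac", "both"):
            raise CrossomixError(f"layer must be rna|atac|both, got {self.layer!r}")
        if self.n_features < 1:
            raise CrossomixError("n_features must be >= 1")
        if not all(np.isfinite(v) for v in self.gfc_pattern.values()):
            raise CrossomixError("gfc_pattern entries must be finite")
        if self.baseline_shift != 0.0 and self.shift_cell_line is None:
            raise CrossomixError("baseline_shift requires shift_cell_line")


def default_design(
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES,
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS,
    times: tuple[str, ...] = DEFAULT_TIMES,
    n_replicates: int = DEFAULT_REPLICATES,
) -> SampleDesign:
    """The study design: 2 cell lines x 3 treatments x 2 times x 3 reps."""
    rows = []
    for cl in cell_lines:
        for tr in treatments:
            for tm in times:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{cl}_{tr}_{tm}_r{rep}",
                            "cell_line": cl,
                            "treatment": tr,
                            "time": tm,
                            "replicate": rep,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows))


def _library_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_perturbation_dataset(
    specs: list[PlantedModuleSpec],
    design: SampleDesign,
    baseline_mean: float = 8.0,
    dispersion: float = 0.1,
    library_size_cv: float = 0.1,
    seed: int = 0,
    n_background_rna: int = 300,
    n_background_atac: int = 300,
    baseline_sd: float = 1.0,
    secondary_peak_fraction: float = 0.0,
) -> tuple[CountMatrix, CountMatrix, PeakAnnotation, dict[str, pd.DataFrame]]:
    """Draw RNA and promoter-ATAC count matrices with planted modules.

    Returns (rna, atac, peak annotation, truth) where truth holds a
    ``features`` table (feature, layer, gene, module, baseline_shift,
    shift_cell_line) and a ``patterns`` table (module x condition group).
    ``secondary_peak_fraction`` plants an extra promoter peak (same signal,
    independent noise) for that fraction of ATAC genes, so reference-peak
    tie-breaking has something to break.
    """
    if dispersion <= 0:
        raise CrossomixError("dispersion must be > 0")
    groups = design.groups()
    group_of_sample = design.group_labels()
    for spec in specs:
        unknown = set(spec.gfc_pattern) - set(groups)
        if unknown:
            raise CrossomixError(
                f"module {spec.module_id}: pattern groups not in design: "
                f"{sorted(unknown)[:3]}"
            )
        if spec.shift_cell_line is not None:
            if spec.shift_cell_line not in set(design.table["cell_line"]):
                raise CrossomixError(
                    f"module {spec.module_id}: unknown cell line "
                    f"{spec.shift_cell_line!r}"
                )
    rng = np.random.default_rng(seed)
    samples = design.sample_ids
    cell_of_sample = pd.Series(
        design.table["cell_line"].values, index=design.table["sample_id"].values
    )

    # assemble per-feature log2 means for both layers
    rna_rows: list[tuple[str, str, str, float, str]] = []   # feature, gene, module, shift, shift_cl
    atac_rows: list[tuple[str, str, str, float, str]] = []  # peak, gene, module, shift, shift_cl
    for spec in specs:
        for k in range(spec.n_features):
            gene = f"{spec.module_id}_g{k:03d}"
            shift_cl = spec.shift_cell_line or ""
            if spec.layer in ("rna", "both"):
                rna_rows.append((gene, gene, spec.module_id, spec.baseline_shift, shift_cl))
            if spec.layer in ("atac", "both"):
                atac_rows.append(
                    (f"pk_{gene}", gene, spec.module_id, spec.baseline_shift, shift_cl)
                )
    for k in range(n_background_rna):
        gene = f"bg_rna_{k:04d}"
        rna_rows.append((gene, gene, "", 0.0, ""))
    for k in range(n_background_atac):
        gene = f"bg_atac_{k:04d}"
        atac_rows.append((f"pk_{gene}", gene, "", 0.0, ""))

    pattern_by_module = {s.module_id: dict(s.gfc_pattern) for s in specs}

    def _log2_means(rows) -> np.ndarray:
        base = rng.normal(baseline_mean, baseline_sd, size=len(rows))
        log2 = np.tile(base[:, None], (1, len(samples)))
        for i, (_, _, module, shift, shift_cl) in enumerate(rows):
            for j, s in enumerate(samples):
                if module:
                    log2[i, j] += pattern_by_module[module].get(group_of_sample[s], 0.0)
                if shift and cell_of_sample[s] == shift_cl:
                    log2[i, j] += shift
        return log2

    lib = _library_factors(rng, len(samples), library_size_cv)

    def _draw(rows) -> pd.DataFrame:
        log2 = _log2_means(rows)
        mu = np.exp2(log2) * lib[None, :]
        counts = _nb_counts(rng, mu, dispersion)
        return pd.DataFrame(counts, index=[r[0] for r in rows], columns=samples)

    rna_df = _draw(rna_rows)
    atac_df = _draw(atac_rows)

    # optional secondary promoter peaks (same signal, fresh noise)
    ann_rows = []
    pos = 1000
    for peak, gene, module, shift, shift_cl in atac_rows:
        ann_rows.append((peak, "chr1", pos, pos + 500, gene, "Promoter", True, True))
        pos += 10_000
    if secondary_peak_fraction > 0:
        n_extra = int(round(secondary_peak_fraction * len(atac_rows)))
        extra = atac_rows[:n_extra]
        extra_rows = [
            (f"{peak}_alt", gene, module, shift, shift_cl)
            for peak, gene, module, shift, shift_cl in extra
        ]
        extra_df = _draw(extra_rows)
        atac_df = pd.concat([atac_df, extra_df])
        for peak, gene, *_ in extra_rows:
            ann_rows.append((peak, "chr1", pos, pos + 500, gene, "Promoter", True, True))
            pos += 10_000

    annotation = PeakAnnotation(
        pd.DataFrame(
            ann_rows,
            columns=["peak_id", "chrom", "start", "end", "gene",
                     "region_class", "is_promoter", "is_protein_coding"],
        )
    )
    feature_truth = pd.DataFrame(
        [("rna", *r) for r in rna_rows]
        + [("atac", *r) for r in atac_rows]
        + (
            [("atac", f"{p}_alt", g, m, sh, sc) for p, g, m, sh, sc in atac_rows[: int(round(secondary_peak_fraction * len(atac_rows)))]]
            if secondary_peak_fraction > 0
            else []
        ),
        columns=["layer", "feature", "gene", "module", "baseline_shift",
                 "shift_cell_line"],
    )
    patterns = pd.DataFrame(
        {m: {g: pat.get(g, 0.0) for g in groups} for m, pat in pattern_by_module.items()}
    ).T
    truth = {"features": feature_truth, "patterns": patterns}
    return (
        CountMatrix(rna_df, layer="rna"),
        CountMatrix(atac_df, layer="atac"),
        annotation,
        truth,
    )


# ---------------------------------------------------------------------------
# Basal cohort with latent sensitivity
# ---------------------------------------------------------------------------

def simulate_cohort(
    signature: Signature,
    n_samples: int,
    n_background: int,
    effect_size: float = 1.0,
    rho_background: float = 0.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    base_level: float = 6.0,
    corr_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Basal expression cohort (samples x genes) with latent sensitivity.

    s_i ~ Uniform(0, 1). Signature-up genes follow
    base + effect_size * s_i + noise, down genes base - effect_size * s_i +
    noise. Of the background genes, a ``corr_fraction`` block correlates
    with s_i at ``rho_background``; the rest are independent noise.

    Returns (expression, truth) with truth columns sample_id and
    latent_sensitivity.
    """
    if not signature.up or not signature.down:
        raise CrossomixError("signature must have non-empty up and down sets")
    if n_samples < 10:
        raise CrossomixError("n_samples must be >= 10")
    if not 0 <= rho_background < 1:
        raise CrossomixError("rho_background must be in [0, 1)")
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.0, 1.0, size=n_samples)
    s_std = (s - s.mean()) / s.std()

    up = sorted(signature.up)
    down = sorted(signature.down)
    bg = [f"cbg_{k:04d}" for k in range(n_background)]
    n_corr = int(round(corr_fraction * n_background)) if rho_background > 0 else 0

    cols = {}
    for g in up:
        cols[g] = base_level + effect_size * s + rng.normal(0, noise_sd, n_samples)
    for g in down:
        cols[g] = base_level - effect_size * s + rng.normal(0, noise_sd, n_samples)
    for k, g in enumerate(bg):
        if k < n_corr:
            eps = rng.normal(0, 1, n_samples)
            z = rho_background * s_std + np.sqrt(1 - rho_background**2) * eps
            cols[g] = base_level + z
        else:
            cols[g] = base_level + rng.normal(0, 1, n_samples)
    expr = pd.DataFrame(cols, index=[f"cohort_{i:04d}" for i in range(n_samples)])
    truth = pd.DataFrame(
        {"sample_id": expr.index, "latent_sensitivity": s}
    ).set_index("sample_id")
    return expr, truth


def cohort_gene_roles(
    signature: Signature, n_background: int, rho_background: float,
    corr_fraction: float = 0.5,
) -> pd.Series:
    """Role of every cohort gene: up / down / correlated_bg / noise_bg."""
    n_corr = int(round(corr_fraction * n_background)) if rho_background > 0 else 0
    roles = {g: "up" for g in sorted(signature.up)}
    roles.update({g: "down" for g in sorted(signature.down)})
    for k in range(n_background):
        roles[f"cbg_{k:04d}"] = "correlated_bg" if k < n_corr else "noise_bg"
    return pd.Series(roles, name="role")


LINKS = ("linear", "neg_linear", "logistic")


def simulate_phenotype(
    truth: pd.DataFrame,
    link: str = "linear",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Phenotype (viability decrease or -log IC50 analogue) from latent
    sensitivity: strictly monotone in the latent before additive Gaussian
    noise. ``neg_linear`` flips the sign (an IC50-style anticorrelated
    readout)."""
    if link not in LINKS:
        raise CrossomixError(f"unknown link {link!r}")
    if "latent_sensitivity" not in truth.columns:
        raise CrossomixError("truth table lacks latent_sensitivity")
    rng = np.random.default_rng(seed)
    s = truth["latent_sensitivity"].to_numpy(dtype=float)
    if link == "linear":
        base = s
    elif link == "neg_linear":
        base = -s
    else:
        base = 1.0 / (1.0 + np.exp(-8.0 * (s - 0.5)))
    pheno = base + rng.normal(0, noise_sd, size=s.size)
    return pd.Series(pheno, index=truth.index, name="phenotype")


# ---------------------------------------------------------------------------
# Ready-made scenarios used by the recovery tests and examples
# ---------------------------------------------------------------------------

def module_recovery_specs(
    n_modules: int = 4, n_features: int = 50, amplitude: float = 2.0
) -> list[PlantedModuleSpec]:
    """Single-layer RNA modules with distinct condition patterns over the
    default 12-group design (each module responds in a different
    treatment/time/cell-line combination)."""
    design = default_design()
    group_keys = sorted(design.groups())
    active = [g for g in group_keys if "|ctrl|" not in g]
    specs = []
    for m in range(n_modules):
        pattern = {active[(2 * m) % len(active)]: amplitude,
                   active[(2 * m + 1) % len(active)]: -amplitude}
        specs.append(
            PlantedModuleSpec(
                module_id=f"plant{m}", layer="rna",
                n_features=n_features, gfc_pattern=pattern,
            )
        )
    return specs


def crosslayer_recovery_specs(
    n_paired: int = 30, n_unpaired: int = 30, amplitude: float = 2.0
) -> list[PlantedModuleSpec]:
    """One cross-layer module (identical pattern in RNA and ATAC) plus one
    unpaired module per layer with distinct patterns."""
    s, r = DEFAULT_CELL_LINES
    return [
        PlantedModuleSpec(
            "paired", "both", n_paired,
            {f"{s}|M|6h": amplitude, f"{r}|M|6h": amplitude,
             f"{s}|M|12h": amplitude / 2, f"{r}|M|12h": amplitude / 2},
        ),
        PlantedModuleSpec(
            "rna_only", "rna", n_unpaired,
            {f"{s}|B|12h": amplitude, f"{r}|B|12h": amplitude},
        ),
        PlantedModuleSpec(
            "atac_only", "atac", n_unpaired,
            {f"{s}|B|6h": -amplitude, f"{r}|B|6h": -amplitude},
        ),
    ]


def signature_recovery_specs(
    n_signature: int = 40,
    n_other: int = 30,
    amplitude: float = 2.0,
    baseline_shift: float = 2.0,
    sensitive: str = DEFAULT_CELL_LINES[0],
    resistant: str = DEFAULT_CELL_LINES[1],
) -> list[PlantedModuleSpec]:
    """End-to-end scenario: two cross-layer modules that respond to drug M
    at 6 h only in the sensitive line (high thr_score) and differ at
    baseline between the lines (one up, one down in the sensitive line),
    plus distractor modules with near-zero or negative thr_score."""
    s, r = sensitive, resistant
    return [
        PlantedModuleSpec(
            "sigup", "both", n_signature,
            {f"{s}|M|6h": amplitude, f"{s}|M|12h": amplitude / 2},
            baseline_shift=baseline_shift, shift_cell_line=s,
        ),
        PlantedModuleSpec(
            "sigdown", "both", n_signature,
            {f"{s}|M|6h": amplitude, f"{s}|B|6h": amplitude,
             f"{s}|B|12h": amplitude},
            baseline_shift=-baseline_shift, shift_cell_line=s,
        ),
        PlantedModuleSpec(
            "shared", "rna", n_other,
            {f"{s}|M|6h": amplitude, f"{r}|M|6h": amplitude,
             f"{s}|M|12h": amplitude, f"{r}|M|12h": amplitude},
        ),
        PlantedModuleSpec(
            "resistant_only", "rna", n_other,
            {f"{r}|M|6h": amplitude, f"{r}|M|12h": amplitude},
        ),
        PlantedModuleSpec(
            "late_both", "atac", n_other,
            {f"{s}|B|12h": amplitude, f"{r}|B|12h": amplitude},
        ),
    ]
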