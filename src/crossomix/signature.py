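"""Perturbation-informed drug-sensitivity signatures.

For each integrated module, the treatment response of a cell line is
summarized as dGFC = mean GFC(treated, early time point) - mean GFC(control),
and the module's threshold score as
thr_score = dGFC(sensitive line) - dGFC(resistant line). Modules with
thr_score strictly above the median (q50) over all modules — i.e. modules
whose regulation differs most between the sensitive and the resistant line —
feed the signature. Their member genes (layer namespace stripped, so an RNA
node and an ATAC node of the same gene count once) are intersected with the
baseline differential contrast between the two untreated cell lines: genes
up in the sensitive line form the up signature, genes down form the down
signature. Random and top-fold-change control signatures of matched size
support specificity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CrossomixError, split_namespace
from .network import ModuleTable


@dataclass
class Signature:
    """Disjoint up/down gene sets with construction provenance."""

    up: set[str]
    down: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise CrossomixError(f"up/down overlap: {sorted(overlap)[:5]}")

    def to_dict(self) -> dict:
        return {
            "up": sorted(self.up),
            "down": sorted(self.down),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(set(d["up"]), set(d["down"]), dict(d.get("provenance", {})))


def module_delta_gfc(
    module_means: pd.DataFrame,
    group_treated: str,
    group_control: str,
) -> pd.Series:
    """dGFC per module: mean GFC of the treated group minus the control
    group (both condition-group columns of ``module_means``)."""
    for g in (group_treated, group_control):
        if g not in module_means.columns:
            raise CrossomixError(f"missing condition group {g!r} in module means")
    out = module_means[group_treated] - module_means[group_control]
    out.name = "dgfc"
    return out


def module_threshold_scores(
    dgfc_sensitive: pd.Series, dgfc_resistant: pd.Series
) -> pd.DataFrame:
    """thr_score = dGFC(sensitive) - dGFC(resistant) per module; a module is
    selected iff its thr_score is strictly above the median (q50, midpoint
    interpolation for even counts)."""
    if set(dgfc_sensitive.index) != set(dgfc_resistant.index):
        raise CrossomixError("module sets differ between the two dGFC vectors")
    if len(dgfc_sensitive) < 2:
        raise CrossomixError("median selection needs >= 2 modules")
    thr = dgfc_sensitive - dgfc_resistant.reindex(dgfc_sensitive.index)
    q50 = float(np.median(thr.to_numpy()))
    return pd.DataFrame(
        {
            "dgfc_sensitive": dgfc_sensitive,
            "dgfc_resistant": dgfc_resistant.reindex(dgfc_sensitive.index),
            "thr_score": thr,
            "selected": thr > q50,
        }
    )


def module_gene_pool(modules: ModuleTable, selected: list[str]) -> set[str]:
    """Union of member gene names over the selected modules, with the layer
    namespace stripped and duplicates across layers collapsed."""
    pool: set[str] = set()
    for module_id in selected:
        for node in modules.members(module_id):
            pool.add(split_namespace(node)[1])
    return pool


def build_signature(
    modules: ModuleTable,
    selected: list[str],
    baseline_de: pd.DataFrame,
    padj_max: float = 0.01,
    lfc_min: float = 1.0,
    drug: str = "",
) -> Signature:
    """Intersect selected-module genes with the baseline contrast
    (sensitive vs resistant untreated controls).

    up = pool genes with padj < padj_max and log2fc > +lfc_min;
    down = pool genes with padj < padj_max and log2fc < -lfc_min.
    """
    if not selected:
        raise CrossomixError("no modules selected")
    pool = module_gene_pool(modules, selected)
    de = baseline_de[baseline_de.index.isin(pool)]
    sig_mask = de["padj"] < padj_max
    up = set(de.index[sig_mask & (de["log2fc"] > lfc_min)])
    down = set(de.index[sig_mask & (de["log2fc"] < -lfc_min)])
    if not up and not down:
        raise CrossomixError("empty signature")
    return Signature(
        up,
        down,
        provenance={
            "modules": list(selected),
            "padj_max": padj_max,
            "lfc_min": lfc_min,
            "drug": drug,
            "n_pool": len(pool),
        },
    )


def make_control_signature(
    universe: list[str],
    sizes: tuple[int, int],
    method: str = "random",
    baseline_de: pd.DataFrame | None = None,
    seed: int = 0,
) -> Signature:
    """Size-matched control signatures.

    ``random`` draws disjoint up/down sets uniformly without replacement
    from the universe; ``top_lfc`` takes the top ``n_up`` genes by baseline
    log2fc and the bottom ``n_down``.
    """
    n_up, n_down = sizes
    if n_up < 0 or n_down < 0 or (n_up + n_down) == 0:
        raise CrossomixError("signature sizes must be non-negative, not both 0")
    if len(universe) < n_up + n_down:
        raise CrossomixError(
            f"universe of {len(universe)} genes cannot supply {n_up}+{n_down}"
        )
    if method == "random":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(universe), size=n_up + n_down, replace=False)
        genes = [universe[i] for i in chosen]
        return Signature(
            set(genes[:n_up]), set(genes[n_up:]),
            provenance={"method": "random", "seed": seed},
        )
    if method == "top_lfc":
        if baseline_de is None:
            raise CrossomixError("top_lfc control needs a baseline DE table")
        de = baseline_de[baseline_de.index.isin(universe)]
        ranked = de["log2fc"].sort_values(ascending=False, kind="stable")
        up = set(ranked.index[:n_up])
        down = set(ranked.index[::-1][:n_down]) - up
        return Signature(up, down, provenance={"method": "top_lfc"})
    raise CrossomixError(f"unknown control method {method!r}")
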