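"""Differential-expression filtering: probe deduplication, fold-change /
p-value thresholding, and cross-condition concordance.

Operates on precomputed differential-expression statistics (the model
fitting itself, e.g. a moderated t-test, is upstream and out of scope).
The canonical table schema is a DataFrame with columns::

    probe_id, gene, log2fc, p_value, mean_expr

Selection uses strict inequalities: up-regulated means log2fc > cut and
p < p_cut; down-regulated means log2fc < -cut and p < p_cut. Two cutoff
presets are provided as module constants: a stringent microarray preset
(|log2FC| > 2, p < 0.01) and a permissive one (|log2FC| > 0.2630344 =
log2(1.2), p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

REQUIRED_COLUMNS = ("probe_id", "gene", "log2fc", "p_value", "mean_expr")

#: Stringent preset: |log2FC| > 2, p < 0.01.
STRICT_LFC_CUT, STRICT_P_CUT = 2.0, 0.01
#: Permissive preset: |log2FC| > log2(1.2) = 0.2630344..., p < 0.05.
FOLD_1P2_LFC_CUT, FOLD_1P2_P_CUT = 0.2630344, 0.05

#: Separators marking probes annotated to multiple genes.
MULTI_GENE_SEPARATORS = ("///", ";")


def _check_schema(t: pd.DataFrame, columns=REQUIRED_COLUMNS) -> None:
    missing = [c for c in columns if c not in t.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")


def load_deg_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, dtype={"probe_id": str, "gene": str})
    _check_schema(t)
    return t


def write_deg_table(t: pd.DataFrame, path: str | Path) -> None:
    t.to_csv(path, index=False)


def dedup_probes(t: pd.DataFrame) -> pd.DataFrame:
    """Collapse to one probe per gene.

    Probes whose gene annotation names multiple genes (contains '///'
    or ';') are dropped first; then, per gene, the probe with the
    highest mean expression is kept (ties broken by the lexicographically
    smallest probe id). Row order follows the input order of the kept
    probes.
    """
    _check_schema(t)
    if t["p_value"].lt(0).any() or t["p_value"].gt(1).any():
        raise ValidationError("p_value outside [0, 1]")
    gene = t["gene"].astype(str)
    multi = np.zeros(len(t), dtype=bool)
    for sep in MULTI_GENE_SEPARATORS:
        multi |= gene.str.contains(sep, regex=False).to_numpy()
    single = t.loc[~multi].copy()
    # sort so the first row per gene is (max mean_expr, min probe_id)
    single = single.sort_values(
        ["gene", "mean_expr", "probe_id"], ascending=[True, False, True], kind="mergesort"
    )
    kept = single.drop_duplicates("gene", keep="first")
    return kept.loc[sorted(kept.index)].reset_index(drop=True)


@dataclass(frozen=True)
class DEGResult:
    """Up/down-regulated gene lists with the cutoffs that produced them."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    lfc_cut: float
    p_cut: float

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(self.up) | frozenset(self.down)

    def direction(self, gene: str) -> int:
        """+1 if up-regulated, -1 if down-regulated."""
        if gene in self.up:
            return 1
        if gene in self.down:
            return -1
        raise KeyError(gene)


def filter_degs(t: pd.DataFrame, lfc_cut: float, p_cut: float) -> DEGResult:
    """Select up/down-regulated genes by strict |log2FC| and p cutoffs.

    Expects a deduplicated table (one probe per gene).
    """
    if lfc_cut < 0 or p_cut < 0:
        raise ValidationError("cutoffs must be non-negative")
    _check_schema(t)
    sig = t["p_value"] < p_cut
    up = t.loc[sig & (t["log2fc"] > lfc_cut), "gene"]
    down = t.loc[sig & (t["log2fc"] < -lfc_cut), "gene"]
    return DEGResult(tuple(up), tuple(down), lfc_cut, p_cut)


def consistent_degs(a: DEGResult, b: DEGResult) -> tuple[frozenset[str], frozenset[str]]:
    """Genes differentially expressed in both conditions.

    Returns (shared, concordant): shared is the intersection of the two
    DEG sets, concordant the subset changing in the same direction.
    """
    shared = a.all_genes & b.all_genes
    concordant = frozenset(g for g in shared if a.direction(g) == b.direction(g))
    return frozenset(shared), concordant


def volcano_table(t: pd.DataFrame, lfc_cut: float, p_cut: float) -> pd.DataFrame:
    """Volcano-plot-ready export: gene, log2fc, -log10(p), status."""
    _check_schema(t)
    res = filter_degs(t, lfc_cut, p_cut)
    status = np.where(
        t["gene"].isin(res.up), "up", np.where(t["gene"].isin(res.down), "down", "ns")
    )
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(t["p_value"].to_numpy())
    return pd.DataFrame(
        {"gene": t["gene"], "log2fc": t["log2fc"], "neg_log10_p": neglogp, "status": status}
    )
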