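"""Binding-affinity unit conversion, consensus averaging, and threshold
screening of predicted-affinity tables.

Predicted binding affinities (BA) are free energies in kcal/mol; more
negative means stronger binding. The conversion from an inhibition
constant Ki (molar) uses dG = RT ln(Ki) at T = 298 K, expressed per
log10 unit as 1.3633 kcal/mol, so Ki = 100 nM corresponds to
-9.54 kcal/mol — the classic potency bar for screening.

Screening keeps records at least as strong as a cutoff (BA <= cutoff);
binning splits a table along a strictly increasing list of cutoffs,
each bin inclusive on its weaker side, with records weaker than the
last cutoff reported separately.

Six small reference tables of published affinity predictions for three
addiction-related targets (mTOR, mGluR5, NMDAR; approved and
investigational DrugBank compounds) ship with the package, see
:func:`load_reference_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

#: kcal/mol per log10 unit of Ki: RT * ln(10) at T = 298 K
#: (R = 1.987e-3 kcal/(mol K)).
KCAL_PER_LOG10_KI = 1.3633

#: The 100 nM potency bar expressed in kcal/mol (2 d.p.: -9.54).
HUNDRED_NM_CUTOFF = KCAL_PER_LOG10_KI * math.log10(100e-9)

TABLE_COLUMNS = ("drug_id", "name", "ba_kcal_mol")

REFERENCE_TABLES = (
    "mtor_approved",
    "mtor_investigational",
    "mglur5_approved",
    "mglur5_investigational",
    "nmdar_approved",
    "nmdar_investigational",
)


def ki_to_binding_affinity(ki: float) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant (M).

    BA = 1.3633 * log10(Ki); strictly increasing, BA(1 M) = 0.
    Any molar potency (Ki or IC50) is converted identically.
    """
    if not (ki > 0 and math.isfinite(ki)):
        raise ValidationError(f"Ki must be a positive finite molar value, got {ki!r}")
    return KCAL_PER_LOG10_KI * math.log10(ki)


def binding_affinity_to_ki(ba: float) -> float:
    """Inverse of :func:`ki_to_binding_affinity` (kcal/mol -> M)."""
    if not math.isfinite(ba):
        raise ValidationError(f"binding affinity must be finite, got {ba!r}")
    return 10.0 ** (ba / KCAL_PER_LOG10_KI)


def consensus(preds: Iterable[float], n_models: int | None = 3, compound: str = "?") -> float:
    """Consensus binding affinity: the arithmetic mean of per-model
    predictions for one compound.

    By default exactly ``n_models`` = 3 finite predictions are expected
    (pass None to accept any positive count); anything missing or
    non-finite raises naming the compound.
    """
    values = list(preds)
    if not values or any(v is None or not math.isfinite(v) for v in values):
        raise ValidationError(f"compound {compound!r}: missing or non-finite prediction")
    if n_models is not None and len(values) != n_models:
        raise ValidationError(
            f"compound {compound!r}: expected {n_models} predictions, got {len(values)}"
        )
    return sum(values) / len(values)


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if table["drug_id"].duplicated().any():
        dup = table.loc[table["drug_id"].duplicated(), "drug_id"].iloc[0]
        raise ValidationError(f"duplicate drug_id {dup!r}")
    if not table["ba_kcal_mol"].map(math.isfinite).all():
        raise ValidationError("non-finite binding affinity in table")


def filter_by_affinity(table: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Records binding at least as strongly as ``cutoff`` (BA <= cutoff),
    original order preserved."""
    if not math.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    _check_table(table)
    return table.loc[table["ba_kcal_mol"] <= cutoff].reset_index(drop=True)


@dataclass(frozen=True)
class AffinityBins:
    """Counts per affinity bin plus the records weaker than every cutoff."""

    cutoffs: tuple[float, ...]
    counts: tuple[int, ...]
    bins: tuple[pd.DataFrame, ...]
    excluded: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def bin_by_affinity(table: pd.DataFrame, cutoffs: Sequence[float]) -> AffinityBins:
    """Split a table along strength cutoffs.

    ``cutoffs`` must be strictly increasing as numbers (strongest
    first, e.g. (-11, -10, -9.54)). Bin 1 holds BA <= cutoffs[0]; bin i
    holds cutoffs[i-1] < BA <= cutoffs[i]; records with BA above the
    last cutoff are excluded and reported separately.
    """
    cut = tuple(float(c) for c in cutoffs)
    if not cut or any(b <= a for a, b in zip(cut, cut[1:])):
        raise ValidationError(f"cutoffs must be non-empty and strictly increasing, got {cut}")
    _check_table(table)
    ba = table["ba_kcal_mol"]
    frames: list[pd.DataFrame] = []
    lo = -math.inf
    for c in cut:
        frames.append(table.loc[(ba > lo) & (ba <= c)].reset_index(drop=True))
        lo = c
    excluded = table.loc[ba > cut[-1]].reset_index(drop=True)
    return AffinityBins(cut, tuple(len(f) for f in frames), tuple(frames), excluded)


# -- I/O and bundled reference tables ---------------------------------


def load_affinity_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"drug_id": str, "name": str})
    _check_table(table)
    return table


def write_affinity_csv(table: pd.DataFrame, path: str | Path) -> None:
    _check_table(table)
    table.to_csv(path, index=False)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the bundled published prediction tables.

    ``name`` is one of :data:`REFERENCE_TABLES` (target x approval
    status). Each table has columns drug_id, name, ba_kcal_mol.
    """
    if name not in REFERENCE_TABLES:
        raise ValidationError(f"unknown table {name!r}; options: {REFERENCE_TABLES}")
    ref = resources.files("topodiff").joinpath(f"data/{name}.csv")
    with resources.as_file(ref) as path:
        return load_affinity_csv(path)
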