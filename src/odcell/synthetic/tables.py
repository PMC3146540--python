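"""Synthetic OD-normalised omics tables with conversion ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..reference import CONSTANTS, ReferenceTable, load_reference_table

__all__ = ["generate_omics_table"]

#: the only accepted input unit for OD-normalised amounts
UNIT_TAG = "mol/ml/OD"


def generate_omics_table(
    n_analytes: int,
    condition_id: str,
    amount_range: tuple = (1e-12, 1e-8),
    seed: int = 0,
    table: ReferenceTable | None = None,
):
    """Log-uniform analyte amounts plus their true per-cell conversions.

    Returns ``(omics, truth)``: ``omics`` has columns ``analyte_id``,
    ``amount_mol_per_ml_od`` and ``unit``; ``truth`` adds the true copies
    per cell and molar concentration computed from the condition's tabulated
    OD-specific cell concentration and total cell volume.
    """
    if table is None:
        table = load_reference_table()
    rec = table.get(condition_id)  # raises KeyError for unknown conditions
    if n_analytes < 0:
        raise ValueError("n_analytes must be non-negative")
    lo, hi = amount_range
    if not (0 < lo <= hi):
        raise ValueError("amount_range must be positive and ordered")

    rng = np.random.default_rng(seed)
    amounts = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n_analytes)
    omics = pd.DataFrame({
        "analyte_id": [f"analyte_{i:04d}" for i in range(n_analytes)],
        "amount_mol_per_ml_od": amounts,
        "unit": UNIT_TAG,
    })
    n_per_ml_od = rec.conc_per_ml_od
    vtot_l = rec.vtot_ul.mean * 1e-6
    truth = omics.drop(columns="unit").assign(
        true_copies_per_cell=amounts * CONSTANTS.avogadro / n_per_ml_od,
        true_conc_molar=amounts / vtot_l,
        condition_id=rec.condition_id,
    )
    return omics, truth
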