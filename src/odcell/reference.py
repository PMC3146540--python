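"""Embedded reference dataset: per-condition E. coli cell parameters.

The table below holds, for 24 growth conditions, the growth rate, mean cell
length and width, single-cell volume, OD-specific cell concentration and
OD-specific total cell volume, together with one-sigma standard deviations
where available.  It is shipped inside the package; nothing is fetched at
runtime.

Units follow the source table exactly: lengths in µm, volumes in fl
(1 fl = 1 µm³), concentrations in 10⁸ cells·ml⁻¹·OD⁻¹ and total volume in
µl·ml⁻¹·OD⁻¹.  SI accessors are provided on :class:`ConditionRecord`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Measured",
    "ConditionRecord",
    "ReferenceTable",
    "Constants",
    "CONSTANTS",
    "TotalVolumeSummary",
    "load_reference_table",
    "get_condition",
    "tabulate_total_volume",
]


@dataclass(frozen=True)
class Measured:
    """A mean with an optional one-sigma standard deviation.

    ``sd`` is ``None`` when the source prints no deviation (never 0.0, so a
    genuine zero spread remains distinguishable from "not reported").
    """

    mean: float
    sd: Optional[float] = None

    @property
    def cv(self) -> Optional[float]:
        """Coefficient of variation, or None when no SD is available."""
        if self.sd is None or self.mean == 0:
            return None
        return self.sd / self.mean

    def __float__(self) -> float:
        return float(self.mean)


@dataclass(frozen=True)
class ConditionRecord:
    """One growth condition with its measured cell parameters."""

    condition_id: str
    category: str  # complex | carbon_source | stress | chemostat | stationary
    strain: str  # BW25113 | MG1655
    mu: Measured  # growth rate, 1/h
    length_um: Measured
    width_um: Measured
    volume_fl: Measured
    conc_e8: Measured  # 1e8 cells/ml/OD
    vtot_ul: Measured  # µl/ml/OD (no SD printed in source)

    @property
    def conc_per_ml_od(self) -> float:
        """OD-specific cell concentration in cells·ml⁻¹·OD⁻¹."""
        return self.conc_e8.mean * 1e8

    @property
    def volume_l(self) -> float:
        """Single-cell volume in litres (1 fl = 1e-15 L)."""
        return self.volume_fl.mean * 1e-15

    @property
    def is_growing(self) -> bool:
        return self.mu.mean > 0


@dataclass(frozen=True)
class Constants:
    """Fixed physical and protocol constants used across the package."""

    mean_width_um: float = 1.26  # population-average cell width, all conditions
    width_sd_um: float = 0.16
    vtot_global_ul: float = 3.6  # total cell volume per ml per OD unit
    avogadro: float = 6.02214076e23
    pixel_um: float = 0.092  # microscope resolution, µm per pixel
    bead_diameter_um: float = 7.0  # counting-bead nominal diameter
    bead_aliquot_ul: float = 20.0  # bead volume spiked into the tube
    sample_aliquot_ul: float = 380.0  # cell-suspension volume in the tube
    daytoday_cv: float = 0.10  # replicate-level concentration CV bound
    stationary_pseudo_mu: float = 0.1  # plotting/fitting stand-in for µ = 0


CONSTANTS = Constants()

# (id, category, strain, mu, mu_sd, l, l_sd, w, w_sd, V, V_sd, N, N_sd, vtot)
_ROWS = [
    ("LB", "complex", "BW25113", 1.61, 0.05, 3.9, 0.9, 1.3, 0.2, 4.4, 1.1, 7.8, 0.8, 3.4),
    ("LB_MG1655", "complex", "MG1655", 1.62, 0.04, 3.5, 0.9, 1.4, 0.1, 3.9, 1.2, 7.5, 0.8, 2.9),
    ("glucose_AA", "complex", "BW25113", 1.49, 0.05, 3.5, 1.0, 1.5, 0.1, 4.0, 1.3, 5.9, 0.6, 2.4),
    ("mannose_AA", "complex", "BW25113", 1.28, 0.07, 3.7, 0.9, 1.5, 0.2, 4.1, 1.2, 6.3, 0.6, 2.5),
    ("glycerol_AA", "complex", "BW25113", 1.26, 0.04, 3.5, 0.9, 1.5, 0.1, 3.9, 1.2, 8.2, 0.8, 3.2),
    ("acetate", "carbon_source", "BW25113", 0.29, 0.02, 2.3, 0.6, 1.2, 0.1, 2.4, 1.3, 16.8, 1.7, 4.0),
    ("fumarate", "carbon_source", "BW25113", 0.47, 0.03, 2.4, 0.6, 1.1, 0.1, 2.4, 1.2, 17.0, 1.7, 4.1),
    ("galactose", "carbon_source", "BW25113", 0.17, 0.02, 2.0, 0.5, 1.1, 0.1, 1.9, 1.2, 19.9, 2.0, 3.8),
    ("glucose", "carbon_source", "BW25113", 0.60, 0.05, 3.0, 0.7, 1.4, 0.2, 3.2, 1.2, 11.1, 1.1, 3.6),
    ("glucose_MG1655", "carbon_source", "MG1655", 0.67, 0.05, 2.8, 0.7, 1.4, 0.2, 3.0, 1.3, 11.0, 1.1, 3.3),
    ("glucosamine", "carbon_source", "BW25113", 0.39, 0.03, 2.7, 0.7, 1.3, 0.1, 2.9, 1.3, 12.2, 1.2, 3.5),
    ("glycerol", "carbon_source", "BW25113", 0.47, 0.03, 2.3, 0.6, 1.2, 0.1, 2.3, 1.3, 19.6, 2.0, 4.5),
    ("pyruvate", "carbon_source", "BW25113", 0.40, 0.03, 2.2, 0.6, 1.0, 0.1, 2.1, 1.2, 21.0, 2.1, 4.5),
    ("succinate", "carbon_source", "BW25113", 0.49, 0.02, 2.4, 0.6, 1.1, 0.2, 2.4, 1.3, 16.7, 1.7, 4.1),
    ("anaerobic", "stress", "BW25113", 0.55, 0.01, 2.8, 0.7, 1.3, 0.2, 2.9, 1.2, 10.4, 1.0, 3.1),
    ("NaCl_50mM", "stress", "BW25113", 0.65, 0.02, 2.6, 0.7, 1.3, 0.2, 2.8, 1.2, 11.3, 1.1, 3.1),
    ("pH6", "stress", "BW25113", 0.50, 0.11, 2.9, 0.8, 1.3, 0.2, 3.1, 1.3, 10.5, 1.1, 3.3),
    ("42C", "stress", "BW25113", 0.65, 0.02, 2.7, 0.7, 1.3, 0.2, 2.8, 1.2, 11.0, 1.1, 3.1),
    ("chemostat_0.50", "chemostat", "BW25113", 0.50, None, 2.5, 1.2, 1.2, 0.2, 2.6, 1.9, 13.4, 1.3, 3.5),
    ("chemostat_0.35", "chemostat", "BW25113", 0.35, None, 2.4, 1.0, 1.0, 0.1, 2.4, 1.7, 19.7, 2.0, 4.8),
    ("chemostat_0.20", "chemostat", "BW25113", 0.20, None, 2.2, 1.0, 1.0, 0.1, 2.2, 1.8, 20.6, 2.1, 4.5),
    ("chemostat_0.12", "chemostat", "BW25113", 0.12, None, 2.1, 1.1, 1.1, 0.1, 2.1, 1.9, 23.0, 2.3, 4.9),
    ("stationary_1d", "stationary", "BW25113", 0.00, None, 1.6, 0.4, 1.1, 0.2, 1.5, 1.2, 21.9, 2.2, 3.3),
    ("stationary_3d", "stationary", "BW25113", 0.00, None, 1.7, 0.3, 1.4, 0.1, 1.6, 1.1, 22.9, 2.3, 3.7),
]

# extra lookup spellings -> canonical id (keys are in normalised form)
_ALIASES = {
    "stationary1day": "stationary_1d",
    "stationary3days": "stationary_3d",
    "stationary3day": "stationary_3d",
    "nacl": "NaCl_50mM",
    "50mmnacl": "NaCl_50mM",
    "lbmg": "LB_MG1655",
    "glucosemg": "glucose_MG1655",
    "chemostat05": "chemostat_0.50",
    "chemostat02": "chemostat_0.20",
    "chemostatmu050": "chemostat_0.50",
    "chemostatmu035": "chemostat_0.35",
    "chemostatmu020": "chemostat_0.20",
    "chemostatmu012": "chemostat_0.12",
}


def _normalise(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "", label.lower())


class ReferenceTable(Sequence[ConditionRecord]):
    """Ordered, immutable collection of :class:`ConditionRecord`.

    Supports integer indexing (table order) and label lookup, which is
    case-insensitive and tolerant of punctuation (``"42°C"`` and ``"42C"``
    resolve to the same record).
    """

    def __init__(self, records: Sequence[ConditionRecord]):
        self._records = tuple(records)
        self._by_key = {_normalise(r.condition_id): r for r in self._records}
        for alias, target in _ALIASES.items():
            if _normalise(target) in self._by_key:
                self._by_key.setdefault(alias, self._by_key[_normalise(target)])

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ConditionRecord]:
        return iter(self._records)

    def __getitem__(self, key):
        if isinstance(key, (int, slice)):
            return self._records[key]
        return self.get(key)

    def get(self, condition_id: str) -> ConditionRecord:
        rec = self._by_key.get(_normalise(condition_id))
        if rec is None:
            valid = ", ".join(r.condition_id for r in self._records)
            raise KeyError(
                f"unknown condition {condition_id!r}; valid labels: {valid}"
            )
        return rec

    @property
    def condition_ids(self) -> tuple:
        return tuple(r.condition_id for r in self._records)

    def filter(self, *, strain: Optional[str] = None,
               category: Optional[str] = None,
               growing: Optional[bool] = None) -> "ReferenceTable":
        recs = self._records
        if strain is not None:
            recs = [r for r in recs if r.strain == strain]
        if category is not None:
            recs = [r for r in recs if r.category == category]
        if growing is not None:
            recs = [r for r in recs if r.is_growing == growing]
        return ReferenceTable(recs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self._records:
            rows.append({
                "condition_id": r.condition_id,
                "category": r.category,
                "strain": r.strain,
                "mu_per_h": r.mu.mean,
                "mu_sd": r.mu.sd,
                "length_um": r.length_um.mean,
                "length_sd_um": r.length_um.sd,
                "width_um": r.width_um.mean,
                "width_sd_um": r.width_um.sd,
                "volume_fl": r.volume_fl.mean,
                "volume_sd_fl": r.volume_fl.sd,
                "conc_e8_per_ml_od": r.conc_e8.mean,
                "conc_e8_sd": r.conc_e8.sd,
                "vtot_ul_per_ml_od": r.vtot_ul.mean,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Write the table as UTF-8 CSV, one row per condition, table order."""
        self.to_dataframe().to_csv(path, index=False)


def load_reference_table() -> ReferenceTable:
    """Return the embedded 24-condition reference table."""
    records = []
    for (cid, cat, strain, mu, mu_sd, l, l_sd, w, w_sd, v, v_sd,
         n, n_sd, vtot) in _ROWS:
        records.append(ConditionRecord(
            condition_id=cid,
            category=cat,
            strain=strain,
            mu=Measured(mu, mu_sd),
            length_um=Measured(l, l_sd),
            width_um=Measured(w, w_sd),
            volume_fl=Measured(v, v_sd),
            conc_e8=Measured(n, n_sd),
            vtot_ul=Measured(vtot, None),
        ))
    return ReferenceTable(records)


def get_condition(condition_id: str,
                  table: Optional[ReferenceTable] = None) -> ConditionRecord:
    """Look up one condition record by (case-insensitive) label."""
    if table is None:
        table = load_reference_table()
    return table.get(condition_id)


@dataclass(frozen=True)
class TotalVolumeSummary:
    n: int
    mean: float
    sd: float  # 0.0 for a single row, by convention
    min: float
    max: float
    ratio: float  # max / min


def tabulate_total_volume(table: ReferenceTable) -> TotalVolumeSummary:
    """Summarise the OD-specific total-cell-volume column of ``table``."""
    if len(table) == 0:
        raise ValueError("empty reference table")
    v = np.array([r.vtot_ul.mean for r in table], dtype=float)
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return TotalVolumeSummary(
        n=len(v),
        mean=float(np.mean(v)),
        sd=sd,
        min=float(np.min(v)),
        max=float(np.max(v)),
        ratio=float(np.max(v) / np.min(v)),
    )
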