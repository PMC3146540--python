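"""Convert OD-normalised amounts to copies per cell and molar concentration.

The two conversions are

* ``copies/cell = amount · N_A / N`` with ``N`` the OD-specific cell
  concentration (cells·ml⁻¹·OD⁻¹), and
* ``mol/L = amount / (V_tot · 10⁻⁶)`` with ``V_tot`` the OD-specific total
  cell volume (µl·ml⁻¹·OD⁻¹),

for amounts in mol·ml⁻¹·OD⁻¹ (the unit tag is mandatory — untagged numbers
are refused).  Uncertainty is propagated either by Monte Carlo over
log-normal factor distributions or by a first-order delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .growth import TotalVolumeFit, VolumeModel, fit_total_volume, fit_volume_vs_mu
from .reference import CONSTANTS, ReferenceTable, load_reference_table

__all__ = [
    "UNIT_TAG",
    "OmicsRecord",
    "ConversionFactors",
    "resolve_factors",
    "to_copies_per_cell",
    "to_molar",
    "convert_table",
    "OdCalibration",
    "calibrate_od",
]

UNIT_TAG = "mol/ml/OD"
_ACCEPTED_TAGS = {UNIT_TAG, "mol·ml⁻¹·OD⁻¹", "mol/ml/od"}


@dataclass(frozen=True)
class OmicsRecord:
    """One analyte amount normalised to sample volume and optical density."""

    analyte_id: str
    amount_mol_per_ml_od: float
    sd: Optional[float] = None
    unit: Optional[str] = UNIT_TAG

    def __post_init__(self):
        if self.unit is None or str(self.unit).strip() == "":
            raise ValueError(
                f"analyte {self.analyte_id!r} carries no unit tag; amounts "
                f"must be explicitly tagged {UNIT_TAG!r}"
            )
        if str(self.unit) not in _ACCEPTED_TAGS:
            raise ValueError(
                f"unsupported unit {self.unit!r} for {self.analyte_id!r}; "
                f"expected {UNIT_TAG!r}"
            )
        if self.amount_mol_per_ml_od < 0:
            raise ValueError("amount must be non-negative")


def to_copies_per_cell(record: OmicsRecord, n_cells_per_ml_od: float) -> float:
    """Copies per cell: ``amount · N_A / N``."""
    if n_cells_per_ml_od <= 0:
        raise ValueError("cell concentration must be strictly positive")
    return record.amount_mol_per_ml_od * CONSTANTS.avogadro / n_cells_per_ml_od


def to_molar(record: OmicsRecord, vtot_ul_per_ml_od: float) -> float:
    """Intracellular molar concentration: ``amount / (V_tot · 10⁻⁶ L)``."""
    if vtot_ul_per_ml_od <= 0:
        raise ValueError("total cell volume must be strictly positive")
    return record.amount_mol_per_ml_od / (vtot_ul_per_ml_od * 1e-6)


@dataclass(frozen=True)
class ConversionFactors:
    """Resolved conversion factors with provenance.

    ``source`` is ``"table"`` when the factors come from a tabulated
    condition and ``"model"`` when they come from the fitted growth models.
    ``vtot_policy`` records how the total volume was chosen: the tabulated
    column (``"printed"``), the product V·N (``"product"``, which makes the
    two conversions exactly consistent), or the fitted global constant
    (``"global"``).
    """

    n_per_ml_od: float
    n_sd: Optional[float]
    volume_fl: float
    volume_sd: Optional[float]
    vtot_ul: float
    source: str
    vtot_policy: str
    condition_id: Optional[str] = None
    mu: Optional[float] = None

    @property
    def n_cv(self) -> float:
        return 0.0 if self.n_sd is None else self.n_sd / self.n_per_ml_od

    @property
    def volume_cv(self) -> float:
        return 0.0 if self.volume_sd is None else self.volume_sd / self.volume_fl

    @property
    def vtot_cv(self) -> float:
        # no SD is tabulated for the total volume; propagate from V and N
        return float(np.hypot(self.n_cv, self.volume_cv))


def resolve_factors(
    condition_id: Optional[str] = None,
    mu: Optional[float] = None,
    table: Optional[ReferenceTable] = None,
    volume_model: Optional[VolumeModel] = None,
    vtot_fit: Optional[TotalVolumeFit] = None,
    vtot_policy: str = "printed",
    force: bool = False,
) -> ConversionFactors:
    """Resolve N, V and V_tot for a condition label or a growth rate."""
    if (condition_id is None) == (mu is None):
        raise ValueError("give exactly one of condition_id or mu")
    if table is None:
        table = load_reference_table()
    if vtot_policy not in ("printed", "product", "global"):
        raise ValueError(f"unknown vtot_policy {vtot_policy!r}")

    if condition_id is not None:
        rec = table.get(condition_id)
        n = rec.conc_per_ml_od
        v = rec.volume_fl.mean
        if vtot_policy == "printed":
            vtot = rec.vtot_ul.mean
        elif vtot_policy == "product":
            vtot = v * n * 1e-9  # fl·cells -> µl
        else:
            vtot = (vtot_fit or fit_total_volume(table)).vtot_hat
        return ConversionFactors(
            n_per_ml_od=n,
            n_sd=None if rec.conc_e8.sd is None else rec.conc_e8.sd * 1e8,
            volume_fl=v,
            volume_sd=rec.volume_fl.sd,
            vtot_ul=vtot,
            source="table",
            vtot_policy=vtot_policy,
            condition_id=rec.condition_id,
        )

    if volume_model is None:
        volume_model = fit_volume_vs_mu(table)
    if vtot_fit is None:
        vtot_fit = fit_total_volume(table)
    v = volume_model.predict(mu, force=force)
    vtot = vtot_fit.vtot_hat
    n = vtot * 1e9 / v
    n_sd = n * float(np.hypot(vtot_fit.sd / vtot, volume_model.residual_sd / v))
    return ConversionFactors(
        n_per_ml_od=n,
        n_sd=n_sd,
        volume_fl=v,
        volume_sd=volume_model.residual_sd,
        vtot_ul=vtot if vtot_policy != "product" else v * n * 1e-9,
        source="model",
        vtot_policy=vtot_policy,
        mu=mu,
    )


def _as_records(omics) -> list:
    if isinstance(omics, pd.DataFrame):
        recs = []
        for row in omics.itertuples(index=False):
            recs.append(OmicsRecord(
                analyte_id=str(row.analyte_id),
                amount_mol_per_ml_od=float(row.amount_mol_per_ml_od),
                sd=float(row.sd) if "sd" in omics.columns and pd.notna(row.sd) else None,
                unit=getattr(row, "unit", None),
            ))
        return recs
    return list(omics)


def _lognormal_params(mean: float, sd: float) -> tuple:
    """(mu, sigma) of a median-matched log-normal for a positive factor.

    The median is pinned to the reported central value and sigma is set
    from the coefficient of variation (``sigma² = ln(1 + cv²)``), keeping
    the plug-in point estimate at the centre of the sampled distribution.
    """
    cv2 = (sd / mean) ** 2
    return np.log(mean), np.sqrt(np.log1p(cv2))


def convert_table(
    omics: Union[pd.DataFrame, Sequence[OmicsRecord]],
    condition_id: Optional[str] = None,
    mu: Optional[float] = None,
    table: Optional[ReferenceTable] = None,
    vtot_policy: str = "printed",
    method: str = "mc",
    mc_samples: int = 10000,
    seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Convert every analyte; returns a tidy result table with SDs.

    Point estimates are plug-in values from the resolved factors.  SDs come
    from Monte Carlo over independent log-normal N and V distributions
    (``method="mc"``, seeded) or from a first-order delta method
    (``method="delta"``).
    """
    factors = resolve_factors(condition_id=condition_id, mu=mu, table=table,
                              vtot_policy=vtot_policy, force=force)
    records = _as_records(omics)
    if method not in ("mc", "delta"):
        raise ValueError(f"unknown method {method!r}")
    if method == "mc" and mc_samples < 100:
        warnings.warn("fewer than 100 Monte Carlo samples: SDs will be noisy")

    if method == "mc":
        rng = np.random.default_rng(seed)
        if factors.n_sd:
            m, s = _lognormal_params(factors.n_per_ml_od, factors.n_sd)
            n_s = np.exp(rng.normal(m, s, mc_samples))
        else:
            n_s = np.full(mc_samples, factors.n_per_ml_od)
        if factors.volume_sd:
            m, s = _lognormal_params(factors.volume_fl, factors.volume_sd)
            v_s = np.exp(rng.normal(m, s, mc_samples))
        else:
            v_s = np.full(mc_samples, factors.volume_fl)
        # keep the sampled total volume consistent with the sampled V and N
        # (relative spread is what matters; the central value follows the
        # chosen policy)
        vtot_s = factors.vtot_ul * (v_s * n_s) / (factors.volume_fl * factors.n_per_ml_od)

    rows = []
    for rec in records:
        a = rec.amount_mol_per_ml_od
        copies = to_copies_per_cell(rec, factors.n_per_ml_od)
        molar = to_molar(rec, factors.vtot_ul)
        a_cv = 0.0 if (rec.sd is None or a == 0) else rec.sd / a
        if method == "delta" or a == 0:
            copies_sd = copies * float(np.hypot(a_cv, factors.n_cv))
            molar_sd = molar * float(np.hypot(a_cv, factors.vtot_cv))
        else:
            if rec.sd:
                m, s = _lognormal_params(a, rec.sd)
                a_s = np.exp(rng.normal(m, s, mc_samples))
            else:
                a_s = a
            copies_sd = float(np.std(a_s * CONSTANTS.avogadro / n_s, ddof=1))
            molar_sd = float(np.std(a_s / (vtot_s * 1e-6), ddof=1))
        rows.append({
            "analyte_id": rec.analyte_id,
            "copies_per_cell": copies,
            "copies_per_cell_sd": copies_sd,
            "conc_molar": molar,
            "conc_molar_sd": molar_sd,
            "n_per_ml_od": factors.n_per_ml_od,
            "volume_fl": factors.volume_fl,
            "vtot_ul_per_ml_od": factors.vtot_ul,
            "factor_source": factors.source,
            "vtot_policy": factors.vtot_policy,
            "condition_id": factors.condition_id,
            "mu": factors.mu,
            "method": method,
            "seed": seed if method == "mc" else None,
        })
    columns = ["analyte_id", "copies_per_cell", "copies_per_cell_sd",
               "conc_molar", "conc_molar_sd", "n_per_ml_od", "volume_fl",
               "vtot_ul_per_ml_od", "factor_source", "vtot_policy",
               "condition_id", "mu", "method", "seed"]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class OdCalibration:
    """Monotone device→reference OD map (PCHIP in log-log space)."""

    device_nodes: np.ndarray
    reference_nodes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "_interp", PchipInterpolator(
            np.log10(self.device_nodes), np.log10(self.reference_nodes)
        ))

    def __call__(self, device_od):
        x = np.asarray(device_od, dtype=float)
        if np.any(x <= 0):
            raise ValueError("OD readings must be strictly positive")
        lo, hi = self.device_nodes[0], self.device_nodes[-1]
        clipped = np.clip(x, lo, hi)
        if np.any(clipped != x):
            warnings.warn(
                "device OD outside the calibrated range "
                f"[{lo:g}, {hi:g}]: output clamped to the range edge"
            )
        out = 10 ** self._interp(np.log10(clipped))
        return float(out) if np.isscalar(device_od) else out


def calibrate_od(device_od: Sequence[float],
                 reference_od: Sequence[float]) -> OdCalibration:
    """Fit a shape-preserving monotone device→reference OD correction.

    Pairs are sorted by device reading; duplicate device readings are
    averaged.  Both coordinates must then be strictly increasing, otherwise
    the device response is not invertible and an error is raised.  Requires
    at least 4 pairs.
    """
    d = np.asarray(device_od, dtype=float)
    r = np.asarray(reference_od, dtype=float)
    if d.shape != r.shape:
        raise ValueError("device and reference arrays differ in length")
    if len(d) < 4:
        raise ValueError("need at least 4 calibration pairs")
    if np.any(d <= 0) or np.any(r <= 0):
        raise ValueError("OD values must be strictly positive")
    order = np.argsort(d)
    d, r = d[order], r[order]
    # average duplicate device readings (simple denoising)
    uniq, inv = np.unique(d, return_inverse=True)
    if len(uniq) < len(d):
        r = np.array([r[inv == i].mean() for i in range(len(uniq))])
        d = uniq
    if len(d) < 4:
        raise ValueError("fewer than 4 distinct device readings")
    if not (np.all(np.diff(d) > 0) and np.all(np.diff(r) > 0)):
        raise ValueError("calibration pairs are not monotone after denoising")
    return OdCalibration(device_nodes=d, reference_nodes=r)
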