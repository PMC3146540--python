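"""Growth-rate-dependent models: V(µ), N(µ) and the total-volume constant.

Cell volume is fitted as a polynomial in log10(µ) (degree 2 by default,
the smallest degree capturing the curvature on a log axis).  OD-specific
cell concentration is modelled as the fitted total-volume constant divided
by the condition-dependent cell volume.  Stationary rows (µ = 0) enter the
volume fit at a pseudo growth rate of 0.1 but are excluded from the
concentration model's domain, where a growth rate is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .reference import CONSTANTS, ReferenceTable, load_reference_table

__all__ = [
    "VolumeModel",
    "TotalVolumeFit",
    "fit_volume_vs_mu",
    "fit_total_volume",
    "predict_volume",
    "predict_cell_concentration",
]

#: observed growth-rate range of the reference table, 1/h
MU_DOMAIN = (0.12, 1.62)


@dataclass(frozen=True)
class VolumeModel:
    """Polynomial in log10(µ) mapping growth rate to cell volume (fl)."""

    coefficients: tuple  # numpy order, highest power first
    degree: int
    residual_sd: float
    mu_range: tuple  # growth rates spanned by the fit (pseudo-µ included)
    stationary_pseudo_mu: Optional[float]
    n: int

    def predict(self, mu, force: bool = False):
        """Predicted volume (fl) at growth rate ``mu`` (1/h).

        Refuses extrapolation outside the fitted range unless ``force``.
        """
        mu_arr = np.asarray(mu, dtype=float)
        if np.any(mu_arr <= 0):
            raise ValueError("growth rate must be strictly positive; map "
                             "stationary cells to a pseudo growth rate first")
        lo, hi = self.mu_range
        if not force and (np.any(mu_arr < lo) or np.any(mu_arr > hi)):
            raise ValueError(
                f"growth rate outside the fitted range [{lo:g}, {hi:g}] 1/h; "
                "pass force=True to extrapolate"
            )
        v = np.polyval(self.coefficients, np.log10(mu_arr))
        return float(v) if np.isscalar(mu) else v

    def is_monotone(self, lo: float = None, hi: float = None,
                    n_grid: int = 512) -> bool:
        """Numerically check non-decreasing volume over [lo, hi]."""
        lo = self.mu_range[0] if lo is None else lo
        hi = self.mu_range[1] if hi is None else hi
        grid = np.geomspace(lo, hi, n_grid)
        pred = np.polyval(self.coefficients, np.log10(grid))
        return bool(np.all(np.diff(pred) >= -1e-12))


def fit_volume_vs_mu(
    table: Optional[ReferenceTable] = None,
    degree: int = 2,
    include_stationary: bool = True,
    stationary_pseudo_mu: Optional[float] = None,
) -> VolumeModel:
    """Least-squares polynomial fit of cell volume against log10(µ).

    Stationary rows are either mapped to ``stationary_pseudo_mu`` (default
    0.1, matching how they are plotted on a log axis) or dropped when
    ``include_stationary`` is false.
    """
    if table is None:
        table = load_reference_table()
    if stationary_pseudo_mu is None and include_stationary:
        stationary_pseudo_mu = CONSTANTS.stationary_pseudo_mu

    mus, vols = [], []
    for rec in table:
        mu = rec.mu.mean
        if mu <= 0:
            if not include_stationary:
                continue
            if stationary_pseudo_mu is None or stationary_pseudo_mu <= 0:
                raise ValueError(
                    "non-positive growth rate in fit data and no positive "
                    "pseudo growth rate configured"
                )
            mu = stationary_pseudo_mu
        mus.append(mu)
        vols.append(rec.volume_fl.mean)
    mus = np.asarray(mus)
    vols = np.asarray(vols)
    if len(mus) < degree + 1:
        raise ValueError(
            f"need at least degree + 1 = {degree + 1} records, got {len(mus)}"
        )
    x = np.log10(mus)
    coeffs = np.polyfit(x, vols, degree)
    resid = vols - np.polyval(coeffs, x)
    dof = len(mus) - (degree + 1)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / dof)) if dof > 0 else 0.0
    model = VolumeModel(
        coefficients=tuple(float(c) for c in coeffs),
        degree=degree,
        residual_sd=residual_sd,
        mu_range=(float(mus.min()), float(mus.max())),
        stationary_pseudo_mu=stationary_pseudo_mu if include_stationary else None,
        n=len(mus),
    )
    if not model.is_monotone():
        warnings.warn("fitted volume model is not monotone non-decreasing "
                      "over the observed growth-rate range")
    return model


@dataclass(frozen=True)
class TotalVolumeFit:
    """OD-specific total-cell-volume constant, µl·ml⁻¹·OD⁻¹."""

    vtot_hat: float
    sd: float
    n: int


def fit_total_volume(table: Optional[ReferenceTable] = None) -> TotalVolumeFit:
    """Unweighted mean (and SD) of the total-volume column across conditions."""
    if table is None:
        table = load_reference_table()
    if len(table) == 0:
        raise ValueError("empty reference table")
    v = np.array([r.vtot_ul.mean for r in table])
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return TotalVolumeFit(vtot_hat=float(v.mean()), sd=sd, n=len(v))


def predict_volume(
    condition_id: Optional[str] = None,
    mu: Optional[float] = None,
    table: Optional[ReferenceTable] = None,
    model: Optional[VolumeModel] = None,
    force: bool = False,
) -> tuple:
    """Single-cell volume (fl) with uncertainty, by lookup or by model.

    A known ``condition_id`` returns the tabulated volume and SD directly;
    otherwise the fitted V(µ) model is evaluated and its residual SD is
    returned as the uncertainty.
    """
    if (condition_id is None) == (mu is None):
        raise ValueError("give exactly one of condition_id or mu")
    if table is None:
        table = load_reference_table()
    if condition_id is not None:
        rec = table.get(condition_id)
        return rec.volume_fl.mean, rec.volume_fl.sd
    if mu <= 0:
        raise ValueError("growth rate must be strictly positive")
    if model is None:
        model = fit_volume_vs_mu(table)
    return model.predict(mu, force=force), model.residual_sd


def predict_cell_concentration(
    od: float,
    condition_id: Optional[str] = None,
    mu: Optional[float] = None,
    table: Optional[ReferenceTable] = None,
    model: Optional[VolumeModel] = None,
    vtot: Optional[TotalVolumeFit] = None,
    force: bool = False,
) -> tuple:
    """Cell concentration (cells/ml) with SD for a sample of the given OD.

    A known ``condition_id`` uses the tabulated OD-specific concentration;
    otherwise ``N(µ) = vtot_hat·10⁹ / V(µ)`` is evaluated with the fitted
    volume model, whose domain excludes stationary pseudo growth rates.
    """
    if od <= 0:
        raise ValueError("od must be strictly positive")
    if (condition_id is None) == (mu is None):
        raise ValueError("give exactly one of condition_id or mu")
    if table is None:
        table = load_reference_table()
    if condition_id is not None:
        rec = table.get(condition_id)
        value = rec.conc_per_ml_od * od
        sd = None if rec.conc_e8.sd is None else rec.conc_e8.sd * 1e8 * od
        return value, sd
    lo, hi = MU_DOMAIN
    if not force and not (lo <= mu <= hi):
        raise ValueError(
            f"growth rate outside the concentration-model domain "
            f"[{lo:g}, {hi:g}] 1/h; pass force=True to extrapolate"
        )
    if model is None:
        model = fit_volume_vs_mu(table)
    if vtot is None:
        vtot = fit_total_volume(table)
    v = model.predict(mu, force=True)
    n_per_ml_od = vtot.vtot_hat * 1e9 / v  # µl -> fl
    value = n_per_ml_od * od
    # independent relative errors of the constant and of the volume model
    rel = np.sqrt((vtot.sd / vtot.vtot_hat) ** 2
                  + (model.residual_sd / v) ** 2)
    return value, value * rel
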