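"""Bead-referenced absolute cell counting and scatter-to-volume calibration.

The counting chain mirrors a four-step bead-referenced protocol: cells are
gated in FL1×SSC, beads in FSC×SSC, the analyzed volume is inferred from
the bead fraction recovered, and the cell concentration follows from count
over volume.  A 400/380 correction undoes the dilution introduced by the
20 µl bead aliquot; it can be disabled for sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RectGate",
    "GateSpec",
    "DEFAULT_GATES",
    "CountResult",
    "gate_events",
    "absolute_concentration",
    "ScatterVolumeModel",
    "calibrate_scatter_to_volume",
    "predict_volume_from_scatter",
    "VolumePrediction",
]

logger = logging.getLogger(__name__)

CHANNELS = ("FSC", "SSC", "FL1")


@dataclass(frozen=True)
class RectGate:
    """Rectangular gate in two log10-channel coordinates.

    Bounds are (low, high) in log10 channel units; ``None`` leaves the side
    unbounded.
    """

    x_channel: str
    y_channel: str
    x_bounds: tuple = (None, None)
    y_bounds: tuple = (None, None)

    def contains(self, events: pd.DataFrame) -> np.ndarray:
        keep = np.ones(len(events), dtype=bool)
        for ch, (lo, hi) in ((self.x_channel, self.x_bounds),
                             (self.y_channel, self.y_bounds)):
            logv = np.log10(events[ch].to_numpy(dtype=float))
            if lo is not None:
                keep &= logv >= lo
            if hi is not None:
                keep &= logv <= hi
        return keep


@dataclass(frozen=True)
class GateSpec:
    cell: RectGate
    bead: RectGate


# Defaults matched to the synthetic generator's class models: every gate
# edge sits more than 3 log-SD from both neighbouring classes.
DEFAULT_GATES = GateSpec(
    cell=RectGate("FL1", "SSC", x_bounds=(2.0, 3.6), y_bounds=(1.0, 2.6)),
    bead=RectGate("FSC", "SSC", x_bounds=(3.0, 4.2), y_bounds=(2.8, 3.6)),
)


def _validate_events(events: pd.DataFrame) -> None:
    if len(events) == 0:
        raise ValueError("empty event table")
    missing = [c for c in CHANNELS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks channel column(s): {missing}")
    for c in CHANNELS:
        if not (events[c].to_numpy(dtype=float) > 0).all():
            raise ValueError(f"channel {c} contains non-positive values")


def gate_events(events: pd.DataFrame,
                gates: GateSpec = DEFAULT_GATES) -> tuple:
    """Count cell- and bead-gated events; returns (cell_count, bead_count).

    Cells are counted in the FL1×SSC projection and beads in FSC×SSC;
    the two gates are applied independently, so an event may in principle
    fall in both.
    """
    _validate_events(events)
    cell_count = int(gates.cell.contains(events).sum())
    bead_count = int(gates.bead.contains(events).sum())
    if cell_count == 0:
        warnings.warn("cell gate matched no events")
    if bead_count == 0:
        warnings.warn("bead gate matched no events")
    return cell_count, bead_count


@dataclass(frozen=True)
class CountResult:
    cell_count: int
    bead_count: int
    analyzed_volume_ml: float
    conc_tube_per_ml: float
    conc_suspension_per_ml: float
    conc_culture_per_ml: float
    od_specific_conc: Optional[float]  # cells/ml/OD, None when OD not given
    conc_se_per_ml: Optional[float]  # Poisson SE on conc_culture
    aliquot_corrected: bool


def absolute_concentration(
    cell_count: int,
    bead_count: int,
    beads_total_in_tube: float,
    tube_volume_ul: float = 400.0,
    sample_aliquot_ul: float = 380.0,
    dilution_factor: float = 1.0,
    od: Optional[float] = None,
    correct_aliquot: bool = True,
) -> CountResult:
    """Absolute cell concentration from gated counts and the bead reference.

    The analyzed volume is the bead-count fraction of the tube volume; the
    tube concentration is cells over that volume.  When ``correct_aliquot``
    is set (default) the tube concentration is scaled by
    ``tube/sample_aliquot`` to undo the bead-aliquot dilution (~5% effect),
    then by ``dilution_factor`` back to the culture.  Poisson counting error
    is the only uncertainty modelled.
    """
    if bead_count < 1:
        raise ValueError("bead_count must be >= 1: the analyzed volume "
                         "cannot be determined without beads")
    if cell_count < 0:
        raise ValueError("cell_count must be non-negative")
    if beads_total_in_tube < bead_count:
        raise ValueError("beads_total_in_tube cannot be below bead_count")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if od is not None and od <= 0:
        raise ValueError("od must be strictly positive")

    analyzed_ul = bead_count / beads_total_in_tube * tube_volume_ul
    analyzed_ml = analyzed_ul * 1e-3
    conc_tube = cell_count / analyzed_ml
    aliquot_factor = tube_volume_ul / sample_aliquot_ul if correct_aliquot else 1.0
    if correct_aliquot:
        logger.debug("bead-aliquot correction factor %.4f applied",
                     aliquot_factor)
    conc_susp = conc_tube * aliquot_factor
    conc_culture = conc_susp * dilution_factor
    if cell_count > 0:
        rel_se = np.sqrt(1.0 / cell_count + 1.0 / bead_count)
        conc_se = conc_culture * rel_se
    else:
        conc_se = None
    return CountResult(
        cell_count=int(cell_count),
        bead_count=int(bead_count),
        analyzed_volume_ml=analyzed_ml,
        conc_tube_per_ml=conc_tube,
        conc_suspension_per_ml=conc_susp,
        conc_culture_per_ml=conc_culture,
        od_specific_conc=None if od is None else conc_culture / od,
        conc_se_per_ml=conc_se,
        aliquot_corrected=correct_aliquot,
    )


@dataclass(frozen=True)
class ScatterVolumeModel:
    """Least-squares line mapping a scatter channel to cell volume (fl)."""

    channel: str
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    scatter_mean: float
    scatter_sxx: float
    scatter_range: tuple
    excluded: tuple = ()


def calibrate_scatter_to_volume(
    scatter: Sequence[float],
    volume_fl: Sequence[float],
    channel: str = "FSC",
    exclude: Sequence[int] = (),
) -> ScatterVolumeModel:
    """Fit ``volume = a·scatter + b`` after dropping excluded indices.

    ``exclude`` lists indices of pairs left out of the fit (e.g. stationary
    points for FSC, chemostat points for SSC); the exclusion is logged.
    """
    s = np.asarray(scatter, dtype=float)
    v = np.asarray(volume_fl, dtype=float)
    if s.shape != v.shape:
        raise ValueError("scatter and volume arrays differ in length")
    keep = np.ones(len(s), dtype=bool)
    for i in exclude:
        keep[i] = False
    if len(exclude):
        logger.info("excluding %d of %d pairs from the %s calibration",
                    len(exclude), len(s), channel)
    s, v = s[keep], v[keep]
    if len(s) < 3:
        raise ValueError("need at least 3 pairs after exclusions")
    if np.ptp(s) == 0:
        raise ValueError("scatter values have zero variance")
    res = stats.linregress(s, v)
    fitted = res.intercept + res.slope * s
    dof = len(s) - 2
    residual_sd = float(np.sqrt(np.sum((v - fitted) ** 2) / dof)) if dof else 0.0
    return ScatterVolumeModel(
        channel=channel,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        residual_sd=residual_sd,
        n=len(s),
        scatter_mean=float(s.mean()),
        scatter_sxx=float(np.sum((s - s.mean()) ** 2)),
        scatter_range=(float(s.min()), float(s.max())),
        excluded=tuple(exclude),
    )


@dataclass(frozen=True)
class VolumePrediction:
    volume_fl: float
    lower_fl: float
    upper_fl: float
    level: float
    extrapolated: bool


def predict_volume_from_scatter(
    model: ScatterVolumeModel,
    scatter: float,
    level: float = 0.95,
) -> VolumePrediction:
    """Point prediction with a prediction interval from the residual SD."""
    if not np.isfinite(model.slope) or model.n < 3:
        raise ValueError("model is not fitted")
    lo, hi = model.scatter_range
    extrapolated = not (lo <= scatter <= hi)
    if extrapolated:
        warnings.warn(
            f"scatter {scatter:g} is outside the fitted range [{lo:g}, {hi:g}]"
        )
    pred = model.intercept + model.slope * scatter
    dof = model.n - 2
    if model.residual_sd == 0 or dof <= 0:
        half = 0.0
    else:
        t = stats.t.ppf(0.5 + level / 2.0, dof)
        half = t * model.residual_sd * np.sqrt(
            1.0 + 1.0 / model.n
            + (scatter - model.scatter_mean) ** 2 / model.scatter_sxx
        )
    return VolumePrediction(
        volume_fl=float(pred),
        lower_fl=float(pred - half),
        upper_fl=float(pred + half),
        level=level,
        extrapolated=extrapolated,
    )
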