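"""Synthetic flow-cytometry event tables and OD calibration pairs.

The virtual instrument draws a fixed volume from a tube containing cells at
a known concentration plus a known number of counting beads (20 µl bead
aliquot added to 380 µl of suspension, 400 µl total by default).  Event
counts per class are Poisson in concentration × analyzed volume; channel
values (FSC, SSC, FL1) are log-normal per class, with the default class
locations separated by well over 3 log-SD so rectangular threshold gates
are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ChannelModel",
    "ClassChannels",
    "EventSpec",
    "EventGroundTruth",
    "generate_events",
    "replicate_specs",
    "OdDeviceModel",
    "generate_od_pairs",
]

_MAX_EXPECTED_EVENTS = 1e7


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal channel model: location and scale in log10 units."""

    loc: float
    scale: float


@dataclass(frozen=True)
class ClassChannels:
    fsc: ChannelModel
    ssc: ChannelModel
    fl1: ChannelModel


# Default class models.  The real instrument's channel ranges are not
# documented anywhere usable, so these scales are arbitrary; only the
# separability between classes matters.
DEFAULT_CHANNELS = {
    "cell": ClassChannels(ChannelModel(1.8, 0.10), ChannelModel(1.8, 0.10),
                          ChannelModel(2.8, 0.10)),
    "bead": ClassChannels(ChannelModel(3.6, 0.06), ChannelModel(3.2, 0.06),
                          ChannelModel(4.2, 0.06)),
    "debris": ClassChannels(ChannelModel(0.8, 0.15), ChannelModel(0.8, 0.15),
                            ChannelModel(0.6, 0.15)),
}


@dataclass(frozen=True)
class EventSpec:
    """Parameters of one virtual counting run."""

    true_cell_conc_per_ml: float = 1e6  # in the measurement tube
    beads_total: int = 20000  # beads spiked into the tube
    tube_volume_ul: float = 400.0  # 20 µl beads + 380 µl suspension
    analyzed_volume_ul: float = 30.0
    channel_models: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    debris_rate_per_ml: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.analyzed_volume_ul > self.tube_volume_ul:
            raise ValueError("analyzed volume cannot exceed tube volume")
        if min(self.true_cell_conc_per_ml, self.beads_total,
               self.debris_rate_per_ml) < 0:
            raise ValueError("concentrations and counts must be >= 0")


@dataclass(frozen=True)
class EventGroundTruth:
    analyzed_volume_ul: float
    class_counts: dict
    true_cell_conc_per_ml: float
    beads_total: int
    tube_volume_ul: float


def generate_events(spec: EventSpec):
    """Generate one shuffled event table plus its ground truth.

    Returns ``(events, truth)`` where ``events`` is a DataFrame with columns
    ``FSC``, ``SSC``, ``FL1`` and ``true_class`` (drop the last column to
    feed the pipeline blind) and ``truth`` records per-class counts and the
    analyzed volume.
    """
    rng = np.random.default_rng(spec.seed)
    vol_ml = spec.analyzed_volume_ul * 1e-3
    bead_conc = spec.beads_total / (spec.tube_volume_ul * 1e-3)
    expectations = {
        "cell": spec.true_cell_conc_per_ml * vol_ml,
        "bead": bead_conc * vol_ml,
        "debris": spec.debris_rate_per_ml * vol_ml,
    }
    if sum(expectations.values()) > _MAX_EXPECTED_EVENTS:
        raise ValueError(
            f"expected event count {sum(expectations.values()):.3g} exceeds "
            f"the {_MAX_EXPECTED_EVENTS:.0g} guard"
        )
    counts = {k: int(rng.poisson(mu)) for k, mu in expectations.items()}

    frames = []
    for cls, n in counts.items():
        if n == 0:
            continue
        cm = spec.channel_models[cls]
        frames.append(pd.DataFrame({
            "FSC": 10 ** rng.normal(cm.fsc.loc, cm.fsc.scale, n),
            "SSC": 10 ** rng.normal(cm.ssc.loc, cm.ssc.scale, n),
            "FL1": 10 ** rng.normal(cm.fl1.loc, cm.fl1.scale, n),
            "true_class": cls,
        }))
    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = events.iloc[rng.permutation(len(events))].reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["FSC", "SSC", "FL1", "true_class"])
    truth = EventGroundTruth(
        analyzed_volume_ul=spec.analyzed_volume_ul,
        class_counts=counts,
        true_cell_conc_per_ml=spec.true_cell_conc_per_ml,
        beads_total=spec.beads_total,
        tube_volume_ul=spec.tube_volume_ul,
    )
    return events, truth


def replicate_specs(base: EventSpec, n_days: int, cv: float = 0.10,
                    seed: int = 0) -> list:
    """Specs for replicate measurement days with day-level concentration noise.

    Each day's true concentration is the base concentration times a
    log-normal factor with coefficient of variation ``cv`` (the documented
    day-to-day variability bound); each day gets its own stream seed.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    out = []
    for day in range(n_days):
        factor = float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
        out.append(replace(
            base,
            true_cell_conc_per_ml=base.true_cell_conc_per_ml * factor,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return out


@dataclass(frozen=True)
class OdDeviceModel:
    """Saturating monotone distortion of a plate-reader OD readout.

    ``device = gain · sat · (1 − exp(−true/sat))``; ``sat = inf`` gives the
    identity (times ``gain``).
    """

    saturation: float = np.inf
    gain: float = 1.0

    def __call__(self, true_od):
        x = np.asarray(true_od, dtype=float)
        if np.isinf(self.saturation):
            return self.gain * x
        return self.gain * self.saturation * (-np.expm1(-x / self.saturation))


def generate_od_pairs(
    n: int,
    device_model: Optional[Callable] = None,
    od_range: tuple = (0.001, 10.0),
    noise_cv: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (true OD, device OD) calibration samples, log-spaced in truth.

    The device response must be strictly monotone over ``od_range`` (checked
    on a grid); multiplicative log-normal noise of CV ``noise_cv`` is applied
    to the device readings.
    """
    if n < 3:
        raise ValueError("need at least 3 calibration pairs")
    lo, hi = od_range
    if not (0 < lo < hi) or hi / lo < 10:
        raise ValueError("true ODs must span at least a decade within (0, inf)")
    if device_model is None:
        device_model = OdDeviceModel()
    grid = np.geomspace(lo, hi, 256)
    resp = np.asarray(device_model(grid), dtype=float)
    if not np.all(np.diff(resp) > 0):
        raise ValueError("device model is not strictly monotone on the range")
    rng = np.random.default_rng(seed)
    true_od = np.geomspace(lo, hi, n)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, n)) if noise_cv > 0 else 1.0
    device = np.asarray(device_model(true_od)) * noise
    return pd.DataFrame({"true_od": true_od, "device_od": device})
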