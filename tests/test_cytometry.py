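import numpy as np
import pandas as pd
import pytest

from odcell.cytometry import (
    DEFAULT_GATES,
    GateSpec,
    RectGate,
    absolute_concentration,
    calibrate_scatter_to_volume,
    gate_events,
    predict_volume_from_scatter,
)
from odcell.synthetic import EventSpec, generate_events, replicate_specs


def _run_pipeline(spec, od=None, dilution=1.0):
    events, truth = generate_events(spec)
    cells, beads = gate_events(events.drop(columns="true_class"))
    return absolute_concentration(
        cells, beads, beads_total_in_tube=spec.beads_total,
        tube_volume_ul=spec.tube_volume_ul, dilution_factor=dilution, od=od,
        correct_aliquot=False,  # compare against the in-tube truth
    ), truth


class TestGateEvents:
    def test_counts_match_truth_exactly(self):
        spec = EventSpec(true_cell_conc_per_ml=2e5, analyzed_volume_ul=30.0,
                         debris_rate_per_ml=5e4, seed=3)
        events, truth = generate_events(spec)
        cells, beads = gate_events(events.drop(columns="true_class"))
        assert cells == truth.class_counts["cell"]
        assert beads == truth.class_counts["bead"]

    def test_whole_plane_gates_count_everything(self):
        events, _ = generate_events(EventSpec(true_cell_conc_per_ml=1e5,
                                              seed=1))
        open_gates = GateSpec(cell=RectGate("FL1", "SSC"),
                              bead=RectGate("FSC", "SSC"))
        cells, beads = gate_events(events, open_gates)
        assert cells == len(events) == beads

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gate_events(pd.DataFrame(columns=["FSC", "SSC", "FL1"]))

    def test_excluding_gate_warns(self):
        events, _ = generate_events(EventSpec(true_cell_conc_per_ml=1e5,
                                              seed=2))
        gates = GateSpec(
            cell=RectGate("FL1", "SSC", x_bounds=(9.0, 10.0)),
            bead=DEFAULT_GATES.bead,
        )
        with pytest.warns(UserWarning, match="cell gate"):
            cells, _ = gate_events(events, gates)
        assert cells == 0

    def test_nonpositive_channel_rejected(self):
        df = pd.DataFrame({"FSC": [1.0, -1.0], "SSC": [1.0, 1.0],
                           "FL1": [1.0, 1.0]})
        with pytest.raises(ValueError, match="non-positive"):
            gate_events(df)


class TestAbsoluteConcentration:
    def test_hand_worked_example(self):
        r = absolute_concentration(30000, 10000, beads_total_in_tube=20000,
                                   tube_volume_ul=400.0)
        assert r.analyzed_volume_ml == pytest.approx(0.2)
        assert r.conc_tube_per_ml == pytest.approx(1.5e5)
        assert r.conc_suspension_per_ml == pytest.approx(1.5e5 * 400 / 380)

    def test_zero_cells(self):
        r = absolute_concentration(0, 5000, beads_total_in_tube=20000)
        assert r.conc_culture_per_ml == 0.0
        assert r.conc_se_per_ml is None

    def test_zero_beads_errors(self):
        with pytest.raises(ValueError, match="bead"):
            absolute_concentration(100, 0, beads_total_in_tube=20000)

    def test_validation(self):
        with pytest.raises(ValueError):
            absolute_concentration(10, 30000, beads_total_in_tube=20000)
        with pytest.raises(ValueError):
            absolute_concentration(10, 10, beads_total_in_tube=20,
                                   dilution_factor=0.5)
        with pytest.raises(ValueError):
            absolute_concentration(10, 10, beads_total_in_tube=20, od=0.0)

    def test_analyzed_volume_never_exceeds_tube(self):
        r = absolute_concentration(10, 20000, beads_total_in_tube=20000,
                                   tube_volume_ul=400.0)
        assert r.analyzed_volume_ml <= 0.4

    def test_od_and_dilution(self):
        r = absolute_concentration(1000, 1000, beads_total_in_tube=2000,
                                   dilution_factor=500, od=0.5,
                                   correct_aliquot=False)
        assert r.conc_culture_per_ml == pytest.approx(500 * 1000 / 0.2)
        assert r.od_specific_conc == pytest.approx(r.conc_culture_per_ml / 0.5)

    def test_aliquot_correction_five_percent(self):
        on = absolute_concentration(100, 100, beads_total_in_tube=200)
        off = absolute_concentration(100, 100, beads_total_in_tube=200,
                                     correct_aliquot=False)
        assert on.conc_suspension_per_ml / off.conc_suspension_per_ml \
            == pytest.approx(400 / 380)

    def test_end_to_end_glucose_like_density(self):
        # OD ~0.001 sample: ~1e6 cells/ml recovered from the event table
        spec = EventSpec(true_cell_conc_per_ml=1e6, analyzed_volume_ul=30.0,
                         seed=17)
        result, truth = _run_pipeline(spec)
        rel_se = np.sqrt(1 / result.cell_count + 1 / result.bead_count)
        assert abs(result.conc_culture_per_ml - 1e6) / 1e6 <= 3 * rel_se

    def test_scale_equivariance(self):
        ests = []
        for conc in (5e5, 1e6):
            est = np.mean([
                _run_pipeline(EventSpec(true_cell_conc_per_ml=conc,
                                        analyzed_volume_ul=10.0,
                                        seed=s))[0].conc_culture_per_ml
                for s in range(8)
            ])
            ests.append(est)
        assert ests[1] / ests[0] == pytest.approx(2.0, rel=0.05)

    def test_day_to_day_cv_bounded(self):
        base = EventSpec(true_cell_conc_per_ml=1e6, analyzed_volume_ul=10.0)
        concs = []
        for spec in replicate_specs(base, n_days=12, cv=0.10, seed=8):
            concs.append(_run_pipeline(spec)[0].conc_culture_per_ml)
        cv = np.std(concs, ddof=1) / np.mean(concs)
        assert cv <= 0.15


class TestScatterCalibration:
    def test_exact_line(self):
        s = np.array([10.0, 20.0, 30.0, 40.0])
        v = 0.5 * s + 1.0
        m = calibrate_scatter_to_volume(s, v)
        assert m.slope == pytest.approx(0.5)
        assert m.intercept == pytest.approx(1.0)
        assert m.r_squared == pytest.approx(1.0)

    def test_exclusions_match_manual_filter(self, rng):
        s = rng.uniform(10, 100, 20)
        v = 0.1 * s + rng.normal(0, 0.5, 20)
        s[0], v[0] = 500.0, 0.0  # gross outlier
        m = calibrate_scatter_to_volume(s, v, exclude=[0])
        oracle = calibrate_scatter_to_volume(s[1:], v[1:])
        assert m.slope == pytest.approx(oracle.slope)
        assert m.intercept == pytest.approx(oracle.intercept)
        assert m.excluded == (0,)

    def test_slope_bias_small(self):
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(100):
            s = rng.uniform(10, 100, 24)
            v = 0.08 * s + 0.5 + rng.normal(0, 0.3, 24)
            slopes.append(calibrate_scatter_to_volume(s, v).slope)
        assert abs(np.mean(slopes) - 0.08) / 0.08 < 0.05

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            calibrate_scatter_to_volume([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            calibrate_scatter_to_volume([1, 2, 3, 4], [1, 2, 3, 4],
                                        exclude=[0, 1])

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="variance"):
            calibrate_scatter_to_volume([5.0] * 4, [1.0, 2.0, 3.0, 4.0])


class TestPredictVolume:
    def test_training_point_on_exact_line(self):
        s = np.array([10.0, 20.0, 30.0, 40.0])
        m = calibrate_scatter_to_volume(s, 0.5 * s + 1.0)
        p = predict_volume_from_scatter(m, 20.0)
        assert p.volume_fl == pytest.approx(11.0)
        assert p.lower_fl == pytest.approx(p.upper_fl)

    def test_extrapolation_warns(self):
        s = np.array([10.0, 20.0, 30.0, 40.0])
        m = calibrate_scatter_to_volume(s, 0.5 * s + 1.0)
        with pytest.warns(UserWarning, match="outside"):
            p = predict_volume_from_scatter(m, 100.0)
        assert p.extrapolated

    def test_interval_coverage(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            s = rng.uniform(10, 100, 24)
            v = 0.08 * s + 0.5 + rng.normal(0, 0.3, 24)
            m = calibrate_scatter_to_volume(s, v)
            s_new = rng.uniform(15, 95)
            v_new = 0.08 * s_new + 0.5 + rng.normal(0, 0.3)
            p = predict_volume_from_scatter(m, s_new)
            hits += p.lower_fl <= v_new <= p.upper_fl
        assert hits >= 90

    def test_unfitted_model_rejected(self):
        from odcell.cytometry import ScatterVolumeModel
        bad = ScatterVolumeModel("FSC", float("nan"), 0.0, 0.0, 0.0, 0,
                                 0.0, 0.0, (0.0, 1.0))
        with pytest.raises(ValueError, match="fitted"):
            predict_volume_from_scatter(bad, 1.0)
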