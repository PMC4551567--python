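"""Single-cell biophysics: kinetics, cable integration, thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retistim.rgc import (
    GATE_NAMES,
    ChannelParams,
    CellState,
    NoThresholdError,
    RGCModel,
    StimulusPulse,
    build_morphology,
    detect_spike,
    find_threshold,
    gate_steady_state,
    membrane_currents,
    rate_constants,
    steady_state,
)


class TestRateConstants:
    @pytest.mark.parametrize("v,gate,which,expected", [
        (-30.0, "m", 0, 6.0),    # removable singularity: 0.6/0.1
        (-55.0, "m", 1, 20.0),
        (-20.0, "h", 1, 3.0),
        (-40.0, "n", 0, 0.2),
        (-13.0, "c", 0, 3.0),    # removable singularity: 0.3/0.1
        (-38.0, "c", 1, 10.0),
    ])
    def test_reference_values(self, v, gate, which, expected):
        assert rate_constants(v)[gate][which] == pytest.approx(expected, rel=1e-6)

    def test_sodium_activation_steady_state(self):
        # x_inf(-30) for m: 6.0 / (6.0 + 20 e^{-25/18})
        x = gate_steady_state(-30.0)["m"]
        assert x == pytest.approx(6.0 / (6.0 + 20.0 * math.exp(-25.0 / 18.0)), rel=1e-6)
        assert x == pytest.approx(0.546, abs=0.002)

    @given(v=st.floats(min_value=-150.0, max_value=80.0))
    @settings(max_examples=200, deadline=None)
    def test_rates_finite_and_nonnegative(self, v):
        for variant in (False, True):
            for a, b in rate_constants(v, alpha_a_printed=variant).values():
                assert math.isfinite(a) and math.isfinite(b)
                assert a >= 0.0 and b >= 0.0

    def test_printed_a_gate_variant_differs_only_near_its_singularity(self):
        default = rate_constants(-40.0)["a"][0]
        printed = rate_constants(-40.0, alpha_a_printed=True)["a"][0]
        assert math.isfinite(printed)
        assert default != pytest.approx(printed)


class TestMembraneCurrents:
    def _state(self, n, v, gates=0.0, ca=1e-4):
        return CellState(v=np.full(n, v),
                         gates={k: np.full(n, gates) for k in GATE_NAMES},
                         ca=np.full(n, ca))

    def test_closed_gates_leave_only_leak(self):
        morph = build_morphology()
        st_ = self._state(morph.n_compartments, -65.0)
        out = membrane_currents(st_, ChannelParams(), morph.segment, e_leak=-65.0)
        for name in ("na", "ca", "kdr", "a", "leak"):
            assert np.allclose(out[name], 0.0, atol=1e-12)
        # K,Ca is calcium- not voltage-gated; at residual [Ca] it is a
        # fraction of a μA/cm², so the total is only approximately zero
        assert np.all(np.abs(out["total"]) < 0.1)

    def test_potassium_current_vanishes_at_reversal(self):
        morph = build_morphology()
        st_ = self._state(morph.n_compartments, -75.0, gates=0.5)
        out = membrane_currents(st_, ChannelParams(), morph.segment)
        assert np.allclose(out["kdr"], 0.0)
        assert np.allclose(out["a"], 0.0)
        assert np.allclose(out["kca"], 0.0)

    def test_open_sodium_current_closed_form(self):
        morph = build_morphology()
        st_ = self._state(morph.n_compartments, 0.0)
        for k in ("m", "h"):
            st_.gates[k][:] = 1.0
        out = membrane_currents(st_, ChannelParams(), morph.segment)
        g_na = ChannelParams().per_compartment(morph.segment)["g_na"]
        assert np.allclose(out["na"], g_na * (0.0 - 35.0))


class TestMorphology:
    def test_segment_path_lengths(self):
        morph = build_morphology()
        assert morph.path_length("S1") == pytest.approx(0.5 + math.pi / 2 * 5 + 40,
                                                        rel=1e-9)
        assert morph.path_length("S1") == pytest.approx(48.35, abs=0.01)
        assert morph.path_length("S2") == pytest.approx(40.0)
        assert morph.path_length("S3") == pytest.approx(1000.0)

    def test_compartment_resolution(self):
        morph = build_morphology()
        seg = morph.segment
        assert np.max(morph.lengths[(seg == 1) | (seg == 2)]) <= 1.0 + 1e-9
        assert np.max(morph.lengths[seg == 3]) <= 5.0 + 1e-9

    def test_axon_runs_nasally_below_the_soma(self):
        morph = build_morphology(soma_xyz=(10.0, -5.0, 49.0))
        tip = morph.positions[-1]
        assert tip[0] == pytest.approx(10.0 - 1085.0 - 2.5, abs=5.0)
        assert tip[2] == pytest.approx(49.0 - 17.5)
        mirrored = build_morphology(soma_xyz=(10.0, -5.0, 49.0),
                                    axon_direction=(1.0, 0.0, 0.0))
        assert mirrored.positions[-1][0] > 10.0

    def test_translation_preserves_shape(self):
        morph = build_morphology()
        moved = morph.translated((50.0, 20.0, 30.0))
        assert np.allclose(moved.positions - morph.positions,
                           [50.0, 20.0, 30.0])


class TestRestingState:
    def test_settled_rest_is_stable_and_bracketed(self):
        st_ = steady_state(settle_ms=20.0, check_ms=50.0)
        assert np.all(st_.v > -75.0) and np.all(st_.v < -55.0)
        assert np.max(np.abs(st_.v - (-65.0))) < 1.0

    def test_passive_cell_stays_at_initial_potential(self):
        params = ChannelParams(g_na=(0,) * 4, g_kdr=(0,) * 4, g_a=(0,) * 4,
                               g_ca=(0,) * 4, g_kca=(0,) * 4)
        model = RGCModel(params=params)
        out = model.simulate(np.zeros(model.morphology.n_compartments),
                             t_total_ms=10.0, stop_on_spike=False)
        assert np.max(np.abs(out["state"].v - (-65.0))) < 1e-6


class TestSimulation:
    def test_rest_without_stimulus(self, rgc_model):
        out = rgc_model.simulate(np.zeros(rgc_model.morphology.n_compartments),
                                 t_total_ms=50.0, stop_on_spike=False)
        assert not out["activated"]
        assert np.max(np.abs(out["state"].v + 65.0)) < 0.5

    def test_uniform_field_cannot_activate(self, rgc_model):
        n = rgc_model.morphology.n_compartments
        with pytest.raises(NoThresholdError):
            find_threshold(rgc_model, np.full(n, -50.0))
        out = rgc_model.simulate(np.full(n, -500.0), stop_on_spike=False)
        assert not out["activated"]

    def test_suprathreshold_pulse_propagates_to_distal_axon(self, rgc_model,
                                                            gaussian_drive):
        thr = find_threshold(rgc_model, gaussian_drive)
        out = rgc_model.simulate(gaussian_drive * 1.2 * thr, record_every=20,
                                 stop_on_spike=False)
        assert out["activated"]
        assert out["v_m"][:, -1].max() > 0.0  # distal S3 end spikes

    def test_gates_stay_in_unit_interval(self, rgc_model, gaussian_drive):
        out = rgc_model.simulate(gaussian_drive * 30.0, stop_on_spike=False)
        for k, g in out["state"].gates.items():
            assert np.all(g >= 0.0) and np.all(g <= 1.0)
        assert np.all(out["state"].ca >= rgc_model.params.ca_rest)

    def test_all_or_none_spike_amplitude(self, rgc_model, gaussian_drive):
        thr = find_threshold(rgc_model, gaussian_drive)
        peaks = []
        for mult in (1.05, 1.4, 2.0):
            out = rgc_model.simulate(gaussian_drive * mult * thr,
                                     stop_on_spike=False)
            assert out["activated"]
            peaks.append(out["peak_monitor_mv"] + 65.0)  # amplitude above rest
        assert np.ptp(peaks) / np.mean(peaks) < 0.05


class TestThresholdSearch:
    def test_threshold_brackets_activation(self, rgc_model, gaussian_drive):
        thr = find_threshold(rgc_model, gaussian_drive, tol=0.01)
        above = rgc_model.simulate(gaussian_drive * thr)["activated"]
        below = rgc_model.simulate(gaussian_drive * 0.97 * thr)["activated"]
        assert above and not below

    def test_zero_field_has_no_threshold(self, rgc_model):
        with pytest.raises(NoThresholdError):
            find_threshold(rgc_model,
                           np.zeros(rgc_model.morphology.n_compartments))

    def test_threshold_dt_convergence(self, rgc_model, gaussian_drive):
        t1 = find_threshold(rgc_model, gaussian_drive, tol=0.005, dt_ms=0.005)
        t2 = find_threshold(rgc_model, gaussian_drive, tol=0.005, dt_ms=0.0025)
        assert abs(t1 - t2) / t1 < 0.02

    def test_threshold_charge_nondecreasing_in_pulse_width(self, rgc_model,
                                                           gaussian_drive):
        widths = (0.1, 0.2, 0.4, 0.8)
        charges = [find_threshold(rgc_model, gaussian_drive, pulse_width_ms=w,
                                  tol=0.005) * w for w in widths]
        assert np.all(np.diff(charges) > -1e-9)

    def test_mirrored_cell_has_mirrored_threshold(self, disk100_erd20):
        from retistim.volume_conductor import sample_potential

        sol = disk100_erd20.scaled_to(-1.0)
        thrs = []
        for direction in ((-1.0, 0.0, 0.0), (1.0, 0.0, 0.0)):
            morph = build_morphology(soma_xyz=(0.0, 0.0, 30.0),
                                     axon_direction=direction)
            ux = direction[0]
            pos = morph.positions.copy()
            pos[:, 0] -= ux * 65.0  # electrode 65 μm along the axon
            model = RGCModel(morph)
            thrs.append(find_threshold(model, sample_potential(sol, pos)))
        assert thrs[0] == pytest.approx(thrs[1], rel=0.01)


class TestSpikeDetection:
    def test_resting_trace_is_silent(self):
        t = np.linspace(0.0, 5.0, 100)
        ok, when = detect_spike(np.full_like(t, -65.0), t)
        assert not ok and when is None

    def test_crossing_time_reported(self):
        t = np.linspace(0.0, 5.0, 501)
        v = np.where(t > 2.0, 30.0, -65.0)
        ok, when = detect_spike(v, t)
        assert ok and when == pytest.approx(2.0, abs=0.02)

    def test_subthreshold_depolarisation_not_a_spike(self):
        t = np.linspace(0.0, 5.0, 100)
        v = -65.0 + 45.0 * np.exp(-((t - 2.0) ** 2))  # peaks at -20 mV
        ok, _ = detect_spike(v, t)
        assert not ok


class TestParameterConfig:
    def test_channel_params_round_trip(self, tmp_path):
        import yaml

        from retistim.rgc import export_traces

        params = ChannelParams(ra=120.0, v_rest=-64.0)
        path = tmp_path / "cell.yaml"
        path.write_text(yaml.safe_dump(params.to_dict()))
        assert ChannelParams.from_file(path) == params

    def test_trace_export(self, rgc_model, tmp_path):
        from retistim.rgc import export_traces

        out = rgc_model.simulate(np.zeros(rgc_model.morphology.n_compartments),
                                 t_total_ms=1.0, record_every=50,
                                 stop_on_spike=False)
        path = tmp_path / "trace.csv"
        export_traces(out, path)
        header = path.read_text().splitlines()[0]
        assert header == "time_ms,compartment,v_m_mv"
        with pytest.raises(ValueError):
            export_traces({"v_m": None}, path)
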