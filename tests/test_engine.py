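"""Simulation engine: coupling currents, determinism, causality, stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stf

from gocnet import engine as eg
from gocnet import network as nw
from gocnet import stimulus as st
from gocnet.errors import ConfigError
from gocnet.neurons import GCParams, GoCParams, simulate_single


class TestGapJunctionCurrent:
    def test_no_driving_force(self):
        assert eg.gap_junction_current(-60.0, -60.0, 1.0) == (0.0, 0.0)

    def test_ohmic_value(self):
        into_i, into_j = eg.gap_junction_current(-65.0, -55.0, 1.0)
        assert into_i == pytest.approx(0.01)  # 1 nS * 10 mV = 10 pA
        assert into_j == pytest.approx(-0.01)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(vi=stf.floats(-100, 50), vj=stf.floats(-100, 50),
           g=stf.floats(0, 5))
    def test_charge_conservation_exact(self, vi, vj, g):
        into_i, into_j = eg.gap_junction_current(vi, vj, g)
        assert into_i + into_j == 0.0  # antisymmetric by construction


def _short_stimulus(n_fibers, seed=1):
    proto = st.MFRateProtocol(mean_rate_hz=10.0, onset_ms=200.0,
                              offset_ms=400.0)
    return st.make_mf_stimulus(proto, n_fibers, seed=seed)


def test_identical_inputs_give_bit_identical_spikes(mini_network):
    stim = _short_stimulus(mini_network.n_mf)
    cfg = eg.SimulationConfig(duration_ms=400.0, seed=5)
    a = eg.run_simulation(mini_network, stim, cfg)
    b = eg.run_simulation(mini_network, stim, cfg)
    for layer in ("GC", "GoC"):
        assert np.array_equal(a.spikes[layer][0], b.spikes[layer][0])
        assert np.array_equal(a.spikes[layer][1], b.spikes[layer][1])


def test_spike_times_ordered_and_within_duration(sim_runs):
    sd = sim_runs("mini", pf=100.0, gj=True)["raw"]
    for layer in ("GC", "GoC"):
        idx, t = sd.spikes[layer]
        assert np.all(t >= 0) and np.all(t <= sd.duration_ms)
        for cell in np.unique(idx)[:20]:
            tc = t[idx == cell]
            assert np.all(np.diff(tc) > 0)  # strictly increasing per cell


def test_granule_cells_silent_before_onset_active_after(sim_runs):
    sd = sim_runs("mini", pf=100.0, gj=True)["raw"]
    _, t_gc = sd.spikes["GC"]
    assert np.all(t_gc >= 1000.0)
    assert (t_gc >= 1000.0).sum() > 0
    _, t_goc = sd.spikes["GoC"]
    assert (t_goc < 1000.0).sum() > 0  # pacemaking throughout


def test_causality_no_response_before_spike_plus_delay(mini_network):
    """A single MF volley at 300 ms cannot move any GC before 300 ms."""
    proto = st.MFRateProtocol(mean_rate_hz=0.0, sd_rate_hz=0.0,
                              onset_ms=250.0, offset_ms=500.0)
    stim = st.MFStimulus(proto, np.zeros(mini_network.n_mf),
                         [np.array([300.0, 300.0, 300.0])
                          if i < 40 else np.empty(0)
                          for i in range(mini_network.n_mf)], seed=0)
    cfg = eg.SimulationConfig(duration_ms=600.0, seed=1,
                              gabaa_weight_percent=0.0)
    sd = eg.run_simulation(mini_network, stim, cfg)
    _, t_gc = sd.spikes["GC"]
    assert np.all(t_gc >= 300.0)
    assert len(t_gc) > 0  # the tripled volley does recruit granule cells


def test_decoupled_network_only_pacemakers_fire(mini_network):
    proto = st.MFRateProtocol(mean_rate_hz=0.0, sd_rate_hz=0.0,
                              onset_ms=100.0, offset_ms=500.0)
    stim = st.MFStimulus(proto, np.zeros(mini_network.n_mf),
                         [np.empty(0)] * mini_network.n_mf, seed=0)
    cfg = eg.SimulationConfig(duration_ms=500.0, seed=1,
                              pf_weight_percent=0.0, gabaa_weight_percent=0.0)
    sd = eg.run_simulation(mini_network, stim, cfg)
    assert sd.layer_spike_count("GC") == 0
    assert sd.layer_spike_count("GoC") > 0


def test_gap_junction_toggle_leaves_mini_feedback_rates_close(sim_runs):
    a = sim_runs("mini", pf=100.0, gj=True)
    b = sim_runs("mini", pf=100.0, gj=False)
    assert a["goc_mfr"] == pytest.approx(b["goc_mfr"], rel=0.10)


def test_halving_dt_changes_layer_rates_below_5pct(sim_runs):
    """Full-scale feedback condition: the explicit step is fine enough that
    halving it leaves both layers' mean rates within 5%."""
    a = sim_runs("default", pf=100.0, gj=True, dt=0.025)
    b = sim_runs("default", pf=100.0, gj=True, dt=0.0125)
    assert b["goc_mfr"] == pytest.approx(a["goc_mfr"], rel=0.05)
    assert b["gc_mfr"] == pytest.approx(a["gc_mfr"], rel=0.05)


def test_feedback_loop_oscillation_signature(sim_runs):
    """With feedback and mossy-fiber drive the GoC PSTH autocorrelation has
    a clear non-zero-lag peak; with neither feedback nor coupling the layer
    is desynchronized."""
    from gocnet import analysis as an
    fb = sim_runs("mini", pf=100.0, gj=True)
    flat = sim_runs("mini", pf=0.0, gj=False)
    ac_fb = an.autocorrelation_peak(fb["goc_psth"])
    ac_flat = an.autocorrelation_peak(flat["goc_psth"])
    assert ac_fb > 0.1 > ac_flat
    assert ac_fb > 2.0 * ac_flat


def test_engine_matches_reference_single_neuron_integrator():
    """The vectorized kernel and the scalar reference integrator must give
    identical spike trains for an isolated cell."""
    for params, current in ((GoCParams(), 0.0), (GoCParams(), 200.0),
                            (GCParams(), 50.0)):
        ref, _ = simulate_single(params, current, 1500.0)
        ker = eg.simulate_isolated(params, [current], 1500.0)[0]
        assert len(ref) == len(ker)
        assert np.allclose(ref, ker, atol=1e-9)


def test_trace_recording_and_bad_ids(mini_network):
    stim = _short_stimulus(mini_network.n_mf)
    cfg = eg.SimulationConfig(duration_ms=300.0, seed=2,
                              record_traces=(("GoC", 0), ("GC", 5)))
    sd = eg.run_simulation(mini_network, stim, cfg)
    v = sd.traces[("GoC", 0)]
    assert np.all(np.isfinite(v))
    assert len(v) == len(sd.trace_times_ms)
    with pytest.raises(ConfigError):
        eg.run_simulation(mini_network, stim, eg.SimulationConfig(
            duration_ms=300.0, record_traces=(("GoC", 10**6),)))


def test_mismatched_stimulus_rejected(mini_network):
    stim = _short_stimulus(mini_network.n_mf + 1)
    with pytest.raises(ConfigError):
        eg.run_simulation(mini_network, stim,
                          eg.SimulationConfig(duration_ms=300.0))


def test_config_validation():
    with pytest.raises(ConfigError):
        eg.SimulationConfig(dt_ms=0.0)
    with pytest.raises(ConfigError):
        eg.SimulationConfig(dt_ms=1.0)
    with pytest.raises(ConfigError):
        eg.SimulationConfig(pf_weight_percent=-1.0)


def test_spikedata_round_trips(tmp_path, sim_runs):
    sd = sim_runs("mini", pf=100.0, gj=True)["raw"]
    h5 = tmp_path / "spikes.h5"
    sd.to_hdf5(h5)
    back = eg.SpikeData.from_hdf5(h5)
    assert back.n_cells == sd.n_cells
    for layer in ("GC", "GoC"):
        assert np.array_equal(back.spikes[layer][1], sd.spikes[layer][1])
    txt = tmp_path / "spikes.tsv"
    sd.to_text(txt)
    lines = txt.read_text().splitlines()
    assert lines[0] == "layer\tneuron_id\ttime_ms"
    n_total = sum(len(t) for _, t in sd.spikes.values())
    assert len(lines) == n_total + 1


class TestTwoCellDemo:
    def test_uncoupled_follower_stays_at_rest(self):
        demo = eg.two_cell_demo(gj_nS=0.0, stimulus="mf_10hz",
                                duration_ms=1500.0)
        assert np.max(np.abs(demo["v_follower"] - demo["v_rest"])) < 1e-6

    def test_pulse_protocol_spikes_only_during_pulse(self):
        demo = eg.two_cell_demo(stimulus="pulse", duration_ms=2000.0)
        sp = demo["driver_spikes"]
        assert len(sp) > 0
        assert np.all((sp >= 1500.0) & (sp < 1650.0))

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            eg.two_cell_demo(gj_location="axon")
        with pytest.raises(ConfigError):
            eg.two_cell_demo(stimulus="ramp")
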