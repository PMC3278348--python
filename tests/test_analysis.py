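"""Analysis pipeline: trimming, rates, PSTHs, spectra, cycles, robustness."""

import math

import numpy as np
import pytest

from gocnet import analysis as an
from gocnet import network as nw
from gocnet.engine import SpikeData
from gocnet.errors import ConfigError


def _fake_spikes(n_cells, events, duration=2000.0):
    """SpikeData for one synthetic GoC layer; events = (cell, time) pairs."""
    idx = np.array([e[0] for e in events], dtype=np.int64)
    t = np.array([e[1] for e in events], dtype=float)
    order = np.argsort(t, kind="stable")
    return SpikeData({"GoC": (idx[order], t[order])}, {"GoC": n_cells},
                     duration, 0.025, 0, "test")


def _psth_from_counts(counts, bin_ms=1.0):
    counts = np.asarray(counts, dtype=np.int64)
    return an.PSTH("GoC", bin_ms, np.arange(len(counts)) * bin_ms, counts)


class TestTrimming:
    def test_default_scale_retains_printed_counts(self):
        cfg = nw.default_config()
        trim = an.default_trim_spec(cfg.layer_dims)
        assert trim.analysis_dims["MF"] == (6, 82)
        assert trim.analysis_dims["GC"] == (18, 246)
        assert trim.analysis_dims["GoC"] == (3, 41)
        assert trim.n_retained("MF") == 492
        assert trim.n_retained("GC") == 4428
        assert trim.n_retained("GoC") == 123

    def test_trim_keeps_center_drops_border(self):
        cfg = nw.default_config(spatial_randomness=0.0)
        geom = nw.build_geometry(cfg, seed=0)
        # cell 0 is the corner; the grid center cell must survive
        center = (5 // 2) * 45 + 45 // 2
        sd = _fake_spikes(225, [(0, 1500.0), (center, 1500.0)])
        trim = an.default_trim_spec(cfg.layer_dims)
        out = an.trim_borders(sd, geom, an.TrimSpec({"GoC":
                                                     trim.analysis_dims["GoC"]}))
        assert out.n_cells["GoC"] == 123
        kept_cells = out.spikes["GoC"][0]
        assert center in kept_cells
        assert 0 not in kept_cells

    def test_trim_equal_dims_is_identity(self):
        cfg = nw.default_config()
        geom = nw.build_geometry(cfg, seed=0)
        sd = _fake_spikes(225, [(0, 10.0), (224, 20.0)])
        out = an.trim_borders(sd, geom, an.TrimSpec({"GoC": (5, 45)}))
        assert out.n_cells["GoC"] == 225
        assert len(out.spikes["GoC"][1]) == 2

    def test_oversized_analysis_dims_rejected(self):
        cfg = nw.default_config()
        geom = nw.build_geometry(cfg, seed=0)
        sd = _fake_spikes(225, [])
        with pytest.raises(ConfigError):
            an.trim_borders(sd, geom, an.TrimSpec({"GoC": (6, 45)}))


class TestMeanFiringRate:
    def test_empty_is_zero(self):
        sd = _fake_spikes(10, [])
        assert an.mean_firing_rate(sd, "GoC") == 0.0

    def test_single_neuron_definition(self):
        sd = _fake_spikes(1, [(0, 1000.0 + 100.0 * k) for k in range(10)])
        assert an.mean_firing_rate(sd, "GoC") == pytest.approx(10.0)

    def test_firing_neuron_convention(self):
        # three neurons with (2, 4, 0) spikes in 1 s -> mean over the two
        # firing neurons = 3 Hz
        ev = [(0, 1100.0), (0, 1200.0)] + [(1, 1300.0 + 10 * k)
                                           for k in range(4)]
        sd = _fake_spikes(3, ev)
        assert an.mean_firing_rate(sd, "GoC") == pytest.approx(3.0)
        assert an.mean_firing_rate(sd, "GoC", firing_only=False) == \
            pytest.approx(2.0)

    def test_window_validation(self):
        sd = _fake_spikes(1, [])
        with pytest.raises(ConfigError):
            an.mean_firing_rate(sd, "GoC", (0.0, 5000.0))


class TestPSTH:
    def test_counts_and_total(self):
        sd = _fake_spikes(5, [(0, 10.2), (1, 10.7), (2, 500.0)])
        psth = an.compute_psth(sd, "GoC")
        assert psth.counts[10] == 2  # two spikes in the same 1-ms bin
        assert psth.counts.sum() == 3
        assert psth.counts.dtype == np.int64

    def test_shift_equivariance(self):
        ev = [(0, 100.0 + 7 * k) for k in range(30)]
        a = an.compute_psth(_fake_spikes(1, ev), "GoC")
        b = an.compute_psth(_fake_spikes(
            1, [(c, t + 5.0) for c, t in ev]), "GoC")
        assert np.array_equal(a.counts[100:300], b.counts[105:305])

    def test_poisson_rate_recovery(self):
        rng = np.random.default_rng(0)
        rate = 400.0  # aggregate spikes/s
        t = np.sort(rng.uniform(0, 2000.0, rng.poisson(rate * 2.0)))
        sd = _fake_spikes(1, [(0, ti) for ti in t])
        psth = an.compute_psth(sd, "GoC")
        se = math.sqrt(rate / 1000.0 / len(psth.counts))
        assert abs(psth.counts.mean() - rate / 1000.0) < 3 * se


class TestWaveletSpectrum:
    def test_sinusoid_peak_recovered_within_1Hz(self):
        t = np.arange(1000)
        for f0 in (15.0, 20.0):
            counts = np.rint(10 + 8 * np.sin(2 * np.pi * f0 * t / 1000.0))
            psth = _psth_from_counts(counts)
            spec = an.wavelet_power(psth, (0.0, 1000.0))
            assert spec.peak_frequency() == pytest.approx(f0, abs=1.0)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(3)
        psth = _psth_from_counts(rng.poisson(10.0, 1000))
        spec = an.wavelet_power(psth, (0.0, 1000.0))
        band = spec.frequencies_hz >= 4.0
        p = spec.power[band]
        assert p.max() < 3.0 * np.median(p)

    def test_all_zero_psth_gives_zero_power(self):
        spec = an.wavelet_power(_psth_from_counts(np.zeros(1000)),
                                (0.0, 1000.0))
        assert np.all(spec.power == 0.0)

    def test_short_window_warns(self):
        psth = _psth_from_counts(np.ones(500))
        with pytest.warns(UserWarning):
            an.wavelet_power(psth, (0.0, 500.0),
                             freqs_hz=np.geomspace(1.0, 120.0, 30))

    def test_normalized_peaks_at_one(self):
        t = np.arange(1000)
        counts = np.rint(10 + 8 * np.sin(2 * np.pi * 20 * t / 1000.0))
        spec = an.wavelet_power(_psth_from_counts(counts), (0.0, 1000.0))
        assert spec.normalized().power.max() == pytest.approx(1.0)


class TestCycles:
    def test_dc_input_unchanged_by_filter(self):
        psth = _psth_from_counts(np.full(2000, 7.0))
        cy = an.filter_and_cycles(psth)
        assert np.allclose(cy.filtered, 7.0, atol=1e-6)

    def test_15Hz_cycle_spacing(self):
        t = np.arange(2000)
        counts = np.rint(20 + 15 * np.sin(2 * np.pi * 15 * (t - 1000) / 1000.0))
        counts[:1000] = 20  # flat pre-onset baseline has SD 0
        counts[:1000] += (t[:1000] % 7 == 0)  # add tiny baseline jitter
        psth = _psth_from_counts(counts)
        cy = an.filter_and_cycles(psth, onset_ms=1000.0)
        gaps = np.diff(cy.peak_times_ms)
        assert np.median(gaps) == pytest.approx(1000.0 / 15.0, abs=2.0)

    def test_single_bump_detected_once(self):
        counts = np.zeros(1500)
        counts[1100:1120] = [5, 9, 14, 18, 20, 21, 20, 18, 14, 9,
                             5, 3, 2, 1, 1, 0, 0, 0, 0, 0]
        cy = an.filter_and_cycles(_psth_from_counts(counts), onset_ms=1000.0)
        assert cy.n_cycles == 1
        assert 1100 <= cy.peak_times_ms[0] <= 1120


class TestLatency:
    def test_simple_subtraction(self):
        cy = an.CycleAnalysis(np.zeros(1), np.zeros(1),
                              np.array([1025.0, 1090.0]),
                              np.array([3.0, 4.0]), 0.0)
        assert an.first_cycle_latency(cy) == 25.0

    def test_no_cycles_gives_nan_sentinel(self):
        cy = an.CycleAnalysis(np.zeros(1), np.zeros(1), np.empty(0),
                              np.empty(0), 0.0)
        lat = an.first_cycle_latency(cy)
        assert math.isnan(lat)
        assert lat != 0.0


def test_robustness_effect_identical_inputs_is_zero():
    t = np.arange(2000)
    counts = np.rint(12 + 10 * np.sin(2 * np.pi * 20 * (t - 1000) / 1000.0))
    counts[:1000] = 2
    psth = _psth_from_counts(counts)
    rob = an.robustness_effect(psth, psth)
    assert rob.delta_amplitude == 0.0
    assert rob.delta_latency_ms == 0.0
    assert rob.n_cycles > 10


def test_primary_oscillation_band_is_physiological(sim_runs):
    """Full-scale feedback network at 5-Hz drive: the GoC PSTH primary
    spectral band falls in the 5-35 Hz range of granular-layer rhythms."""
    res = sim_runs("default", pf=100.0, gj=True)
    spec = an.wavelet_power(res["goc_psth"])
    peak = spec.peak_frequency(fmin_hz=4.0)
    half = spec.power >= 0.5 * spec.power.max()
    lo = spec.frequencies_hz[half].min()
    hi = spec.frequencies_hz[half].max()
    print(f"primary band: peak {peak:.1f} Hz, half-power {lo:.1f}-{hi:.1f} Hz")
    assert 5.0 <= peak <= 35.0


def test_layer_rates_nondecreasing_in_drive(sim_runs):
    """Mean firing rates grow with mossy-fiber rate (both layers) and with
    feedback weight (GoC layer), as the input-output surfaces require."""
    slow = sim_runs("mini", pf=10.0, gj=True, mf=5.0)
    fast = sim_runs("mini", pf=10.0, gj=True, mf=40.0)
    assert fast["goc_mfr"] >= slow["goc_mfr"]
    assert fast["gc_mfr"] >= slow["gc_mfr"]
    strong = sim_runs("mini", pf=100.0, gj=True, mf=5.0)
    assert strong["goc_mfr"] >= slow["goc_mfr"]


def test_resonance_scan_api(mini_network):
    freqs, power, peak = an.resonance_scan(
        mini_network, [10.0, 20.0], gj_enabled=False, seed=1,
        duration_ms=800.0)
    assert len(freqs) == len(power) == 2
    assert np.all(np.isfinite(power))
    assert power.max() == pytest.approx(1.0)  # normalized to curve max
    assert peak in freqs


def test_export_tables(tmp_path):
    psth = _psth_from_counts(np.arange(10))
    psth.export_text(tmp_path / "psth.tsv")
    header = (tmp_path / "psth.tsv").read_text().splitlines()[0]
    assert header == "time_ms\tcount"
    spec = an.wavelet_power(_psth_from_counts(np.ones(1000) * 3),
                            (0.0, 1000.0))
    spec.export_text(tmp_path / "spec.tsv")
    assert (tmp_path / "spec.tsv").read_text().splitlines()[0] == \
        "freq_Hz\tpower"
    rob = an.RobustnessSummary(1.0, 0.5, 2.0, 10,
                               {"mf_rate_hz": 5, "pf_weight_percent": 10})
    an.export_robustness_table(tmp_path / "rob.tsv", [rob])
    lines = (tmp_path / "rob.tsv").read_text().splitlines()
    assert len(lines) == 2 and lines[1].startswith("5\t10\t1")
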