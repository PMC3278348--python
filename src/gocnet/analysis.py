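"""Measurement pipeline for population oscillations.

Mirrors the published analysis chain: border trimming (only the central
cells of each layer are analyzed, so edge cells with reduced in-degree do
not bias the statistics), mean firing rates over the stimulation window
(averaged across *firing* neurons), 1-ms population spike-time histograms
(PSTHs), Morlet-wavelet spectra of the Golgi-layer PSTH, Butterworth
low-pass filtering for cycle extraction, first-cycle latency, and the
paired with/without-gap-junction robustness quantification.

A note on the cycle filter: the stated low-pass cutoff (500 Hz, order 5)
sits exactly at the Nyquist frequency of the 1-kHz PSTH sampling, so the
filter is implemented with its normalized cutoff clipped just below 1 and
applied forward-backward (zero phase), which preserves cycle peak times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.signal import butter, filtfilt, find_peaks

from .errors import ConfigError
from .engine import SpikeData, SimulationConfig, run_simulation
from .network import Network, LAYER_MF, LAYER_GC, LAYER_GOC
from .stimulus import (MFRateProtocol, SinusoidProtocol, make_mf_stimulus,
                       BACKGROUND_NOISE_HZ)

#: Morlet wavelet used for PSTH spectra (bandwidth 1.5, center freq 1.0).
WAVELET = "cmor1.5-1.0"

#: Fraction of rows / columns retained by default border trimming. These
#: reproduce the published analysis dims on the full-scale grids:
#: MF 10x90 -> 6x82 (492), GC 30x270 -> 18x246 (4428), GoC 5x45 -> 3x41 (123).
TRIM_ROW_FRACTION = 0.6
TRIM_COL_FRACTION = 41.0 / 45.0


@dataclass(frozen=True)
class TrimSpec:
    """Centered analysis window (rows, cols) per layer."""

    analysis_dims: dict

    def __post_init__(self):
        for layer, (r, c) in self.analysis_dims.items():
            if r <= 0 or c <= 0:
                raise ConfigError(f"{layer}: analysis dims must be positive")

    def n_retained(self, layer: str) -> int:
        r, c = self.analysis_dims[layer]
        return r * c


def default_trim_spec(layer_dims: dict) -> TrimSpec:
    """Trim rule: keep the centered 60% of rows and ~91% of columns."""
    dims = {}
    for layer, (rows, cols) in layer_dims.items():
        keep_r = max(1, round(rows * TRIM_ROW_FRACTION))
        keep_c = max(1, round(cols * TRIM_COL_FRACTION))
        dims[layer] = (min(keep_r, rows), min(keep_c, cols))
    return TrimSpec(dims)


def retained_indices(geometry, keep_dims) -> np.ndarray:
    """Flat indices of cells inside the centered analysis window."""
    rows, cols = geometry.grid_dims
    keep_r, keep_c = keep_dims
    if keep_r > rows or keep_c > cols:
        raise ConfigError("analysis dims exceed build dims")
    r0 = (rows - keep_r) // 2
    c0 = (cols - keep_c) // 2
    rr, cc = np.meshgrid(np.arange(r0, r0 + keep_r),
                         np.arange(c0, c0 + keep_c), indexing="ij")
    return (rr * cols + cc).ravel()


def trim_borders(spikes: SpikeData, geometry: dict,
                 trim_spec: TrimSpec) -> SpikeData:
    """Restrict spikes to the centered analysis window of each layer."""
    new_spikes, new_n = {}, {}
    for layer, (idx, t) in spikes.spikes.items():
        if layer not in trim_spec.analysis_dims:
            new_spikes[layer] = (idx, t)
            new_n[layer] = spikes.n_cells[layer]
            continue
        keep = retained_indices(geometry[layer],
                                trim_spec.analysis_dims[layer])
        mask = np.isin(idx, keep)
        new_spikes[layer] = (idx[mask], t[mask])
        new_n[layer] = len(keep)
    return replace(spikes, spikes=new_spikes, n_cells=new_n)


def mean_firing_rate(spikes: SpikeData, layer: str,
                     window_ms=(1000.0, 2000.0),
                     firing_only: bool = True) -> float:
    """Layer mean firing rate (Hz) over a window.

    By convention the average runs over *firing* neurons (cells with zero
    spikes in the window are excluded), which raises the sparse granule
    layer's value relative to an all-neuron mean.
    """
    t0, t1 = window_ms
    if t1 <= t0 or t1 > spikes.duration_ms + 1e-9:
        raise ConfigError("window must lie within the simulation")
    idx, t = spikes.spikes[layer]
    m = (t >= t0) & (t < t1)
    if not m.any():
        return 0.0
    counts = np.bincount(idx[m], minlength=spikes.n_cells[layer])
    denom = (counts > 0).sum() if firing_only else spikes.n_cells[layer]
    if denom == 0:
        return 0.0
    return counts.sum() / denom / ((t1 - t0) / 1000.0)


@dataclass
class PSTH:
    """Population spike-time histogram of one layer (integer counts)."""

    layer: str
    bin_ms: float
    edges_ms: np.ndarray   # left bin edges
    counts: np.ndarray

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.bin_ms

    def window(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        sel = (self.edges_ms >= t0_ms) & (self.edges_ms < t1_ms)
        return self.counts[sel]

    def export_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.edges_ms, self.counts]),
                   fmt=("%.3f", "%d"), delimiter="\t",
                   header="time_ms\tcount", comments="")


def compute_psth(spikes: SpikeData, layer: str, bin_ms: float = 1.0,
                 t_range=None) -> PSTH:
    """Total spikes of a layer per time bin (default 1 ms)."""
    if t_range is None:
        t_range = (0.0, spikes.duration_ms)
    _, t = spikes.spikes[layer]
    n_bins = int(round((t_range[1] - t_range[0]) / bin_ms))
    counts, edges = np.histogram(t, bins=n_bins, range=t_range)
    return PSTH(layer, bin_ms, edges[:-1], counts.astype(np.int64))


@dataclass
class SpectralResult:
    """Time-averaged Morlet scalogram of a PSTH window."""

    frequencies_hz: np.ndarray
    power: np.ndarray
    method: str
    window_ms: tuple

    def peak_frequency(self, fmin_hz: float = None, fmax_hz: float = None):
        sel = np.ones(len(self.frequencies_hz), dtype=bool)
        if fmin_hz is not None:
            sel &= self.frequencies_hz >= fmin_hz
        if fmax_hz is not None:
            sel &= self.frequencies_hz <= fmax_hz
        f, p = self.frequencies_hz[sel], self.power[sel]
        return float(f[np.argmax(p)])

    def power_at(self, freq_hz: float) -> float:
        return float(self.power[np.argmin(np.abs(self.frequencies_hz
                                                 - freq_hz))])

    def normalized(self) -> "SpectralResult":
        peak = self.power.max()
        p = self.power / peak if peak > 0 else self.power
        return replace(self, power=p)

    def export_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.frequencies_hz, self.power]),
                   fmt="%.6g", delimiter="\t",
                   header="freq_Hz\tpower", comments="")


def wavelet_power(psth: PSTH, window_ms=(1000.0, 2000.0),
                  freqs_hz=None) -> SpectralResult:
    """Morlet-wavelet spectrum of the mean-subtracted PSTH window.

    Power is the squared coefficient magnitude averaged over time within
    the window. The frequency grid spans 1-120 Hz (log-spaced) by default.
    """
    if freqs_hz is None:
        freqs_hz = np.geomspace(1.0, 120.0, 120)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    x = psth.window(*window_ms).astype(float)
    dur_ms = window_ms[1] - window_ms[0]
    if dur_ms < 2000.0 / freqs_hz.min():
        warnings.warn(
            f"analysis window ({dur_ms} ms) holds fewer than two cycles of "
            f"the lowest requested frequency ({freqs_hz.min()} Hz)")
    if len(x) == 0 or not np.any(x):
        return SpectralResult(freqs_hz, np.zeros(len(freqs_hz)),
                              WAVELET, window_ms)
    scales = pywt.frequency2scale(WAVELET, freqs_hz * psth.bin_ms / 1000.0)
    coef, _ = pywt.cwt(x - x.mean(), scales, WAVELET,
                       sampling_period=psth.bin_ms / 1000.0)
    power = (np.abs(coef) ** 2).mean(axis=1)
    return SpectralResult(freqs_hz, power, WAVELET, window_ms)


def autocorrelation_peak(psth: PSTH, window_ms=(1000.0, 2000.0),
                         lag_range_ms=(5.0, 100.0)) -> float:
    """Largest normalized PSTH autocorrelation at non-zero lag.

    Values near zero indicate desynchronized firing; a clear positive peak
    marks a population rhythm with that period.
    """
    x = psth.window(*window_ms).astype(float)
    if len(x) == 0 or not np.any(x):
        return 0.0
    x = x - x.mean()
    ac = np.correlate(x, x, "full")[len(x) - 1:]
    if ac[0] <= 0:
        return 0.0
    ac = ac / ac[0]
    lo = int(round(lag_range_ms[0] / psth.bin_ms))
    hi = int(round(lag_range_ms[1] / psth.bin_ms))
    return float(ac[lo:hi].max())


def oscillation_strength(psth: PSTH, window_ms, band_hz=(4.0, 120.0)) -> float:
    """Peak-to-median spectral power ratio inside a band (~1 for no rhythm)."""
    spec = wavelet_power(psth, window_ms)
    sel = ((spec.frequencies_hz >= band_hz[0])
           & (spec.frequencies_hz <= band_hz[1]))
    p = spec.power[sel]
    med = np.median(p)
    if med <= 0:
        return 0.0
    return float(p.max() / med)


@dataclass
class CycleAnalysis:
    """Low-pass-filtered PSTH with detected oscillation cycles."""

    filtered: np.ndarray
    edges_ms: np.ndarray
    peak_times_ms: np.ndarray
    amplitudes: np.ndarray   # filtered PSTH value at each peak, spikes/bin
    noise_floor: float

    @property
    def n_cycles(self) -> int:
        return len(self.peak_times_ms)


def filter_and_cycles(psth: PSTH, cutoff_hz: float = 500.0, order: int = 5,
                      onset_ms: float = 1000.0,
                      min_cycle_interval_ms: float = 8.0) -> CycleAnalysis:
    """Zero-phase Butterworth low-pass, then cycle (peak) extraction.

    Cycles are local maxima of the filtered trace exceeding a noise floor
    of (pre-onset mean + 3 SD), with a prominence of at least 5% of the
    post-onset peak-to-peak range (rejecting quantization ripple that the
    near-Nyquist filter passes); the minimum peak separation corresponds
    to a 125-Hz ceiling on detectable cycle rates.
    """
    fs = psth.sampling_hz
    wn = min(cutoff_hz / (fs / 2.0), 0.99)
    b, a = butter(order, wn, btype="low")
    x = psth.counts.astype(float)
    filtered = filtfilt(b, a, x)
    pre = filtered[psth.edges_ms < onset_ms]
    if len(pre):
        floor = pre.mean() + 3.0 * pre.std()
    else:
        floor = 0.0
    post = filtered[psth.edges_ms >= onset_ms]
    distance = max(1, int(round(min_cycle_interval_ms / psth.bin_ms)))
    prominence = max(0.05 * (post.max() - post.min()), 1e-9) if len(post) else None
    peaks, _ = find_peaks(post, height=max(floor, 1e-12), distance=distance,
                          prominence=prominence)
    offset = len(filtered) - len(post)
    times = psth.edges_ms[offset + peaks]
    return CycleAnalysis(filtered, psth.edges_ms, times, post[peaks], floor)


def first_cycle_latency(cycles: CycleAnalysis,
                        stimulus_onset_ms: float = 1000.0) -> float:
    """Time from stimulus onset to the first oscillation cycle peak (ms).

    Returns NaN (the no-oscillation sentinel) when no cycle was detected
    after onset — never 0.
    """
    after = cycles.peak_times_ms[cycles.peak_times_ms >= stimulus_onset_ms]
    if len(after) == 0:
        return math.nan
    return float(after[0] - stimulus_onset_ms)


@dataclass
class RobustnessSummary:
    """Paired gap-junction on/off oscillation metrics.

    ``delta_amplitude`` is the mean over paired cycles of (amplitude with
    couplings - amplitude without), in spikes/bin; ``delta_latency`` is
    latency(without) - latency(with), so both are positive when the
    couplings strengthen and advance the oscillation.
    """

    delta_amplitude: float
    delta_amplitude_sd: float
    delta_latency_ms: float
    n_cycles: int
    condition: dict = None


def robustness_effect(psth_gj: PSTH, psth_nogj: PSTH,
                      window_ms=(1000.0, 2000.0),
                      onset_ms: float = 1000.0,
                      condition: dict = None) -> RobustnessSummary:
    """Quantify how much gap junctions strengthen/advance the oscillation.

    Both PSTHs must come from the same network seed and stimulus with only
    the gap-junction flag toggled. Cycles within the analysis window are
    paired by index up to the shorter cycle list.
    """
    cy_gj = filter_and_cycles(psth_gj, onset_ms=onset_ms)
    cy_ng = filter_and_cycles(psth_nogj, onset_ms=onset_ms)

    def in_window(cy):
        sel = ((cy.peak_times_ms >= window_ms[0])
               & (cy.peak_times_ms < window_ms[1]))
        return cy.amplitudes[sel]

    a_gj, a_ng = in_window(cy_gj), in_window(cy_ng)
    m = min(len(a_gj), len(a_ng))
    if m > 0:
        deltas = a_gj[:m] - a_ng[:m]
        d_amp, d_sd = float(deltas.mean()), float(deltas.std())
    else:
        # degenerate: one side has no cycles at all
        d_amp = float((a_gj.mean() if len(a_gj) else 0.0)
                      - (a_ng.mean() if len(a_ng) else 0.0))
        d_sd = math.nan
    lat_gj = first_cycle_latency(cy_gj, onset_ms)
    lat_ng = first_cycle_latency(cy_ng, onset_ms)
    d_lat = lat_ng - lat_gj  # NaN propagates as the sentinel
    return RobustnessSummary(d_amp, d_sd, d_lat, m, condition)


def resonance_scan(network: Network, frequencies_hz, gj_enabled: bool,
                   seed: int, pf_weight_percent: float = 0.0,
                   amplitude_nA: float = 0.1, duration_ms: float = 2000.0,
                   dt_ms: float = 0.025, trim: TrimSpec = None):
    """GoC-layer oscillation power versus sinusoidal drive frequency.

    Every GoC soma receives A sin(2 pi f t) on top of background mossy-fiber
    noise (7 +- 2.86 Hz); one simulation per frequency. The response power
    is the time-averaged wavelet power of the trimmed GoC PSTH at the drive
    frequency, normalized to the curve maximum.

    Returns (frequencies, normalized power, peak frequency).
    """
    trim = trim or default_trim_spec(network.config.layer_dims)
    mean, sd = BACKGROUND_NOISE_HZ
    powers = []
    for f in frequencies_hz:
        proto = MFRateProtocol(mean_rate_hz=mean, sd_rate_hz=sd,
                               onset_ms=0.0, offset_ms=duration_ms)
        stim = make_mf_stimulus(proto, network.n_mf, seed=seed,
                                sinusoid=SinusoidProtocol(
                                    amplitude_nA=amplitude_nA,
                                    frequency_hz=f))
        cfg = SimulationConfig(dt_ms=dt_ms, duration_ms=duration_ms,
                               seed=seed, gap_junctions_enabled=gj_enabled,
                               pf_weight_percent=pf_weight_percent)
        sd_out = run_simulation(network, stim, cfg)
        trimmed = trim_borders(sd_out, network.geometry, trim)
        psth = compute_psth(trimmed, LAYER_GOC)
        spec = wavelet_power(psth, (duration_ms / 2.0, duration_ms))
        powers.append(spec.power_at(f))
    powers = np.asarray(powers, dtype=float)
    if powers.max() > 0:
        norm = powers / powers.max()
    else:
        norm = powers
    peak = float(np.asarray(frequencies_hz)[np.argmax(powers)])
    return np.asarray(frequencies_hz, dtype=float), norm, peak


def export_robustness_table(path, summaries) -> None:
    """Delimited table: mf_rate, pf_weight, delta_amp, delta_amp_sd,
    delta_latency."""
    with open(path, "w") as fh:
        fh.write("mf_rate_hz\tpf_weight_pct\tdelta_amp\tdelta_amp_sd"
                 "\tdelta_latency_ms\n")
        for s in summaries:
            cond = s.condition or {}
            fh.write(f"{cond.get('mf_rate_hz', '')}\t"
                     f"{cond.get('pf_weight_percent', '')}\t"
                     f"{s.delta_amplitude:.6g}\t{s.delta_amplitude_sd:.6g}\t"
                     f"{s.delta_latency_ms:.6g}\n")
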