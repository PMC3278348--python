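"""Synthetic network inputs: mossy-fiber spike trains and sinusoidal drive.

Mossy fibers are spike generators. Each fiber's firing rate is drawn once
per trial from a Gaussian whose (mean, SD) pairs are the published
stimulation set (e.g. 5 +- 1.90 Hz); negative draws are truncated to zero,
which slightly biases the realized mean upward at the lowest rates. Spikes
are then a homogeneous Poisson process per fiber, restricted to the
stimulation window: every simulation runs 1 s without input followed by
1 s of stimulation.

For resonance scans, a sinusoidal current (+-0.1 nA) is injected into every
Golgi-cell soma while the whole network receives background 7 +- 2.86 Hz
mossy-fiber noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

#: Published (mean, SD) Gaussian parameters of the MF rate distributions (Hz).
RATE_TABLE = {
    1: 0.71, 5: 1.90, 10: 3.00, 15: 3.33,
    20: 4.28, 40: 6.16, 70: 7.57, 100: 8.72,
}

#: Extended 16-entry table used with the 6-mm elongated network.
ELONGATED_RATE_TABLE = {
    1: 0.71, 5: 1.90, 10: 3.00, 15: 3.33, 20: 4.28, 30: 4.92, 40: 6.15,
    45: 6.34, 50: 6.63, 55: 6.86, 60: 7.17, 65: 7.39, 70: 7.57, 80: 8.10,
    90: 8.24, 100: 8.72,
}

#: Background MF noise used during sinusoidal resonance scans (mean, SD) Hz.
BACKGROUND_NOISE_HZ = (7.0, 2.86)

#: Sinusoid frequencies of the resonance protocol (Hz).
SINUSOID_FREQUENCIES_HZ = (1, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90, 100)


def sd_for_rate(mean_rate_hz: float, table=None) -> float:
    """SD paired with a mean rate; interpolates for unlisted means."""
    table = table or RATE_TABLE
    if mean_rate_hz in table:
        return table[mean_rate_hz]
    keys = sorted(table)
    return float(np.interp(mean_rate_hz, keys, [table[k] for k in keys]))


@dataclass(frozen=True)
class MFRateProtocol:
    """Gaussian-rate mossy-fiber stimulation protocol.

    The silent pre-period occupies [0, onset); fibers fire at their drawn
    rates during [onset, offset).
    """

    mean_rate_hz: float = 5.0
    sd_rate_hz: float = None
    onset_ms: float = 1000.0
    offset_ms: float = 2000.0

    def __post_init__(self):
        if self.sd_rate_hz is None:
            object.__setattr__(self, "sd_rate_hz", sd_for_rate(self.mean_rate_hz))
        if self.sd_rate_hz < 0:
            raise ConfigError("sd_rate must be >= 0")
        if not self.onset_ms < self.offset_ms:
            raise ConfigError("onset must precede offset")

    @property
    def pre_period_ms(self) -> float:
        return self.onset_ms


@dataclass(frozen=True)
class SinusoidProtocol:
    """Somatic sinusoidal current into every GoC, over background MF noise."""

    amplitude_nA: float = 0.1
    frequency_hz: float = 10.0
    background_mf_hz: tuple = BACKGROUND_NOISE_HZ

    def __post_init__(self):
        if self.amplitude_nA <= 0 or self.frequency_hz <= 0:
            raise ConfigError("amplitude and frequency must be > 0")


def draw_fiber_rates(protocol: MFRateProtocol, n_fibers: int, seed: int) -> np.ndarray:
    """Per-fiber rates ~ Normal(mean, sd), truncated at 0; seeded."""
    if n_fibers <= 0:
        raise ConfigError("n_fibers must be > 0")
    rng = np.random.default_rng(seed)
    rates = rng.normal(protocol.mean_rate_hz, protocol.sd_rate_hz, n_fibers)
    return np.maximum(rates, 0.0)


def generate_spike_trains(rates_hz: np.ndarray, protocol: MFRateProtocol,
                          seed: int) -> list:
    """Homogeneous Poisson trains per fiber inside [onset, offset).

    Returns a list of sorted spike-time arrays (ms), empty before onset.
    """
    rng = np.random.default_rng(seed)
    window_s = (protocol.offset_ms - protocol.onset_ms) / 1000.0
    trains = []
    for r in rates_hz:
        n = rng.poisson(r * window_s)
        t = np.sort(rng.uniform(protocol.onset_ms, protocol.offset_ms, n))
        trains.append(t)
    return trains


def sinusoid_current_nA(protocol: SinusoidProtocol, t_ms) -> float:
    """A sin(2 pi f t); identical waveform for every GoC."""
    if np.any(np.asarray(t_ms) < 0):
        raise ConfigError("t must be >= 0")
    return protocol.amplitude_nA * np.sin(
        2.0 * np.pi * protocol.frequency_hz * np.asarray(t_ms) / 1000.0)


@dataclass
class MFStimulus:
    """Realized stimulus: one spike train per fiber plus optional extras.

    ``goc_active_mask`` marks which fibers drive Golgi cells (all, unless a
    sparse-input variant is applied; granule-cell drive is never masked).
    ``sinusoid`` optionally injects a somatic current into every GoC.
    """

    protocol: MFRateProtocol
    rates_hz: np.ndarray
    spike_trains: list
    seed: int
    goc_active_mask: np.ndarray = None
    sinusoid: SinusoidProtocol = None

    def __post_init__(self):
        if self.goc_active_mask is None:
            self.goc_active_mask = np.ones(len(self.rates_hz), dtype=bool)

    @property
    def n_fibers(self) -> int:
        return len(self.rates_hz)

    def merged_events(self):
        """(fiber_id, time_ms) arrays of all spikes sorted by time."""
        ids = np.concatenate([
            np.full(len(t), i, dtype=np.int32)
            for i, t in enumerate(self.spike_trains)
        ]) if self.spike_trains else np.empty(0, np.int32)
        times = (np.concatenate(self.spike_trains)
                 if self.spike_trains else np.empty(0))
        order = np.argsort(times, kind="stable")
        return ids[order], times[order]

    def export_text(self, path) -> None:
        """Two-column delimited spike file (neuron_id, time_ms)."""
        ids, times = self.merged_events()
        with open(path, "w") as fh:
            fh.write("neuron_id\ttime_ms\n")
            for i, t in zip(ids, times):
                fh.write(f"{i}\t{t:.4f}\n")


def make_mf_stimulus(protocol: MFRateProtocol, n_fibers: int, seed: int,
                     sinusoid: SinusoidProtocol = None) -> MFStimulus:
    """Draw rates and trains from one master seed (rates and the Poisson
    process use independent child streams)."""
    ss = np.random.SeedSequence(seed)
    s_rates, s_trains = [int(c.generate_state(1)[0]) % (2**31)
                         for c in ss.spawn(2)]
    rates = draw_fiber_rates(protocol, n_fibers, s_rates)
    trains = generate_spike_trains(rates, protocol, s_trains)
    return MFStimulus(protocol, rates, trains, seed, sinusoid=sinusoid)


def sparse_mf_variant(stimulus: MFStimulus, active_fraction: float,
                      seed: int) -> MFStimulus:
    """Restrict the Golgi-cell drive to a seeded random subset of fibers.

    Only MF->GoC inputs are thinned; the granule-cell drive is unchanged.
    ``active_fraction = 1`` reproduces the base stimulus exactly.
    """
    if not (0.0 < active_fraction <= 1.0):
        raise ConfigError("active_fraction must be in (0, 1]")
    if active_fraction == 1.0:
        mask = np.ones(stimulus.n_fibers, dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        mask = rng.random(stimulus.n_fibers) < active_fraction
    return replace(stimulus, goc_active_mask=mask)
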