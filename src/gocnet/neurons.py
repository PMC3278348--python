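"""Reduced spiking models of cerebellar Golgi cells and granule cells.

Both cell types are exponential integrate-and-fire neurons with a
conductance-based afterhyperpolarization (AHP) variable:

    C dV/dt = gL (EL - V) + gK (EK - V)
              + gNa * DeltaT * exp((V - VT) / DeltaT)      (spike initiation)
              + gAHP (EAHP - V) + I_syn + I_gap + I_ext

A spike is detected when V crosses 0 mV; the trace is then pinned at a
peak value for one step, reset, and the AHP conductance is incremented so
the membrane shows an explicit undershoot. The exponential term stands in
for the sodium spike-initiation current, so "suppressing sodium" (gNa = 0)
removes spiking while leaving the passive membrane intact.

Golgi cell (GoC)
    The passive membrane combines a depolarizing leak (E = -44.5 mV) and a
    background K conductance (E = -80 mV) balanced so the sodium-suppressed
    cell rests at -60 mV with a somatic input resistance of 159 MOhm. With
    the sodium term enabled there is no stable subthreshold fixed point, so
    the cell is an intrinsic pacemaker. The pacemaker rate at zero injected
    current is a calibration target chosen at 8 Hz (within the 2-10 Hz range
    of spontaneous Golgi firing in vitro); gNa and the AHP parameters were
    calibrated once to meet it.

Granule cell (GC)
    A single spherical compartment (diameter 11.8 um for bookkeeping) with
    input resistance 1.62 GOhm, silent at rest, rheobase ~10 pA, and firing
    ~150 Hz at 50 pA sustained current. Capacitance and reset were
    calibrated jointly so that one mossy-fiber input at the network-mean
    conductance stays subthreshold while two coincident inputs spike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np

from .errors import ConfigError, IntegrationError

#: Hard ceiling on the integration step accepted by the models (ms). Above
#: this the explicit update of the exponential spike current is unreliable.
MAX_STABLE_DT_MS = 0.25


@dataclass(frozen=True)
class GoCParams:
    """Golgi-cell model parameters (defaults are the calibrated values)."""

    input_resistance_MOhm: float = 159.0
    v_rest_mV: float = -60.0
    e_leak_mV: float = -44.5          # depolarizing leak reversal
    e_k_mV: float = -80.0             # background K reversal
    c_m_pF: float = 80.0
    g_na_nS: float = 13.0             # spike-initiation conductance scale
    v_t_mV: float = -57.0             # exponential threshold
    delta_t_mV: float = 3.0           # spike-initiation sharpness
    v_peak_mV: float = 10.0
    v_reset_mV: float = -62.0
    spike_detect_mV: float = 0.0
    refractory_ms: float = 1.0
    ahp_increment_nS: float = 1.5
    ahp_tau_ms: float = 60.0
    e_ahp_mV: float = -80.0
    pacemaker_rate_hz: float = 8.0    # calibration target at 0 pA
    membrane_area_scale: float = 1.0
    n_compartments: int = 1           # 1 soma; 4 = soma + 3 passive dendrites
    sodium_enabled: bool = True
    #: (current pA, rate Hz) anchors; used only as monotonicity constraints.
    fi_anchors: tuple = ((0.0, 8.0), (200.0, 25.0), (400.0, 45.0))

    def __post_init__(self):
        if self.input_resistance_MOhm <= 0:
            raise ConfigError("input_resistance must be > 0")
        if self.n_compartments not in (1, 4):
            raise ConfigError("n_compartments must be 1 or 4")

    @property
    def g_total_nS(self) -> float:
        """Total static conductance set by the somatic input resistance."""
        return 1000.0 / self.input_resistance_MOhm

    @property
    def g_leak_nS(self) -> float:
        """Depolarizing-leak share fixing the rest potential at v_rest."""
        frac = (self.e_k_mV - self.v_rest_mV) / (self.e_k_mV - self.e_leak_mV)
        return self.g_total_nS * frac

    @property
    def g_k_nS(self) -> float:
        return self.g_total_nS - self.g_leak_nS


@dataclass(frozen=True)
class GCParams:
    """Granule-cell model parameters (defaults are the calibrated values)."""

    diameter_um: float = 11.8
    input_resistance_GOhm: float = 1.62
    v_rest_mV: float = -70.0
    c_m_pF: float = 10.0
    v_t_mV: float = -52.8
    delta_t_mV: float = 1.0
    v_peak_mV: float = 10.0
    v_reset_mV: float = -75.0
    spike_detect_mV: float = 0.0
    refractory_ms: float = 2.0
    ahp_increment_nS: float = 0.0
    ahp_tau_ms: float = 30.0
    e_ahp_mV: float = -80.0
    rheobase_pA: float = 10.0         # calibration target
    fi_anchor_50pA_hz: float = 150.0  # calibration target
    membrane_area_scale: float = 1.0
    sodium_enabled: bool = True

    def __post_init__(self):
        if self.input_resistance_GOhm <= 0:
            raise ConfigError("input_resistance must be > 0")

    @property
    def g_total_nS(self) -> float:
        return 1.0 / self.input_resistance_GOhm

    # Same engine interface as the GoC: single leak, no background K.
    @property
    def e_leak_mV(self) -> float:
        return self.v_rest_mV

    @property
    def g_leak_nS(self) -> float:
        return self.g_total_nS

    @property
    def g_k_nS(self) -> float:
        return 0.0

    @property
    def e_k_mV(self) -> float:
        return -80.0

    @property
    def g_na_nS(self) -> float:
        return self.g_total_nS

    @property
    def n_compartments(self) -> int:
        return 1


@dataclass
class NeuronState:
    """Mutable single-neuron integration state."""

    v_mV: float
    g_ahp_nS: float = 0.0
    refractory_steps: int = 0
    pending_reset: bool = False
    last_spike_time_ms: float = math.nan
    t_ms: float = 0.0


def initial_state(params) -> NeuronState:
    return NeuronState(v_mV=params.v_rest_mV)


def suppress_sodium(params):
    """Return a copy of ``params`` that never spikes (gNa = 0).

    The passive/subthreshold response is untouched, so the suppressed cell
    settles at its configured resting potential. Idempotent.
    """
    return replace(params, sodium_enabled=False)


def step_neuron(state: NeuronState, params, input_current_nA: float,
                synaptic_conductances=(), dt_ms: float = 0.025):
    """Advance one neuron by one explicit step; return (state, spiked).

    ``synaptic_conductances`` is an iterable of (g_nS, e_rev_mV) pairs
    applied as ohmic conductances. The update order mirrors the vectorized
    network kernel exactly (reset, AHP decay, currents, clamp, spike test)
    so single-cell and in-network trajectories coincide.
    """
    if not (0.0 < dt_ms <= MAX_STABLE_DT_MS):
        raise ConfigError(
            f"dt must be in (0, {MAX_STABLE_DT_MS}] ms, got {dt_ms}"
        )
    if not math.isfinite(state.v_mV) or not math.isfinite(input_current_nA):
        raise IntegrationError(
            f"non-finite state or input at t={state.t_ms} ms",
            time_ms=state.t_ms,
        )

    v = state.v_mV
    if state.pending_reset:
        v = params.v_reset_mV
        state.g_ahp_nS += params.ahp_increment_nS
        state.pending_reset = False
    state.g_ahp_nS *= math.exp(-dt_ms / params.ahp_tau_ms)

    i_pA = params.g_leak_nS * (params.e_leak_mV - v)
    i_pA += params.g_k_nS * (params.e_k_mV - v)
    if params.sodium_enabled:
        arg = min((v - params.v_t_mV) / params.delta_t_mV, 16.0)
        i_pA += params.g_na_nS * params.delta_t_mV * math.exp(arg)
    i_pA += state.g_ahp_nS * (params.e_ahp_mV - v)
    for g_nS, e_rev in synaptic_conductances:
        i_pA += g_nS * (e_rev - v)
    i_pA += input_current_nA * 1000.0

    v = v + dt_ms * i_pA / params.c_m_pF
    if not math.isfinite(v):
        raise IntegrationError(
            f"integration blew up at t={state.t_ms} ms", time_ms=state.t_ms
        )
    if v > params.v_peak_mV:
        v = params.v_peak_mV

    spiked = False
    if state.refractory_steps > 0:
        state.refractory_steps -= 1
    elif params.sodium_enabled and v >= params.spike_detect_mV:
        spiked = True
        v = params.v_peak_mV
        state.pending_reset = True
        state.refractory_steps = max(1, int(round(params.refractory_ms / dt_ms)))
        state.last_spike_time_ms = state.t_ms

    state.v_mV = v
    state.t_ms += dt_ms
    return state, spiked


def simulate_single(params, i_const_pA: float = 0.0, duration_ms: float = 1000.0,
                    dt_ms: float = 0.025, record: bool = False,
                    i_pulse=None):
    """Integrate one isolated neuron; return (spike_times_ms, trace | None).

    ``i_pulse`` optionally adds a square pulse (t_on_ms, t_off_ms, amp_pA).
    Plain-Python scalar loop: fast enough for calibration-scale durations
    and independent of the network kernel, so it doubles as its oracle.
    """
    state = initial_state(params)
    n_steps = int(round(duration_ms / dt_ms))
    spikes = []
    trace = np.empty((n_steps, 2)) if record else None
    i_nA = i_const_pA / 1000.0
    for s in range(n_steps):
        i_step = i_nA
        if i_pulse is not None:
            t_on, t_off, amp = i_pulse
            if t_on <= state.t_ms < t_off:
                i_step += amp / 1000.0
        state, spiked = step_neuron(state, params, i_step, (), dt_ms)
        if spiked:
            spikes.append(state.last_spike_time_ms)
        if record:
            trace[s, 0] = state.t_ms
            trace[s, 1] = state.v_mV
    return np.asarray(spikes), trace


def fi_curve(params, currents_pA, duration_s: float = 10.0,
             dt_ms: float = 0.025):
    """Mean firing rate (Hz) versus injected current (pA).

    Rates are spike count / duration over the whole simulation, matching
    the convention used for single-cell frequency-current curves.
    """
    if duration_s < 1.0:
        raise ConfigError("duration must be >= 1 s")
    currents = np.asarray(currents_pA, dtype=float)
    if np.any(np.diff(currents) < 0):
        raise ConfigError("currents must be sorted ascending")
    rates = []
    for i_pA in currents:
        spikes, _ = simulate_single(params, i_pA, duration_s * 1000.0, dt_ms)
        rates.append(len(spikes) / duration_s)
    return np.asarray(rates)


def export_fi_table(path, currents_pA, rates_hz) -> None:
    """Write a delimited (current_pA, rate_Hz) table."""
    arr = np.column_stack([currents_pA, rates_hz])
    np.savetxt(path, arr, fmt="%.6g", delimiter="\t",
               header="current_pA\trate_Hz", comments="")


def input_resistance_check(params, step_pA: float = -5.0,
                           settle_ms: float = 1500.0,
                           dt_ms: float = 0.025) -> float:
    """Measured input resistance (MOhm) from a small hyperpolarizing step.

    Uses the sodium-suppressed model so the estimate reflects the passive
    membrane, as in a voltage-deflection measurement below rest.
    """
    p = suppress_sodium(params)
    _, tr0 = simulate_single(p, 0.0, settle_ms, dt_ms, record=True)
    _, tr1 = simulate_single(p, step_pA, settle_ms, dt_ms, record=True)
    dv = tr1[-1, 1] - tr0[-1, 1]
    return (dv / step_pA) * 1000.0  # mV/pA -> MOhm
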