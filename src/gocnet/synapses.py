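"""Double-exponential synaptic receptor kinetics.

Each receptor type (AMPAR, NMDAR, GABAaR) produces a conductance transient

    g(t) = g_peak * N * (exp(-t / tau_decay) - exp(-t / tau_rise)),  t >= 0

where ``N`` normalizes the waveform so that its maximum equals ``g_peak``.
Events from different presynaptic spikes sum linearly, with no saturation.

Two evaluation routes are provided and must agree to 0.1%:

* :func:`conductance_waveform` — the closed form, used as the oracle;
* :class:`DoubleExpState` — an event-driven two-state-variable recursion
  with exact exponential updates per time step, used by the simulation
  engine for O(neurons) cost per step.

The NMDAR conductance is voltage-independent by default (no Mg2+ block);
an optional block is exposed as a simulation-engine flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

AMPAR = "AMPAR"
NMDAR = "NMDAR"
GABAAR = "GABAaR"

#: Engine receptor channel indices (column order of conductance state arrays).
RECEPTOR_INDEX = {AMPAR: 0, NMDAR: 1, GABAAR: 2}


@dataclass(frozen=True)
class ReceptorKinetics:
    """Kinetic constants of one receptor type.

    Parameters
    ----------
    receptor:
        Receptor name, one of ``AMPAR``, ``NMDAR``, ``GABAaR``.
    tau_rise_ms, tau_decay_ms:
        Rise and decay time constants of the double exponential (ms);
        ``0 < tau_rise < tau_decay`` is required.
    e_rev_mV:
        Reversal potential of the synaptic current (mV).
    """

    receptor: str
    tau_rise_ms: float
    tau_decay_ms: float
    e_rev_mV: float

    def __post_init__(self):
        if not (0.0 < self.tau_rise_ms < self.tau_decay_ms):
            raise ConfigError(
                f"{self.receptor}: need 0 < tau_rise < tau_decay, got "
                f"({self.tau_rise_ms}, {self.tau_decay_ms}) ms"
            )

    @property
    def time_to_peak_ms(self) -> float:
        """Time at which the normalized waveform reaches its maximum."""
        t1, t2 = self.tau_rise_ms, self.tau_decay_ms
        return (t1 * t2 / (t2 - t1)) * math.log(t2 / t1)

    @property
    def norm(self) -> float:
        """Amplitude factor making ``max_t g(t) == g_peak``."""
        tp = self.time_to_peak_ms
        return 1.0 / (
            math.exp(-tp / self.tau_decay_ms) - math.exp(-tp / self.tau_rise_ms)
        )


#: Default kinetics: fast AMPAR, slow voltage-independent NMDAR, GABAaR.
DEFAULT_KINETICS = {
    AMPAR: ReceptorKinetics(AMPAR, 0.03, 0.5, 0.0),
    NMDAR: ReceptorKinetics(NMDAR, 1.0, 13.3, 0.0),
    GABAAR: ReceptorKinetics(GABAAR, 0.31, 8.8, -75.0),
}


def conductance_waveform(kinetics: ReceptorKinetics, peak_g_nS, t_since_event_ms):
    """Closed-form conductance (nS) at time ``t`` after a single event.

    Accepts scalars or arrays for ``t_since_event_ms``; negative times are
    rejected (events have no acausal effect).
    """
    t = np.asarray(t_since_event_ms, dtype=float)
    if np.any(t < 0):
        raise ConfigError("t_since_event_ms must be >= 0")
    g = peak_g_nS * kinetics.norm * (
        np.exp(-t / kinetics.tau_decay_ms) - np.exp(-t / kinetics.tau_rise_ms)
    )
    if np.isscalar(t_since_event_ms):
        return float(g)
    return g


def synaptic_current_nA(g_nS, v_post_mV, e_rev_mV):
    """Ohmic synaptic current, positive = outward: I = g (V - E_rev).

    nS * mV = pA, hence the /1000 to express the result in nA.
    """
    return np.multiply(g_nS, np.subtract(v_post_mV, e_rev_mV)) / 1000.0


class DoubleExpState:
    """Event-driven recursion for one double-exponential conductance.

    Keeps two state variables decaying with ``tau_rise`` and ``tau_decay``;
    each event adds ``peak_g * norm`` to both, and the conductance is their
    difference. The per-step decay is the exact exponential, so the recursion
    reproduces the closed form to rounding error for event times aligned to
    the step grid.
    """

    def __init__(self, kinetics: ReceptorKinetics):
        self.kinetics = kinetics
        self.g_rise = 0.0
        self.g_decay = 0.0

    def add_event(self, peak_g_nS: float) -> None:
        inc = peak_g_nS * self.kinetics.norm
        self.g_rise += inc
        self.g_decay += inc

    def step(self, dt_ms: float) -> None:
        self.g_rise *= math.exp(-dt_ms / self.kinetics.tau_rise_ms)
        self.g_decay *= math.exp(-dt_ms / self.kinetics.tau_decay_ms)

    @property
    def conductance_nS(self) -> float:
        return self.g_decay - self.g_rise


@dataclass
class EventQueue:
    """Queue of delayed synaptic activations, summed linearly per synapse.

    ``deliver_event`` schedules an activation at ``spike_time + delay``;
    ``conductance`` evaluates the summed closed-form waveform of one synapse
    at an arbitrary time. This is the reference path used in tests; the
    engine uses ring buffers quantized to its time step.
    """

    events: dict = field(default_factory=dict)  # synapse id -> list of activation times

    def deliver_event(self, synapse, spike_time_ms: float, delay_ms: float) -> None:
        if spike_time_ms < 0 or delay_ms < 0:
            raise ConfigError("spike_time and delay must be >= 0")
        self.events.setdefault(synapse, []).append(spike_time_ms + delay_ms)

    def conductance(self, synapse, kinetics: ReceptorKinetics,
                    peak_g_nS: float, t_ms: float) -> float:
        total = 0.0
        for t_act in self.events.get(synapse, ()):
            if t_ms >= t_act:
                total += conductance_waveform(kinetics, peak_g_nS, t_ms - t_act)
        return total


def export_kinetics_table(path, kinetics=None) -> None:
    """Write a delimited table (receptor, tau1_ms, tau2_ms, erev_mV)."""
    kinetics = kinetics or DEFAULT_KINETICS
    with open(path, "w") as fh:
        fh.write("receptor\ttau1_ms\ttau2_ms\terev_mV\n")
        for kin in kinetics.values():
            fh.write(
                f"{kin.receptor}\t{kin.tau_rise_ms}\t{kin.tau_decay_ms}\t{kin.e_rev_mV}\n"
            )
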