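"""Time-stepped co-simulation of neurons, synapses and gap junctions.

The engine wires a built :class:`~gocnet.network.Network` to a realized
:class:`~gocnet.stimulus.MFStimulus` and integrates everything with a fixed
explicit step (default 0.025 ms). Synaptic events are delivered through
per-synapse delays quantized to the step (max rounding error dt/2, well
below every population-mean delay); gap-junction currents are ohmic and
computed from previous-step voltages. Given identical (network, stimulus,
config) the result is bit-identical.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import h5py
import yaml

from . import _core
from .errors import ConfigError, IntegrationError
from .network import (Network, LAYER_GC, LAYER_GOC, MF_GC_AMPA, MF_GC_NMDA,
                      MF_GOC_AMPA, PF_GOC_AMPA, GOC_GC_GABAA)
from .neurons import MAX_STABLE_DT_MS, GoCParams, suppress_sodium
from .stimulus import MFStimulus
from .synapses import DEFAULT_KINETICS, AMPAR, NMDAR, GABAAR, RECEPTOR_INDEX


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level knobs: integration step, duration, toggles and scalings.

    ``pf_weight_percent`` scales all PF->GoC conductances (the feedback-loop
    strength; 0 gives the feedforward configuration) and
    ``gabaa_weight_percent`` scales the GoC->GC inhibition. ``seed`` drives
    the initial-membrane-potential randomization only; the stimulus and
    network carry their own seeds.
    """

    dt_ms: float = 0.025
    duration_ms: float = 2000.0
    seed: int = 0
    gap_junctions_enabled: bool = True
    pf_weight_percent: float = 100.0
    gabaa_weight_percent: float = 100.0
    nmda_mg_block: bool = False
    record_traces: tuple = ()          # ((layer, index), ...)
    trace_decim_ms: float = 0.1
    v_init_randomization: float = 0.2  # fraction of rest, scaled by cell_randomness
    max_rate_cap_hz: float = 400.0     # sizes the spike buffer

    def __post_init__(self):
        if not (0.0 < self.dt_ms <= MAX_STABLE_DT_MS):
            raise ConfigError(
                f"dt must be in (0, {MAX_STABLE_DT_MS}] ms, got {self.dt_ms}")
        if self.duration_ms <= 0:
            raise ConfigError("duration must be > 0")
        if self.pf_weight_percent < 0 or self.gabaa_weight_percent < 0:
            raise ConfigError("weight percents must be >= 0")

    def content_hash(self) -> str:
        return hashlib.sha1(
            yaml.safe_dump(asdict(self)).encode()).hexdigest()[:12]


@dataclass
class SpikeData:
    """Per-layer spike times with provenance metadata.

    ``spikes[layer]`` is a pair (cell_index, time_ms) of equal-length arrays
    sorted by time; per-cell times are strictly increasing (the refractory
    period enforces separation).
    """

    spikes: dict
    n_cells: dict
    duration_ms: float
    dt_ms: float
    seed: int
    config_hash: str
    traces: dict = field(default_factory=dict)  # (layer, idx) -> v array
    trace_times_ms: np.ndarray = None

    def times_for(self, layer: str, cell: int) -> np.ndarray:
        idx, t = self.spikes[layer]
        return t[idx == cell]

    def layer_spike_count(self, layer: str) -> int:
        return len(self.spikes[layer][1])

    def to_text(self, path) -> None:
        """Delimited spike list: layer, neuron_id, time_ms."""
        with open(path, "w") as fh:
            fh.write("layer\tneuron_id\ttime_ms\n")
            for layer, (idx, t) in self.spikes.items():
                for i, ti in zip(idx, t):
                    fh.write(f"{layer}\t{i}\t{ti:.4f}\n")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["duration_ms"] = self.duration_ms
            fh.attrs["dt_ms"] = self.dt_ms
            fh.attrs["seed"] = self.seed
            fh.attrs["config_hash"] = self.config_hash
            for layer, (idx, t) in self.spikes.items():
                grp = fh.create_group(layer)
                grp.attrs["n_cells"] = self.n_cells[layer]
                grp.create_dataset("cell", data=idx)
                grp.create_dataset("time_ms", data=t)

    @classmethod
    def from_hdf5(cls, path) -> "SpikeData":
        with h5py.File(path, "r") as fh:
            spikes, n_cells = {}, {}
            for layer in fh:
                spikes[layer] = (fh[layer]["cell"][...],
                                 fh[layer]["time_ms"][...])
                n_cells[layer] = int(fh[layer].attrs["n_cells"])
            return cls(spikes, n_cells, float(fh.attrs["duration_ms"]),
                       float(fh.attrs["dt_ms"]), int(fh.attrs["seed"]),
                       str(fh.attrs["config_hash"]))


def gap_junction_current(v_i_mV, v_j_mV, gj_nS):
    """Ohmic coupling currents (nA) into cells i and j; antisymmetric."""
    into_i = gj_nS * (np.subtract(v_j_mV, v_i_mV)) / 1000.0
    return into_i, -into_i


def _neuron_param_arrays(network: Network):
    """Flat per-neuron parameter arrays (GCs first, then GoCs) with the
    per-cell leak/area randomization applied."""
    gc, goc = network.gc_params, network.goc_params
    n_gc, n_goc = network.n_gc, network.n_goc
    N = n_gc + n_goc

    def fill(gc_val, goc_val):
        a = np.empty(N)
        a[:n_gc] = gc_val
        a[n_gc:] = goc_val
        return a

    arr = {
        "c": fill(gc.c_m_pF, goc.c_m_pF),
        "g1": fill(gc.g_leak_nS, goc.g_leak_nS),
        "e1": fill(gc.e_leak_mV, goc.e_leak_mV),
        "g2": fill(gc.g_k_nS, goc.g_k_nS),
        "e2": fill(gc.e_k_mV, goc.e_k_mV),
        "gna": fill(gc.g_na_nS, goc.g_na_nS),
        "vt": fill(gc.v_t_mV, goc.v_t_mV),
        "dti": fill(gc.delta_t_mV, goc.delta_t_mV),
        "v_reset": fill(gc.v_reset_mV, goc.v_reset_mV),
        "v_peak": fill(gc.v_peak_mV, goc.v_peak_mV),
        "v_detect": fill(gc.spike_detect_mV, goc.spike_detect_mV),
        "ahp_b": fill(gc.ahp_increment_nS, goc.ahp_increment_nS),
        "e_ahp": fill(gc.e_ahp_mV, goc.e_ahp_mV),
        "v_rest": fill(gc.v_rest_mV, goc.v_rest_mV),
    }
    arr["na_on"] = fill(float(gc.sodium_enabled),
                        float(goc.sodium_enabled)).astype(np.uint8)
    # leak randomization scales conductances; area randomization scales C
    leak = np.concatenate([network.gc_leak_scale, network.goc_leak_scale])
    area = np.concatenate([network.gc_area_scale, network.goc_area_scale])
    arr["g1"] *= leak
    arr["g2"] *= leak
    arr["c"] *= area
    arr["tref_ms"] = fill(gc.refractory_ms, goc.refractory_ms)
    arr["ahp_tau"] = fill(gc.ahp_tau_ms, goc.ahp_tau_ms)
    return arr


def _csr(pre, post, rec, w, dsteps, n_pre):
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    ptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(ptr, pre + 1, 1)
    ptr = np.cumsum(ptr)
    return (ptr, post[order].astype(np.int32), rec[order].astype(np.int8),
            w[order].astype(float), dsteps[order].astype(np.int64))


def _delay_steps(delay_ms, dt):
    return np.maximum(1, np.rint(delay_ms / dt).astype(np.int64))


def run_simulation(network: Network, stimulus: MFStimulus,
                   config: SimulationConfig) -> SpikeData:
    """Simulate the network under a stimulus; return spikes (+ traces).

    Granule cells are silent until the mossy-fiber onset; Golgi cells fire
    throughout (intrinsic pacemaking). Toggling ``gap_junctions_enabled``
    with everything else fixed reuses the identical network and stimulus,
    which is how paired with/without-coupling comparisons are run.
    """
    dt = config.dt_ms
    n_steps = int(round(config.duration_ms / dt))
    n_gc, n_goc, n_mf = network.n_gc, network.n_goc, network.n_mf
    N = n_gc + n_goc
    if stimulus.n_fibers != n_mf:
        raise ConfigError(
            f"stimulus has {stimulus.n_fibers} fibers, network {n_mf}")

    p = _neuron_param_arrays(network)
    kin = DEFAULT_KINETICS
    rec_e = np.array([kin[AMPAR].e_rev_mV, kin[NMDAR].e_rev_mV,
                      kin[GABAAR].e_rev_mV])
    dec_r = np.array([math.exp(-dt / kin[k].tau_rise_ms)
                      for k in (AMPAR, NMDAR, GABAAR)])
    dec_d = np.array([math.exp(-dt / kin[k].tau_decay_ms)
                      for k in (AMPAR, NMDAR, GABAAR)])
    norm = np.array([kin[k].norm for k in (AMPAR, NMDAR, GABAAR)])

    proj = network.projections
    # internal synapses: PF->GoC (pre GC, global post = n_gc + goc) and
    # GoC->GC (global pre = n_gc + goc)
    pf = proj[PF_GOC_AMPA]
    gg = proj[GOC_GC_GABAA]
    pre = np.concatenate([pf.pre, gg.pre + n_gc])
    post = np.concatenate([pf.post + n_gc, gg.post])
    rec = np.concatenate([np.full(pf.n_synapses, RECEPTOR_INDEX[AMPAR]),
                          np.full(gg.n_synapses, RECEPTOR_INDEX[GABAAR])])
    w = np.concatenate([pf.g_nS * (config.pf_weight_percent / 100.0),
                        gg.g_nS * (config.gabaa_weight_percent / 100.0)])
    d = np.concatenate([_delay_steps(pf.delay_ms, dt),
                        _delay_steps(gg.delay_ms, dt)])
    keep = w > 0
    out = _csr(pre[keep], post[keep], rec[keep], w[keep], d[keep], N)

    # mossy-fiber synapses; the GoC projection honours the sparse-input mask
    ma, mn, mg = proj[MF_GC_AMPA], proj[MF_GC_NMDA], proj[MF_GOC_AMPA]
    goc_keep = stimulus.goc_active_mask[mg.pre]
    mf_pre = np.concatenate([ma.pre, mn.pre, mg.pre[goc_keep]])
    mf_post = np.concatenate([ma.post, mn.post, mg.post[goc_keep] + n_gc])
    mf_rec = np.concatenate([
        np.full(ma.n_synapses, RECEPTOR_INDEX[AMPAR]),
        np.full(mn.n_synapses, RECEPTOR_INDEX[NMDAR]),
        np.full(int(goc_keep.sum()), RECEPTOR_INDEX[AMPAR])])
    mf_w = np.concatenate([ma.g_nS, mn.g_nS, mg.g_nS[goc_keep]])
    mf_d = np.concatenate([_delay_steps(ma.delay_ms, dt),
                           _delay_steps(mn.delay_ms, dt),
                           _delay_steps(mg.delay_ms[goc_keep], dt)])
    mfc = _csr(mf_pre, mf_post, mf_rec, mf_w, mf_d, n_mf)

    fibers, times = stimulus.merged_events()
    steps = np.rint(times / dt).astype(np.int64)
    in_run = steps < n_steps
    mf_steps, mf_fiber = steps[in_run], fibers[in_run].astype(np.int32)

    if config.gap_junctions_enabled and network.gap_junctions.n_pairs:
        gj = network.gap_junctions
        gj_a = (gj.goc_i.astype(np.int64) + n_gc)
        gj_b = (gj.goc_j.astype(np.int64) + n_gc)
        gj_g = gj.g_nS.astype(float)
    else:
        gj_a = np.empty(0, np.int64)
        gj_b = np.empty(0, np.int64)
        gj_g = np.empty(0)

    # static stability check: explicit step must stay well below the
    # fastest passive time constant including gap-junction load
    g_static = p["g1"] + p["g2"]
    np.add.at(g_static, gj_a, gj_g)
    np.add.at(g_static, gj_b, gj_g)
    if np.any(dt * g_static / p["c"] > 0.5):
        raise ConfigError("dt too large for the static conductance load")

    sin_amp_pA, sin_freq = 0.0, 0.0
    sin_mask = np.zeros(N)
    if stimulus.sinusoid is not None:
        sin_amp_pA = stimulus.sinusoid.amplitude_nA * 1000.0
        sin_freq = stimulus.sinusoid.frequency_hz
        sin_mask[n_gc:] = 1.0

    rng = np.random.default_rng(config.seed)
    frac = config.v_init_randomization * network.config.cell_randomness
    v = p["v_rest"] * (1.0 + rng.uniform(-frac, frac, N))
    g_ahp = np.zeros(N)

    S = int(max(out[4].max() if len(out[4]) else 1,
                mfc[4].max() if len(mfc[4]) else 1)) + 2
    trace_every = max(1, int(round(config.trace_decim_ms / dt)))
    trace_ids = []
    for layer, idx in config.record_traces:
        if layer == LAYER_GC and 0 <= idx < n_gc:
            trace_ids.append(idx)
        elif layer == LAYER_GOC and 0 <= idx < n_goc:
            trace_ids.append(n_gc + idx)
        else:
            raise ConfigError(f"unknown trace target ({layer}, {idx})")
    trace_ids = np.asarray(trace_ids, dtype=np.int32)
    n_samples = (n_steps + trace_every - 1) // trace_every
    traces = np.zeros((len(trace_ids), n_samples))

    max_spikes = max(10000, int(N * config.duration_ms / 1000.0
                                * config.max_rate_cap_hz))
    spike_i = np.zeros(max_spikes, dtype=np.int32)
    spike_t = np.zeros(max_spikes)
    status = np.zeros(3, dtype=np.int64)

    n_spikes = _core.run_core(
        dt, n_steps, n_gc,
        p["c"], p["g1"], p["e1"], p["g2"], p["e2"], p["gna"], p["vt"],
        p["dti"], p["na_on"], p["v_reset"], p["v_peak"], p["v_detect"],
        np.maximum(1, np.rint(p["tref_ms"] / dt)).astype(np.int64),
        p["ahp_b"], np.exp(-dt / p["ahp_tau"]), p["e_ahp"],
        rec_e, dec_r, dec_d, norm,
        *out, *mfc, mf_steps, mf_fiber,
        gj_a, gj_b, gj_g,
        np.zeros(N), sin_amp_pA, sin_freq, sin_mask,
        v, g_ahp, S, trace_ids, trace_every, traces,
        spike_i, spike_t, status)

    if status[0] == 1:
        i = int(status[1])
        layer = LAYER_GC if i < n_gc else LAYER_GOC
        raise IntegrationError(
            f"non-finite membrane potential in {layer} neuron "
            f"{i if i < n_gc else i - n_gc} at t={status[2] * dt:.3f} ms",
            neuron_index=i, time_ms=float(status[2] * dt))
    if status[0] == 2:
        raise IntegrationError(
            f"spike buffer overflow at t={status[2] * dt:.3f} ms "
            f"(rate cap {config.max_rate_cap_hz} Hz)")

    idx = spike_i[:n_spikes]
    t = spike_t[:n_spikes]
    is_goc = idx >= n_gc
    spikes = {
        LAYER_GC: (idx[~is_goc].copy(), t[~is_goc].copy()),
        LAYER_GOC: ((idx[is_goc] - n_gc).copy(), t[is_goc].copy()),
    }
    trace_dict = {key: traces[k] for k, key in enumerate(config.record_traces)}
    trace_times = np.arange(n_samples) * trace_every * dt
    return SpikeData(spikes, {LAYER_GC: n_gc, LAYER_GOC: n_goc},
                     config.duration_ms, dt, config.seed,
                     config.content_hash(), trace_dict, trace_times)


def simulate_isolated(params, i_const_pA, duration_ms: float = 1000.0,
                      dt_ms: float = 0.025):
    """Integrate unconnected copies of one model, one per current value.

    Returns a list of spike-time arrays. Shares the network kernel, so
    single-cell behavior in and out of the network is identical by
    construction.
    """
    currents = np.atleast_1d(np.asarray(i_const_pA, dtype=float))
    n = len(currents)
    n_steps = int(round(duration_ms / dt_ms))
    ones = np.ones(n)

    def fill(val):
        return np.full(n, float(val))

    empty_ptr = np.zeros(n + 1, dtype=np.int64)
    e32 = np.empty(0, np.int32)
    e8 = np.empty(0, np.int8)
    ef = np.empty(0)
    e64 = np.empty(0, np.int64)
    traces = np.zeros((0, 1))
    max_spikes = max(1000, int(n * duration_ms))
    spike_i = np.zeros(max_spikes, dtype=np.int32)
    spike_t = np.zeros(max_spikes)
    status = np.zeros(3, dtype=np.int64)
    n_spikes = _core.run_core(
        dt_ms, n_steps, n,
        fill(params.c_m_pF), fill(params.g_leak_nS), fill(params.e_leak_mV),
        fill(params.g_k_nS), fill(params.e_k_mV), fill(params.g_na_nS),
        fill(params.v_t_mV), fill(params.delta_t_mV),
        (ones * float(params.sodium_enabled)).astype(np.uint8),
        fill(params.v_reset_mV), fill(params.v_peak_mV),
        fill(params.spike_detect_mV),
        np.maximum(1, np.rint(fill(params.refractory_ms) / dt_ms)).astype(np.int64),
        fill(params.ahp_increment_nS), np.exp(-dt_ms / fill(params.ahp_tau_ms)),
        fill(params.e_ahp_mV),
        np.zeros(3), np.zeros(3), np.zeros(3), np.ones(3),
        empty_ptr, e32, e8, ef, e64,
        np.zeros(1, dtype=np.int64), e32, e8, ef, e64,
        e64, e32,
        e64, e64, ef,
        currents.copy(), 0.0, 0.0, np.zeros(n),
        fill(params.v_rest_mV), np.zeros(n),
        3, np.empty(0, np.int32), 1, traces,
        spike_i, spike_t, status)
    if status[0] != 0:
        raise IntegrationError("isolated-neuron integration failed")
    out = []
    for j in range(n):
        sel = spike_i[:n_spikes] == j
        out.append(spike_t[:n_spikes][sel])
    return out


# --------------------------------------------------------------------------
# Two coupled Golgi cells (electrical-coupling demonstration)
# --------------------------------------------------------------------------

def _goc_compartments(params: GoCParams):
    """Compartment parameters for the 1- or 4-compartment Golgi variant.

    The 4-compartment variant splits the static conductance 55% soma / 15%
    per passive dendrite (so the summed input conductance is preserved) and
    divides capacitance evenly; dendrites couple to the soma with a fixed
    axial conductance. Spike machinery lives in the soma.
    """
    if params.n_compartments == 1:
        return dict(n=1, c=[params.c_m_pF],
                    gl=[params.g_leak_nS], gk=[params.g_k_nS],
                    axial_nS=0.0)
    soma_frac, dend_frac = 0.55, 0.15
    c_each = params.c_m_pF / 4.0
    return dict(
        n=4,
        c=[c_each] * 4,
        gl=[params.g_leak_nS * soma_frac] + [params.g_leak_nS * dend_frac] * 3,
        gk=[params.g_k_nS * soma_frac] + [params.g_k_nS * dend_frac] * 3,
        axial_nS=3.0,
    )


def two_cell_demo(gj_location: str = "soma", stimulus: str = "mf_10hz",
                  gj_nS: float = 1.0, duration_ms: float = 3000.0,
                  dt_ms: float = 0.025, seed: int = 0,
                  goc_params: GoCParams = None):
    """Two gap-junction-coupled Golgi cells: spiking driver, passive follower.

    The driver either pacemakes under 10-Hz mossy-fiber input (``mf_10hz``)
    or is held at -0.1 nA and fires on a 0.5 nA / 100 ms pulse at 1500 ms
    (``pulse``). The follower's spike mechanism is suppressed (gNa = 0) so
    its trace shows the transmitted spikelet: a fast depolarizing component
    from the spike peak and a slower hyperpolarizing one from the
    undershoot, the fast component being attenuated more (low-pass
    filtering). ``gj_location`` attaches the coupling at the soma or at a
    dendrite of the 4-compartment variant.

    Returns a dict with the time axis, somatic traces of both cells, driver
    spike times and the stimulus descriptor.
    """
    if gj_location not in ("soma", "dendrite"):
        raise ConfigError("gj_location must be 'soma' or 'dendrite'")
    if stimulus not in ("mf_10hz", "pulse"):
        raise ConfigError("stimulus must be 'mf_10hz' or 'pulse'")
    base = goc_params or GoCParams()
    if gj_location == "dendrite" and base.n_compartments == 1:
        from dataclasses import replace
        base = replace(base, n_compartments=4)
    driver = base
    follower = suppress_sodium(base)

    comp = _goc_compartments(base)
    nc = comp["n"]
    gj_comp = 0 if gj_location == "soma" else 1

    kin_a = DEFAULT_KINETICS[AMPAR]
    dec_r = math.exp(-dt_ms / kin_a.tau_rise_ms)
    dec_d = math.exp(-dt_ms / kin_a.tau_decay_ms)

    mf_times = np.empty(0)
    if stimulus == "mf_10hz":
        rng = np.random.default_rng(seed)
        n_ev = rng.poisson(10.0 * duration_ms / 1000.0)
        mf_times = np.sort(rng.uniform(0.0, duration_ms, n_ev))
    mf_steps = set(np.rint(mf_times / dt_ms).astype(int).tolist())
    mf_w = 0.706  # network-mean MF->GoC peak conductance

    n_steps = int(round(duration_ms / dt_ms))
    # state: v[cell, comp]
    v = np.full((2, nc), base.v_rest_mV)
    g_ahp = np.zeros(2)
    refrac = np.zeros(2, dtype=int)
    pend = np.zeros(2, dtype=bool)
    gr = gd = 0.0  # driver somatic AMPA state
    tref_steps = max(1, int(round(base.refractory_ms / dt_ms)))
    ahp_dec = math.exp(-dt_ms / base.ahp_tau_ms)

    t_axis = np.arange(n_steps) * dt_ms
    v_drv = np.empty(n_steps)
    v_fol = np.empty(n_steps)
    spikes = []
    cells = (driver, follower)

    for s in range(n_steps):
        gr *= dec_r
        gd *= dec_d
        if s in mf_steps:
            gr += mf_w * kin_a.norm
            gd += mf_w * kin_a.norm
        g_syn = gd - gr
        t = s * dt_ms

        i_gap = gj_nS * (v[1, gj_comp] - v[0, gj_comp])
        i_ext_drv = 0.0
        if stimulus == "pulse":
            i_ext_drv = -100.0  # holding, pA
            if 1500.0 <= t < 1600.0:
                i_ext_drv += 500.0

        new_v = v.copy()
        for cell in (0, 1):
            par = cells[cell]
            if pend[cell]:
                new_v[cell, 0] = par.v_reset_mV
                v[cell, 0] = par.v_reset_mV
                g_ahp[cell] += par.ahp_increment_nS
                pend[cell] = False
            g_ahp[cell] *= ahp_dec
            for k in range(nc):
                vk = v[cell, k]
                cur = comp["gl"][k] * (par.e_leak_mV - vk)
                cur += comp["gk"][k] * (par.e_k_mV - vk)
                if k == 0:
                    if par.sodium_enabled:
                        arg = min((vk - par.v_t_mV) / par.delta_t_mV, 16.0)
                        cur += par.g_na_nS * par.delta_t_mV * math.exp(arg)
                    cur += g_ahp[cell] * (par.e_ahp_mV - vk)
                    if cell == 0:
                        cur += g_syn * (kin_a.e_rev_mV - vk)
                        cur += i_ext_drv
                    if nc > 1:
                        for kk in range(1, nc):
                            cur += comp["axial_nS"] * (v[cell, kk] - vk)
                else:
                    cur += comp["axial_nS"] * (v[cell, 0] - vk)
                if k == gj_comp:
                    cur += i_gap if cell == 0 else -i_gap
                c_k = comp["c"][k]
                vn = vk + dt_ms * cur / c_k
                if vn > par.v_peak_mV:
                    vn = par.v_peak_mV
                new_v[cell, k] = vn
            if refrac[cell] > 0:
                refrac[cell] -= 1
            elif par.sodium_enabled and new_v[cell, 0] >= par.spike_detect_mV:
                new_v[cell, 0] = par.v_peak_mV
                pend[cell] = True
                refrac[cell] = tref_steps
                if cell == 0:
                    spikes.append(t)
        v = new_v
        v_drv[s] = v[0, 0]
        v_fol[s] = v[1, 0]

    return dict(t_ms=t_axis, v_driver=v_drv, v_follower=v_fol,
                driver_spikes=np.asarray(spikes), stimulus=stimulus,
                gj_location=gj_location, gj_nS=gj_nS,
                v_rest=base.v_rest_mV)


def spikelet_metrics(demo: dict) -> dict:
    """Attenuation of the fast (peak) vs slow (undershoot) spike components.

    The fast component is the excursion above each cell's slow level while
    the driver is spiking; the slow component is the dip below the
    non-spiking baseline. Low-pass coupling implies
    ``peak_attenuation < undershoot_attenuation`` — the transmitted
    fraction of the fast peak is smaller than that of the undershoot.
    """
    t = demo["t_ms"]
    vd, vf = demo["v_driver"], demo["v_follower"]
    if demo["stimulus"] == "pulse":
        # spikes ride on the 0.5-nA plateau during [1500, 1600) ms; the
        # accumulated afterhyperpolarization appears after pulse offset
        base_win = (t >= 1300.0) & (t < 1500.0)
        fast_win = (t >= 1500.0) & (t < 1600.0)
        slow_win = (t >= 1600.0) & (t < 1900.0)
    else:
        # pacemaking driver: fast and slow components recur throughout
        base_win = fast_win = slow_win = t >= 200.0
    drv_peak = vd[fast_win].max() - np.median(vd[fast_win])
    fol_peak = vf[fast_win].max() - np.median(vf[fast_win])
    drv_under = np.median(vd[base_win]) - vd[slow_win].min()
    fol_under = np.median(vf[base_win]) - vf[slow_win].min()
    return dict(
        driver_peak_mV=drv_peak, driver_undershoot_mV=drv_under,
        follower_peak_mV=fol_peak, follower_undershoot_mV=fol_under,
        peak_attenuation=fol_peak / drv_peak if drv_peak > 0 else 0.0,
        undershoot_attenuation=(fol_under / drv_under
                                if drv_under > 0 else 0.0),
    )
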