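"""Shared fixtures: session-cached network builds and simulation runs."""

import numpy as np
import pytest

from gocnet import analysis as an
from gocnet import engine as eg
from gocnet import network as nw
from gocnet import stimulus as st

# One fixed seed triple for all cached runs: network realization, stimulus
# realization, initial-condition randomization.
NET_SEED = 42
STIM_SEED = 7
SIM_SEED = 3

#: Stimulus seeds for per-condition averaging (3 trials per condition).
TRIAL_STIM_SEEDS = (7, 8, 9)


@pytest.fixture(scope="session")
def network_cache():
    """Factory for seeded network builds, cached per configuration."""
    cache = {}

    def get(scale="mini", randomness=1.0, seed=NET_SEED):
        key = (scale, randomness, seed)
        if key not in cache:
            maker = {"mini": nw.mini_config, "default": nw.default_config}[scale]
            cfg = maker(cell_randomness=randomness,
                        spatial_randomness=randomness)
            cache[key] = nw.build_network(cfg, seed=seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def mini_network(network_cache):
    return network_cache("mini")


@pytest.fixture(scope="session")
def default_network(network_cache):
    return network_cache("default")


@pytest.fixture(scope="session")
def sim_runs(network_cache):
    """Factory running (and caching) trimmed, analyzed simulations.

    Gap-junction on/off pairs automatically share the network instance and
    stimulus realization, as the paired comparison requires.
    """
    cache = {}

    def run(scale="mini", pf=100.0, gj=True, mf=5.0, randomness=1.0,
            stim_seed=STIM_SEED, dt=0.025):
        key = (scale, pf, gj, mf, randomness, stim_seed, dt)
        if key in cache:
            return cache[key]
        net = network_cache(scale, randomness)
        stim = st.make_mf_stimulus(
            st.MFRateProtocol(mean_rate_hz=mf), net.n_mf, seed=stim_seed)
        cfg = eg.SimulationConfig(dt_ms=dt, pf_weight_percent=pf,
                                  gap_junctions_enabled=gj, seed=SIM_SEED)
        raw = eg.run_simulation(net, stim, cfg)
        trimmed = an.trim_borders(
            raw, net.geometry, an.default_trim_spec(net.config.layer_dims))
        res = {
            "net": net,
            "raw": raw,
            "trimmed": trimmed,
            "goc_psth": an.compute_psth(trimmed, "GoC"),
            "goc_mfr": an.mean_firing_rate(trimmed, "GoC"),
            "gc_mfr": an.mean_firing_rate(trimmed, "GC"),
        }
        cache[key] = res
        return res

    return run


def mean_robustness(sim_runs, scale, pf, mf, randomness=1.0,
                    stim_seeds=TRIAL_STIM_SEEDS):
    """Across-trial mean of the paired gap-junction effect at one condition."""
    amps, lats = [], []
    for ss in stim_seeds:
        a = sim_runs(scale, pf, True, mf, randomness, stim_seed=ss)
        b = sim_runs(scale, pf, False, mf, randomness, stim_seed=ss)
        rob = an.robustness_effect(a["goc_psth"], b["goc_psth"])
        amps.append(rob.delta_amplitude)
        lats.append(rob.delta_latency_ms)
    return float(np.mean(amps)), float(np.nanmean(lats))
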