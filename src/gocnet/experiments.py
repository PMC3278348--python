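"""Config-driven orchestration of the standard experiment grid.

An :class:`ExperimentSpec` names a condition grid (mossy-fiber rates x
feedback weights x gap junctions on/off x randomness levels x seeds);
:func:`run_experiment` executes it condition by condition, pairing the
with/without-gap-junction runs on identical network and stimulus
realizations, writes analysis tables, and keeps a manifest mapping every
output file to the (config hash, seed) pair that reproduces it. Completed
conditions are skipped on re-run; failures are recorded per condition and
the sweep continues.

``make_preset`` provides named specs for the canonical protocols (two-cell
coupling demo, resonance scan, firing-rate grid, feedforward vs feedback
comparisons, robustness grid, randomness tuning, sparse mossy-fiber drive,
the 6-mm elongated network, and a fast ``mini_ci`` check).
"""

from __future__ import annotations

import json
import os
import traceback
from dataclasses import dataclass, field, asdict

import numpy as np

from . import analysis as an
from . import plots
from .engine import SimulationConfig, run_simulation, two_cell_demo, spikelet_metrics
from .errors import ConfigError
from .network import (build_network, default_config, mini_config,
                      elongated_config, LAYER_GC, LAYER_GOC)
from .stimulus import (MFRateProtocol, make_mf_stimulus, sparse_mf_variant,
                       SINUSOID_FREQUENCIES_HZ, ELONGATED_RATE_TABLE,
                       sd_for_rate)

DEFAULT_PF_WEIGHTS = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class ExperimentSpec:
    """A named condition grid plus execution parameters."""

    name: str
    kind: str = "grid"                  # grid | two_cell | resonance
    scale: str = "default"              # default | mini | elongated
    mf_rates_hz: tuple = (5.0,)
    pf_weights_percent: tuple = (100.0,)
    gj_flags: tuple = (True, False)
    randomness_levels: tuple = (1.0,)
    sparse_fraction: float = 1.0
    sinusoid_frequencies_hz: tuple = ()
    seeds: tuple = (1, 2, 3)
    duration_ms: float = 2000.0
    dt_ms: float = 0.025
    rate_table: str = "standard"        # standard | elongated
    notes: str = ""

    def network_config(self, randomness: float = 1.0):
        maker = {"default": default_config, "mini": mini_config,
                 "elongated": elongated_config}[self.scale]
        return maker(cell_randomness=randomness,
                     spatial_randomness=randomness)


PRESET_BUILDERS = {}


def _preset(name):
    def deco(fn):
        PRESET_BUILDERS[name] = fn
        return fn
    return deco


@_preset("fig3_two_cell")
def _p_two_cell():
    return ExperimentSpec("fig3_two_cell", kind="two_cell", seeds=(1,),
                          notes="paired spiking/passive GoC coupling demo")


@_preset("fig4_resonance")
def _p_resonance():
    return ExperimentSpec(
        "fig4_resonance", kind="resonance",
        sinusoid_frequencies_hz=SINUSOID_FREQUENCIES_HZ,
        pf_weights_percent=(0.0, 100.0), seeds=(1,),
        notes="GoC-layer resonance under somatic sinusoids + MF noise")


@_preset("fig5_mfr_grid")
def _p_mfr_grid():
    return ExperimentSpec(
        "fig5_mfr_grid", mf_rates_hz=(1, 5, 10, 15, 20, 40, 70, 100),
        pf_weights_percent=DEFAULT_PF_WEIGHTS,
        notes="layer mean firing rates over the full input grid")


@_preset("fig6_feedforward")
def _p_ff():
    return ExperimentSpec("fig6_feedforward", mf_rates_hz=(5.0,),
                          pf_weights_percent=(0.0,),
                          notes="no parallel fibers: gap-junction-driven sync")


@_preset("fig7_feedback_grid")
def _p_fb_grid():
    return ExperimentSpec(
        "fig7_feedback_grid", mf_rates_hz=(1, 5, 10, 20, 40, 70),
        pf_weights_percent=DEFAULT_PF_WEIGHTS,
        notes="PSTH power spectra over the feedback grid")


@_preset("fig8_feedback")
def _p_fb():
    return ExperimentSpec("fig8_feedback", mf_rates_hz=(5.0,),
                          pf_weights_percent=(100.0,))


@_preset("fig9_feedback_100hz")
def _p_fb100():
    return ExperimentSpec("fig9_feedback_100hz", mf_rates_hz=(100.0,),
                          pf_weights_percent=(100.0,))


@_preset("fig10_weakPF")
def _p_weak():
    return ExperimentSpec("fig10_weakPF", mf_rates_hz=(5.0,),
                          pf_weights_percent=(10.0,))


@_preset("fig11_robustness_grid")
def _p_robust():
    return ExperimentSpec(
        "fig11_robustness_grid", mf_rates_hz=(5, 10, 20, 40, 70, 100),
        pf_weights_percent=DEFAULT_PF_WEIGHTS,
        notes="paired cycle-amplitude and latency differences")


@_preset("fig12_randomness")
def _p_random():
    return ExperimentSpec(
        "fig12_randomness", mf_rates_hz=(5.0,), pf_weights_percent=(20.0,),
        randomness_levels=(0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5),
        notes="robustness effect vs cellular+spatial randomness level")


@_preset("sparse_mf")
def _p_sparse():
    return ExperimentSpec("sparse_mf", mf_rates_hz=(5.0,),
                          pf_weights_percent=(20.0,), sparse_fraction=0.5,
                          notes="half the fibers drive GoCs; GC drive intact")


@_preset("elongated_6mm")
def _p_elongated():
    return ExperimentSpec(
        "elongated_6mm", scale="elongated",
        mf_rates_hz=tuple(ELONGATED_RATE_TABLE),
        pf_weights_percent=(100.0,), rate_table="elongated",
        notes="6-mm network at reduced density (same cell counts)")


@_preset("mini_ci")
def _p_mini():
    return ExperimentSpec("mini_ci", scale="mini", mf_rates_hz=(5.0,),
                          pf_weights_percent=(10.0,), seeds=(1,),
                          notes="fast end-to-end weak-feedback robustness check")


def make_preset(name: str) -> ExperimentSpec:
    """A fully populated spec for a documented preset name."""
    if name not in PRESET_BUILDERS:
        raise ConfigError(
            f"unknown preset {name!r}; available: "
            + ", ".join(sorted(PRESET_BUILDERS)))
    return PRESET_BUILDERS[name]()


def preset_names():
    return sorted(PRESET_BUILDERS)


# --------------------------------------------------------------------------


def _condition_key(randomness, mf, pf, seed):
    return f"r{randomness:g}_mf{mf:g}_pf{pf:g}_s{seed}"


def _run_grid_condition(spec, outdir, randomness, mf, pf, seed,
                        net_cache) -> dict:
    cache_key = (randomness, seed)
    if cache_key not in net_cache:
        net_cache[cache_key] = build_network(
            spec.network_config(randomness), seed=seed)
    net = net_cache[cache_key]
    table = (ELONGATED_RATE_TABLE if spec.rate_table == "elongated" else None)
    proto = MFRateProtocol(mean_rate_hz=mf,
                           sd_rate_hz=sd_for_rate(mf, table),
                           offset_ms=spec.duration_ms)
    stim = make_mf_stimulus(proto, net.n_mf, seed=seed + 1000)
    if spec.sparse_fraction < 1.0:
        stim = sparse_mf_variant(stim, spec.sparse_fraction, seed=seed + 2000)
    trim = an.default_trim_spec(net.config.layer_dims)

    entry = {"files": {}, "seed": seed, "summaries": {}}
    psths = {}
    for gj in spec.gj_flags:
        cfg = SimulationConfig(dt_ms=spec.dt_ms, duration_ms=spec.duration_ms,
                               seed=seed, gap_junctions_enabled=gj,
                               pf_weight_percent=pf)
        sd = run_simulation(net, stim, cfg)
        tr = an.trim_borders(sd, net.geometry, trim)
        tag = "gj" if gj else "nogj"
        psth = an.compute_psth(tr, LAYER_GOC)
        psths[gj] = psth
        spec_res = an.wavelet_power(psth)
        base = os.path.join(outdir, f"{tag}")
        psth.export_text(base + "_goc_psth.tsv")
        spec_res.export_text(base + "_goc_spectrum.tsv")
        entry["files"][tag] = [base + "_goc_psth.tsv",
                               base + "_goc_spectrum.tsv"]
        entry["summaries"][tag] = {
            "config_hash": cfg.content_hash(),
            "goc_mfr_hz": an.mean_firing_rate(tr, LAYER_GOC,
                                              (1000.0, spec.duration_ms)),
            "gc_mfr_hz": an.mean_firing_rate(tr, LAYER_GC,
                                             (1000.0, spec.duration_ms)),
            "peak_freq_hz": spec_res.peak_frequency(fmin_hz=4.0),
        }
    if True in psths and False in psths:
        rob = an.robustness_effect(psths[True], psths[False],
                                   condition={"mf_rate_hz": mf,
                                              "pf_weight_percent": pf})
        entry["summaries"]["robustness"] = {
            "delta_amplitude": rob.delta_amplitude,
            "delta_amplitude_sd": rob.delta_amplitude_sd,
            "delta_latency_ms": rob.delta_latency_ms,
            "n_cycles": rob.n_cycles,
        }
    return entry


def run_experiment(spec: ExperimentSpec, outdir, overwrite: bool = False) -> dict:
    """Execute a spec; return the manifest (also written to manifest.json).

    Conditions already present in the manifest with existing output files
    are skipped, so interrupted sweeps resume where they stopped. A failing
    condition records the traceback and does not abort the sweep.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest_path = os.path.join(outdir, "manifest.json")
    manifest = {"name": spec.name, "spec": asdict(spec), "conditions": {}}
    if os.path.exists(manifest_path) and not overwrite:
        with open(manifest_path) as fh:
            manifest = json.load(fh)

    def save():
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    if spec.kind == "two_cell":
        for loc in ("soma", "dendrite"):
            for stim_kind in ("mf_10hz", "pulse"):
                key = f"{loc}_{stim_kind}"
                if key in manifest["conditions"] and not overwrite:
                    continue
                demo = two_cell_demo(gj_location=loc, stimulus=stim_kind,
                                     seed=spec.seeds[0])
                path = os.path.join(outdir, f"traces_{key}.tsv")
                np.savetxt(path, np.column_stack(
                    [demo["t_ms"], demo["v_driver"], demo["v_follower"]]),
                    fmt="%.5g", delimiter="\t",
                    header="time_ms\tv_driver_mV\tv_follower_mV", comments="")
                metrics = spikelet_metrics(demo)
                manifest["conditions"][key] = {
                    "files": [path],
                    "metrics": {k: float(v) for k, v in metrics.items()},
                }
                save()
        return manifest

    if spec.kind == "resonance":
        for pf in spec.pf_weights_percent:
            for gj in spec.gj_flags:
                key = f"pf{pf:g}_{'gj' if gj else 'nogj'}"
                if key in manifest["conditions"] and not overwrite:
                    continue
                net = build_network(spec.network_config(), seed=spec.seeds[0])
                freqs, power, peak = an.resonance_scan(
                    net, spec.sinusoid_frequencies_hz, gj,
                    seed=spec.seeds[0], pf_weight_percent=pf,
                    duration_ms=spec.duration_ms, dt_ms=spec.dt_ms)
                path = os.path.join(outdir, f"resonance_{key}.tsv")
                np.savetxt(path, np.column_stack([freqs, power]),
                           fmt="%.6g", delimiter="\t",
                           header="freq_Hz\tnorm_power", comments="")
                manifest["conditions"][key] = {
                    "files": [path], "peak_frequency_hz": peak}
                save()
        return manifest

    # grid experiment
    net_cache = {}
    for randomness in spec.randomness_levels:
        for mf in spec.mf_rates_hz:
            for pf in spec.pf_weights_percent:
                for seed in spec.seeds:
                    key = _condition_key(randomness, mf, pf, seed)
                    prior = manifest["conditions"].get(key)
                    if (prior and not overwrite and "error" not in prior
                            and all(os.path.exists(f)
                                    for fs in prior.get("files", {}).values()
                                    for f in fs)):
                        continue
                    cond_dir = os.path.join(outdir, key)
                    os.makedirs(cond_dir, exist_ok=True)
                    try:
                        entry = _run_grid_condition(
                            spec, cond_dir, randomness, mf, pf, seed,
                            net_cache)
                    except Exception:
                        entry = {"error": traceback.format_exc()}
                    manifest["conditions"][key] = entry
                    save()
    return manifest


def write_report(manifest: dict, outdir) -> list:
    """Render PSTH overlays for every completed paired grid condition."""
    import matplotlib.pyplot as plt
    written = []
    for key, entry in manifest.get("conditions", {}).items():
        files = entry.get("files")
        if not isinstance(files, dict) or "gj" not in files or "nogj" not in files:
            continue
        series = {}
        for tag in ("gj", "nogj"):
            data = np.loadtxt(files[tag][0], skiprows=1)
            series[tag] = data
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.plot(series["nogj"][:, 0], series["nogj"][:, 1],
                color=plots.NOGJ_COLOR, lw=0.8, label="without Gj")
        ax.plot(series["gj"][:, 0], series["gj"][:, 1],
                color=plots.GJ_COLOR, lw=0.8, label="with Gj")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("GoC spikes/bin")
        ax.set_title(key)
        ax.legend(frameon=False)
        path = os.path.join(outdir, f"psth_{key}.png")
        plots.save(fig, path)
        written.append(path)
    return written
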