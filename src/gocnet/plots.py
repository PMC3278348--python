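"""Figure helpers: rasters, PSTH overlays and power curves.

Convention throughout: red = with gap junctions, blue = without.
"""

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

GJ_COLOR, NOGJ_COLOR = "crimson", "royalblue"


def raster(spike_data, layer, ax=None, color="k", t_range=None, **kw):
    """Dot raster of one layer (one row per cell)."""
    ax = ax or plt.gca()
    idx, t = spike_data.spikes[layer]
    if t_range is not None:
        m = (t >= t_range[0]) & (t < t_range[1])
        idx, t = idx[m], t[m]
    ax.plot(t, idx, ".", ms=1.5, color=color, **kw)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"{layer} cell")
    return ax


def psth_overlay(psth_gj, psth_nogj, ax=None, t_range=None):
    """Gap-junction (red) vs no-gap-junction (blue) PSTH overlay."""
    ax = ax or plt.gca()
    for psth, color, label in ((psth_nogj, NOGJ_COLOR, "without Gj"),
                               (psth_gj, GJ_COLOR, "with Gj")):
        e, c = psth.edges_ms, psth.counts
        if t_range is not None:
            m = (e >= t_range[0]) & (e < t_range[1])
            e, c = e[m], c[m]
        ax.plot(e, c, color=color, lw=0.8, label=label)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("spikes / bin")
    ax.legend(frameon=False)
    return ax


def spectrum_overlay(spec_gj, spec_nogj, ax=None, normalize=True):
    ax = ax or plt.gca()
    for spec, color, label in ((spec_nogj, NOGJ_COLOR, "without Gj"),
                               (spec_gj, GJ_COLOR, "with Gj")):
        s = spec.normalized() if normalize else spec
        ax.plot(s.frequencies_hz, s.power, color=color, label=label)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("normalized power" if normalize else "power")
    ax.set_xscale("log")
    ax.legend(frameon=False)
    return ax


def resonance_curves(freqs, power_gj, power_nogj, ax=None):
    ax = ax or plt.gca()
    ax.plot(freqs, power_nogj, "^-", color=NOGJ_COLOR, label="without Gj")
    ax.plot(freqs, power_gj, "^-", color=GJ_COLOR, label="with Gj")
    ax.set_xlabel("sinusoid frequency (Hz)")
    ax.set_ylabel("normalized GoC PSTH power")
    ax.legend(frameon=False)
    return ax


def power_surface(pf_weights, freqs, power_matrix, ax=None, title=None):
    """Heat map of spectral power vs (frequency, feedback weight)."""
    ax = ax or plt.gca()
    im = ax.pcolormesh(freqs, pf_weights, power_matrix, shading="auto")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PF synaptic weight (%)")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="normalized power")
    return ax


def two_cell_traces(demo, ax=None, t_range=None):
    ax = ax or plt.subplots(2, 1, sharex=True)[1]
    t = demo["t_ms"]
    sel = np.ones(len(t), bool)
    if t_range is not None:
        sel = (t >= t_range[0]) & (t < t_range[1])
    ax[0].plot(t[sel], demo["v_driver"][sel], "k", lw=0.7)
    ax[0].set_ylabel("driver Vm (mV)")
    ax[1].plot(t[sel], demo["v_follower"][sel], "r", lw=0.7)
    ax[1].axhline(demo["v_rest"], ls=":", color="gray")
    ax[1].set_ylabel("follower Vm (mV)")
    ax[1].set_xlabel("time (ms)")
    return ax


def save(fig, path, dpi=150):
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
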