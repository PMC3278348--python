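"""Construction of the three-layer granular-network architecture.

The model is three two-dimensional grids of cells over a shared physical
extent (default 150 x 1500 um): 10x90 = 900 mossy fibers (MF), 30x270 =
8100 granule cells (GC) and 5x45 = 225 Golgi cells (GoC), 9,225 units in
total. Grid positions are jittered by +-20% of the local grid spacing, and
all distance-dependent quantities (conduction delays, synaptic conductances,
gap-junction strengths) are computed from the jittered positions, so the
positional randomization effectively randomizes the coupling structure.

Connectivity rules (convergence onto each postsynaptic cell):

====================  ===========  =======================================
projection            convergence  selection rule
====================  ===========  =======================================
MF -> GC              4            nearest presynaptic MFs
MF -> GoC             100          distance-kernel sample, exp(-0.0075 d)
PF -> GoC             4000         uniform over GCs whose parallel fiber
                                   passes within the GoC's x-window
GoC -> GC             8            nearest GoCs
====================  ===========  =======================================

Per-cell convergence is drawn as round(Normal(mean, 0.05 mean)), floored at
1, so realized synapse counts scatter around the targets. Conduction delays
are Euclidean distance / 0.5 m/s (for parallel fibers: distance along the
fiber axis plus an optional ascending-segment constant). All conductances
except PF->GoC decay as exp(-0.01/um x distance); base weights are
calibrated per network instance so population means match the target means
(see ``TARGET_MEAN_CONDUCTANCES``).

Gap junctions couple GoC pairs within a cutoff radius; their conductance
decays with inter-soma distance (0.03/um), is randomized multiplicatively
by +-60%, and is capped so that short-range couplings fall in the
0.25-1.25 nS range.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import h5py
import yaml
from scipy.spatial import cKDTree

from .errors import ConfigError
from .neurons import GCParams, GoCParams
from .synapses import AMPAR, NMDAR, GABAAR

LAYER_MF, LAYER_GC, LAYER_GOC = "MF", "GC", "GoC"

#: Projection names (keys of the connection table).
MF_GC_AMPA = "mf_gc_ampa"
MF_GC_NMDA = "mf_gc_nmda"
MF_GOC_AMPA = "mf_goc_ampa"
PF_GOC_AMPA = "pf_goc_ampa"
GOC_GC_GABAA = "goc_gc_gabaa"

#: Target population-mean conductances (nS) used for base-weight calibration.
TARGET_MEAN_CONDUCTANCES = {
    MF_GC_AMPA: 2.28,
    MF_GC_NMDA: 0.198,
    MF_GOC_AMPA: 0.706,
    GOC_GC_GABAA: 0.968,
    PF_GOC_AMPA: 2.588,
}

# Macroscopic single-contact conductances from voltage-clamp literature,
# recorded here for provenance only (they do not enter the simulation):
# MF->GC ~124 pS, MF->GoC ~833 pS, GoC->GC 137-420 pS, PF->GoC ~666 pS.


@dataclass(frozen=True)
class GapJunctionConfig:
    base_nS: float = 2.5              # conductance at zero inter-soma distance
    decay_per_um: float = 0.03
    randomization_fraction: float = 0.6
    cutoff_grid_spacings: float = 2.0
    max_nS: float = 1.25              # cap = top of the short-distance range
    short_distance_range_nS: tuple = (0.25, 1.25)

    def __post_init__(self):
        if not (0.0 <= self.randomization_fraction < 1.0):
            raise ConfigError("randomization_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ConnectivityRules:
    convergence: dict = field(default_factory=lambda: {
        MF_GC_AMPA: 4, MF_GOC_AMPA: 100, PF_GOC_AMPA: 4000, GOC_GC_GABAA: 8,
    })
    convergence_jitter_fraction: float = 0.05
    conductance_decay_per_um: float = 0.01
    propagation_speed_m_s: float = 0.5
    pf_extent_um: float = 2500.0      # parallel-fiber reach in each x direction
    ascending_fiber_um: float = 0.0   # constant added to the PF path length
    #: MF->GoC sampling-kernel decay; calibrated so the realized mean
    #: MF->GoC delay reproduces the published 0.312 ms population mean.
    mf_goc_kernel_per_um: float = 0.0075

    def divergence(self, n_pre: dict, n_post: dict) -> dict:
        """Mean divergences implied by the convergences and layer counts."""
        out = {}
        for name, conv in self.convergence.items():
            pre, post = PROJECTION_LAYERS[name]
            out[name] = conv * n_post[post] / n_pre[pre]
        return out


PROJECTION_LAYERS = {
    MF_GC_AMPA: (LAYER_MF, LAYER_GC),
    MF_GC_NMDA: (LAYER_MF, LAYER_GC),
    MF_GOC_AMPA: (LAYER_MF, LAYER_GOC),
    PF_GOC_AMPA: (LAYER_GC, LAYER_GOC),
    GOC_GC_GABAA: (LAYER_GOC, LAYER_GC),
}

PROJECTION_RECEPTOR = {
    MF_GC_AMPA: AMPAR,
    MF_GC_NMDA: NMDAR,
    MF_GOC_AMPA: AMPAR,
    PF_GOC_AMPA: AMPAR,
    GOC_GC_GABAA: GABAAR,
}


@dataclass(frozen=True)
class NetworkConfig:
    """Full architectural configuration with the published defaults."""

    mf_dims: tuple = (10, 90)
    gc_dims: tuple = (30, 270)
    goc_dims: tuple = (5, 45)
    extent_um: tuple = (150.0, 1500.0)   # (y, x)
    jitter_fraction: float = 0.2
    spatial_randomness: float = 1.0      # multiplier on positional jitter
    cell_randomness: float = 1.0         # multiplier on leak/area randomization
    cell_randomization_fraction: float = 0.2
    rules: ConnectivityRules = field(default_factory=ConnectivityRules)
    gap_junctions: GapJunctionConfig = field(default_factory=GapJunctionConfig)

    def __post_init__(self):
        for dims in (self.mf_dims, self.gc_dims, self.goc_dims):
            if dims[0] <= 0 or dims[1] <= 0:
                raise ConfigError(f"grid dims must be positive, got {dims}")
        if self.extent_um[0] <= 0 or self.extent_um[1] <= 0:
            raise ConfigError("extent must be positive")

    @property
    def layer_dims(self) -> dict:
        return {LAYER_MF: self.mf_dims, LAYER_GC: self.gc_dims,
                LAYER_GOC: self.goc_dims}

    @property
    def counts(self) -> dict:
        return {k: d[0] * d[1] for k, d in self.layer_dims.items()}


def default_config(**overrides) -> NetworkConfig:
    """The full-scale published architecture (0.15 x 1.5 mm)."""
    return NetworkConfig(**overrides)


def mini_config(**overrides) -> NetworkConfig:
    """Reduced test-scale network preserving densities and local rules.

    Grids 5x30 MF / 15x90 GC / 3x15 GoC over 75 x 500 um; the broad
    convergences scale with the shrunken presynaptic pools (MF->GoC 17,
    PF->GoC 667) while the local ones (MF->GC 4, GoC->GC 8) are unchanged.
    """
    rules = ConnectivityRules(convergence={
        MF_GC_AMPA: 4, MF_GOC_AMPA: 17, PF_GOC_AMPA: 667, GOC_GC_GABAA: 8,
    })
    kw = dict(mf_dims=(5, 30), gc_dims=(15, 90), goc_dims=(3, 15),
              extent_um=(75.0, 500.0), rules=rules)
    kw.update(overrides)
    return NetworkConfig(**kw)


def elongated_config(**overrides) -> NetworkConfig:
    """6-mm-long variant (same cell counts, stretched extent) used for
    parallel-fiber resonance; densities are reduced accordingly."""
    kw = dict(extent_um=(150.0, 6000.0))
    kw.update(overrides)
    return NetworkConfig(**kw)


@dataclass
class LayerGeometry:
    """Jittered 2D lattice positions of one cell layer.

    ``positions`` is (n, 2) in (x, y) um; cell index = row * cols + col
    (row-major). ``grid_spacing_um`` is (sx, sy).
    """

    layer_id: str
    grid_dims: tuple
    extent_um: tuple
    positions: np.ndarray
    jitter_fraction: float

    @property
    def n_cells(self) -> int:
        return self.grid_dims[0] * self.grid_dims[1]

    @property
    def grid_spacing_um(self) -> tuple:
        rows, cols = self.grid_dims
        return (self.extent_um[1] / cols, self.extent_um[0] / rows)

    def grid_coords(self, index) -> tuple:
        """(row, col) of flat cell indices."""
        cols = self.grid_dims[1]
        index = np.asarray(index)
        return index // cols, index % cols


def build_geometry(config: NetworkConfig, seed: int) -> dict:
    """Jittered lattice positions for the three layers, seeded.

    Each cell sits at its lattice-cell center displaced uniformly by at
    most ``jitter_fraction * spatial_randomness`` of the grid spacing per
    axis, then clamped to the extent.
    """
    rng = np.random.default_rng(seed)
    ey, ex = config.extent_um
    out = {}
    jit = config.jitter_fraction * config.spatial_randomness
    for layer, dims in config.layer_dims.items():
        rows, cols = dims
        sx, sy = ex / cols, ey / rows
        cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
        x = (cc.ravel() + 0.5) * sx
        y = (rr.ravel() + 0.5) * sy
        n = rows * cols
        x = x + rng.uniform(-jit, jit, n) * sx
        y = y + rng.uniform(-jit, jit, n) * sy
        pos = np.column_stack([np.clip(x, 0, ex), np.clip(y, 0, ey)])
        out[layer] = LayerGeometry(layer, dims, config.extent_um, pos,
                                   config.jitter_fraction)
    return out


@dataclass
class Projection:
    """Per-synapse records of one projection (struct-of-arrays)."""

    name: str
    pre_layer: str
    post_layer: str
    receptor: str
    pre: np.ndarray          # presynaptic cell indices
    post: np.ndarray         # postsynaptic cell indices
    distance_um: np.ndarray  # path length used for delay/conductance scaling
    delay_ms: np.ndarray = None
    g_nS: np.ndarray = None

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def mean_convergence(self, n_post: int) -> float:
        return self.n_synapses / n_post


def _draw_convergences(rng, mean, jitter_frac, n, n_available):
    k = np.rint(rng.normal(mean, jitter_frac * mean, n)).astype(int)
    k = np.clip(k, 1, n_available)
    return k


def connect_layers(geometry: dict, rules: ConnectivityRules, seed: int) -> dict:
    """Realize the synaptic connection table from the geometry.

    Returns a dict of :class:`Projection` (delays/conductances unassigned;
    see :func:`assign_delays` and :func:`assign_conductances`). The MF->GC
    NMDAR projection duplicates the AMPAR one synapse-for-synapse, as both
    receptors sit in the same glomerular contact.
    """
    rng = np.random.default_rng(seed)
    mf, gc, goc = geometry[LAYER_MF], geometry[LAYER_GC], geometry[LAYER_GOC]
    conv = rules.convergence
    for name, c in conv.items():
        n_pre = geometry[PROJECTION_LAYERS[name][0]].n_cells
        if c > n_pre:
            raise ConfigError(
                f"{name}: convergence {c} exceeds presynaptic pool {n_pre}"
            )
    jf = rules.convergence_jitter_fraction
    table = {}

    def knn_projection(name, pre_geom, post_geom, mean_k):
        tree = cKDTree(pre_geom.positions)
        n_post = post_geom.n_cells
        ks = _draw_convergences(rng, mean_k, jf, n_post, pre_geom.n_cells)
        kmax = ks.max()
        dist, idx = tree.query(post_geom.positions, k=kmax)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        pres, posts, dists = [], [], []
        for j in range(n_post):
            k = ks[j]
            pres.append(idx[j, :k])
            posts.append(np.full(k, j))
            dists.append(dist[j, :k])
        return Projection(name, pre_geom.layer_id, post_geom.layer_id,
                          PROJECTION_RECEPTOR[name],
                          np.concatenate(pres).astype(np.int32),
                          np.concatenate(posts).astype(np.int32),
                          np.concatenate(dists))

    # Local projections: k nearest presynaptic cells.
    ampa = knn_projection(MF_GC_AMPA, mf, gc, conv[MF_GC_AMPA])
    table[MF_GC_AMPA] = ampa
    table[MF_GC_NMDA] = Projection(
        MF_GC_NMDA, LAYER_MF, LAYER_GC, NMDAR,
        ampa.pre.copy(), ampa.post.copy(), ampa.distance_um.copy())
    table[GOC_GC_GABAA] = knn_projection(GOC_GC_GABAA, goc, gc,
                                         conv[GOC_GC_GABAA])

    # MF -> GoC: broad distance-kernel sampling without replacement.
    ks = _draw_convergences(rng, conv[MF_GOC_AMPA], jf, goc.n_cells,
                            mf.n_cells)
    pres, posts, dists = [], [], []
    for j in range(goc.n_cells):
        d = np.linalg.norm(mf.positions - goc.positions[j], axis=1)
        w = np.exp(-rules.mf_goc_kernel_per_um * d)
        p = w / w.sum()
        sel = rng.choice(mf.n_cells, size=ks[j], replace=False, p=p)
        pres.append(sel)
        posts.append(np.full(ks[j], j))
        dists.append(d[sel])
    table[MF_GOC_AMPA] = Projection(
        MF_GOC_AMPA, LAYER_MF, LAYER_GOC, AMPAR,
        np.concatenate(pres).astype(np.int32),
        np.concatenate(posts).astype(np.int32),
        np.concatenate(dists))

    # PF -> GoC: the GC axon ascends and runs along x in both directions;
    # a GoC samples uniformly among GCs whose fiber passes its x position.
    ks = _draw_convergences(rng, conv[PF_GOC_AMPA], jf, goc.n_cells,
                            gc.n_cells)
    pres, posts, dists = [], [], []
    gx = gc.positions[:, 0]
    for j in range(goc.n_cells):
        dx = np.abs(gx - goc.positions[j, 0])
        eligible = np.flatnonzero(dx <= rules.pf_extent_um)
        if len(eligible) < ks[j]:
            raise ConfigError(
                f"PF->GoC: only {len(eligible)} fibers reach GoC {j}, "
                f"need {ks[j]}"
            )
        sel = rng.choice(eligible, size=ks[j], replace=False)
        pres.append(sel)
        posts.append(np.full(ks[j], j))
        dists.append(rules.ascending_fiber_um + dx[sel])
    table[PF_GOC_AMPA] = Projection(
        PF_GOC_AMPA, LAYER_GC, LAYER_GOC, AMPAR,
        np.concatenate(pres).astype(np.int32),
        np.concatenate(posts).astype(np.int32),
        np.concatenate(dists))
    return table


def assign_delays(table: dict, speed_m_s: float = 0.5) -> dict:
    """Set conduction delays: path length / propagation speed, in ms.

    0.5 m/s = 500 um/ms, so ``delay_ms = distance_um / (1000 * speed)``.
    """
    um_per_ms = speed_m_s * 1000.0
    for proj in table.values():
        proj.delay_ms = proj.distance_um / um_per_ms
    return table


def calibrate_base_weights(table: dict, targets=None,
                           decay_per_um: float = 0.01) -> dict:
    """Solve zero-distance base weights so realized means hit the targets.

    For the distance-scaled projections the realized mean is
    ``base * mean(exp(-decay d))``; the parallel-fiber projection is
    distance-constant, so its base equals its target directly.
    """
    targets = targets or TARGET_MEAN_CONDUCTANCES
    base = {}
    for name, target in targets.items():
        proj = table[name]
        if name == PF_GOC_AMPA:
            base[name] = target
        else:
            base[name] = target / float(
                np.mean(np.exp(-decay_per_um * proj.distance_um)))
    return base


def assign_conductances(table: dict, base_weights: dict,
                        decay_per_um: float = 0.01) -> dict:
    """Distance-scale peak conductances: g(d) = g_base exp(-decay d).

    The PF->GoC projection is constant along the fiber (g = g_base).
    """
    if decay_per_um < 0:
        raise ConfigError("decay must be >= 0")
    for name, proj in table.items():
        g0 = base_weights[name]
        if name == PF_GOC_AMPA:
            proj.g_nS = np.full(proj.n_synapses, g0)
        else:
            proj.g_nS = g0 * np.exp(-decay_per_um * proj.distance_um)
    return table


@dataclass
class GapJunctionSet:
    """Symmetric GoC-GoC electrical couplings (each unordered pair once)."""

    goc_i: np.ndarray
    goc_j: np.ndarray
    g_nS: np.ndarray
    distance_um: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.goc_i)

    def total_coupling_per_cell(self, n_goc: int) -> np.ndarray:
        tot = np.zeros(n_goc)
        np.add.at(tot, self.goc_i, self.g_nS)
        np.add.at(tot, self.goc_j, self.g_nS)
        return tot


def build_gap_junctions(goc_geometry: LayerGeometry,
                        gj_config: GapJunctionConfig, seed: int) -> GapJunctionSet:
    """Distance-decayed, randomized gap junctions between nearby GoCs.

    Couples pairs within ``cutoff_grid_spacings`` x the larger grid spacing.
    Gj = min(base * exp(-decay d) * u, max), u ~ Uniform(1-f, 1+f) with
    f the randomization fraction; the cap keeps short-range couplings
    inside the physiological 0.25-1.25 nS range.
    """
    cfg = gj_config
    sx, sy = goc_geometry.grid_spacing_um
    cutoff = cfg.cutoff_grid_spacings * max(sx, sy)
    tree = cKDTree(goc_geometry.positions)
    pairs = sorted(tree.query_pairs(cutoff))
    if not pairs:
        return GapJunctionSet(np.empty(0, np.int32), np.empty(0, np.int32),
                              np.empty(0), np.empty(0))
    rng = np.random.default_rng(seed)
    i = np.array([p[0] for p in pairs], np.int32)
    j = np.array([p[1] for p in pairs], np.int32)
    d = np.linalg.norm(goc_geometry.positions[i] - goc_geometry.positions[j],
                       axis=1)
    f = cfg.randomization_fraction
    u = rng.uniform(1.0 - f, 1.0 + f, len(d))
    g = np.minimum(cfg.base_nS * np.exp(-cfg.decay_per_um * d) * u, cfg.max_nS)
    return GapJunctionSet(i, j, g, d)


def network_census(table: dict) -> dict:
    """Connection counts per projection plus the grand synapse total.

    MF->GC contacts carry both AMPAR and NMDAR, counted separately in the
    total (as in the published bookkeeping) but reported once per pair
    under ``mf_gc_pairs``.
    """
    counts = {name: proj.n_synapses for name, proj in table.items()}
    counts["mf_gc_pairs"] = counts.get(MF_GC_AMPA, 0)
    counts["total"] = sum(proj.n_synapses for proj in table.values())
    return counts


@dataclass
class Network:
    """A fully realized network instance (geometry + synapses + couplings).

    ``gc_leak_scale``/``gc_area_scale`` (and the GoC equivalents) are the
    per-cell +-20% randomization factors applied to leak conductances and
    to membrane capacitance respectively.
    """

    config: NetworkConfig
    seed: int
    geometry: dict
    projections: dict
    gap_junctions: GapJunctionSet
    goc_params: GoCParams
    gc_params: GCParams
    gc_leak_scale: np.ndarray
    gc_area_scale: np.ndarray
    goc_leak_scale: np.ndarray
    goc_area_scale: np.ndarray

    @property
    def n_gc(self) -> int:
        return self.geometry[LAYER_GC].n_cells

    @property
    def n_goc(self) -> int:
        return self.geometry[LAYER_GOC].n_cells

    @property
    def n_mf(self) -> int:
        return self.geometry[LAYER_MF].n_cells

    def census(self) -> dict:
        return network_census(self.projections)

    # ------------------------------------------------------------------ IO
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["seed"] = self.seed
            fh.attrs["config_yaml"] = yaml.safe_dump(asdict(self.config))
            for layer, geom in self.geometry.items():
                grp = fh.create_group(f"geometry/{layer}")
                grp.attrs["grid_dims"] = geom.grid_dims
                grp.attrs["extent_um"] = geom.extent_um
                grp.attrs["jitter_fraction"] = geom.jitter_fraction
                grp.create_dataset("positions", data=geom.positions)
            for name, proj in self.projections.items():
                grp = fh.create_group(f"projections/{name}")
                grp.attrs["pre_layer"] = proj.pre_layer
                grp.attrs["post_layer"] = proj.post_layer
                grp.attrs["receptor"] = proj.receptor
                for key in ("pre", "post", "distance_um", "delay_ms", "g_nS"):
                    grp.create_dataset(key, data=getattr(proj, key))
            grp = fh.create_group("gap_junctions")
            for key in ("goc_i", "goc_j", "g_nS", "distance_um"):
                grp.create_dataset(key, data=getattr(self.gap_junctions, key))
            grp = fh.create_group("cell_scales")
            for key in ("gc_leak_scale", "gc_area_scale",
                        "goc_leak_scale", "goc_area_scale"):
                grp.create_dataset(key, data=getattr(self, key))

    def export_edge_lists(self, directory) -> None:
        """Delimited edge lists: pre_id, post_id, receptor, g_nS, delay_ms."""
        import os
        os.makedirs(directory, exist_ok=True)
        for name, proj in self.projections.items():
            path = os.path.join(directory, f"{name}.tsv")
            with open(path, "w") as fh:
                fh.write("pre_id\tpost_id\treceptor\tg_nS\tdelay_ms\n")
                for k in range(proj.n_synapses):
                    fh.write(f"{proj.pre[k]}\t{proj.post[k]}\t{proj.receptor}"
                             f"\t{proj.g_nS[k]:.6g}\t{proj.delay_ms[k]:.6g}\n")


def build_network(config: NetworkConfig, seed: int,
                  goc_params: GoCParams = None,
                  gc_params: GCParams = None) -> Network:
    """Build a complete seeded network instance.

    One master seed drives geometry, connectivity, gap junctions and the
    per-cell randomization, each through an independent child generator so
    the instance is bit-reproducible.
    """
    goc_params = goc_params or GoCParams()
    gc_params = gc_params or GCParams()
    ss = np.random.SeedSequence(seed)
    s_geom, s_conn, s_gj, s_cell = [int(c.generate_state(1)[0]) % (2**31)
                                    for c in ss.spawn(4)]
    geometry = build_geometry(config, s_geom)
    table = connect_layers(geometry, config.rules, s_conn)
    assign_delays(table, config.rules.propagation_speed_m_s)
    base = calibrate_base_weights(table,
                                  decay_per_um=config.rules.conductance_decay_per_um)
    assign_conductances(table, base, config.rules.conductance_decay_per_um)
    gj = build_gap_junctions(geometry[LAYER_GOC], config.gap_junctions, s_gj)

    rng = np.random.default_rng(s_cell)
    frac = config.cell_randomization_fraction * config.cell_randomness
    n_gc, n_goc = geometry[LAYER_GC].n_cells, geometry[LAYER_GOC].n_cells
    gc_leak = rng.uniform(1 - frac, 1 + frac, n_gc)
    gc_area = rng.uniform(1 - frac, 1 + frac, n_gc)
    goc_leak = rng.uniform(1 - frac, 1 + frac, n_goc)
    goc_area = rng.uniform(1 - frac, 1 + frac, n_goc)
    return Network(config, seed, geometry, table, gj, goc_params, gc_params,
                   gc_leak, gc_area, goc_leak, goc_area)


def load_network_hdf5(path) -> Network:
    """Inverse of :meth:`Network.to_hdf5`."""
    with h5py.File(path, "r") as fh:
        cfg_dict = yaml.safe_load(fh.attrs["config_yaml"])
        cfg_dict["rules"] = ConnectivityRules(**{
            **cfg_dict["rules"],
            "convergence": dict(cfg_dict["rules"]["convergence"]),
        })
        cfg_dict["gap_junctions"] = GapJunctionConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg_dict["gap_junctions"].items()
        })
        for key in ("mf_dims", "gc_dims", "goc_dims", "extent_um"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = NetworkConfig(**cfg_dict)
        seed = int(fh.attrs["seed"])
        geometry = {}
        for layer in fh["geometry"]:
            grp = fh[f"geometry/{layer}"]
            geometry[layer] = LayerGeometry(
                layer, tuple(int(v) for v in grp.attrs["grid_dims"]),
                tuple(float(v) for v in grp.attrs["extent_um"]),
                grp["positions"][...], float(grp.attrs["jitter_fraction"]))
        table = {}
        for name in fh["projections"]:
            grp = fh[f"projections/{name}"]
            table[name] = Projection(
                name, grp.attrs["pre_layer"], grp.attrs["post_layer"],
                grp.attrs["receptor"], grp["pre"][...], grp["post"][...],
                grp["distance_um"][...], grp["delay_ms"][...],
                grp["g_nS"][...])
        gj = GapJunctionSet(fh["gap_junctions/goc_i"][...],
                            fh["gap_junctions/goc_j"][...],
                            fh["gap_junctions/g_nS"][...],
                            fh["gap_junctions/distance_um"][...])
        scales = {k: fh[f"cell_scales/{k}"][...]
                  for k in ("gc_leak_scale", "gc_area_scale",
                            "goc_leak_scale", "goc_area_scale")}
    return Network(config, seed, geometry, table, gj, GoCParams(), GCParams(),
                   **scales)


def config_to_yaml(config: NetworkConfig, path=None):
    text = yaml.safe_dump(asdict(config))
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> NetworkConfig:
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(io.StringIO(str(source)).read())
    if "rules" in data:
        data["rules"] = ConnectivityRules(**data["rules"])
    if "gap_junctions" in data:
        gj = {k: tuple(v) if isinstance(v, list) else v
              for k, v in data["gap_junctions"].items()}
        data["gap_junctions"] = GapJunctionConfig(**gj)
    for key in ("mf_dims", "gc_dims", "goc_dims", "extent_um"):
        if key in data:
            data[key] = tuple(data[key])
    return NetworkConfig(**data)
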