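"""Geometry, connectivity, conductance scaling and gap-junction structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gocnet import network as nw
from gocnet.errors import ConfigError


def test_default_layer_counts():
    cfg = nw.default_config()
    assert cfg.counts == {"MF": 900, "GC": 8100, "GoC": 225}
    assert sum(cfg.counts.values()) == 9225
    assert cfg.counts["GC"] / cfg.counts["GoC"] == 36


def test_geometry_jitter_zero_gives_exact_lattice():
    cfg = nw.default_config(spatial_randomness=0.0)
    geom = nw.build_geometry(cfg, seed=0)["GoC"]
    sx, sy = geom.grid_spacing_um
    rows, cols = geom.grid_dims
    expect_x = (np.arange(cols) + 0.5) * sx
    assert np.allclose(np.unique(geom.positions[:, 0]), expect_x)
    expect_y = (np.arange(rows) + 0.5) * sy
    assert np.allclose(np.unique(geom.positions[:, 1]), expect_y)


def test_geometry_jitter_bounded_and_inside_extent():
    cfg = nw.default_config()
    for layer, geom in nw.build_geometry(cfg, seed=3).items():
        sx, sy = geom.grid_spacing_um
        rows, cols = geom.grid_dims
        rr, cc = geom.grid_coords(np.arange(geom.n_cells))
        dx = geom.positions[:, 0] - (cc + 0.5) * sx
        dy = geom.positions[:, 1] - (rr + 0.5) * sy
        assert np.all(np.abs(dx) <= 0.2 * sx + 1e-9)
        assert np.all(np.abs(dy) <= 0.2 * sy + 1e-9)
        assert geom.positions[:, 0].min() >= 0
        assert geom.positions[:, 0].max() <= geom.extent_um[1]


def test_geometry_deterministic_per_seed():
    cfg = nw.default_config()
    g1 = nw.build_geometry(cfg, seed=11)
    g2 = nw.build_geometry(cfg, seed=11)
    g3 = nw.build_geometry(cfg, seed=12)
    for layer in g1:
        assert np.array_equal(g1[layer].positions, g2[layer].positions)
    assert not np.array_equal(g1["GC"].positions, g3["GC"].positions)


def test_invalid_dims_rejected():
    with pytest.raises(ConfigError):
        nw.NetworkConfig(mf_dims=(0, 90))
    with pytest.raises(ConfigError):
        nw.NetworkConfig(extent_um=(0.0, 1500.0))


@pytest.fixture(scope="module")
def built(default_network):
    return default_network


def test_realized_convergences_match_targets(built):
    n_post = {"GC": built.n_gc, "GoC": built.n_goc}
    targets = built.config.rules.convergence
    conv = {
        nw.MF_GC_AMPA: built.projections[nw.MF_GC_AMPA].n_synapses / built.n_gc,
        nw.GOC_GC_GABAA: built.projections[nw.GOC_GC_GABAA].n_synapses / built.n_gc,
        nw.MF_GOC_AMPA: built.projections[nw.MF_GOC_AMPA].n_synapses / built.n_goc,
        nw.PF_GOC_AMPA: built.projections[nw.PF_GOC_AMPA].n_synapses / built.n_goc,
    }
    assert conv[nw.MF_GC_AMPA] == pytest.approx(4.0, abs=0.2)
    assert conv[nw.GOC_GC_GABAA] == pytest.approx(8.0, abs=1.0)
    for name, c in conv.items():
        assert c == pytest.approx(targets[name], rel=0.10)


def test_convergence_divergence_consistency(built):
    """Realized conv x n_post equals divergence x n_pre within 15%."""
    n = {"MF": built.n_mf, "GC": built.n_gc, "GoC": built.n_goc}
    div = built.config.rules.divergence(n, n)
    for name, proj in built.projections.items():
        if name == nw.MF_GC_NMDA:
            continue
        pre_l, post_l = nw.PROJECTION_LAYERS[name]
        conv = proj.n_synapses / n[post_l]
        assert conv * n[post_l] == pytest.approx(div[name] * n[pre_l],
                                                 rel=0.15)


def test_nmda_pairs_ampa_synapse_for_synapse(built):
    a = built.projections[nw.MF_GC_AMPA]
    n = built.projections[nw.MF_GC_NMDA]
    assert np.array_equal(a.pre, n.pre)
    assert np.array_equal(a.post, n.post)


def test_census_counts(built):
    census = built.census()
    assert census["mf_gc_pairs"] == pytest.approx(32547, rel=0.05)
    assert census["total"] == sum(
        p.n_synapses for p in built.projections.values())
    empty = nw.network_census({})
    assert empty["total"] == 0 and empty["mf_gc_pairs"] == 0


def test_delay_is_distance_over_speed(built):
    for proj in built.projections.values():
        assert np.allclose(proj.delay_ms, proj.distance_um / 500.0)
    # hand-computed example: 156 um at 0.5 m/s -> 0.312 ms
    toy = nw.Projection("toy", "MF", "GC", "AMPAR",
                        np.array([0]), np.array([0]), np.array([156.0]))
    nw.assign_delays({"toy": toy}, speed_m_s=0.5)
    assert toy.delay_ms[0] == pytest.approx(0.312)
    zero = nw.Projection("z", "MF", "GC", "AMPAR",
                         np.array([0]), np.array([0]), np.array([0.0]))
    nw.assign_delays({"z": zero})
    assert zero.delay_ms[0] == 0.0


def test_conductance_distance_scaling(built):
    toy = nw.Projection("toy", "MF", "GC", "AMPAR", np.array([0, 0]),
                        np.array([0, 1]), np.array([0.0, 100.0]))
    nw.assign_conductances({"toy": toy}, {"toy": 2.0}, decay_per_um=0.01)
    assert toy.g_nS[0] == pytest.approx(2.0)          # g(0) = g_base
    assert toy.g_nS[1] == pytest.approx(2.0 * np.exp(-1.0))
    # parallel fibers: distance-constant
    pf = built.projections[nw.PF_GOC_AMPA]
    assert np.allclose(pf.g_nS, 2.588)


def test_locality_ordering_of_mean_distances(built):
    d_mf_gc = built.projections[nw.MF_GC_AMPA].distance_um.mean()
    d_mf_goc = built.projections[nw.MF_GOC_AMPA].distance_um.mean()
    d_pf = built.projections[nw.PF_GOC_AMPA].distance_um.mean()
    assert d_mf_gc < d_mf_goc < d_pf


def test_half_size_network_preserves_local_connection_distances(built):
    cfg = nw.default_config()
    half = nw.NetworkConfig(mf_dims=(10, 45), gc_dims=(30, 135),
                            goc_dims=(5, 22),
                            extent_um=(150.0, 750.0), rules=cfg.rules)
    net_h = nw.build_network(half, seed=5)
    for name in (nw.MF_GC_AMPA, nw.GOC_GC_GABAA):
        d_full = built.projections[name].distance_um.mean()
        d_half = net_h.projections[name].distance_um.mean()
        assert d_half == pytest.approx(d_full, rel=0.20)


def test_excess_convergence_rejected():
    rules = nw.ConnectivityRules(convergence={
        nw.MF_GC_AMPA: 4, nw.MF_GOC_AMPA: 10**6,
        nw.PF_GOC_AMPA: 667, nw.GOC_GC_GABAA: 8})
    cfg = nw.mini_config(rules=rules)
    with pytest.raises(ConfigError):
        nw.build_network(cfg, seed=0)


class TestGapJunctions:
    def test_symmetric_unique_pairs(self, built):
        gj = built.gap_junctions
        assert np.all(gj.goc_i < gj.goc_j)
        pairs = set(zip(gj.goc_i.tolist(), gj.goc_j.tolist()))
        assert len(pairs) == gj.n_pairs
        assert np.all(gj.g_nS > 0)

    def test_nearest_neighbor_range(self, built):
        gj = built.gap_junctions
        sx, sy = built.geometry["GoC"].grid_spacing_um
        nn = gj.distance_um < 1.2 * max(sx, sy)
        assert nn.sum() > 50
        assert gj.g_nS[nn].min() >= 0.25
        assert gj.g_nS[nn].max() <= 1.25


    def test_conductance_decreases_with_distance(self, built):
        gj = built.gap_junctions
        rho = spearmanr(gj.distance_um, gj.g_nS).statistic
        assert rho < -0.3

    def test_zero_distance_without_randomization_gives_base(self):
        geom = nw.LayerGeometry("GoC", (1, 2), (100.0, 100.0),
                                np.array([[50.0, 50.0], [50.0, 50.0]]), 0.0)
        cfg = nw.GapJunctionConfig(randomization_fraction=0.0, max_nS=10.0)
        gj = nw.build_gap_junctions(geom, cfg, seed=0)
        assert gj.n_pairs == 1
        assert gj.g_nS[0] == pytest.approx(cfg.base_nS)

    def test_invalid_randomization_fraction(self):
        with pytest.raises(ConfigError):
            nw.GapJunctionConfig(randomization_fraction=1.0)

    def test_deterministic_per_seed(self, built):
        geom = built.geometry["GoC"]
        cfg = built.config.gap_junctions
        a = nw.build_gap_junctions(geom, cfg, seed=9)
        b = nw.build_gap_junctions(geom, cfg, seed=9)
        assert np.array_equal(a.g_nS, b.g_nS)


def test_build_network_bit_reproducible():
    cfg = nw.mini_config()
    n1 = nw.build_network(cfg, seed=77)
    n2 = nw.build_network(cfg, seed=77)
    for name in n1.projections:
        assert np.array_equal(n1.projections[name].g_nS,
                              n2.projections[name].g_nS)
        assert np.array_equal(n1.projections[name].delay_ms,
                              n2.projections[name].delay_ms)
    assert np.array_equal(n1.gap_junctions.g_nS, n2.gap_junctions.g_nS)
    assert np.array_equal(n1.gc_leak_scale, n2.gc_leak_scale)


def test_hdf5_round_trip(tmp_path):
    net = nw.build_network(nw.mini_config(), seed=4)
    path = tmp_path / "net.h5"
    net.to_hdf5(path)
    back = nw.load_network_hdf5(path)
    assert back.config == net.config
    for name in net.projections:
        assert np.allclose(back.projections[name].g_nS,
                           net.projections[name].g_nS)
    assert np.allclose(back.geometry["GC"].positions,
                       net.geometry["GC"].positions)
    assert np.allclose(back.gap_junctions.g_nS, net.gap_junctions.g_nS)


def test_config_yaml_round_trip(tmp_path):
    cfg = nw.mini_config()
    path = tmp_path / "cfg.yaml"
    nw.config_to_yaml(cfg, path)
    assert nw.config_from_yaml(path) == cfg


def test_edge_list_export(tmp_path, mini_network):
    mini_network.export_edge_lists(tmp_path / "edges")
    path = tmp_path / "edges" / "goc_gc_gabaa.tsv"
    lines = path.read_text().splitlines()
    assert lines[0] == "pre_id\tpost_id\treceptor\tg_nS\tdelay_ms"
    assert len(lines) == mini_network.projections["goc_gc_gabaa"].n_synapses + 1
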