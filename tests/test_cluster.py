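"""Cluster permutation: stat maps, cluster formation, permutation p-values."""

import numpy as np
import pytest
from scipy.stats import f as f_dist, t as t_dist

from rovingmmn.cluster import (
    ClusterTestConfig,
    channel_adjacency,
    form_clusters,
    permutation_test,
    stat_map_paired_t,
    stat_map_rm_F,
)
from rovingmmn.montage import Montage, default_montage


def test_adjacency_radius_extremes(montage):
    tiny = channel_adjacency(montage, radius=1e-6)
    assert tiny.degrees().sum() == 0
    full = channel_adjacency(montage, radius=10.0)
    n = montage.n_channels
    assert (full.degrees() == n - 1).all()
    with pytest.raises(ValueError):
        channel_adjacency(montage, radius=0.0)


def test_default_adjacency_connected_reasonable_degree(montage):
    adj = channel_adjacency(montage)
    assert adj.is_connected()
    assert 4 <= np.median(adj.degrees()) <= 6
    assert np.all(adj.matrix == adj.matrix.T)
    assert not np.any(np.diag(adj.matrix))


def test_paired_t_map_hand_computed_toy():
    """Three subjects, one channel, two samples: t from first principles."""
    diffs = np.array([[[1.0, 2.0]], [[2.0, 0.0]], [[3.0, 1.0]]])
    t_map, thr = stat_map_paired_t(diffs, cluster_alpha=0.05)
    for j in range(2):
        x = diffs[:, 0, j]
        t_hand = x.mean() / (x.std(ddof=1) / np.sqrt(3))
        assert t_map[0, j] == pytest.approx(t_hand, abs=1e-12)
    assert thr == pytest.approx(t_dist.ppf(0.975, 2))


def test_paired_t_threshold_at_n35():
    diffs = np.random.default_rng(0).standard_normal((35, 2, 4))
    _, thr = stat_map_paired_t(diffs)
    assert thr == pytest.approx(2.032, abs=5e-4)  # t_{0.975}(34)


def test_t_map_zero_for_identical_conditions_and_zero_variance():
    diffs = np.zeros((5, 2, 3))
    with pytest.warns(RuntimeWarning):
        t_map, _ = stat_map_paired_t(diffs)
    assert np.all(t_map == 0.0)


def test_rm_F_map_identities(rng):
    data = rng.standard_normal((8, 2, 3, 10))
    f_map, thr_f = stat_map_rm_F(data)
    # two-condition degenerate case: F equals the paired t squared
    t_map, _ = stat_map_paired_t(data[:, 0] - data[:, 1])
    assert np.allclose(f_map, t_map**2, atol=1e-8)
    same = np.stack([data[:, 0]] * 3, axis=1)
    with pytest.warns(RuntimeWarning):
        f0, _ = stat_map_rm_F(same)
    assert np.allclose(f0, 0.0)


def test_rm_F_threshold_at_n35():
    data = np.random.default_rng(1).standard_normal((35, 3, 2, 4))
    _, thr = stat_map_rm_F(data)
    assert thr == pytest.approx(f_dist.ppf(0.95, 2, 68), abs=1e-9)


def _grid_montage(n_ch):
    # channels on a line, spacing 0.1: neighbors are adjacent indices
    pos = np.zeros((n_ch, 2))
    pos[:, 0] = np.linspace(-0.45, 0.45, n_ch)
    return Montage(tuple(f"ch{i}" for i in range(n_ch)), pos, roi=("ch0",))


def _flood_fill_oracle(stat_map, threshold, adj, tail):
    """Recursive flood fill over supra-threshold cells (independent oracle)."""
    n_ch, n_t = stat_map.shape
    masks = [(stat_map > threshold, 1)]
    if tail == "two-sided":
        masks.append((stat_map < -threshold, -1))
    out = []
    for supra, sign in masks:
        seen = np.zeros_like(supra, dtype=bool)
        for c0 in range(n_ch):
            for t0 in range(n_t):
                if not supra[c0, t0] or seen[c0, t0]:
                    continue
                stack, cells = [(c0, t0)], []
                seen[c0, t0] = True
                while stack:
                    c, t = stack.pop()
                    cells.append((c, t))
                    for t2 in (t - 1, t + 1):
                        if 0 <= t2 < n_t and supra[c, t2] and not seen[c, t2]:
                            seen[c, t2] = True
                            stack.append((c, t2))
                    for c2 in range(n_ch):
                        if adj[c, c2] and supra[c2, t] and not seen[c2, t]:
                            seen[c2, t] = True
                            stack.append((c2, t))
                mass = sum(stat_map[c, t] for c, t in cells)
                out.append((sign, frozenset(cells), mass))
    return out


def test_cluster_formation_matches_flood_fill_oracle():
    """1,000 random 6-channel x 40-sample maps against a flood-fill oracle."""
    mont = _grid_montage(6)
    graph = channel_adjacency(mont, radius=0.2)
    rng = np.random.default_rng(2023)
    for _ in range(1000):
        stat_map = rng.standard_normal((6, 40)) * 1.5
        ours = form_clusters(stat_map, 2.0, graph, tail="two-sided")
        oracle = _flood_fill_oracle(stat_map, 2.0, graph.matrix, "two-sided")
        ours_set = {
            (c.sign, frozenset(zip(c.channels.tolist(), c.times.tolist())))
            for c in ours
        }
        oracle_set = {(s, cells) for s, cells, _ in oracle}
        assert ours_set == oracle_set
        our_masses = sorted(round(c.mass, 9) for c in ours)
        oracle_masses = sorted(round(m, 9) for _, _, m in oracle)
        assert our_masses == oracle_masses


def test_cluster_formation_simple_cases():
    mont = _grid_montage(4)
    graph = channel_adjacency(mont, radius=0.35)
    stat_map = np.zeros((4, 10))
    stat_map[1, 3] = 5.0
    single = form_clusters(stat_map, 2.0, graph)
    assert len(single) == 1 and single[0].n_cells == 1
    assert single[0].mass == pytest.approx(5.0)
    # non-adjacent channels at disjoint times: two clusters
    stat_map[3, 8] = 4.0
    two = form_clusters(stat_map, 2.0, graph)
    assert len(two) == 2
    # same channel, contiguous samples: one cluster
    stat_map2 = np.zeros((4, 10))
    stat_map2[0, 2:5] = 3.0
    one = form_clusters(stat_map2, 2.0, graph)
    assert len(one) == 1 and one[0].n_cells == 3


def test_permutation_p_floor_and_determinism(small_montage):
    rng = np.random.default_rng(5)
    # strong common effect: observed mass should beat every permutation
    diffs = 3.0 + 0.5 * rng.standard_normal((12, small_montage.n_channels, 60))
    adj = channel_adjacency(small_montage)
    cfg = ClusterTestConfig(n_permutations=1024, seed=11)
    res = permutation_test(diffs, adj, cfg)
    assert res.clusters[0].p_value == pytest.approx(1 / 1025, abs=1e-12)
    res2 = permutation_test(diffs, adj, cfg)
    assert np.array_equal(res.null_max_mass, res2.null_max_mass)
    assert [c.mass for c in res.clusters] == [c.mass for c in res2.clusters]


def test_sign_symmetry(small_montage, rng):
    diffs = rng.standard_normal((10, small_montage.n_channels, 50))
    diffs[:, :2, 10:20] += 1.5
    adj = channel_adjacency(small_montage)
    t_pos, _ = stat_map_paired_t(diffs)
    t_neg, _ = stat_map_paired_t(-diffs)
    assert np.allclose(t_neg, -t_pos, atol=1e-10)
    pos = form_clusters(t_pos, 2.1, adj)
    neg = form_clusters(t_neg, 2.1, adj)
    assert sorted(round(c.mass, 9) for c in pos) == sorted(
        round(-c.mass, 9) for c in neg
    )
    assert sorted(c.sign for c in pos) == sorted(-c.sign for c in neg)


def test_effect_scaling_monotone_max_mass(small_montage):
    """Scaling the injected effect up never shrinks the observed max mass."""
    rng = np.random.default_rng(8)
    noise = rng.standard_normal((10, small_montage.n_channels, 60))
    bump = np.zeros((small_montage.n_channels, 60))
    bump[:3, 20:35] = 1.0
    adj = channel_adjacency(small_montage)
    masses = []
    for scale in (0.0, 0.5, 1.0, 2.0, 4.0):
        t_map, thr = stat_map_paired_t(noise + scale * bump)
        clusters = form_clusters(t_map, thr, adj)
        masses.append(max((abs(c.mass) for c in clusters), default=0.0))
    assert all(b >= a - 1e-9 for a, b in zip(masses, masses[1:]))


def test_rm_F_permutation_runs_and_detects(small_montage):
    rng = np.random.default_rng(4)
    data = rng.standard_normal((12, 3, small_montage.n_channels, 60))
    data[:, 1, :3, 20:35] += 1.2  # condition 1 differs
    adj = channel_adjacency(small_montage)
    cfg = ClusterTestConfig(n_permutations=256, seed=2, test="rm_F")
    res = permutation_test(data, adj, cfg)
    assert res.min_p() < 0.05
    null = np.stack([data[:, 0]] * 3, axis=1)
    rng_n = np.random.default_rng(9)
    null = null + 0.001 * rng_n.standard_normal(null.shape)
    res_null = permutation_test(null, adj, cfg)
    assert res_null.min_p() > 0.05


def test_observed_clusters_match_mne(small_montage, rng):
    """Observed t-map, clusters and masses agree with the reference
    spatio-temporal cluster implementation (permutation draws differ, so
    p-values are not compared)."""
    mne = pytest.importorskip("mne")
    from scipy import sparse

    diffs = rng.standard_normal((9, small_montage.n_channels, 40))
    diffs[:, :3, 10:22] += 0.9
    adj = channel_adjacency(small_montage)
    t_map, thr = stat_map_paired_t(diffs)
    ours = form_clusters(t_map, thr, adj)

    X = np.transpose(diffs, (0, 2, 1))  # obs x time x space
    t_obs, clusters, _, _ = mne.stats.spatio_temporal_cluster_1samp_test(
        X,
        threshold=thr,
        n_permutations=64,
        adjacency=sparse.coo_matrix(adj.matrix),
        tail=0,
        seed=0,
        out_type="indices",
        verbose="error",
    )
    assert np.allclose(t_obs.T, t_map, atol=1e-8)
    mne_sets = set()
    mne_masses = []
    for time_idx, space_idx in clusters:
        cells = frozenset(zip(space_idx.tolist(), time_idx.tolist()))
        mne_sets.add(cells)
        mne_masses.append(t_obs[time_idx, space_idx].sum())
    ours_sets = {
        frozenset(zip(c.channels.tolist(), c.times.tolist())) for c in ours
    }
    assert ours_sets == mne_sets
    assert sorted(round(m, 8) for m in mne_masses) == sorted(
        round(c.mass, 8) for c in ours
    )
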