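"""Condensate graphs: topology metrics, association, Weibull clusters."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sticklat.fixtures import (
    make_planted_hub_graph,
    make_ws_graph,
    sample_weibull_clusters,
)
from sticklat.graphs import (
    betweenness,
    betweenness_by_degree,
    build_condensate_graph,
    centrality_distance_distribution,
    centrality_persistence,
    discrete_weibull_cdf,
    fit_weibull_from_samples,
    fit_weibull_linearized,
    ratio_of_association,
    small_world_summary,
    sticker_cluster_sizes,
    sticker_cluster_weibull,
    sticker_contact_lifetime,
    top_central_chains,
)
from sticklat.mc import Frame, Trajectory
from sticklat.sequences import encode_sequence


# -- independent brute-force oracles ---------------------------------------

def brute_betweenness(g):
    """Exhaustive all-pairs shortest-path enumeration (unordered pairs)."""
    bc = {v: 0.0 for v in g}
    nodes = list(g)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            bc[v] += on / len(paths)
    return bc


def brute_path_length_and_clustering(g):
    nodes = list(g)
    n = len(nodes)
    total = 0
    for s, t in itertools.combinations(nodes, 2):
        total += nx.shortest_path_length(g, s, t)
    L = 2 * total / (n * (n - 1))
    cs = []
    for v in nodes:
        nb = list(g.neighbors(v))
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        e = sum(1 for a, b in itertools.combinations(nb, 2) if g.has_edge(a, b))
        cs.append(2 * e / (k * (k - 1)))
    return L, float(np.mean(cs))


class TestGraphConstruction:
    def test_single_sticker_contact_one_edge(self, make_config, model):
        chains = [[(2, 2, 2), (3, 2, 2)], [(3, 3, 3), (4, 3, 3)]]
        cfg = make_config(12, chains, ["YG", "YG"])
        g = build_condensate_graph(cfg, model)
        assert set(g.edges) == {(0, 1)}

    def test_sticker_spacer_contact_no_edge(self, make_config, model):
        # chain 1's sticker touches only chain 2's spacer
        chains = [[(2, 2, 2), (1, 2, 2)], [(3, 3, 3), (4, 4, 4)]]
        cfg = make_config(14, chains, ["YG", "GY"])
        # Y(2,2,2) adjacent to G(3,3,3); the two Y beads are far apart
        g = build_condensate_graph(cfg, model)
        assert g.number_of_edges() == 0

    def test_planted_five_chain_edges_match_audit(self, make_config, model):
        rng = np.random.default_rng(3)
        chains, seqs = [], []
        taken = set()
        for c in range(5):
            base = rng.integers(0, 10, size=3)
            chain = []
            for i in range(3):
                q = tuple((base + (i, 0, 0)) % 12)
                chain.append(q)
            if any(q in taken for q in chain):
                chain = [((q[0] + 5) % 12, q[1], q[2]) for q in chain]
            if any(q in taken for q in chain):
                continue
            taken.update(chain)
            chains.append(chain)
            seqs.append("YGY")
        cfg = make_config(12, chains, seqs)
        g = build_condensate_graph(cfg, model)
        # brute-force audit over all sticker pairs
        expect = set()
        st_idx = np.nonzero(cfg.sticker_mask)[0]
        for i, j in itertools.combinations(st_idx, 2):
            ci, cj = cfg.chain_of[i], cfg.chain_of[j]
            if ci == cj:
                continue
            d = np.abs(cfg.positions[i] - cfg.positions[j])
            d = np.minimum(d, 12 - d)
            if d.max() <= 1:
                expect.add((min(ci, cj), max(ci, cj)))
        full = nx.Graph()
        full.add_nodes_from(range(cfg.n_chains))
        full.add_edges_from(expect)
        giant = max(nx.connected_components(full), key=len)
        expect_giant = {e for e in expect if e[0] in giant and e[1] in giant}
        assert {tuple(sorted(e)) for e in g.edges} == expect_giant


class TestBetweenness:
    def test_three_node_path_middle_is_one(self):
        g = nx.path_graph(3)
        assert betweenness(g)[1] == pytest.approx(1.0)
        assert betweenness(g, ordered=True)[1] == pytest.approx(2.0)

    def test_complete_graph_all_zero(self):
        g = nx.complete_graph(6)
        assert all(v == 0 for v in betweenness(g).values())

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        bc = betweenness(g)
        expect = brute_betweenness(g)
        for v in g:
            assert bc[v] == pytest.approx(expect[v], abs=1e-9)

    def test_sum_identity_path_lengths(self):
        # sum of betweenness = sum over pairs of (path length - 1)
        g = nx.gnp_random_graph(12, 0.35, seed=7)
        giant = max(nx.connected_components(g), key=len)
        g = g.subgraph(giant).copy()
        bc = betweenness(g)
        total = sum(
            nx.shortest_path_length(g, s, t) - 1
            for s, t in itertools.combinations(g, 2)
        )
        assert sum(bc.values()) == pytest.approx(total, abs=1e-9)

    def test_conditional_distribution_ring_is_degenerate(self):
        g = nx.cycle_graph(10)
        vals = betweenness_by_degree(g, 2)
        assert len(vals) == 10
        assert np.ptp(vals) == pytest.approx(0.0)
        assert betweenness_by_degree(g, 5).size == 0


class TestSmallWorld:
    def test_triangle(self):
        s = small_world_summary(nx.complete_graph(3))
        assert s.L == pytest.approx(1.0)
        assert s.C == pytest.approx(1.0)

    def test_star_graph_hand_enumeration(self):
        s = small_world_summary(nx.star_graph(4))  # 5 nodes
        assert s.L == pytest.approx(1.6)
        assert s.C == pytest.approx(0.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_L_C_match_brute_force(self, seed):
        g = nx.gnp_random_graph(10, 0.5, seed=seed)
        giant = max(nx.connected_components(g), key=len)
        g = g.subgraph(giant).copy()
        if g.number_of_nodes() < 3 or 2 * g.number_of_edges() <= g.number_of_nodes():
            return
        s = small_world_summary(g)
        L, C = brute_path_length_and_clustering(g)
        assert s.L == pytest.approx(L, abs=1e-9)
        assert s.C == pytest.approx(C, abs=1e-9)

    def test_watts_strogatz_is_small_world(self):
        g = make_ws_graph(500, 10, 0.1, seed=4)
        s = small_world_summary(g)
        assert s.C_ratio > 5
        assert s.L_ratio < 2


class TestCentralitySpace:
    def test_planted_hubs_rank_top(self):
        g, hubs = make_planted_hub_graph(100, 2, seed=0)
        top = top_central_chains(g, 0.05)
        assert set(hubs) <= set(top)

    def test_coincident_chains_zero_distance(self, make_config, model):
        # 25 single-bead "chains" stacked along an axis; top nodes of a
        # clique graph tie and are broken by chain id
        chains = [[(i % 5, i // 5, 2)] for i in range(25)]
        cfg = make_config(10, chains, ["Y"] * 25)
        g = nx.complete_graph(25)
        d = centrality_distance_distribution(cfg, g, top_fraction=0.08)
        assert d.min() >= 0
        assert len(d) == 1  # 2 chains selected -> 1 pair

    def test_small_graph_rejected(self, make_config, model):
        chains = [[(i, 0, 0)] for i in range(5)]
        cfg = make_config(10, chains, ["Y"] * 5)
        with pytest.raises(ValueError, match="20"):
            centrality_distance_distribution(cfg, nx.complete_graph(5))


def _static_traj(chains, seqs, box=14, n_frames=4, step=50):
    from tests.conftest import build_config
    cfg = build_config(box, chains, seqs)
    frames = [Frame(i * step, cfg.positions.copy(), 0.0)
              for i in range(n_frames)]
    return Trajectory(box_side=box, chain_lens=cfg.chain_lens,
                      sequences=cfg.sequences,
                      chain_seq_index=cfg.chain_seq_index, T=50.0, seed=0,
                      frames=frames, local_only=True, equilibrated_from=0)


class TestCentralityTime:
    def test_frozen_trajectory_persistence_one(self, model):
        rng = np.random.default_rng(0)
        chains, seqs = [], []
        taken = set()
        while len(chains) < 30:
            q = tuple(rng.integers(0, 6, size=3))
            if q in taken:
                continue
            taken.add(q)
            chains.append([q])
            seqs.append("Y")
        traj = _static_traj(chains, seqs)
        assert centrality_persistence(traj, lag=1, model=model) == 1.0

    def test_lag_out_of_range(self, model):
        traj = _static_traj([[(0, 0, 0)], [(1, 1, 1)]], ["Y", "Y"])
        with pytest.raises(ValueError, match="lag"):
            centrality_persistence(traj, lag=10, model=model)


class TestStickerLifetime:
    def test_contact_lasting_exactly_seven_frames(self):
        seq = encode_sequence("Y")
        a = np.array([[2, 2, 2]])
        near, far = np.array([[3, 3, 3]]), np.array([[8, 8, 8]])
        frames = []
        # 1 frame apart, 7 frames together, then apart again
        seq_pos = [far] + [near] * 7 + [far, far]
        for i, p in enumerate(seq_pos):
            frames.append(Frame(i * 100, np.concatenate([a, p]), 0.0))
        traj = Trajectory(box_side=14, chain_lens=np.array([1, 1]),
                          sequences=[seq, seq],
                          chain_seq_index=np.array([0, 1]), T=50.0, seed=0,
                          frames=frames, local_only=True, equilibrated_from=0)
        assert sticker_contact_lifetime(traj) == pytest.approx(700.0)


class TestAssociation:
    def test_self_reference_is_one(self, make_config, model):
        chains = [[(2, 2, 2), (3, 2, 2)], [(3, 3, 3), (4, 3, 3)]]
        cfg = make_config(12, chains, ["YG", "YG"])
        res = ratio_of_association(cfg, cfg, model, model)
        assert res.g_a == 1.0

    def test_hand_built_ratio(self, make_config, uniform_model):
        # seq config: focal stickers with 6 sticker and 18 spacer
        # neighbor events; ref config: 8 and 16 -> (6/24)/(8/24) = 0.75
        def ring_config(n_st, n_sp):
            # one central sticker surrounded by n_st stickers + n_sp
            # spacers among its 26 neighbor sites (other chains)
            chains = [[(5, 5, 5)]]
            seqs = ["Y"]
            offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                    for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
            for i, o in enumerate(offs[: n_st + n_sp]):
                chains.append([(5 + o[0], 5 + o[1], 5 + o[2])])
                seqs.append("Y" if i < n_st else "G")
            return chains, seqs

        # focal tallies are summed over *all* stickers; build the
        # counts so the totals match the worked ratio
        c1 = ring_config(3, 9)   # central Y sees 3 st + 9 sp
        c2 = ring_config(4, 8)
        cfg1 = make_config(16, *c1)
        cfg2 = make_config(16, *c2)
        res = ratio_of_association(cfg1, cfg2, uniform_model, uniform_model,
                                   dense_only=False)
        # p_seq counts: every sticker's neighbors (central + ring Ys)
        assert res.p_a_seq < res.p_a_ref
        assert 0 < res.g_a < 1

    def test_translation_invariance(self, make_config, model):
        chains = [[(2, 2, 2), (3, 2, 2)], [(3, 3, 3), (4, 3, 3)],
                  [(1, 3, 2), (1, 4, 3)]]
        cfg = make_config(12, chains, ["YG", "YG", "YY"])
        cfg2 = cfg.copy()
        cfg2.positions[:] = (cfg2.positions + np.array([4, 9, 2])) % 12
        r1 = ratio_of_association(cfg, cfg, model, model, dense_only=False)
        r2 = ratio_of_association(cfg2, cfg2, model, model, dense_only=False)
        assert r1.p_a_seq == pytest.approx(r2.p_a_seq)

    def test_no_stickers_rejected(self, make_config, model):
        cfg = make_config(10, [[(1, 1, 1)]], ["G"])
        with pytest.raises(ValueError, match="sticker"):
            ratio_of_association(cfg, cfg, model, model)


class TestWeibull:
    def test_cdf_closed_form_at_lambda(self):
        lam = 10.0
        assert discrete_weibull_cdf(lam - 1, lam, 1.5) == pytest.approx(
            1 - math.exp(-1)
        )

    def test_exact_cdf_recovered_to_machine_precision(self):
        lam, k = 7.0, 1.3
        sizes = np.arange(1, 40)
        cdf = discrete_weibull_cdf(sizes, lam, k)
        fit = fit_weibull_linearized(sizes, cdf)
        assert fit.lam == pytest.approx(lam, abs=1e-9)
        assert fit.k == pytest.approx(k, abs=1e-9)

    def test_parameter_recovery_from_samples(self):
        s = sample_weibull_clusters(10.0, 1.5, 100_000, seed=3)
        fit = fit_weibull_from_samples(s)
        assert fit.lam == pytest.approx(10.0, rel=0.05)
        assert fit.k == pytest.approx(1.5, rel=0.05)

    def test_all_isolated_stickers_rejected(self, make_config):
        chains = [[(0, 0, 0)], [(5, 5, 5)], [(9, 9, 2)]]
        cfg = make_config(12, chains, ["Y", "Y", "Y"])
        with pytest.raises(ValueError, match="degenerate|fewer"):
            sticker_cluster_weibull([cfg])

    def test_cluster_sizes_brute_force(self, make_config):
        # 3 stickers in a row + 1 isolated: clusters {3, 1}
        chains = [[(2, 2, 2)], [(3, 3, 3)], [(4, 4, 4)], [(9, 9, 9)]]
        cfg = make_config(14, chains, ["Y"] * 4)
        assert sorted(sticker_cluster_sizes(cfg)) == [1, 3]

    def test_per_sticker_probabilities_sum_to_one(self, make_config):
        from sticklat.graphs import sticker_cluster_distribution
        chains = [[(2, 2, 2)], [(3, 3, 3)], [(9, 9, 9)]]
        cfg = make_config(14, chains, ["Y"] * 3)
        dist = sticker_cluster_distribution([cfg])
        assert dist.pmf.sum() == pytest.approx(1.0)
        # 2 of 3 stickers in the pair cluster
        assert dict(zip(dist.sizes, dist.pmf))[2] == pytest.approx(2 / 3)
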