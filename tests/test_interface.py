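"""Radial profiles, tanh interface fits and radial statistics."""

import math

import numpy as np
import pytest

from sticklat.fixtures import make_droplet_config
from sticklat.interface import (
    RadialProfile,
    SHELL_WIDTH,
    asphericity,
    average_profiles,
    chain_property_profile,
    condensate_center,
    crosslinks_per_sticker_profile,
    detect_plateau,
    distinct_chains_per_residue,
    fit_interface,
    interface_width_scaling,
    orientation_profile,
    radial_density_profile,
    shell_site_counts,
    tanh_log_profile,
)


def synthetic_profile(phi_d, phi_D, r_mid, delta, r_max=40.0, noise=None,
                      rng=None):
    r = np.arange(SHELL_WIDTH / 2, r_max, SHELL_WIDTH)
    phi = 10.0 ** tanh_log_profile(r, math.log10(phi_D), math.log10(phi_d),
                                   r_mid, delta)
    if noise is not None:
        phi = phi * np.exp(rng.normal(0.0, noise, size=len(phi)))
    n = len(r)
    edges = np.arange(n + 1) * SHELL_WIDTH
    big = np.full(n, 1e9)  # effectively noise-free weights
    return RadialProfile(edges=edges, value=phi, count=big,
                         se=np.full(n, np.nan))


class TestShells:
    def test_site_prior_conserves_box_volume(self):
        for box in (12, 20):
            prior = shell_site_counts(box, np.array([box / 2 - 0.5] * 3))
            assert prior.sum() == box**3

    def test_density_profile_counts_conserve_beads(self, model):
        cfg, truth = make_droplet_config(24, 5e-3, 0.4, r_mid=6, delta=2,
                                         chain_length=4, seed=0)
        prof = radial_density_profile(cfg, center=truth["center"])
        assert prof.count.sum() == cfg.n_beads
        assert prof.prior.sum() == 24**3

    def test_uniform_ball_flat_then_empty(self, make_config):
        # fill a Chebyshev ball of radius 2 around the center completely
        chains, seqs = [], []
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                for dz in range(-2, 3):
                    chains.append([(8 + dx, 8 + dy, 8 + dz)])
                    seqs.append("G")
        cfg = make_config(17, chains, seqs)
        prof = radial_density_profile(cfg, center=np.array([8., 8., 8.]),
                                      require_single_droplet=False)
        inner = prof.centers < 2.0
        assert np.nanmin(prof.value[inner & (prof.prior > 0)]) == 1.0
        far = prof.centers > 4.0
        assert np.nansum(prof.value[far]) == 0.0


class TestInterfaceFit:
    def test_exact_roundtrip_machine_precision(self):
        prof = synthetic_profile(1e-4, 0.6, 25.0, 6.0)
        fit = fit_interface(prof)
        assert fit.phi_dilute == pytest.approx(1e-4, rel=1e-9)
        assert fit.phi_dense == pytest.approx(0.6, rel=1e-9)
        assert fit.r_mid == pytest.approx(25.0, abs=1e-9)
        assert fit.delta == pytest.approx(6.0, abs=1e-9)

    def test_noisy_roundtrip_within_five_percent(self):
        rng = np.random.default_rng(8)
        prof = synthetic_profile(1e-4, 0.6, 25.0, 6.0,
                                 noise=0.05 * math.log(10), rng=rng)
        fit = fit_interface(prof, weight_by_counts=False)
        assert fit.delta == pytest.approx(6.0, rel=0.05)
        assert fit.r_mid == pytest.approx(25.0, rel=0.05)

    def test_flat_profile_rejected(self):
        prof = synthetic_profile(0.3, 0.31, 25.0, 6.0)
        with pytest.raises(ValueError, match="sigmoidal"):
            fit_interface(prof)

    def test_shift_moves_rmid_not_delta(self):
        f1 = fit_interface(synthetic_profile(1e-4, 0.6, 20.0, 6.0))
        f2 = fit_interface(synthetic_profile(1e-4, 0.6, 27.0, 6.0))
        assert f2.r_mid - f1.r_mid == pytest.approx(7.0, abs=1e-6)
        assert f2.delta == pytest.approx(f1.delta, abs=1e-6)

    def test_planted_droplet_recovery(self):
        cfg, truth = make_droplet_config(64, 1e-4, 0.6, r_mid=25, delta=6,
                                         chain_length=4, seed=3)
        prof = radial_density_profile(cfg, center=truth["center"])
        fit = fit_interface(prof)
        assert fit.delta == pytest.approx(6.0, rel=0.10)
        assert fit.r_mid == pytest.approx(25.0, abs=0.5)


class TestCrosslinks:
    def test_isolated_sticker_zero(self, make_config):
        cfg = make_config(12, [[(3, 3, 3)]], ["Y"])
        total, intra, inter = crosslinks_per_sticker_profile(
            cfg, center=np.array([3., 3., 3.]))
        assert np.nansum(total.value * total.count) == 0.0

    def test_hand_built_triad(self, make_config):
        # focal sticker touches one intra-chain and one inter-chain sticker
        chains = [[(5, 5, 5), (6, 5, 5)], [(5, 6, 5)]]
        cfg = make_config(12, chains, ["YY", "Y"])
        center = np.array([5.0, 5.0, 5.0])
        total, intra, inter = crosslinks_per_sticker_profile(cfg, center=center)
        # focal bead (5,5,5): intra partner (6,5,5) is bonded -> excluded;
        # its crosslinks: inter (5,6,5) only.  (6,5,5)-(5,6,5) also contact.
        got_total = np.nansum(total.value * total.count)
        got_intra = np.nansum(intra.value * intra.count)
        got_inter = np.nansum(inter.value * inter.count)
        assert got_total == got_intra + got_inter
        assert got_inter == 4.0  # 2 inter contacts counted from both sides
        assert got_intra == 0.0

    def test_total_equals_intra_plus_inter_everywhere(self, model):
        cfg, truth = make_droplet_config(24, 5e-3, 0.4, r_mid=6, delta=2,
                                         chain_length=3, seed=2)
        total, intra, inter = crosslinks_per_sticker_profile(
            cfg, center=truth["center"])
        m = total.count > 0
        np.testing.assert_allclose(
            total.value[m] * total.count[m],
            intra.value[m] * intra.count[m] + inter.value[m] * inter.count[m],
        )


class TestChainProperties:
    def test_rod_asphericity_is_prolate_limit(self):
        coords = np.array([[i, 0, 0] for i in range(10)], dtype=float)
        d = coords - coords.mean(axis=0)
        assert asphericity(d.T @ d / len(d)) == pytest.approx(1.0)

    def test_planar_ring_below_cigar_threshold(self):
        t = np.linspace(0, 2 * math.pi, 24, endpoint=False)
        coords = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        d = coords - coords.mean(axis=0)
        assert asphericity(d.T @ d / len(d)) < 0.4

    def test_bead_weighted_shell_split(self, make_config):
        # one 10-bead chain along x straddling two coarse regions
        chain = [(x, 8, 8) for x in range(3, 13)]
        cfg = make_config(16, [chain], ["G" * 10])
        center = np.array([3.0, 8.0, 8.0])
        prof = chain_property_profile(cfg, "rg", center=center)
        # all beads carry the same chain Rg; shell counts sum to 10
        assert prof.count.sum() == 10
        vals = prof.value[prof.count > 0]
        assert np.allclose(vals, vals[0])

    def test_local_extension_exact_distance(self, make_config):
        chain = [(x, 8, 8) for x in range(3, 13)]
        cfg = make_config(16, [chain], ["G" * 10])
        prof = chain_property_profile(cfg, "local_extension",
                                      center=np.array([3.0, 8.0, 8.0]))
        vals = prof.value[prof.count > 0]
        assert np.allclose(vals, 5.0)  # straight chain, |i-j| = 5

    def test_short_chains_skipped_for_extension(self, make_config):
        cfg = make_config(12, [[(2, 2, 2), (3, 2, 2)]], ["GG"])
        with pytest.raises(ValueError, match="eligible"):
            chain_property_profile(cfg, "local_extension",
                                   center=np.array([2.0, 2.0, 2.0]))


class TestDistinctChains:
    def test_worked_example_eight_over_24(self, make_config):
        # 8 chains contribute 24 beads to the shell r in [5, 5.25)
        chains, seqs = [], []
        # place 8 chains of 3 beads each on a sphere of radius ~5 from
        # center: use axis-aligned positions at exact distance 5
        dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                (0, 0, -1), (3, 4, 0), (-3, 4, 0)]
        for d in dirs:
            base = np.array([10, 10, 10]) + np.array(d) * (5 / np.linalg.norm(d))
            base = base.astype(int)
            chains.append([tuple(base), tuple(base + (0, 0, 1) if d[2] == 0
                                              else base + (1, 0, 0)),
                           tuple(base + (0, 1, 0) if d[1] == 0
                                 else base + (1, 1, 0))])
            seqs.append("GGG")
        cfg = make_config(21, chains, seqs)
        prof = distinct_chains_per_residue(cfg, center=np.array([10.] * 3))
        # every populated shell: value = distinct chains / beads in (0, 1]
        m = prof.count > 0
        assert np.all(prof.value[m] > 0) and np.all(prof.value[m] <= 1)
        total_pairs = (prof.value[m] * prof.count[m]).sum()
        assert total_pairs >= 8  # each chain counted once per shell it spans

    def test_single_chain_one_over_m(self, make_config):
        chain = [(8, 8, 8), (9, 8, 8), (9, 9, 8)]
        cfg = make_config(16, [chain], ["GGG"])
        prof = distinct_chains_per_residue(cfg, center=np.array([8.5, 8.2, 8.0]))
        m = prof.count > 0
        # shells holding k beads of the single chain give 1/k
        np.testing.assert_allclose(prof.value[m], 1.0 / prof.count[m])

    def test_all_distinct_chains_gives_one(self, make_config):
        chains = [[(4, 4, 4)], [(12, 4, 4)], [(4, 12, 4)]]
        cfg = make_config(16, chains, ["G"] * 3)
        prof = distinct_chains_per_residue(cfg, center=np.array([8.] * 3))
        m = prof.count > 0
        np.testing.assert_allclose(prof.value[m], 1.0)


class TestOrientation:
    def test_radial_chain_cos2_one(self, make_config):
        chain = [(10, 8, 8), (11, 8, 8), (12, 8, 8)]
        cfg = make_config(16, [chain], ["GGG"])
        prof = orientation_profile(cfg, center=np.array([8., 8., 8.]))
        m = prof.count > 0
        np.testing.assert_allclose(prof.value[m], 1.0)

    def test_tangential_chain_cos2_zero(self, make_config):
        chain = [(12, 8, 8), (12, 9, 8)]
        cfg = make_config(16, [chain], ["GG"])
        prof = orientation_profile(cfg, center=np.array([8., 8., 8.]))
        m = prof.count > 0
        # end-to-end along y, radius along x: nearly perpendicular at
        # both ends (exactly at one end)
        assert np.nanmax(prof.value[m]) < 0.05

    def test_isotropic_ensemble_averages_to_third(self, make_config):
        rng = np.random.default_rng(4)
        chains, seqs = [], []
        taken = set()
        while len(chains) < 400:
            base = rng.integers(1, 30, size=3)
            off = rng.integers(-1, 2, size=3)
            if not off.any():
                continue
            a, b = tuple(base), tuple((base + off) % 31)
            if a in taken or b in taken or a == b:
                continue
            taken.update((a, b))
            chains.append([a, b])
            seqs.append("GG")
        cfg = make_config(31, chains, seqs)
        prof = orientation_profile(cfg, center=np.array([15.] * 3))
        m = prof.count > 0
        mean = float((prof.value[m] * prof.count[m]).sum() / prof.count[m].sum())
        assert mean == pytest.approx(1 / 3, abs=0.04)

    def test_zero_end_to_end_excluded(self, make_config):
        # ring-like chain with identical ends is skipped
        chain = [(8, 8, 8), (9, 8, 8), (9, 9, 8), (8, 9, 8)]
        cfg = make_config(16, [chain], ["GGGG"])
        with pytest.raises(ValueError, match="nonzero"):
            # single chain whose e2e vector is (0,1,0)... use a true ring
            ring_cfg = make_config(
                16, [[(8, 8, 8)] ], ["G"])
            orientation_profile(ring_cfg, center=np.array([4.] * 3))


class TestWidthScaling:
    def test_exact_power_law_recovered(self):
        truth = 0.45
        series = {}
        for N in (50, 100, 200, 400):
            dp = 2.0 * N**truth
            series[N] = [(40.0, dp), (42.0, dp), (44.0, dp), (46.0, dp + 2.0)]
        plateaus, exponent = interface_width_scaling(series)
        assert exponent == pytest.approx(truth, abs=1e-9)
        assert plateaus[100] == pytest.approx(2.0 * 100**truth)

    def test_strictly_increasing_series_rejected(self):
        series = [(40.0, 1.0), (42.0, 3.0), (44.0, 6.0)]
        with pytest.raises(ValueError, match="plateau"):
            detect_plateau(series, slope_threshold=0.1)

    def test_needs_three_lengths(self):
        with pytest.raises(ValueError, match="3"):
            interface_width_scaling({50: [(40.0, 1.0), (41.0, 1.0)]})


def test_average_profiles_pools_densities(model):
    cfg, truth = make_droplet_config(24, 5e-3, 0.4, r_mid=6, delta=2,
                                     chain_length=4, seed=0)
    p1 = radial_density_profile(cfg, center=truth["center"])
    pooled = average_profiles([p1, p1], count_weighted=False)
    m = p1.prior > 0
    np.testing.assert_allclose(pooled.value[m], p1.value[m])
    assert pooled.count.sum() == 2 * cfg.n_beads
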