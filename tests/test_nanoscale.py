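"""Nearest-neighbour statistics, proximity classification, shell profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from papsim.errors import InputError
from papsim.nanoscale import (
    LocalizationSet,
    VoxelMask,
    classify_proximity,
    group_synapses,
    nearest_neighbor_distances,
    nnd_density,
    profile_width,
    shell_vf,
)
from papsim.synth import gen_localizations, gen_masks


class TestNearestNeighbor:
    def test_self_distances_zero(self, rng):
        pts = rng.uniform(0, 1000, (50, 3))
        d = nearest_neighbor_distances(pts, pts)
        np.testing.assert_allclose(d, 0.0)

    def test_empty_channel_rejected(self):
        with pytest.raises(InputError):
            nearest_neighbor_distances(np.zeros((0, 3)), np.ones((5, 3)))

    def test_poisson_nearest_neighbor_law(self, rng):
        # for a uniform Poisson process of intensity lam, P(D > r) =
        # exp(-4/3 pi lam r^3); compare the empirical mean NND with the
        # closed-form mean lam^(-1/3) Gamma(4/3) / (4 pi / 3)^(1/3)
        from scipy.special import gamma

        box = 2000.0
        n = 4000
        lam = n / box**3
        targets = rng.uniform(0, box, (n, 3))
        sources = rng.uniform(300, box - 300, (800, 3))  # avoid edge effects
        d = nearest_neighbor_distances(sources, targets)
        mean_expected = gamma(4.0 / 3.0) / (4.0 / 3.0 * np.pi * lam) ** (
            1.0 / 3.0
        )
        assert d.mean() == pytest.approx(mean_expected, rel=0.05)

    def test_displaced_shell_shifts_density_mode(self):
        near, _ = gen_localizations(glt1_radial_mean=150.0, seed=3)
        far, _ = gen_localizations(glt1_radial_mean=200.0, seed=3)
        d_near = nearest_neighbor_distances(near, near)
        d_far = nearest_neighbor_distances(far, far)
        shift = np.median(d_far) - np.median(d_near)
        assert shift == pytest.approx(50.0, abs=15.0)

    def test_rigid_transform_invariance(self, rng):
        src = rng.uniform(0, 500, (40, 3))
        tgt = rng.uniform(0, 500, (60, 3))
        d0 = nearest_neighbor_distances(src, tgt)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shiftv = np.array([100.0, -50.0, 30.0])
        d1 = nearest_neighbor_distances(src @ rot.T + shiftv, tgt @ rot.T + shiftv)
        np.testing.assert_allclose(np.sort(d0), np.sort(d1), rtol=1e-9)


class TestNndDensity:
    def test_normalisation(self, rng):
        d = rng.exponential(100.0, 500)
        out = nnd_density(d, bin_width=25.0)
        integral = (out["density"] * (out["bin_right"] - out["bin_left"])).sum()
        assert abs(integral - 1.0) < 1e-9

    def test_identical_distances_single_bin(self):
        out = nnd_density(np.full(10, 40.0), bin_width=50.0)
        occupied = out[out["density"] > 0]
        assert len(occupied) == 1
        assert occupied["density"].iloc[0] == pytest.approx(1.0 / 50.0)

    def test_two_group_sem_matches_direct_formula(self, rng):
        d = np.concatenate([rng.exponential(80, 200), rng.exponential(120, 200)])
        groups = np.repeat([0, 1], 200)
        out = nnd_density(d, bin_width=50.0, groups=groups)
        edges = np.append(out["bin_left"].to_numpy(), out["bin_right"].iloc[-1])
        per = np.stack(
            [
                np.histogram(d[groups == g], bins=edges)[0] / (200 * 50.0)
                for g in (0, 1)
            ]
        )
        sem = per.std(axis=0, ddof=1) / np.sqrt(2)
        np.testing.assert_allclose(out["sem"].to_numpy(), sem, rtol=1e-9)

    def test_single_group_sem_absent(self, rng):
        out = nnd_density(
            rng.exponential(80, 100), bin_width=50.0, groups=np.zeros(100)
        )
        assert out["sem"].isna().all()


class TestProximity:
    def test_boundary_cases(self):
        assert classify_proximity(0.0)
        assert classify_proximity(20.0)
        assert not classify_proximity(21.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            classify_proximity(-1.0)

    @given(
        d1=st.floats(min_value=0.0, max_value=100.0),
        d2=st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_distance(self, d1, d2):
        lo, hi = sorted([d1, d2])
        if classify_proximity(hi):
            assert classify_proximity(lo)

    def test_large_pixel_extends_contact_rule(self):
        # one pixel of 30 nm still counts as contact
        assert classify_proximity(25.0, pixel_size=30.0)


class TestProfileWidth:
    def test_rectangular_profile(self):
        prof = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        assert profile_width(prof, pixel_size=10.0) == pytest.approx(30.0)

    def test_gaussian_profile_analytic(self):
        from papsim.optical import FWHM_PER_SIGMA

        pixel = 19.53
        sigma = 80.0
        x = (np.arange(41) - 20) * pixel
        prof = np.exp(-(x**2) / (2 * sigma**2))
        fwhm = profile_width(prof, pixel_size=pixel)
        assert abs(fwhm - FWHM_PER_SIGMA * sigma) <= pixel

    def test_edge_peak_rejected(self):
        with pytest.raises(InputError):
            profile_width(np.array([1.0, 0.5, 0.2]))


class TestShellVf:
    def test_full_mask_unity(self):
        mask, _ = gen_masks(
            [{"center": (600, 600, 600), "radii": 5000.0}], pitch=10.0
        )
        prof = shell_vf(mask, (600, 600, 600))
        np.testing.assert_allclose(prof.vf, 1.0)

    def test_empty_mask_zero(self):
        mask, _ = gen_masks([], pitch=10.0)
        prof = shell_vf(mask, (600, 600, 600))
        np.testing.assert_allclose(prof.vf, 0.0)

    def test_solid_sphere_matches_analytic_intersection(self):
        # 5 nm pitch: voxelised shell VF within 2% of the closed-form
        # sphere-shell intersection fractions
        r_sphere = 250.0
        c = 600.0
        mask, _ = gen_masks(
            [{"center": (c, c, c), "radii": r_sphere}],
            grid_shape=(240, 240, 240),
            pitch=5.0,
        )
        prof = shell_vf(mask, (c, c, c))
        edges = prof.edges
        for k in range(len(edges) - 1):
            inner, outer = edges[k], edges[k + 1]
            vol = lambda r: 4 / 3 * np.pi * min(r, r_sphere) ** 3
            expected = (vol(outer) - vol(inner)) / (
                4 / 3 * np.pi * (outer**3 - inner**3)
            )
            assert prof.vf[k] == pytest.approx(expected, abs=0.02)

    def test_centroid_outside_grid_rejected(self):
        mask, _ = gen_masks([], pitch=10.0)
        with pytest.raises(InputError):
            shell_vf(mask, (1e5, 0.0, 0.0))

    def test_truncated_shells_flagged(self):
        mask, _ = gen_masks([], grid_shape=(40, 40, 40), pitch=10.0)
        prof = shell_vf(mask, (30.0, 200.0, 200.0))
        assert prof.truncated.any()

    def test_surface_area_scale(self):
        # solid sphere of radius 200: total exposed area ~ 4 pi r^2 after
        # the 2/3 face-counting correction (documented estimator, not exact)
        mask, _ = gen_masks(
            [{"center": (600, 600, 600), "radii": 200.0}], pitch=10.0
        )
        prof = shell_vf(mask, (600.0, 600.0, 600.0), max_radius=400.0)
        total = prof.surface_area.sum() * 1e6  # nm^2
        assert total == pytest.approx(4 * np.pi * 200.0**2, rel=0.15)

    def test_hdf5_round_trip(self, tmp_path):
        mask, _ = gen_masks(
            [{"center": (300, 300, 300), "radii": 100.0}],
            grid_shape=(60, 60, 60),
        )
        p = tmp_path / "mask.h5"
        mask.write_hdf5(p)
        back = VoxelMask.read_hdf5(p)
        np.testing.assert_array_equal(back.occupancy, mask.occupancy)
        assert back.pitch == mask.pitch


class TestLocalizationSet:
    def test_csv_round_trip(self, tmp_path):
        locs, _ = gen_localizations(n_synapses=2, seed=1)
        p = tmp_path / "locs.csv"
        locs.write_csv(p)
        back = LocalizationSet.read_csv(p)
        np.testing.assert_allclose(back.points, locs.points)
        np.testing.assert_array_equal(back.channels, locs.channels)

    def test_unknown_channel_rejected(self):
        with pytest.raises(InputError):
            LocalizationSet(np.zeros((2, 3)), np.array(["x", "bassoon"]))

    def test_group_synapses_recovers_count(self):
        locs, truth = gen_localizations(
            n_synapses=4, background_rate=0.0, seed=5
        )
        grouped = group_synapses(locs, eps=120.0, min_samples=5)
        n_found = len(
            set(grouped.synapse_ids[grouped.synapse_ids >= 0])
        )
        assert n_found == truth["n_synapses"]
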