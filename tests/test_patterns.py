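"""Pattern generators, floodfill oracles and region diagnostics."""

import numpy as np
import pytest

from wavegate.patterns import (
    detect_filled_region,
    dilation_fill,
    floodfill_oracle,
    frequency_map,
    interior_mask,
    make_annulus,
    make_band_1d,
    make_boxes_2d,
    make_labyrinth,
    periodic_label,
)


class TestBand1D:
    def test_values(self):
        g = make_band_1d(256, 0.5, (96, 160), band_L=5, flank_width=16)
        assert np.all(g[:16] == 0.5) and np.all(g[-16:] == 0.5)
        assert np.all(g[96:160] == pytest.approx(np.exp(-0.05)))
        assert np.all(g[16:96] == 1.0)

    def test_L_zero_means_no_attenuation(self):
        g = make_band_1d(256, 0.5, (96, 160), band_L=0, flank_width=16)
        assert np.all(g[96:160] == 1.0)

    def test_band_overlapping_flanks_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            make_band_1d(256, 0.5, (4, 60), band_L=1, flank_width=16)


class TestBoxes2D:
    def test_default_wall_value_and_interiors(self):
        pat = make_boxes_2d((64, 64), wall_thickness=6)
        assert np.all(pat.gamma[pat.wall] == 0.1)
        assert np.all(pat.gamma[~pat.wall] == 1.0)
        assert not (pat.left_box & pat.right_box).any()
        assert np.all(pat.gamma[pat.left_box] == 1.0)

    def test_middle_wall_contiguous_without_hole(self):
        pat = make_boxes_2d((64, 64), wall_thickness=6)
        mid = pat.wall[:, 29:35]
        assert mid.all()

    def test_hole_restores_exactly_requested_sites(self):
        t = 6
        intact = make_boxes_2d((64, 64), wall_thickness=t)
        holed = make_boxes_2d((64, 64), wall_thickness=t, hole=(28, 36))
        restored = intact.wall & ~holed.wall
        assert restored.sum() == 8 * t
        assert np.all(holed.gamma[restored] == 1.0)

    def test_hole_outside_middle_wall_rejected(self):
        with pytest.raises(ValueError, match="hole"):
            make_boxes_2d((64, 64), wall_thickness=6, hole=(0, 10))


class TestLabyrinth:
    def test_median_split_without_regularization(self):
        pat = make_labyrinth((64, 64), 2, 6, seed=0, min_feature=0)
        assert pat.go.mean() == pytest.approx(0.5, abs=2 / 64)

    def test_deterministic_per_seed(self):
        a = make_labyrinth((64, 64), 2, 6, seed=3)
        b = make_labyrinth((64, 64), 2, 6, seed=3)
        assert np.array_equal(a.go, b.go)
        assert not np.array_equal(a.go, make_labyrinth((64, 64), 2, 6, seed=4).go)

    def test_default_gamma_mapping(self):
        pat = make_labyrinth((64, 64), 2, 6, seed=0)
        g = pat.to_gamma()
        assert set(np.unique(g)) == {0.01, 1.0}
        assert np.all(g[pat.go] == 1.0)

    def test_band_validation(self):
        with pytest.raises(ValueError, match="band"):
            make_labyrinth((64, 64), 6, 2, seed=0)

    def test_regularization_removes_thin_features(self):
        pat = make_labyrinth((128, 128), 3, 6, threshold_quantile=0.62, seed=0,
                             min_feature=2)
        # no isolated go sites: every go site has a go 4-neighbor
        go = pat.go
        neigh = sum(np.roll(go, s, axis=a) for a in (0, 1) for s in (1, -1))
        assert np.all(neigh[go] >= 1)


class TestAnnulus:
    def test_rotation_is_2pi_periodic(self):
        a = make_annulus((96, 96), (12, 18), rotation_angle=0.7)
        b = make_annulus((96, 96), (12, 18), rotation_angle=0.7 + 2 * np.pi)
        assert np.allclose(a, b)

    def test_border_taper_endpoints_exact(self):
        g = make_annulus((96, 96), (12, 18), wall_gamma=0.1, taper_width=8)
        assert g[0, 48] == pytest.approx(0.1)  # lattice edge at the wall value
        assert g[9, 48] == pytest.approx(1.0)  # just inside the taper

    def test_gap_is_a_quarter_turn(self):
        g = make_annulus((128, 128), (20, 28), wall_gamma=0.1, taper_width=6)
        # sample the wall ring: fraction of angles left open ~ 1/4
        yy, xx = np.indices((128, 128))
        r = np.hypot(yy - 63.5, xx - 63.5)
        ring = (r > 22) & (r < 26)
        open_frac = np.mean(g[ring] > 0.9)
        assert open_frac == pytest.approx(0.25, abs=0.06)


class TestFloodfill:
    def test_connected_region_fully_filled(self):
        go = np.zeros((16, 16), bool)
        go[2:10, 3:12] = True
        filled = floodfill_oracle(go, (5, 5))
        assert np.array_equal(filled, go)

    def test_disjoint_blob_not_reached(self):
        go = np.zeros((16, 16), bool)
        go[1:4, 1:4] = True
        go[10:14, 10:14] = True
        filled = floodfill_oracle(go, (2, 2))
        assert filled[1:4, 1:4].all() and not filled[10:14, 10:14].any()

    def test_wraps_periodically(self):
        go = np.zeros((8, 8), bool)
        go[0, :] = True
        go[-1, :] = True
        assert floodfill_oracle(go, (0, 0))[-1, 0]

    def test_seed_in_nogo_rejected(self):
        with pytest.raises(ValueError, match="no-go"):
            floodfill_oracle(np.zeros((4, 4), bool), (0, 0))

    @pytest.mark.parametrize("seed", range(20))
    def test_bfs_equals_morphological_dilation(self, seed):
        rng = np.random.default_rng(seed)
        go = rng.random((24, 24)) < 0.55
        sites = np.argwhere(go)
        site = tuple(sites[rng.integers(len(sites))])
        assert np.array_equal(floodfill_oracle(go, site), dilation_fill(go, site))

    def test_periodic_label_counts_wrapped_component_once(self):
        go = np.zeros((8, 8), bool)
        go[:2, 0] = True
        go[-2:, 0] = True
        labels, n = periodic_label(go)
        assert n == 1
        go[4, 4] = True
        _, n2 = periodic_label(go)
        assert n2 == 2


class TestDetection:
    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        amp = rng.random((32, 32))
        ref = np.ones((32, 32), bool)
        lo = detect_filled_region(amp, 0.2, ref)
        hi = detect_filled_region(amp, 0.8, ref)
        assert np.all(hi <= lo)

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            detect_filled_region(np.zeros((8, 8)), 0.5, np.ones((8, 8), bool))

    def test_interior_mask_strips_margin(self):
        m = np.zeros((16, 16), bool)
        m[4:12, 4:12] = True
        inner = interior_mask(m, 2)
        assert inner[8, 8] and not inner[4, 4]
        assert inner.sum() == 16


class TestFrequencyMap:
    def test_uniform_rotation_recovered(self):
        rng = np.random.default_rng(1)
        Zb = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        omega = 0.01
        lag = 200
        Za = np.exp(1j * omega * lag) * Zb
        fm = frequency_map(Za, Zb, lag=lag)
        assert np.allclose(fm, omega)

    def test_zero_sites_masked_as_nan(self):
        Za = np.array([[1.0 + 0j, 0.0]])
        Zb = np.array([[1.0 + 0j, 1.0]])
        fm = frequency_map(Za, Zb, lag=10)
        assert np.isnan(fm[0, 1]) and fm[0, 0] == 0.0

    def test_lag_validation(self):
        with pytest.raises(ValueError):
            frequency_map(np.ones((2, 2)), np.ones((2, 2)), lag=0)
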