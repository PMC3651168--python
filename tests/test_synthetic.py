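"""Ground-truth generator: class shares, constraints, detection physics."""

import numpy as np
import pandas as pd
import pytest

from habtex.raster import Raster
from habtex.synthetic import (DISC_AREA_HA, GRASSLAND, SAVANNA, WOODLAND,
                              TruthConfig, generate_habitat_map,
                              place_sample_points, render_reflectance,
                              simulate_bird_surveys, simulate_richness)
from habtex.texture import focal_variance


class TestHabitatMap:
    def test_class_shares_near_requested(self):
        hm = generate_habitat_map((2000, 2000), 10.0, (0.25, 0.35, 0.40),
                                  300.0, seed=5)
        lab = np.asarray(hm.values)
        for k, f in zip((GRASSLAND, SAVANNA, WOODLAND), (0.25, 0.35, 0.40)):
            assert abs((lab == k).mean() - f) < 0.03

    def test_degenerate_fractions_single_class(self):
        hm = generate_habitat_map((500, 500), 10.0, (1.0, 0.0, 0.0), 100.0,
                                  seed=1)
        assert np.all(np.asarray(hm.values) == GRASSLAND)

    def test_deterministic_given_seed(self):
        a = generate_habitat_map(seed=3)
        b = generate_habitat_map(seed=3)
        assert np.array_equal(a.values, b.values)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            generate_habitat_map((20, 20), 10.0, (0.3, 0.3, 0.4), 50.0)

    def test_shares_converge_with_extent(self):
        devs = []
        for ext in (300, 1500):
            hm = generate_habitat_map((ext, ext), 10.0, (0.25, 0.35, 0.40),
                                      120.0, seed=8)
            lab = np.asarray(hm.values)
            devs.append(max(abs((lab == k).mean() - f) for k, f in
                            zip(range(3), (0.25, 0.35, 0.40))))
        assert devs[1] <= devs[0] + 1e-9


class TestReflectance:
    def one_class_map(self, cls, ext=300):
        vals = np.full((ext // 10, ext // 10), cls, dtype=np.int16)
        return Raster(vals, 0.0, float(ext), 10.0)

    def test_savanna_has_highest_fine_variance(self):
        cfg = TruthConfig(extent_m=(300.0, 300.0))
        means = {}
        for cls in (GRASSLAND, SAVANNA, WOODLAND):
            img = render_reflectance(self.one_class_map(cls), "fine", cfg,
                                     seed=4)
            means[cls] = focal_variance(img, 3).band(0).mean()
        assert means[SAVANNA] > means[GRASSLAND]
        assert means[SAVANNA] > means[WOODLAND]

    def test_no_crowns_no_noise_constant(self):
        cfg = TruthConfig()
        for p in cfg.reflectance.values():
            p.noise_sd = 0.0
            p.crown_density = 0.0
        img = render_reflectance(self.one_class_map(GRASSLAND), "fine",
                                 cfg, seed=0)
        assert np.ptp(img.band(0)) == 0.0

    def test_deterministic_given_seed(self):
        cfg = TruthConfig()
        hm = self.one_class_map(SAVANNA)
        a = render_reflectance(hm, "fine", cfg, seed=9)
        b = render_reflectance(hm, "fine", cfg, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_unknown_label_rejected(self):
        cfg = TruthConfig()
        bad = Raster(np.full((10, 10), 7, dtype=np.int16), 0.0, 100.0,
                     10.0)
        with pytest.raises(ValueError):
            render_reflectance(bad, "fine", cfg)

    def test_coarse_two_bands_ndvi_ordering(self):
        cfg = TruthConfig()
        g = render_reflectance(self.one_class_map(GRASSLAND), "coarse",
                               cfg, seed=2)
        w = render_reflectance(self.one_class_map(WOODLAND), "coarse",
                               cfg, seed=2)
        assert g.n_bands == 2
        ndvi = lambda r: ((r.values[1] - r.values[0])
                          / (r.values[1] + r.values[0])).mean()
        assert ndvi(w) > ndvi(g)


class TestSamplePoints:
    def test_unique_feasible_location_returned(self):
        vals = np.full((5, 5), GRASSLAND, dtype=np.int16)
        hm = Raster(vals, 0.0, 50.0, 10.0)
        excl = np.ones((5, 5))
        excl[2, 2] = 0.0  # only the center pixel is off the mask
        em = Raster(excl, 0.0, 50.0, 10.0)
        pts = place_sample_points(hm, 200, 1.0, em, 5.0, 0.0, seed=3)
        assert len(pts) == 1
        assert pts.iloc[0]["x"] == 25.0 and pts.iloc[0]["y"] == 25.0

    def test_unsatisfiable_constraints_empty_with_warning(self):
        vals = np.full((5, 5), GRASSLAND, dtype=np.int16)
        hm = Raster(vals, 0.0, 50.0, 10.0)
        em = Raster(np.ones((5, 5)), 0.0, 50.0, 10.0)
        with pytest.warns(UserWarning):
            pts = place_sample_points(hm, 50, 1.0, em, 10.0, 0.0, seed=3)
        assert len(pts) == 0

    def test_all_constraints_hold_by_bruteforce(self):
        hm = generate_habitat_map((1500, 1500), 10.0, (0.25, 0.35, 0.40),
                                  400.0, seed=6)
        pts = place_sample_points(hm, 300, 150.0, None, 0.0, 60.0, seed=7)
        assert len(pts) >= 10
        xy = pts[["x", "y"]].to_numpy()
        # exhaustive pairwise separation check
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                assert np.hypot(*(xy[i] - xy[j])) >= 150.0 - 1e-9
        # exhaustive other-class pixel-center distance check
        lab = np.asarray(hm.values)
        rows, cols = np.indices(lab.shape)
        px = (cols + 0.5) * 10.0
        py = 1500.0 - (rows + 0.5) * 10.0
        for rec in pts.itertuples(index=False):
            other = lab != rec.habitat
            d = np.hypot(px[other] - rec.x, py[other] - rec.y)
            assert d.min() >= 60.0 - 1e-9

    def test_habitat_label_matches_map(self):
        hm = generate_habitat_map((1000, 1000), 10.0, (0.25, 0.35, 0.40),
                                  300.0, seed=2)
        pts = place_sample_points(hm, 100, 100.0, None, 0.0, 30.0, seed=1)
        lab = np.asarray(hm.values)
        for rec in pts.itertuples(index=False):
            r, c = hm.xy_to_rowcol(rec.x, rec.y)
            assert lab[r, c] == rec.habitat


class TestBirdSurveys:
    def points(self, n=200):
        return pd.DataFrame({"id": [f"p{i}" for i in range(n)],
                             "x": 0.0, "y": 0.0, "habitat": GRASSLAND})

    def test_detected_fraction_matches_disc_average(self):
        """Uniform-in-disc placement + half-normal detection: the expected
        detected fraction is 2 sigma^2 (1 - e^{-w^2/2s^2}) / w^2."""
        cfg = TruthConfig(density_beta=(5.0, 0.0),
                          detection_sigma=(40.0,))
        pts = self.points(300)
        obs = simulate_bird_surveys(pts, np.zeros(300), cfg, years=1,
                                    visits=(4,), seed=21)
        expected_birds = 5.0 * DISC_AREA_HA * 300 * 4
        frac = len(obs) / expected_birds
        p_true = 2 * 40 ** 2 * (1 - np.exp(-100 ** 2 / (2 * 40 ** 2))) \
            / 100 ** 2
        assert frac == pytest.approx(p_true, abs=0.02)

    def test_huge_sigma_detects_everything(self):
        cfg = TruthConfig(density_beta=(5.0, 0.0),
                          detection_sigma=(1e6,))
        pts = self.points(100)
        obs = simulate_bird_surveys(pts, np.zeros(100), cfg, years=1,
                                    visits=(2,), seed=22)
        expected = 5.0 * DISC_AREA_HA * 100 * 2
        assert len(obs) / expected == pytest.approx(1.0, abs=0.05)

    def test_doubling_density_doubles_detections(self):
        pts = self.points(400)
        n = []
        for lam in (3.0, 6.0):
            cfg = TruthConfig(density_beta=(lam, 0.0),
                              detection_sigma=(40.0,))
            obs = simulate_bird_surveys(pts, np.zeros(400), cfg, years=1,
                                        visits=(3,), seed=23)
            n.append(len(obs))
        assert n[1] / n[0] == pytest.approx(2.0, abs=0.1)

    def test_distances_within_truncation(self):
        cfg = TruthConfig(density_beta=(4.0, 0.0))
        obs = simulate_bird_surveys(self.points(50), np.zeros(50), cfg,
                                    seed=2)
        assert obs["distance_m"].between(0, 100).all()

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            TruthConfig(detection_sigma=(0.0,))


class TestRichness:
    def test_noise_free_intercept(self):
        pts = pd.DataFrame({"id": ["p"]})
        r = simulate_richness(pts, np.array([0.0]),
                              (7.08, 0.40, -0.0021), 0.0, seed=0)
        assert r[0] == 7

    def test_constant_coefficients(self):
        pts = pd.DataFrame({"id": list("abcd")})
        r = simulate_richness(pts, np.zeros(4), (12.3, 0.0, 0.0), 0.0,
                              seed=0)
        assert np.all(r == 12)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_richness(pd.DataFrame({"id": ["p"]}), np.zeros(1),
                              noise_sd=-1.0)

    def test_deterministic_given_seed(self):
        pts = pd.DataFrame({"id": [f"p{i}" for i in range(30)]})
        x = np.linspace(0, 90, 30)
        a = simulate_richness(pts, x, seed=5)
        b = simulate_richness(pts, x, seed=5)
        assert np.array_equal(a, b)
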