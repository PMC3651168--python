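"""Distance-sampling detection functions, AIC selection, densities."""

import numpy as np
import pandas as pd
import pytest

from habtex.distance import (DensityEstimate, DetectionModel,
                             average_detection_probability, fit_detection,
                             fit_model_set, multi_year_density,
                             point_densities, select_detection_model)

from conftest import simulate_halfnormal_radii


def halfnormal_model(sigma, w=100.0):
    return DetectionModel("half-normal", "none", 0, (sigma,), (), w,
                          0.0, 0.0, 1.0)


def analytic_p_halfnormal(sigma, w):
    return 2 * sigma ** 2 * (1 - np.exp(-w ** 2 / (2 * sigma ** 2))) / w ** 2


class TestAverageDetectability:
    def test_halfnormal_sigma40_closed_form(self):
        m = halfnormal_model(40.0)
        p = average_detection_probability(m)
        assert p == pytest.approx(analytic_p_halfnormal(40.0, 100.0),
                                  abs=1e-6)
        assert p == pytest.approx(0.30594, abs=1e-4)

    def test_huge_sigma_approaches_one(self):
        assert average_detection_probability(halfnormal_model(1e6)) == \
            pytest.approx(1.0, abs=1e-6)

    def test_uniform_key_exactly_one(self):
        m = fit_detection(np.linspace(5, 95, 30), "uniform")
        assert m.p_det == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_sigma(self):
        ps = [average_detection_probability(halfnormal_model(s))
              for s in (10, 20, 40, 80, 160)]
        assert np.all(np.diff(ps) > 0)


class TestFitting:
    def test_uniform_no_terms_flat(self):
        m = fit_detection(np.linspace(1, 99, 50), "uniform", "none", 0)
        assert m.n_params == 0
        assert np.allclose(m.g(np.linspace(0, 100, 7)), 1.0)

    def test_sigma_recovery_within_ten_percent(self, rng):
        sig_hats = []
        for _ in range(20):
            r = simulate_halfnormal_radii(500, 40.0, 100.0, rng)
            sig_hats.append(fit_detection(r, "half-normal").key_params[0])
        assert abs(np.median(sig_hats) - 40.0) / 40.0 < 0.10

    def test_aic_is_definitional(self, rng):
        r = simulate_halfnormal_radii(200, 40.0, 100.0, rng)
        for key, adj, k in [("half-normal", "none", 0),
                            ("hazard-rate", "cosine", 1)]:
            m = fit_detection(r, key, adj, k)
            assert m.aic == pytest.approx(2 * m.n_params - 2 * m.loglik,
                                          abs=1e-9)

    def test_loglik_at_optimum_beats_truth(self, rng):
        r = simulate_halfnormal_radii(300, 40.0, 100.0, rng)
        m = fit_detection(r, "half-normal")
        mu_true = 40.0 ** 2 * (1 - np.exp(-100.0 ** 2 / (2 * 40.0 ** 2)))
        ll_true = float(np.sum(np.log(r) - r * r / (2 * 40.0 ** 2))
                        - r.size * np.log(mu_true))
        assert m.loglik >= ll_true - 1e-6

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_detection(np.array([-1.0, 5.0] * 10), "half-normal")
        with pytest.raises(ValueError):
            fit_detection(np.array([5.0, 150.0] * 10), "half-normal")


class TestSelection:
    def make(self, aic, k, key="half-normal"):
        return DetectionModel(key, "none", 0, tuple([30.0] * k), (), 100.0,
                              -aic / 2, aic, 0.5)

    def test_argmin_aic(self):
        models = [self.make(100.2, 1), self.make(99.1, 1),
                  self.make(105.0, 1)]
        assert select_detection_model(models) is models[1]

    def test_tie_prefers_fewer_parameters(self):
        m2 = self.make(100.0, 1)
        m3 = DetectionModel("hazard-rate", "none", 0, (30.0, 2.0), (),
                            100.0, -50.0 + 1.0, 100.0, 0.5)
        assert select_detection_model([m3, m2]) is m2

    def test_nonconverged_excluded(self):
        good = self.make(120.0, 1)
        bad = self.make(90.0, 1)
        bad.converged = False
        assert select_detection_model([bad, good]) is good
        bad2 = self.make(90.0, 1)
        bad2.converged = False
        with pytest.raises(RuntimeError):
            select_detection_model([bad2])

    def test_sweep_matches_bruteforce_refit(self, rng):
        """The packaged sweep equals independently re-fitting all six
        pairs at every term count and taking the AIC argmin."""
        r = simulate_halfnormal_radii(300, 40.0, 100.0, rng)
        sweep = select_detection_model(fit_model_set(r, max_terms=1))
        brute = []
        for key, adj in [("half-normal", "cosine"),
                         ("half-normal", "hermite-polynomial"),
                         ("uniform", "cosine"),
                         ("uniform", "simple-polynomial"),
                         ("hazard-rate", "cosine"),
                         ("hazard-rate", "simple-polynomial")]:
            for n_terms in (0, 1):
                try:
                    m = fit_detection(r, key, adj, n_terms)
                except Exception:
                    continue
                if m.converged:
                    brute.append(m)
        best_brute = min(brute, key=lambda m: m.aic)
        assert sweep.aic == pytest.approx(best_brute.aic, abs=1e-6)


class TestDensities:
    def test_hand_density_arithmetic(self):
        m = halfnormal_model(40.0)
        m.p_det = 1.0
        obs = pd.DataFrame({"point_id": ["p1"] * 5, "year": [2007] * 5,
                            "visit": 1, "species": "SP1",
                            "distance_m": 10.0})
        pts = pd.DataFrame({"id": ["p1"]})
        est = point_densities(obs, pts, m, visits=1, species="SP1",
                              year=2007)[0]
        assert est.density == pytest.approx(5 / (np.pi * 1.0), abs=1e-3)

    def test_zero_detections_zero_density(self):
        m = halfnormal_model(40.0)
        est = point_densities(pd.DataFrame(columns=["point_id", "year",
                                                    "visit", "species",
                                                    "distance_m"]),
                              pd.DataFrame({"id": ["p1"]}), m, 1, "SP1",
                              2007)[0]
        assert est.density == 0.0

    def test_halving_p_doubles_density(self):
        obs = pd.DataFrame({"point_id": ["p1"] * 4, "year": [2007] * 4,
                            "visit": 1, "species": "SP1",
                            "distance_m": 20.0})
        pts = pd.DataFrame({"id": ["p1"]})
        m1, m2 = halfnormal_model(40.0), halfnormal_model(40.0)
        m1.p_det, m2.p_det = 0.5, 0.25
        d1 = point_densities(obs, pts, m1, 1, "SP1", 2007)[0].density
        d2 = point_densities(obs, pts, m2, 1, "SP1", 2007)[0].density
        assert d2 == pytest.approx(2 * d1)

    def test_multi_year_mean(self):
        def est(pid, year, d):
            return DensityEstimate(pid, year, "SP1", d, 1, 0.5)
        out = multi_year_density([[est("a", 1, 2.0), est("b", 1, 5.0)],
                                  [est("a", 2, 4.0)],
                                  [est("a", 3, 6.0)]])
        by = out.set_index("point_id")["density"]
        assert by["a"] == pytest.approx(4.0)
        assert by["b"] == pytest.approx(5.0)
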