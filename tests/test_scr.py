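import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rollscr as rs
from rollscr.errors import EstimationError, ParameterError

from conftest import random_small_instance
from oracles import brute_force_negloglik


def _single_trap():
    return rs.TrapArray([rs.Detector("S01", 0.0, 0.0)])


class TestBuildMask:
    def test_single_trap_small_mask_by_hand(self):
        mask = rs.build_mask(_single_trap(), buffer=1000.0, spacing=1000.0)
        assert mask.M == 4  # ceil(2000/1000)^2
        assert mask.cell_area == pytest.approx(1.0)
        np.testing.assert_allclose(
            sorted(map(tuple, mask.points)),
            [(-500.0, -500.0), (-500.0, 500.0), (500.0, -500.0), (500.0, 500.0)],
        )

    def test_doubling_spacing_quarters_point_count(self, paper_traps):
        fine = rs.build_mask(paper_traps, buffer=10_000.0, spacing=500.0)
        coarse = rs.build_mask(paper_traps, buffer=10_000.0, spacing=1000.0)
        nx_f = math.ceil(26_000 / 500)
        # quartering up to one extra row/column of edge cells
        assert fine.M / 4 <= coarse.M <= (nx_f / 2 + 1) * (28_000 / 1000 + 1)
        assert abs(coarse.M * 4 - fine.M) <= nx_f + 28_000 / 500 + 4

    def test_every_trap_near_a_mask_point(self, paper_traps):
        mask = rs.build_mask(paper_traps, buffer=30_000.0, spacing=300.0)
        d2 = (
            (paper_traps.coords()[:, None, :] - mask.points[None, :, :]) ** 2
        ).sum(-1)
        assert np.sqrt(d2.min(axis=1)).max() <= 300.0 * math.sqrt(2) / 2 + 1e-9

    def test_bad_arguments(self, paper_traps):
        with pytest.raises(ParameterError):
            rs.build_mask(paper_traps, buffer=-1.0)
        with pytest.warns(UserWarning, match="coarse"):
            rs.build_mask(paper_traps, buffer=1000.0, spacing=5000.0)


class TestHalfnormal:
    def test_definition_points(self):
        assert rs.halfnormal_p(0.0, 0.07, 3600.0) == pytest.approx(0.07)
        half_height = 3600.0 * math.sqrt(2 * math.log(2))
        assert rs.halfnormal_p(half_height, 0.07, 3600.0) == pytest.approx(0.035)
        assert rs.halfnormal_p(3600.0, 0.06, 3600.0) == pytest.approx(
            0.06 * math.exp(-0.5)
        )

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            rs.halfnormal_p(10.0, 0.05, 0.0)

    @given(
        st.floats(0, 50_000),
        st.floats(1, 49_999),
        st.floats(0.001, 0.99),
        st.floats(100.0, 10_000.0),
    )
    def test_monotone_nonincreasing_in_distance(self, d, delta, g0, sigma):
        assert rs.halfnormal_p(d + delta, g0, sigma) <= rs.halfnormal_p(d, g0, sigma)


class TestPdot:
    def test_g0_zero_limit(self):
        assert rs.pdot((0.0, 0.0), _single_trap(), 0.0, 1000.0, 90) == 0.0

    def test_closed_form_one_trap(self):
        assert rs.pdot((0.0, 0.0), _single_trap(), 0.05, 1000.0, 2) == pytest.approx(
            1 - 0.95**2
        )

    def test_increasing_in_T(self, paper_traps):
        s = (20_000.0, 20_000.0)  # far enough that detection never saturates
        vals = [rs.pdot(s, paper_traps, 0.06, 3600.0, T) for T in (1, 30, 90, 180)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    def test_matches_monte_carlo_detection_frequency(self):
        # frequency of >= 1 detection from the generator at a fixed centre
        traps = rs.TrapArray(
            [rs.Detector("S01", 0.0, 0.0), rs.Detector("S02", 4000.0, 0.0)]
        )
        T, n_rep = 30, 3000
        s = (1500.0, 1000.0)
        scn = rs.SimScenario(
            D_true=0.02, g0_true=0.06, sigma_true=3600.0, sex_ratio_male=1.0,
            total_days=T, region=(-5000.0, -5000.0, 9000.0, 5000.0), seed=17,
        )
        pop = rs.Population([(f"i{j}", "male", s) for j in range(n_rep)])
        rec = rs.simulate_detections(pop, traps, scn)
        detected = len({r.individual for r in rec.records})
        p = rs.pdot(s, traps, 0.06, 3600.0, T)
        se = math.sqrt(p * (1 - p) / n_rep)
        assert abs(detected / n_rep - p) < 3 * se


class TestCollapseHistories:
    @pytest.fixture()
    def records(self):
        traps = rs.TrapArray(
            [rs.Detector("S01", 0, 0), rs.Detector("S02", 2000, 0)]
        )
        recs = [
            rs.DetectionRecord("A", "male", "S01", 5),
            rs.DetectionRecord("A", "male", "S01", 6),
            rs.DetectionRecord("A", "male", "S02", 7),
            rs.DetectionRecord("B", "female", "S01", 8),
            rs.DetectionRecord("C", "male", "S02", 200),
        ]
        return rs.DetectionRecordSet.from_records(recs, traps, 365)

    def test_counting_example(self, records):
        hist = rs.collapse_histories(records, (1, 90), "male")
        assert hist.n == 1 and hist.T == 90
        np.testing.assert_array_equal(hist.counts, [[2.0, 1.0]])

    def test_all_records_outside_window(self, records):
        hist = rs.collapse_histories(records, (300, 365), "male")
        assert hist.n == 0

    def test_sex_filter(self, records):
        assert rs.collapse_histories(records, (1, 90), "female").n == 1
        assert rs.collapse_histories(records, (1, 365), "all").n == 3

    def test_invalid_window(self, records):
        with pytest.raises(ParameterError):
            rs.collapse_histories(records, (90, 1), "male")
        with pytest.raises(ParameterError):
            rs.collapse_histories(records, (1, 400), "male")

    def test_consecutive_windows_differ_by_edge_days(self, year_records):
        h1 = rs.collapse_histories(year_records, (1, 90), "male")
        h2 = rs.collapse_histories(year_records, (2, 91), "male")
        edge = [
            r for r in year_records.records
            if r.sex == "male" and r.day in (1, 91)
        ]
        # total detection counts reconcile through the two edge days
        day1 = sum(1 for r in edge if r.day == 1)
        day91 = sum(1 for r in edge if r.day == 91)
        assert h2.n_detections == h1.n_detections - day1 + day91


class TestNegloglik:
    def test_hand_computed_single_point_case(self):
        traps = _single_trap()
        mask = rs.HabitatMask(points=np.array([[0.0, 0.0]]), spacing=1000.0, buffer=1.0)
        hist = rs.SessionHistories(["A"], np.array([[1.0]]), T=1, K=1)
        theta = np.array([math.log(1.0 / mask.cell_area), 0.0, math.log(500.0)])
        # D*a = 1, g0 = 0.5, one detection in one occasion at d = 0:
        # log L = log(0.5) - 0.5
        assert -rs.negloglik(theta, hist, traps, mask) == pytest.approx(
            -0.5 + math.log(0.5), abs=1e-12
        )

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            theta, hist, traps, mask = random_small_instance(rng)
            fast = rs.negloglik(theta, hist, traps, mask)
            slow = brute_force_negloglik(
                theta, hist.counts, hist.T, traps.coords(), mask.points,
                mask.cell_area,
            )
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_quadrature_invariance_under_point_duplication(self):
        rng = np.random.default_rng(5)
        theta, hist, traps, mask = random_small_instance(rng)
        doubled = rs.HabitatMask(
            points=np.vstack([mask.points, mask.points]),
            spacing=mask.spacing / math.sqrt(2),  # halves the cell area
            buffer=mask.buffer,
        )
        assert rs.negloglik(theta, hist, traps, doubled) == pytest.approx(
            rs.negloglik(theta, hist, traps, mask), rel=1e-12
        )

    def test_empty_mask_rejected(self):
        traps = _single_trap()
        mask = rs.HabitatMask(points=np.empty((0, 2)), spacing=100.0, buffer=1.0)
        hist = rs.SessionHistories(["A"], np.array([[1.0]]), T=1, K=1)
        with pytest.raises(EstimationError):
            rs.negloglik(np.zeros(3), hist, traps, mask)


class TestFitScr:
    def test_matches_dense_grid_search_on_tiny_instance(self):
        # K=3 traps, coarse mask: the link-scale optimum from the optimizer
        # must beat / match a dense grid search within the grid resolution
        traps = rs.TrapArray(
            [rs.Detector("A", 0, 0), rs.Detector("B", 1500, 0), rs.Detector("C", 0, 1500)]
        )
        mask = rs.build_mask(traps, buffer=4000.0, spacing=1000.0)
        rng = np.random.default_rng(8)
        scn = rs.SimScenario(
            D_true=2.0, g0_true=0.2, sigma_true=1500.0, sex_ratio_male=1.0,
            total_days=20, region=(-4000, -4000, 5500, 5500), seed=8,
        )
        pop = rs.simulate_population(scn)
        recs = rs.simulate_detections(pop, traps, scn)
        hist = rs.collapse_histories(recs, (1, 20), "male")
        fit = rs.fit_scr(hist, traps, mask)

        grids = [
            np.linspace(fit.link_estimates[i] - 1.0, fit.link_estimates[i] + 1.0, 21)
            for i in range(3)
        ]
        from rollscr.scr import _LikelihoodCache

        cache = _LikelihoodCache(hist, traps, mask)
        best = min(
            (cache.neg_loglik(np.array([a, b, c])), (a, b, c))
            for a in grids[0] for b in grids[1] for c in grids[2]
        )
        assert -fit.logLik <= best[0] + 1e-9
        step = grids[0][1] - grids[0][0]
        assert np.abs(np.array(best[1]) - fit.link_estimates).max() <= step + 1e-12

    def test_sigma_unidentifiable_without_spatial_recaptures(self):
        traps = rs.TrapArray([rs.Detector("A", 0, 0), rs.Detector("B", 2000, 0)])
        mask = rs.build_mask(traps, buffer=2000.0, spacing=1000.0)
        hist = rs.SessionHistories(
            ["x", "y"], np.array([[3.0, 0.0], [0.0, 2.0]]), T=10, K=2
        )
        with pytest.raises(EstimationError, match="sigma unidentifiable"):
            rs.fit_scr(hist, traps, mask)

    def test_no_detections_rejected(self):
        traps = _single_trap()
        mask = rs.build_mask(traps, buffer=2000.0, spacing=1000.0)
        hist = rs.SessionHistories([], np.zeros((0, 1)), T=10, K=1)
        with pytest.raises(EstimationError, match="no detections"):
            rs.fit_scr(hist, traps, mask)

    def test_ci_brackets_estimate(self, year_records, paper_traps, coarse_mask):
        hist = rs.collapse_histories(year_records, (1, 90), "male")
        fit = rs.fit_scr(hist, paper_traps, coarse_mask)
        for name, value in (
            ("D", fit.params.D), ("g0", fit.params.g0), ("sigma", fit.params.sigma)
        ):
            lo, hi = fit.ci95[name]
            assert lo < value < hi

    def test_buffer_and_spacing_sufficiency(self, year_records, paper_traps):
        # D-hat is insensitive to buffer 15 -> 30 km and spacing 600 -> 300 m
        hist = rs.collapse_histories(year_records, (1, 90), "male")

        def fit_d(buffer, spacing):
            mask = rs.build_mask(paper_traps, buffer=buffer, spacing=spacing)
            return rs.fit_scr(hist, paper_traps, mask, compute_ci=False).params.D

        d_b15 = fit_d(15_000.0, 1000.0)
        d_b30 = fit_d(30_000.0, 1000.0)
        assert abs(d_b30 - d_b15) / d_b15 < 0.01
        d_s600 = fit_d(15_000.0, 600.0)
        d_s300 = fit_d(15_000.0, 300.0)
        assert abs(d_s300 - d_s600) / d_s600 < 0.01


class TestDensityScale:
    def test_per_100km2_conversion(self, year_records, paper_traps, coarse_mask):
        hist = rs.collapse_histories(year_records, (1, 90), "male")
        fit = rs.fit_scr(hist, paper_traps, coarse_mask)
        est, lo, hi = rs.density_per_100km2(fit)
        assert est == fit.params.D * 100.0
        assert lo == fit.ci95["D"][0] * 100.0 and hi == fit.ci95["D"][1] * 100.0
        assert lo < est < hi
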