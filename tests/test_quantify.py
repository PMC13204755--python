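"""Threshold sweep/selection, grid density, and log-concentration calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from blinkcount import (
    FilterParams,
    GridSpec,
    ImageStack,
    MovieRecord,
    SweepResult,
    compare_methods,
    fit_log_linear,
    grid_density,
    select_threshold,
    sweep_thresholds,
)


def make_sweep(counts: dict[str, list[int]], taus: list[float]) -> SweepResult:
    df = pd.DataFrame.from_dict(counts, orient="index", columns=taus)
    df.index.name = "movie"
    return SweepResult(taus=taus, counts=df)


class TestSweep:
    def test_all_zero_movie_counts_zero_everywhere(self):
        movie = MovieRecord("blank", 1.0, ImageStack(np.zeros((6, 12, 12), np.uint8)))
        sweep = sweep_thresholds([movie], [1.0, 10.0])
        assert sweep.counts.loc["blank"].tolist() == [0, 0]

    def test_counts_non_increasing_in_tau(self):
        gen = np.random.default_rng(17)
        movie = MovieRecord(
            "noisy", 1.0, ImageStack(gen.integers(0, 256, (8, 16, 16), dtype=np.uint8))
        )
        sweep = sweep_thresholds([movie], [5.0, 50.0])
        row = sweep.counts.loc["noisy"]
        assert row[5.0] >= row[50.0]

    def test_monotonicity_violation_rejected_on_construction(self):
        with pytest.raises(ValueError):
            make_sweep({"m": [5, 10]}, [1.0, 2.0])

    def test_sweep_table_matches_per_cell_pipeline_recomputation(self):
        from blinkcount import DetectorParams, SimulationConfig, render_movie, run_pipeline

        taus = [20.0, 60.0, 120.0]
        movies = []
        for i, n in enumerate((3, 6, 12)):
            cfg = SimulationConfig(n_frames=10, height=32, width=32,
                                   n_emitters=n, seed=40 + i)
            stack, _ = render_movie(cfg)
            movies.append(MovieRecord(f"m{n}", float(n), stack))
        sweep = sweep_thresholds(movies, taus)
        for rec in movies:
            for tau in taus:
                expected = run_pipeline(
                    rec.stack(), FilterParams(), DetectorParams(tau=tau)
                ).count
                assert sweep.counts.loc[rec.label, tau] == expected

    def test_empty_taus_rejected(self):
        movie = MovieRecord("m", 1.0, ImageStack(np.zeros((3, 4, 4), np.uint8)))
        with pytest.raises(ValueError):
            sweep_thresholds([movie], [])


class TestSelectThreshold:
    CONC = {"c1": 1.0, "c2": 10.0, "c3": 100.0, "c4": 1000.0}

    def test_monotone_threshold_beats_non_monotone(self):
        # at tau=50 counts dip with concentration; at tau=150 they rise strictly
        sweep = make_sweep(
            {"c1": [100, 1], "c2": [80, 5], "c3": [120, 20], "c4": [130, 60]},
            [50.0, 150.0],
        )
        tau_star, diag = select_threshold(sweep, self.CONC)
        assert tau_star == 150.0
        assert not diag.attrs["warning"]
        assert diag.loc[150.0, "monotone"] and not diag.loc[50.0, "monotone"]

    def test_single_tau_returned(self):
        sweep = make_sweep({"c1": [1], "c2": [5], "c3": [9], "c4": [12]}, [77.0])
        tau_star, _ = select_threshold(sweep, self.CONC)
        assert tau_star == 77.0

    def test_warning_when_no_tau_is_monotone(self):
        sweep = make_sweep({"c1": [9], "c2": [5], "c3": [7], "c4": [2]}, [10.0])
        tau_star, diag = select_threshold(sweep, self.CONC)
        assert tau_star == 10.0
        assert diag.attrs["warning"]

    def test_requires_two_distinct_concentrations(self):
        sweep = make_sweep({"a": [3], "b": [2]}, [1.0])
        with pytest.raises(ValueError):
            select_threshold(sweep, {"a": 5.0, "b": 5.0})

    def test_matches_exhaustive_scoring_oracle(self):
        """The selector equals brute-force evaluation of its documented score."""
        gen = np.random.default_rng(5)
        taus = [10.0, 20.0, 30.0, 40.0]
        counts = {}
        for lab in self.CONC:
            base = np.sort(gen.integers(0, 500, size=len(taus)))[::-1]
            counts[lab] = base.tolist()
        sweep = make_sweep(counts, taus)
        tau_star, _ = select_threshold(sweep, self.CONC)

        labels = list(sweep.counts.index)
        conc = np.array([self.CONC[lab] for lab in labels])
        blank_label = labels[int(np.argmin(conc))]
        best, best_score = None, None
        for tau in taus:
            y = sweep.counts[tau].to_numpy(float)
            if np.ptp(y) == 0:
                rho = float("-inf")
            else:
                rho = stats.spearmanr(conc, y).statistic
                rho = float("-inf") if np.isnan(rho) else float(rho)
            try:
                fit = fit_log_linear(list(zip(conc, y)))
                r2 = fit.r_squared if fit.r_squared_defined else float("-inf")
            except ValueError:
                r2 = float("-inf")
            score = (rho, r2, -float(sweep.counts.loc[blank_label, tau]))
            if best_score is None or score > best_score:
                best, best_score = tau, score
        assert tau_star == best

    def test_pure_function_of_inputs(self):
        sweep = make_sweep(
            {"c1": [4, 1], "c2": [9, 3], "c3": [20, 8], "c4": [44, 21]},
            [5.0, 25.0],
        )
        assert select_threshold(sweep, self.CONC)[0] == select_threshold(
            sweep, self.CONC
        )[0]


class TestGridDensity:
    def test_12x12_field_at_unit_pixel_gives_four_grids(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:3, 0:3] = True  # 9 true pixels inside the first 6x6 grid
        result = grid_density(mask, GridSpec(pixel_size=1.0, square_area=36.0))
        assert result.n_grids == 4
        assert result.per_grid_counts[0, 0] == 9
        assert result.densities[0, 0] == pytest.approx(9 / 36)  # 0.25 per um^2

    def test_empty_mask_all_zero_densities(self):
        result = grid_density(
            np.zeros((12, 12), dtype=bool), GridSpec(pixel_size=1.0)
        )
        assert np.all(result.densities == 0) and result.mean_density == 0

    def test_counts_match_brute_force_tally(self):
        gen = np.random.default_rng(2)
        mask = gen.random((20, 26)) < 0.3
        spec = GridSpec(pixel_size=1.0, square_area=36.0)  # side 6
        result = grid_density(mask, spec)
        for gy in range(3):
            for gx in range(4):
                tally = int(
                    mask[gy * 6 : (gy + 1) * 6, gx * 6 : (gx + 1) * 6].sum()
                )
                assert result.per_grid_counts[gy, gx] == tally

    def test_partial_edge_squares_discarded_conservation(self):
        gen = np.random.default_rng(3)
        mask = gen.random((13, 13)) < 0.5
        result = grid_density(mask, GridSpec(pixel_size=1.0))
        assert result.per_grid_counts.sum() <= mask.sum()
        exact = grid_density(mask[:12, :12], GridSpec(pixel_size=1.0))
        assert exact.per_grid_counts.sum() == mask[:12, :12].sum()

    def test_selected_grids_mean(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:6, 0:6] = True  # grid 0 full: 36 counts; others empty
        result = grid_density(
            mask, GridSpec(pixel_size=1.0), selected_grids=[0, 3]
        )
        assert result.mean_density == pytest.approx((1.0 + 0.0) / 2)

    def test_random_selection_is_seeded(self):
        gen = np.random.default_rng(4)
        mask = gen.random((18, 18)) < 0.2
        a = grid_density(mask, GridSpec(pixel_size=1.0), n_random=3, seed=9)
        b = grid_density(mask, GridSpec(pixel_size=1.0), n_random=3, seed=9)
        assert a.selected_grids == b.selected_grids
        assert a.mean_density == b.mean_density

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            grid_density(np.zeros((4, 4), dtype=bool), GridSpec(pixel_size=1.0))


class TestFitLogLinear:
    def test_exact_line_on_decade_spaced_points(self):
        fit = fit_log_linear([(1.0, 1.0), (10.0, 3.0), (100.0, 5.0)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_flags_undefined_r_squared(self):
        fit = fit_log_linear([(1.0, 4.0), (10.0, 4.0), (100.0, 4.0)])
        assert fit.slope == pytest.approx(0.0)
        assert not fit.r_squared_defined and fit.r_squared is None

    def test_matches_closed_form_sums_and_linregress(self):
        gen = np.random.default_rng(6)
        conc = np.array([0.5, 2.0, 8.0, 50.0, 400.0])
        y = 1.7 * np.log10(conc) + 0.4 + gen.normal(0, 0.2, size=5)
        fit = fit_log_linear(list(zip(conc, y)))

        # independent closed-form oracle from raw sums
        x = np.log10(conc)
        n = len(x)
        sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

        lr = stats.linregress(x, y)
        assert fit.slope == pytest.approx(lr.slope, rel=1e-10)
        assert fit.r_squared == pytest.approx(lr.rvalue**2, rel=1e-10)

    @pytest.mark.parametrize(
        "points,err",
        [
            ([(1.0, 2.0)], "2 points"),
            ([(0.0, 1.0), (1.0, 2.0)], "positive"),
            ([(5.0, 1.0), (5.0, 2.0)], "identical"),
        ],
    )
    def test_invalid_inputs_rejected(self, points, err):
        with pytest.raises(ValueError, match=err):
            fit_log_linear(points)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        shift=st.floats(-50, 50), scale=st.floats(0.01, 100),
        seed=st.integers(0, 2**16),
    )
    def test_affine_response_invariance(self, shift, scale, seed):
        """y -> k*y + c scales slope/intercept by k, shifts intercept by c, keeps R^2."""
        gen = np.random.default_rng(seed)
        conc = np.array([1.0, 5.0, 20.0, 100.0])
        y = gen.normal(size=4)
        if np.ptp(y) == 0:
            return
        base = fit_log_linear(list(zip(conc, y)))
        moved = fit_log_linear(list(zip(conc, scale * y + shift)))
        assert moved.slope == pytest.approx(scale * base.slope, rel=1e-8, abs=1e-10)
        assert moved.intercept == pytest.approx(
            scale * base.intercept + shift, rel=1e-8, abs=1e-8
        )
        assert moved.r_squared == pytest.approx(base.r_squared, rel=1e-8)


class TestCompareMethods:
    SERIES = {1.0: 2.0, 10.0: 4.5, 100.0: 6.1}

    def test_identical_series_identical_fits(self):
        cmp = compare_methods(self.SERIES, dict(self.SERIES))
        assert cmp.manual_fit.slope == cmp.auto_fit.slope
        assert cmp.manual_fit.r_squared == cmp.auto_fit.r_squared

    def test_scaled_series_scales_slope_keeps_r_squared(self):
        scaled = {c: v * 0.01 for c, v in self.SERIES.items()}
        cmp = compare_methods(scaled, self.SERIES)
        assert cmp.manual_fit.slope == pytest.approx(0.01 * cmp.auto_fit.slope)
        assert cmp.manual_fit.r_squared == pytest.approx(cmp.auto_fit.r_squared)

    def test_mismatched_concentrations_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(self.SERIES, {1.0: 2.0, 10.0: 4.5})

    def test_report_equals_independent_recomputation(self):
        gen = np.random.default_rng(8)
        concs = [1.0, 10.0, 100.0, 1000.0]
        manual = {c: float(gen.random()) for c in concs}
        auto = {c: float(gen.integers(10, 500)) for c in concs}
        cmp = compare_methods(manual, auto)
        m = fit_log_linear([(c, manual[c]) for c in concs])
        a = fit_log_linear([(c, auto[c]) for c in concs])
        assert cmp.manual_fit.slope == m.slope
        assert cmp.auto_fit.slope == a.slope
        assert list(cmp.table["concentration_pg_per_ml"]) == concs
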