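"""CP build-up/decay model: evaluation, stationary point, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resinate.cpdyn import (
    CPDynamicsModel,
    VCTCurve,
    eq1,
    extract_vct_curve,
    fit_cp_dynamics,
    fit_sample_table,
    t_max,
)
from resinate.errors import ContractError
from resinate.specmodel import Peak
from resinate.synthdata import default_peak_table, generate_vct_series

TC_GRID = np.geomspace(20.0, 50_000.0, 24)


class TestEq1:
    def test_zero_contact_time_gives_zero(self):
        assert eq1(0.0, 123.0, 500.0, 50.0) == 0.0

    def test_reference_value(self):
        # S0=1, TCH=1000 us, T1rhoH=100 ms at tc=1000 us:
        # (1 - e^-1) * e^-0.01
        assert eq1(1000.0, 1.0, 1000.0, 100.0) == pytest.approx(
            0.62583, abs=5e-6)

    def test_linear_in_amplitude(self):
        tc = np.linspace(10, 40000, 30)
        np.testing.assert_allclose(eq1(tc, 2.0, 800.0, 60.0),
                                   2 * eq1(tc, 1.0, 800.0, 60.0), rtol=1e-14)

    def test_nonpositive_time_constants_rejected(self):
        with pytest.raises(ContractError):
            eq1(10.0, 1.0, -5.0, 50.0)
        with pytest.raises(ContractError):
            eq1(10.0, 1.0, 500.0, 0.0)


class TestStationaryPoint:
    def test_equal_time_constants_give_ln2(self):
        # TCH = T1rhoH = 1000 us (i.e. 1 ms)
        assert t_max(1000.0, 1.0) == pytest.approx(1000.0 * np.log(2.0))

    def test_drug_c2_maximum_near_ten_ms(self):
        # closed form on the pure-drug quinoline C2 time constants
        assert t_max(2420.0, 140.0) == pytest.approx(9861.5, abs=0.5)

    def test_resin_carboxylate_maximum(self):
        assert t_max(1930.0, 9.7) == pytest.approx(3466.4, rel=2e-3)

    @given(tch=st.floats(50.0, 2e4), t1r=st.floats(1.0, 500.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_unique_interior_maximum(self, tch, t1r):
        """The curve rises before t* and falls after it (finite-difference
        sign change at the closed-form stationary point)."""
        ts = t_max(tch, t1r)
        h = 1e-4 * ts
        before = eq1(ts - h, 1.0, tch, t1r)
        at = eq1(ts, 1.0, tch, t1r)
        after = eq1(ts + h, 1.0, tch, t1r)
        assert before < at
        assert after < at


def _noiseless_curve(S0=100.0, tch=2420.0, t1r=140.0, tc=TC_GRID):
    return VCTCurve("C2", 145.2, tc, eq1(tc, S0, tch, t1r))


class TestFit:
    def test_noiseless_identifiability(self):
        fit = CPDynamicsModel(_noiseless_curve()).fit()
        assert fit.status == "ok"
        assert fit.S0 == pytest.approx(100.0, rel=1e-4)
        assert fit.TCH_us == pytest.approx(2420.0, rel=1e-4)
        assert fit.T1rhoH_ms == pytest.approx(140.0, rel=1e-4)

    def test_noiseless_identifiability_all_table_rows(self, sample_specs):
        for spec in (sample_specs["MQ"], sample_specs["R"],
                     sample_specs["MQ-R"]):
            for site in spec.dynamics_sites():
                y = eq1(TC_GRID, site.S0, site.TCH, site.T1rhoH)
                fit = CPDynamicsModel.from_arrays(TC_GRID, y).fit()
                assert fit.TCH_us == pytest.approx(site.TCH, rel=1e-4), \
                    site.assignment
                assert fit.T1rhoH_ms == pytest.approx(site.T1rhoH,
                                                      rel=1e-4), \
                    site.assignment

    def test_noisy_recovery_median_within_ten_percent(self):
        meds = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            y = eq1(TC_GRID, 100.0, 2420.0, 140.0)
            y = y * (1 + rng.normal(0, 0.02, y.shape))
            meds.append(CPDynamicsModel.from_arrays(TC_GRID, y)
                        .fit().T1rhoH_ms)
        assert np.median(meds) == pytest.approx(140.0, rel=0.10)

    def test_too_few_points_not_determined(self):
        tc = np.array([100.0, 500.0, 2000.0, 10000.0])
        fit = CPDynamicsModel.from_arrays(tc, eq1(tc, 1, 500, 50)).fit()
        assert fit.status == "n.d."
        assert not fit.converged

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        y = eq1(TC_GRID, 100.0, 1500.0, 80.0) * (1 + rng.normal(0, 0.02, 24))
        f1 = CPDynamicsModel.from_arrays(TC_GRID, y).fit()
        f2 = CPDynamicsModel.from_arrays(TC_GRID, 1e3 * y).fit()
        assert f2.S0 == pytest.approx(1e3 * f1.S0, rel=1e-8)
        assert f2.TCH_us == pytest.approx(f1.TCH_us, rel=1e-8)
        assert f2.T1rhoH_ms == pytest.approx(f1.T1rhoH_ms, rel=1e-8)

    def test_grid_search_oracle(self):
        """Brute-force SSE over a 200x200 log grid never beats the NLS
        optimum, and on noiseless data the NLS optimum falls within one grid
        cell of the grid argmin."""
        curve = _noiseless_curve(S0=50.0, tch=1200.0, t1r=60.0)
        fit = CPDynamicsModel(curve).fit()
        tch_grid = np.geomspace(10.0, 1e5, 200)
        t1r_grid = np.geomspace(1.0, 1e3, 200)  # ms
        tc = curve.contact_times
        y = curve.intensities
        # shape basis per (tch, t1r) pair; optimal S0 in closed form
        build = 1.0 - np.exp(-tc[None, None, :] / tch_grid[:, None, None])
        decay = np.exp(-tc[None, None, :]
                       / (1000.0 * t1r_grid[None, :, None]))
        f = build * decay
        denom = np.sum(f * f, axis=2)
        s0 = np.sum(f * y[None, None, :], axis=2) / denom
        sse = np.sum((s0[:, :, None] * f - y[None, None, :]) ** 2, axis=2)
        nls_sse = float(np.sum((fit.predict(tc) - y) ** 2))
        assert sse.min() >= nls_sse - 1e-9
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        # within one log-grid cell of the grid argmin
        ratio_tch = np.log(fit.TCH_us / tch_grid[i])
        ratio_t1r = np.log(fit.T1rhoH_ms / t1r_grid[j])
        step_tch = np.log(tch_grid[1] / tch_grid[0])
        step_t1r = np.log(t1r_grid[1] / t1r_grid[0])
        assert abs(ratio_tch) <= step_tch
        assert abs(ratio_t1r) <= step_t1r

    def test_parameter_recovery_bias_and_coverage(self):
        """Across parameter draws inside the published ranges with 2%
        noise: small median T1rhoH bias, and +/-1 se intervals covering
        truth at a plausible nominal rate."""
        rng = np.random.default_rng(42)
        bias, covered = [], []
        for _ in range(200):
            tch = np.exp(rng.uniform(np.log(300.0), np.log(6400.0)))
            t1r = np.exp(rng.uniform(np.log(9.0), np.log(212.0)))
            y = eq1(TC_GRID, 100.0, tch, t1r)
            y = y * (1 + rng.normal(0, 0.02, y.shape))
            fit = CPDynamicsModel.from_arrays(TC_GRID, y).fit()
            if fit.status != "ok":
                continue
            bias.append((fit.T1rhoH_ms - t1r) / t1r)
            covered.append(abs(fit.T1rhoH_ms - t1r) <= fit.T1rhoH_se)
        assert len(bias) > 150
        assert abs(np.median(bias)) < 0.03
        assert 0.55 <= np.mean(covered) <= 0.80

    def test_overlapping_timescales_inflate_se(self):
        """When the decay outruns the build-up (T1rhoH comparable to or
        shorter than TCH) the two exponentials compete over the same part
        of the curve; the fit must report large uncertainty rather than
        silently precise values. Median relative se over seeds, same grid
        and noise in both arms."""
        tc = TC_GRID
        rel_bad, rel_good = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = eq1(tc, 100.0, 20_000.0, 4.0)   # T1rho(us)/TCH = 0.2
            f = CPDynamicsModel.from_arrays(
                tc, y * (1 + rng.normal(0, 0.02, tc.shape))).fit()
            rel_bad.append(f.T1rhoH_se / f.T1rhoH_ms)
            y = eq1(tc, 100.0, 2000.0, 20.0)    # T1rho(us)/TCH = 10
            f = CPDynamicsModel.from_arrays(
                tc, y * (1 + rng.normal(0, 0.02, tc.shape))).fit()
            rel_good.append(f.T1rhoH_se / f.T1rhoH_ms)
        assert np.median(rel_bad) > 3 * np.median(rel_good)
        assert np.median(rel_bad) > 0.08


class TestSeriesExtraction:
    def test_round_trip_single_site(self, sample_specs):
        from resinate.synthdata import CarbonSite, SampleSpec
        site = sample_specs["MQ"].site("C2")
        solo = SampleSpec("C2-only", [CarbonSite("C2", site.shifts,
                                                 site.TCH, site.T1rhoH)],
                          noise_mult=0.0, noise_add=0.0)
        series = generate_vct_series(solo, seed=0)
        peak = Peak(145.2, "C2", (144.3, 146.1))
        curve = extract_vct_curve(series, peak, readout_mode="height")
        expect = eq1(curve.contact_times, site.S0, site.TCH, site.T1rhoH)
        # heights follow the amplitude law exactly up to one constant
        # discretization factor (the line center falls between grid points)
        ratio = curve.intensities / expect
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
        np.testing.assert_allclose(curve.intensities, expect, rtol=3e-3)

    def test_overlap_peak_marked_contaminated_and_nd(self, sample_specs):
        spec = sample_specs["MQ-R"]
        series = generate_vct_series(spec, seed=0)
        table = default_peak_table(spec)
        overlapped = [p for p in table if p.overlap_group is not None]
        assert {p.assignment for p in overlapped} >= {"C14", "C15", "C16",
                                                      "C17"}
        curve = extract_vct_curve(series, overlapped[0])
        assert curve.contaminated
        assert fit_cp_dynamics(curve).status == "n.d."
        forced = fit_cp_dynamics(curve, force=True)
        assert forced.status in ("ok", "poor_fit", "n.d.")
        assert forced.n_points == len(series)

    def test_mq_fixture_full_table_all_determined_rows_ok(self,
                                                          sample_specs):
        spec = sample_specs["MQ"]
        series = generate_vct_series(spec, seed=11)
        table = default_peak_table(spec)
        fits = fit_sample_table(series, table)
        assert len(fits) == len(table)
        determined = {
            (s.assignment, shift)
            for s in spec.dynamics_sites() for shift in s.shifts
        }
        for peak, fit in fits:
            if (peak.assignment, peak.center) in determined:
                assert fit.status == "ok", (peak.assignment, fit.message)

    def test_empty_series_rejected(self, sample_specs):
        with pytest.raises(ContractError):
            fit_sample_table([], default_peak_table(sample_specs["MQ"]))

    def test_missing_window_rejected(self, sample_specs):
        series = generate_vct_series(sample_specs["MQ"],
                                     axis=(0.0, 200.0, 1024), seed=0)
        bad = Peak(300.0, "X", (295.0, 305.0))
        with pytest.raises(Exception):
            extract_vct_curve(series, bad)
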