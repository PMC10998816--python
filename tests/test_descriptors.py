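"""Kinetic descriptors: yields, productivities, specific rates, tables."""

import numpy as np
import pytest

from fermkin import (
    DescriptorError,
    InsufficientDataError,
    UndefinedRateError,
    compute_descriptors,
    descriptor_table,
    generate_study,
    specific_growth_rate,
    specific_production_series,
    specific_production_summary,
    StressParams,
    substrate_uptake,
    volumetric_productivity,
    yields,
    ze75_preset,
)

from conftest import make_timecourse


def _flat_tc(peak_p, peak_x, s_g0=150.0, t_peak=72.0, substrate=None):
    """Three-point course reaching its maxima at t_peak."""
    times = [0.0, t_peak / 2, t_peak]
    return make_timecourse(
        times,
        [peak_x / 10, peak_x / 2, peak_x],
        [0.0, peak_p / 2, peak_p],
        substrate,
        s_g0=s_g0,
    )


class TestYields:
    @pytest.mark.parametrize(
        "peak_p, s_g0, expected",
        [
            (89.77, 150.0, 0.598),   # glucose screening peak
            (69.36, 150.0, 0.4624),
            (84.48, 150.0, 0.563),
            (78.50, 150.0, 0.5233),
            (104.04, 175.0, 0.5945),
        ],
    )
    def test_ethanol_yield_on_initial_substrate(self, peak_p, s_g0, expected):
        y_ps, _ = yields(_flat_tc(peak_p, 5.0, s_g0=s_g0))
        assert y_ps == pytest.approx(peak_p / s_g0, rel=1e-12)
        digits = len(str(expected).split(".")[1])
        assert round(y_ps, digits) == pytest.approx(expected, abs=1e-12)

    def test_biomass_yield(self):
        _, y_xs = yields(_flat_tc(50.0, 7.49, s_g0=150.0))
        assert round(y_xs, 4) == pytest.approx(0.0499, abs=5e-5)

    def test_zero_ethanol_gives_zero_yield(self):
        y_ps, _ = yields(make_timecourse([0, 6, 12], [1, 2, 3], [0, 0, 0]))
        assert y_ps == 0.0


class TestVolumetricProductivity:
    def test_peak_over_time_of_peak(self):
        # t=72 h reconstructed from the printed (E_p, Q_p) pair (89.77, 1.247)
        q_p = volumetric_productivity(_flat_tc(89.77, 9.0, t_peak=72.0))
        assert q_p == pytest.approx(1.2468055555555555, rel=1e-12)
        q_p2 = volumetric_productivity(_flat_tc(98.65, 9.0, t_peak=72.0))
        assert q_p2 == pytest.approx(1.370138888888889, rel=1e-12)

    def test_earliest_peak_time_wins_on_ties(self):
        tc = make_timecourse([0, 6, 12, 24], [1, 2, 3, 4], [0, 10, 10, 10])
        assert volumetric_productivity(tc) == pytest.approx(10.0 / 6.0)

    def test_peak_at_time_zero_is_undefined(self):
        tc = make_timecourse([0, 6, 12], [1, 2, 3], [0, 0, 0])
        with pytest.raises(UndefinedRateError):
            volumetric_productivity(tc)


class TestSubstrateUptake:
    def test_consumed_over_peak_window(self):
        tc = make_timecourse(
            [0.0, 36.0, 72.0], [1, 5, 9], [0, 45, 90], [150.0, 80.0, 6.0]
        )
        assert substrate_uptake(tc) == pytest.approx((150 - 6) / 72)

    def test_constant_substrate_gives_zero(self):
        tc = make_timecourse([0, 6, 12], [1, 2, 3], [0, 1, 2],
                             [100.0, 100.0, 100.0])
        assert substrate_uptake(tc) == 0.0

    def test_absent_series_gives_none(self):
        assert substrate_uptake(_flat_tc(50, 5)) is None


class TestSpecificProductionSeries:
    def test_linear_ethanol_constant_biomass(self):
        t = np.arange(0.0, 20.0, 4.0)
        tc = make_timecourse(t, np.full_like(t, 2.0), 1.0 * t)
        v = specific_production_series(tc)
        np.testing.assert_allclose(v[:, 1], 0.5, rtol=1e-12)

    def test_central_difference_exact_for_quadratic(self):
        t = np.linspace(0.0, 8.0, 5)
        p = 0.3 * t**2 + 1.5 * t  # dP/dt = 0.6 t + 1.5
        tc = make_timecourse(t, np.full_like(t, 2.0), p)
        v = specific_production_series(tc)
        np.testing.assert_allclose(
            v[1:-1, 1], (0.6 * t[1:-1] + 1.5) / 2.0, rtol=1e-12
        )

    def test_constant_ethanol_gives_zero(self):
        tc = make_timecourse([0, 4, 8], [1, 2, 3], [5.0, 5.0, 5.0])
        v = specific_production_series(tc)
        np.testing.assert_array_equal(v[:, 1], 0.0)

    def test_interior_zero_biomass_raises(self):
        tc = make_timecourse([0, 4, 8], [1.0, 0.0, 3.0], [0, 1, 2])
        with pytest.raises(DescriptorError, match="4"):
            specific_production_series(tc)


class TestSpecificProductionSummary:
    @pytest.mark.parametrize(
        "q_p_pair, expected",
        [((1.247, 9.044), 0.138), ((1.1733, 6.944), 0.169)],
    )
    def test_reproduces_printed_specific_rates(self, q_p_pair, expected):
        q_p, x_m = q_p_pair
        tc = _flat_tc(q_p * 72.0, x_m, t_peak=72.0)
        assert round(specific_production_summary(tc), 3) == pytest.approx(
            expected, abs=5e-4
        )

    def test_zero_ethanol_gives_zero(self):
        tc = make_timecourse([0, 6, 12], [1, 2, 3], [0, 0, 0])
        assert specific_production_summary(tc) == 0.0


class TestSpecificGrowthRate:
    def test_exact_exponential_recovers_rate_over_full_range(self, exponential_tc):
        mu, window = specific_growth_rate(exponential_tc)
        assert mu == pytest.approx(0.12, rel=1e-12)
        assert window == (0.0, 24.0)

    def test_exponential_then_plateau_confines_window(self):
        t = np.arange(0.0, 76.0, 4.0)
        x = np.where(t <= 24.0, 0.5 * np.exp(0.12 * t),
                     0.5 * np.exp(0.12 * 24.0))
        tc = make_timecourse(t, x, 0.1 * t)
        mu, window = specific_growth_rate(tc)
        assert mu == pytest.approx(0.12, rel=0.02)
        assert window[1] <= 28.0

    def test_decreasing_biomass_gives_zero_and_empty_window(self):
        t = np.arange(0.0, 24.0, 4.0)
        tc = make_timecourse(t, 5.0 * np.exp(-0.1 * t), 0.1 * t)
        mu, window = specific_growth_rate(tc)
        assert mu == 0.0 and window is None

    def test_too_few_positive_points_raises(self):
        tc = make_timecourse([0, 4, 8], [1, 2, 4], [0, 1, 2])
        with pytest.raises(InsufficientDataError):
            specific_growth_rate(tc)

    def test_simulated_growth_rate_matches_generator(self, default_noise_free_run):
        # early-window log-linear slope ~ generating mu at t->0 (S ~ s0, P ~ 0)
        p, tc = default_noise_free_run
        mu, _ = specific_growth_rate(tc)
        mu_true = p.mu_max * p.s0 / (p.ks + p.s0)
        assert mu == pytest.approx(mu_true, rel=0.05)


class TestDescriptorTable:
    def test_identities_hold_for_every_row(self, default_noise_free_run):
        _, tc = default_noise_free_run
        d = compute_descriptors(tc)
        assert d.y_ps * d.s_g0 == pytest.approx(d.e_p, rel=1e-12)
        assert d.y_xs * d.s_g0 == pytest.approx(d.x_m, rel=1e-12)
        assert d.v_g * d.x_m == pytest.approx(d.q_p, rel=1e-12)

    def test_scaling_concentrations_scales_extensive_descriptors(self, exponential_tc):
        from dataclasses import replace as dc_replace

        d1 = compute_descriptors(exponential_tc)
        scaled = dc_replace(exponential_tc, biomass=3.0 * exponential_tc.biomass,
                            ethanol=3.0 * exponential_tc.ethanol)
        d3 = compute_descriptors(scaled)
        assert d3.e_p == pytest.approx(3 * d1.e_p)
        assert d3.x_m == pytest.approx(3 * d1.x_m)
        assert d3.q_p == pytest.approx(3 * d1.q_p)
        assert d3.v_g == pytest.approx(d1.v_g)

    def test_cardinality_and_zero_sd_without_noise(self):
        recs = generate_study(
            ze75_preset(noise_cv=0.0, t_end=24.0, dt_out=4.0), StressParams(),
            s0_grid=[100, 150], ph_grid=[4.5], salinity_grid=["seawater"],
            replicates=3, seed=2,
        )
        table = descriptor_table(recs)
        assert (table["stat"] == "replicate").sum() == 6
        assert (table["stat"] == "mean").sum() == 2
        sd_rows = table[table["stat"] == "sd"]
        assert len(sd_rows) == 2
        assert (sd_rows["e_p"].abs() < 1e-9).all()

    def test_default_preset_yield_lands_near_point_six(self):
        recs = generate_study(
            ze75_preset(), StressParams(), s0_grid=[150.0], ph_grid=[4.5],
            salinity_grid=["seawater"], replicates=3, seed=9,
        )
        table = descriptor_table(recs)
        mean_y_ps = float(table.loc[table["stat"] == "mean", "y_ps"].iloc[0])
        assert mean_y_ps == pytest.approx(0.6, rel=0.10)

    def test_sampling_density_invariance(self):
        from dataclasses import replace as dc_replace

        base = ze75_preset(noise_cv=0.0)
        from fermkin import Condition, simulate_batch

        cond = Condition(condition_id="c", s_g0=150.0, ph=4.5,
                         salinity="seawater")
        coarse = compute_descriptors(
            simulate_batch(dc_replace(base, dt_out=4.0), cond, StressParams())
        )
        fine = compute_descriptors(
            simulate_batch(dc_replace(base, dt_out=2.0), cond, StressParams())
        )
        assert fine.e_p == pytest.approx(coarse.e_p, rel=1e-3)
        assert fine.x_m == pytest.approx(coarse.x_m, rel=1e-3)
        assert fine.y_ps == pytest.approx(coarse.y_ps, rel=1e-3)
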