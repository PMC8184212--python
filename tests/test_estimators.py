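"""Assay estimators against hand arithmetic, brute-force oracles and
simulated ground truth."""

import numpy as np
import pytest

from crossfeed import (
    ChemostatConfig,
    CytometrySample,
    MoserParams,
    StandardCurve,
    bioassay_concentration,
    chemostat_steady_state,
    community_growth_rate,
    community_steady_growth,
    cytometry_densities,
    detect_steady_state,
    dilution_rate_from_doubling,
    doubling_time_from_dilution,
    exchange_ratio,
    exchange_ratio_replicates,
    fit_moser,
    fit_standard_curve,
    flow_rate_for_doubling,
    generations_from_od,
    growth_rate_from_timeseries,
    moser_rate,
    simulate_chemostat,
    simulate_community,
)
from crossfeed.synth import (
    ancestor_phenotype,
    default_chemostat_config,
    default_community_config,
    mutant_phenotype,
)


class TestGrowthRate:
    @pytest.mark.parametrize("window", [3, 4])
    @pytest.mark.parametrize("rate", [0.05, 0.2, 0.44])
    def test_exact_exponential_recovered(self, window, rate):
        t = np.linspace(0, 10, 9)
        y = 50.0 * np.exp(rate * t)
        est = growth_rate_from_timeseries(t, y, window=window)
        assert est.rate == pytest.approx(rate, abs=1e-9)
        assert not est.no_growth

    def test_uneven_sampling_still_exact(self):
        t = np.array([0.0, 0.7, 1.1, 2.9, 3.4, 6.0, 7.7])
        y = np.exp(0.3 * t)
        est = growth_rate_from_timeseries(t, y)
        assert est.rate == pytest.approx(0.3, abs=1e-9)

    def test_constant_signal_flags_no_growth(self):
        t = np.arange(6.0)
        est = growth_rate_from_timeseries(t, np.full(6, 7.0))
        assert est.rate == 0.0 and est.no_growth

    def test_decaying_signal_flags_no_growth(self):
        t = np.arange(6.0)
        est = growth_rate_from_timeseries(t, 10 * np.exp(-0.2 * t))
        assert est.rate == 0.0 and est.no_growth

    def test_matches_brute_force_window_search(self):
        """Seeded noisy series: result equals the max over all window OLS
        slopes computed independently with polyfit."""
        rng = np.random.default_rng(7)
        t = np.arange(12.0)
        y = 100 * np.exp(0.25 * np.clip(t - 3, 0, None)) * rng.lognormal(0, 0.05, 12)
        for w in (3, 4):
            est = growth_rate_from_timeseries(t, y, window=w)
            logy = np.log(y / y[0])
            brute = max(
                np.polyfit(t[i : i + w], logy[i : i + w], 1)[0]
                for i in range(len(t) - w + 1)
            )
            assert est.rate == pytest.approx(brute, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            growth_rate_from_timeseries([0, 1], [1.0, 2.0], window=3)
        with pytest.raises(ValueError):
            growth_rate_from_timeseries([0, 1, 2], [1.0, 0.0, 2.0])
        with pytest.raises(ValueError):
            growth_rate_from_timeseries([0, 1, 2, 3], [1, 2, 3, 4], window=5)


class TestFitMoser:
    TRUTH = MoserParams(b_max=0.44, K=2.0, n=2.0)
    CONCS = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])

    def test_noiseless_self_consistency(self):
        pts = [(L, moser_rate(L, self.TRUTH)) for L in self.CONCS]
        fit = fit_moser(pts)
        assert fit.params.b_max == pytest.approx(0.44, rel=1e-6)
        assert fit.params.K == pytest.approx(2.0, rel=1e-6)
        assert fit.params.n == pytest.approx(2.0, rel=1e-5)
        assert fit.rss < 1e-12

    def test_parameter_recovery_under_noise(self):
        """5% multiplicative noise, 8 concentrations x 3 replicates:
        b_max within 5% and K within 15% in >= 90% of 20 seeds."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = []
            for _ in range(3):
                for L in self.CONCS:
                    pts.append((L, moser_rate(L, self.TRUTH) * rng.lognormal(0, 0.05)))
            fit = fit_moser(pts)
            if abs(fit.params.b_max - 0.44) / 0.44 < 0.05 and abs(fit.params.K - 2.0) / 2.0 < 0.15:
                ok += 1
        assert ok >= 18

    def test_under_determined_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_moser([(1.0, 0.1), (2.0, 0.2)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_moser([(L, 0.3) for L in self.CONCS])


class TestDetectSteadyState:
    def test_constant_series(self):
        ss = detect_steady_state(np.arange(10.0), np.full(10, 4.2))
        assert ss.reached and ss.t_onset == 0.0 and ss.mean == pytest.approx(4.2)

    def test_monotone_ramp_not_reached(self):
        t = np.arange(101.0)
        ss = detect_steady_state(t, np.linspace(1.0, 1.5, 101))
        assert not ss.reached

    def test_simulated_chemostat_plateau(self):
        cfg = default_chemostat_config()
        phen = ancestor_phenotype()
        traj = simulate_chemostat(cfg, phen, np.arange(0.0, 120.1, 2.0))
        ss = detect_steady_state(traj.times, traj.product)
        truth = chemostat_steady_state(cfg, phen)["product_uM"]
        assert ss.reached
        assert ss.mean == pytest.approx(truth, rel=0.02)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            detect_steady_state([0, 1, 2], [1, 1, 1])


class TestExchangeRatio:
    def test_zero_product_gives_zero(self):
        assert exchange_ratio(0.1, 0.0, 20.0).value == 0.0

    def test_unit_ratio(self):
        dil = np.log(2) / 6
        assert exchange_ratio(dil, 20.0, 20.0).value == pytest.approx(dil)

    def test_zero_inflow_rejected(self):
        with pytest.raises(ValueError):
            exchange_ratio(0.1, 1.0, 0.0)

    @pytest.mark.parametrize("doubling", [4.0, 6.0, 8.0])
    def test_round_trip_against_simulation(self, doubling):
        """dil*H_ss/L0 from a simulated chemostat recovers the generating
        r/c within 2% whenever residual nutrient < 1% of the feed."""
        cfg = default_chemostat_config(doubling)
        phen = ancestor_phenotype()
        traj = simulate_chemostat(cfg, phen, np.arange(0.0, 120.1, 2.0))
        assert traj.nutrient[-1] < 0.01 * cfg.inflow_conc
        ss = detect_steady_state(traj.times, traj.product)
        est = exchange_ratio(cfg.dilution_rate, ss.mean, cfg.inflow_conc)
        assert est.value == pytest.approx(phen.exchange_ratio, rel=0.02)

    def test_replicates_carry_interval(self):
        est = exchange_ratio_replicates(0.1, [19.0, 20.0, 21.0], 20.0)
        assert est.ci[0] < est.value < est.ci[1]
        assert len(est.replicates) == 3


class TestCytometry:
    def test_identity_configuration(self):
        s = CytometrySample(500, 0, 500, bead_stock_density=1e6, bead_volume=1.0, sample_volume=1.0)
        live, dead = cytometry_densities(s)
        assert live == pytest.approx(1e6) and dead == 0.0

    def test_hand_arithmetic(self):
        s = CytometrySample(2000, 0, 500, bead_stock_density=1e6, bead_volume=0.05, sample_volume=1.0)
        live, _ = cytometry_densities(s)
        assert live == pytest.approx(2e5)

    def test_zero_beads_rejected(self):
        s = CytometrySample(10, 10, 0, 1e6, 0.05, 1.0)
        with pytest.raises(ValueError):
            cytometry_densities(s)


class TestBioassay:
    CURVE = StandardCurve(slope=0.02, intercept=0.05, valid_range=(0.0, 40.0))

    def test_intercept_maps_to_zero(self):
        assert bioassay_concentration(self.CURVE, 0.05).value == 0.0

    def test_hand_inversion(self):
        res = bioassay_concentration(self.CURVE, 0.45)
        assert res.value == pytest.approx(20.0) and res.in_range

    def test_below_intercept_flagged(self):
        with pytest.warns(UserWarning, match="outside"):
            res = bioassay_concentration(self.CURVE, 0.03)
        assert res.value < 0 and not res.in_range

    def test_curve_fit_from_points(self):
        pts = [(c, 0.05 + 0.02 * c) for c in (0.0, 10.0, 20.0, 40.0)]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(0.02)
        assert curve.intercept == pytest.approx(0.05)
        with pytest.raises(ValueError):
            fit_standard_curve(pts[:2])


class TestCommunityGrowthRate:
    def test_pure_exponential_whole_series(self):
        t = np.arange(20.0)
        fit = community_growth_rate(t, 1e4 * np.exp(0.12 * t))
        assert fit.rate == pytest.approx(0.12, abs=1e-10)
        assert fit.window == (0, 20)

    def test_lag_then_exponential_excludes_lag(self):
        t = np.arange(24.0)
        y = np.where(t < 6, 1e4, 1e4 * np.exp(0.1 * (t - 6)))
        fit = community_growth_rate(t, y)
        assert fit.rate == pytest.approx(0.1, rel=1e-6)
        assert fit.window[0] >= 6

    def test_simulated_community_matches_theory(self):
        cfg = default_community_config(mutant_phenotype())
        traj = simulate_community(cfg, np.arange(0.0, 72.1, 2.0))
        fit = community_growth_rate(traj.times, traj.total)
        g = community_steady_growth(cfg.phenotype_1, cfg.phenotype_2)
        assert fit.rate == pytest.approx(g, rel=0.05)

    def test_no_consistent_window_errors(self):
        t = np.arange(8.0)
        y = np.exp(np.array([0.0, 1.0, 0.2, 1.4, 0.1, 2.0, 0.3, 2.5]))
        with pytest.raises(ValueError, match="no trailing window"):
            community_growth_rate(t, y, rel_tol=0.01)


class TestGenerationsAndDilution:
    def test_one_doubling_no_dilution(self):
        assert generations_from_od([(0.1, 1.0), (0.2, 1.0)]) == pytest.approx(1.0)

    def test_dilution_accumulates(self):
        # OD 0.1, then 10x dilution, read 0.04 -> accumulated 0.4 -> 2 generations
        assert generations_from_od([(0.1, 10.0), (0.04, 1.0)]) == pytest.approx(2.0)

    def test_constant_od_zero_generations(self):
        assert generations_from_od([(0.3, 1.0), (0.3, 1.0), (0.3, 1.0)]) == pytest.approx(0.0)

    def test_invalid_records(self):
        with pytest.raises(ValueError):
            generations_from_od([(0.0, 1.0)])
        with pytest.raises(ValueError):
            generations_from_od([(0.1, 0.5)])

    def test_flow_rate_arithmetic(self):
        assert flow_rate_for_doubling(np.log(2), 1.0) == pytest.approx(1.0)
        assert flow_rate_for_doubling(8.0, 19.0) == pytest.approx(19 * np.log(2) / 8)
        assert flow_rate_for_doubling(1e9, 19.0) == pytest.approx(0.0, abs=1e-7)

    def test_dilution_doubling_inverse_pair(self):
        assert doubling_time_from_dilution(dilution_rate_from_doubling(6.0)) == pytest.approx(6.0)
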