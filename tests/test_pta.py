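"""fT>MIC measurement and the Monte Carlo attainment engine."""

import numpy as np
import pytest
from scipy.stats import norm

from meropk.model_core import Regimen
from meropk.pta import (
    EUCAST_PA_MIC_2024,
    MIC_LADDER,
    MICDistribution,
    PDTarget,
    campaign,
    fraction_above_threshold,
    ft_above_mic,
    pta,
    pta_curve,
    weighted_attainment,
)

TARGET_40 = PDTarget(0.40, 1)
TARGET_40_4X = PDTarget(0.40, 4)


class TestFtAboveMic:
    def test_continuous_closed_form(self, typical):
        """2 g/day continuous at CL 12.4: free Css 6.59 mg/L > MIC 4 -> 1.0."""
        r = Regimen(dose=2000.0, mode="continuous")
        assert ft_above_mic(typical, r, 4.0, PDTarget(1.0, 1)) == 1.0
        assert ft_above_mic(typical, r, 8.0, PDTarget(1.0, 1)) == 0.0

    def test_tiny_mic_gives_full_window(self, typical, standard_regimen):
        assert ft_above_mic(typical, standard_regimen, 1e-6, TARGET_40) == 1.0

    def test_threshold_above_peak_gives_zero(self, typical, standard_regimen):
        assert ft_above_mic(typical, standard_regimen, 500.0, TARGET_40) == 0.0

    def test_rejects_nonpositive_mic(self, typical, standard_regimen):
        with pytest.raises(ValueError):
            ft_above_mic(typical, standard_regimen, 0.0, TARGET_40)

    def test_grid_refinement_converged(self, typical, standard_regimen):
        """Halving the grid step moves fT>MIC by far less than 0.5% of window."""
        for mic in (0.5, 2.0, 8.0):
            a = ft_above_mic(typical, standard_regimen, mic, TARGET_40, grid_step=0.005)
            b = ft_above_mic(typical, standard_regimen, mic, TARGET_40, grid_step=0.0025)
            assert abs(a - b) < 0.005

    def test_matches_brute_force_time_counting(self, typical):
        """Crossing-refined fraction agrees with dense-grid counting."""
        from meropk.model_core import concentration

        r = Regimen(dose=1000.0, infusion_duration=0.5, interval=8.0)
        t = np.linspace(0.0, 8.0, 800_001)
        free = 0.98 * concentration(typical, r, t, steady_state=True)
        for mic in (1.0, 4.0):
            brute = np.mean(free > mic)
            refined = ft_above_mic(typical, r, mic, PDTarget(0.40, 1))
            assert refined == pytest.approx(brute, abs=2e-5)

    def test_interval_fraction_equals_24h_fraction(self, typical):
        """At steady state the per-interval fraction tiles to the 24-h one."""
        from meropk.model_core import concentration

        r = Regimen(dose=1000.0, infusion_duration=0.5, interval=8.0)
        t24 = np.linspace(0.0, 24.0, 960_001)
        free = 0.98 * concentration(typical, r, t24, steady_state=True)
        frac24 = np.mean(free > 2.0)
        frac_interval = ft_above_mic(typical, r, 2.0, PDTarget(0.40, 1))
        assert frac_interval == pytest.approx(frac24, abs=2e-5)

    def test_grid_step_must_fit_interval(self, typical, standard_regimen):
        with pytest.raises(ValueError):
            fraction_above_threshold(typical, standard_regimen, 1.0, grid_step=10.0)


class TestPTA:
    def test_monotone_nonincreasing_in_mic(self, small_population):
        r = Regimen(dose=1000.0, infusion_duration=0.5, interval=8.0)
        curve = pta_curve(r, TARGET_40, MIC_LADDER, small_population)
        assert np.all(np.diff(curve.pta) <= 0)
        assert np.all((curve.pta >= 0) & (curve.pta <= 1))

    def test_nondecreasing_in_dose(self, small_population):
        t = PDTarget(0.40, 1)
        lo = pta(Regimen(dose=500.0, interval=8.0), t, 2.0, small_population)
        hi = pta(Regimen(dose=2000.0, interval=8.0), t, 2.0, small_population)
        assert hi >= lo

    def test_fourfold_dose_multiplier_identity(self, small_population):
        """PTA(4D, fT>4MIC) is bit-identical to PTA(D, fT>MIC)."""
        a = pta_curve(
            Regimen(dose=2000.0, interval=8.0), TARGET_40_4X, MIC_LADDER, small_population
        )
        b = pta_curve(
            Regimen(dose=500.0, interval=8.0), TARGET_40, MIC_LADDER, small_population
        )
        assert np.array_equal(a.pta, b.pta)

    def test_continuous_closed_form_matches_population_and_theory(self, small_population):
        """Continuous-infusion PTA is P(CL < f*rate/threshold); cross-check
        against the analytic log-normal clearance distribution."""
        r = Regimen(dose=2000.0, mode="continuous")
        target = PDTarget(1.0, 4)
        observed = pta(r, target, 1.0, small_population)
        cl_thresh = 0.98 * (2000.0 / 24.0) / 4.0
        direct = np.mean(small_population["CL"] < cl_thresh)
        assert observed == pytest.approx(direct, abs=1e-12)
        # analytic: ln CL ~ N(mu, sig^2) from log-normal CR and eta
        sig_cr2 = np.log1p(0.190**2)
        mu_lncr = np.log(0.863) - 0.5 * sig_cr2
        mu = np.log(12.4) + (-0.392) * (mu_lncr - np.log(0.86))
        sig = np.sqrt((-0.392) ** 2 * sig_cr2 + 0.262**2)
        theory = norm.cdf((np.log(cl_thresh) - mu) / sig)
        n = len(small_population)
        assert abs(observed - theory) < 3 * np.sqrt(theory * (1 - theory) / n) + 0.005

    def test_continuous_equal_threshold_trio(self, small_population):
        """2 g/day vs 4xMIC 1, 2 g/day vs MIC 4 and 8 g/day vs 4xMIC 4 share
        the same clearance cutoff and must return identical PTA."""
        a = pta(Regimen(dose=2000.0, mode="continuous"), PDTarget(1.0, 4), 1.0, small_population)
        b = pta(Regimen(dose=2000.0, mode="continuous"), PDTarget(1.0, 1), 4.0, small_population)
        c = pta(Regimen(dose=8000.0, mode="continuous"), PDTarget(1.0, 4), 4.0, small_population)
        assert a == b == c

    def test_empty_population_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            pta(Regimen(dose=500.0), TARGET_40, 1.0, pd.DataFrame(columns=["CL", "V1", "Q", "V2"]))


class TestWeightedAttainment:
    def test_point_mass_equals_pta(self, small_population):
        r = Regimen(dose=1000.0, interval=8.0)
        dist = MICDistribution(mics=(2.0,), probabilities=(1.0,))
        w = weighted_attainment(r, TARGET_40, dist, small_population)
        assert w == pytest.approx(pta(r, TARGET_40, 2.0, small_population), abs=1e-12)

    def test_eucast_ladder_weights(self):
        probs = np.asarray(EUCAST_PA_MIC_2024.probabilities)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        # printed weight for MIC 0.06 is 4.43% before renormalization
        assert probs[0] == pytest.approx(0.0443 / 0.9495, rel=1e-3)

    def test_random_assignment_agrees_with_expectation(self, small_population):
        r = Regimen(dose=1000.0, interval=8.0)
        exp = weighted_attainment(r, TARGET_40, EUCAST_PA_MIC_2024, small_population)
        diffs = [
            abs(
                weighted_attainment(
                    r, TARGET_40, EUCAST_PA_MIC_2024, small_population,
                    mode="random_assignment", seed=s,
                )
                - exp
            )
            for s in range(5)
        ]
        assert np.mean(diffs) < 0.02

    def test_distribution_validation(self):
        with pytest.raises(ValueError):
            MICDistribution(mics=(1.0, 2.0), probabilities=(0.2, 0.2))
        with pytest.raises(ValueError):
            MICDistribution(mics=(1.0,), probabilities=(-1.0,))


class TestCampaign:
    def test_tidy_table_shape_and_content(self, small_population):
        regimens = [
            Regimen(dose=500.0, interval=8.0),
            Regimen(dose=1000.0, interval=8.0),
            Regimen(dose=2000.0, mode="continuous"),
        ]
        targets = [PDTarget(0.40, 1), PDTarget(1.0, 4)]
        table = campaign(regimens, targets, small_population, seed=11)
        assert len(table) == 3 * 2 * len(MIC_LADDER)
        assert set(table["target"]) == {"40%fT>MIC", "100%fT>4MIC"}
        assert table["pta"].between(0, 1).all()
        assert (table["n"] == len(small_population)).all()
        assert (table["seed"] == 11).all()

    def test_continuous_rows_independent_of_grid_step(self, small_population):
        regimens = [Regimen(dose=4000.0, mode="continuous")]
        targets = [PDTarget(1.0, 1)]
        a = campaign(regimens, targets, small_population, grid_step=0.005)
        b = campaign(regimens, targets, small_population, grid_step=0.05)
        assert np.array_equal(a["pta"].to_numpy(), b["pta"].to_numpy())
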