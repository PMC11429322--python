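"""Two-compartment closed-form kinetics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meropk.model_core import (
    PKParameters,
    Regimen,
    concentration,
    half_lives,
    micro_constants,
    ode_oracle,
)

from conftest import random_parameter_sets

param_floats = st.floats(min_value=0.5, max_value=50.0, allow_nan=False)


class TestMicroConstants:
    def test_typical_values_match_eigenvalue_oracle(self, typical):
        """Hybrid rates equal the eigenvalues of the 2x2 rate matrix."""
        mc = micro_constants(typical)
        A = np.array(
            [[-(mc.k10 + mc.k12), mc.k21], [mc.k12, -mc.k21]]
        )
        eig = np.sort(np.abs(np.linalg.eigvals(A)))
        assert mc.lambda2 == pytest.approx(eig[0], rel=1e-10)
        assert mc.lambda1 == pytest.approx(eig[1], rel=1e-10)
        # frozen values for the published typical subject
        assert mc.k10 == pytest.approx(1.5012, rel=1e-4)
        assert mc.lambda1 == pytest.approx(2.7055, rel=1e-4)
        assert mc.lambda2 == pytest.approx(0.71342, rel=1e-4)

    @given(cl=param_floats, v1=param_floats, q=param_floats, v2=param_floats)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_vieta_identities(self, cl, v1, q, v2):
        mc = micro_constants(PKParameters(cl, v1, q, v2))
        assert mc.lambda1 * mc.lambda2 == pytest.approx(mc.k10 * mc.k21, rel=1e-9)
        assert mc.lambda1 + mc.lambda2 == pytest.approx(
            mc.k10 + mc.k12 + mc.k21, rel=1e-12
        )
        assert mc.lambda1 > mc.lambda2 >= 0

    def test_one_compartment_limit(self):
        mc = micro_constants(PKParameters(CL=12.0, V1=10.0, Q=0.0, V2=4.0))
        assert mc.k10 == pytest.approx(1.2)
        assert mc.lambda1 == pytest.approx(1.2)
        assert mc.lambda2 == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            PKParameters(CL=-1.0, V1=8.0, Q=5.0, V2=4.0)
        with pytest.raises(ValueError):
            PKParameters(CL=12.0, V1=0.0, Q=5.0, V2=4.0)


class TestConcentration:
    def test_matches_ode_oracle_multiple_doses(self, typical):
        r = Regimen(dose=1000.0, infusion_duration=0.5, interval=8.0)
        t = np.linspace(0.01, 24.0, 200)
        closed = concentration(typical, r, t, n_doses=3)
        numeric = ode_oracle(typical, r, t, n_doses=3)
        assert np.max(np.abs(closed - numeric) / closed) < 1e-6

    def test_matches_ode_oracle_random_parameters(self, standard_regimen):
        t = np.linspace(0.05, 24.0, 97)
        for p in random_parameter_sets(10, seed=42):
            closed = concentration(p, standard_regimen, t, n_doses=3)
            numeric = ode_oracle(p, standard_regimen, t, n_doses=3)
            assert np.max(np.abs(closed - numeric) / np.max(closed)) < 1e-6

    def test_steady_state_equals_50_dose_superposition(self, typical, standard_regimen):
        t = np.linspace(0.0, 8.0, 81)
        ss = concentration(typical, standard_regimen, t, steady_state=True)
        sup = concentration(typical, standard_regimen, t + 49 * 8.0, n_doses=50)
        assert np.max(np.abs(ss - sup) / ss) < 1e-8

    def test_time_averaged_steady_state_is_dose_over_cl_tau(self, typical, standard_regimen):
        t = np.linspace(0.0, 8.0, 80001)
        css = concentration(typical, standard_regimen, t, steady_state=True)
        avg = np.trapezoid(css, t) / 8.0
        assert avg == pytest.approx(500.0 / (12.4 * 8.0), rel=1e-6)

    def test_dose_linearity_is_exact(self, typical):
        t = np.linspace(0.0, 12.0, 121)
        r1 = Regimen(dose=500.0, infusion_duration=0.5, interval=8.0)
        r2 = Regimen(dose=1000.0, infusion_duration=0.5, interval=8.0)
        c1 = concentration(typical, r1, t, n_doses=2)
        c2 = concentration(typical, r2, t, n_doses=2)
        assert np.array_equal(2.0 * c1, c2)

    def test_zero_dose_gives_zero(self, typical):
        r = Regimen(dose=0.0, infusion_duration=0.5, interval=8.0)
        assert np.all(concentration(typical, r, np.linspace(0, 8, 17)) == 0.0)

    def test_negative_time_rejected(self, typical, standard_regimen):
        with pytest.raises(ValueError):
            concentration(typical, standard_regimen, np.array([-1.0, 2.0]))

    def test_continuous_plateau(self, typical):
        r = Regimen(dose=2000.0, mode="continuous")
        css = concentration(typical, r, np.array([0.0, 5.0]), steady_state=True)
        assert css == pytest.approx(2000.0 / 24.0 / 12.4, rel=1e-12)
        # the rising curve approaches the plateau after ~10 terminal half-lives
        t10 = 10 * half_lives(typical)["t_half_beta"]
        rising = concentration(typical, r, np.array([t10]))
        assert rising[0] == pytest.approx(css[0], rel=1e-2)

    def test_continuous_rising_matches_ode(self, typical):
        r = Regimen(dose=4000.0, mode="continuous")
        t = np.linspace(0.1, 12.0, 60)
        closed = concentration(typical, r, t)
        numeric = ode_oracle(typical, r, t)
        assert np.max(np.abs(closed - numeric) / closed) < 1e-6

    def test_ode_oracle_zero_rate_is_zero(self, typical):
        r = Regimen(dose=0.0, infusion_duration=0.5, interval=8.0)
        assert np.all(ode_oracle(typical, r, np.linspace(0, 6, 13)) == 0.0)

    def test_ode_area_under_curve_is_dose_over_cl(self, typical, standard_regimen):
        t = np.linspace(0.0, 30.0, 6001)
        numeric = ode_oracle(typical, standard_regimen, t)
        auc = np.trapezoid(numeric, t)
        assert auc == pytest.approx(500.0 / 12.4, rel=5e-4)


class TestHalfLives:
    def test_typical_values(self, typical):
        hl = half_lives(typical)
        assert hl["t_half_alpha"] == pytest.approx(0.2562, rel=1e-3)
        assert hl["t_half_beta"] == pytest.approx(0.9716, rel=1e-3)

    def test_one_compartment_limit(self):
        hl = half_lives(PKParameters(CL=12.0, V1=10.0, Q=0.0, V2=4.0))
        assert hl["t_half_alpha"] == pytest.approx(math.log(2) * 10.0 / 12.0)
        assert math.isinf(hl["t_half_beta"])

    @given(cl=param_floats, v1=param_floats, q=param_floats, v2=param_floats, c=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_joint_scaling_leaves_half_lives_unchanged(self, cl, v1, q, v2, c):
        hl1 = half_lives(PKParameters(cl, v1, q, v2))
        hl2 = half_lives(PKParameters(c * cl, c * v1, c * q, c * v2))
        assert hl1["t_half_alpha"] == pytest.approx(hl2["t_half_alpha"], rel=1e-9)
        assert hl1["t_half_beta"] == pytest.approx(hl2["t_half_beta"], rel=1e-9)


class TestRegimen:
    def test_invalid_infusion_duration(self):
        with pytest.raises(ValueError):
            Regimen(dose=500.0, infusion_duration=9.0, interval=8.0)

    def test_continuous_rate(self):
        assert Regimen(dose=2400.0, mode="continuous").rate == pytest.approx(100.0)
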