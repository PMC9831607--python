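"""Dissociative/noncompetitive rate law: closed form vs full network, IC50."""

import numpy as np
import pytest

from dimerfit.equilibrium import EquilibriumConstants, Totals
from dimerfit.kinetics import (
    FitQualityError,
    KineticDataset,
    KineticParameters,
    RatePoint,
    estimate_ic50,
    limiting_rate_ratio,
    model_ic50,
    predict_initial_rate,
    rate_at_free,
    solve_with_substrate,
)

import oracles


def _kin(**over):
    base = dict(k=0.9, k_prime=0.9, k_dblprime=0.1, K1=1e-5, K2=1e-5, K3=2e-5)
    eq = over.pop("eq", EquilibriumConstants(K_D=80e-9, K_I=1e-6, K_I1=1e-5, K_I2=1e-5))
    base.update(over)
    return KineticParameters(eq=eq, **base)


class TestPredictInitialRate:
    def test_saturating_ceiling_of_tight_dimer(self):
        p = _kin(eq=EquilibriumConstants(K_D=1e-15, K_I=1e-6, K_I1=1e-5, K_I2=1e-5))
        v = predict_initial_rate(1e-1, 0.0, 600e-9, p)
        assert v == pytest.approx(p.k * 600e-9 / 2, rel=1e-3)

    def test_reference_value_against_network_oracle(self, kin_c3):
        # no inhibitor, 25 uM substrate, 600 nM protein: v ~ 1.68e-7 M/s
        v = predict_initial_rate(25e-6, 0.0, 600e-9, kin_c3)
        assert v == pytest.approx(1.68e-7, rel=5e-3)
        st_ = solve_with_substrate(Totals(600e-9, 0.0, 25e-6), kin_c3)
        assert st_.M2S == pytest.approx(1.86e-7, rel=5e-3)
        ref = oracles.oracle_rate(600e-9, 0.0, 25e-6, kin_c3.k, kin_c3.k_prime,
                                  kin_c3.k_dblprime, kin_c3.K1, kin_c3.K2, kin_c3.K3,
                                  kin_c3.eq.K_D, kin_c3.eq.K_I, kin_c3.eq.K_I1, kin_c3.eq.K_I2)
        assert v == pytest.approx(ref, rel=1e-8)

    def test_dead_saturated_complex(self):
        p = _kin(k_dblprime=0.0)
        v = predict_initial_rate(25e-6, 1e-1, 600e-9, p)
        assert v < 1e-3 * predict_initial_rate(25e-6, 0.0, 600e-9, p)

    def test_closed_form_equals_full_numeric_over_random_draws(self, rng):
        # 1e3 random parameter/concentration draws: the quadratic-root path
        # evaluated at the solved free concentrations equals the species sum
        # computed by the independent full-network oracle to <= 1e-6 relative
        for _ in range(1000):
            kd, ki, ki1, ki2 = 10.0 ** rng.uniform(-9, -4, size=4)
            k1, k2, k3 = 10.0 ** rng.uniform(-6, -4, size=3)
            k, kp, kpp = 10.0 ** rng.uniform(-2, 1, size=3)
            p = _kin(k=k, k_prime=kp, k_dblprime=kpp, K1=k1, K2=k2, K3=k3,
                     eq=EquilibriumConstants(K_D=kd, K_I=ki, K_I1=ki1, K_I2=ki2))
            e = 10.0 ** rng.uniform(-8, -6)
            s_tot = 10.0 ** rng.uniform(-6, -4)
            i_tot = 10.0 ** rng.uniform(-7, -4)
            v = predict_initial_rate(s_tot, i_tot, e, p)
            ref = oracles.oracle_rate(e, i_tot, s_tot, k, kp, kpp, k1, k2, k3,
                                      kd, ki, ki1, ki2)
            assert v == pytest.approx(ref, rel=1e-6)

    def test_rate_decreasing_in_inhibitor(self, kin_c3):
        for s in (1e-6, 5e-6, 25e-6, 1e-4):
            I = np.array([0.0, 12e-6, 24e-6, 36e-6])
            v = predict_initial_rate(np.full(4, s), I, 600e-9, kin_c3)
            assert np.all(np.diff(v) < 0)

    def test_substrate_free_limit_matches_equilibrium_core(self, kin_c3):
        from dimerfit.equilibrium import solve_coupled_equilibria

        a = solve_with_substrate(Totals(600e-9, 20e-6, 0.0), kin_c3)
        b = solve_coupled_equilibria(Totals(600e-9, 20e-6), kin_c3.eq)
        for name in ("M", "MI", "M2", "M2I", "M2I2", "I"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-10)

    def test_free_substrate_correction_regimes(self, kin_c3):
        # approximating free S by total S is fine at S >= 50 E, wrong below
        e = 600e-9
        for s_tot, max_err in ((50 * e, 0.01), (2 * e, None)):
            exact = predict_initial_rate(s_tot, 0.0, e, kin_c3)
            approx_v = float(rate_at_free(s_tot, 0.0, e, kin_c3))
            rel = abs(approx_v - exact) / exact
            if max_err is not None:
                assert rel < max_err
            else:
                assert rel > 0.01


class TestLimitingRateRatio:
    def test_dead_complex_gives_zero(self):
        assert limiting_rate_ratio(_kin(k_dblprime=0.0), 25e-6, 600e-9) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_inhibitor_neutral_symmetry(self):
        p = _kin(k_dblprime=0.9, K3=1e-5,
                 eq=EquilibriumConstants(K_D=80e-9, K_I=1e-6, K_I1=1e-6, K_I2=1e-6))
        assert p.eq.K_D_dblprime == pytest.approx(p.eq.K_D, rel=1e-12)
        assert limiting_rate_ratio(p, 25e-6, 600e-9) == pytest.approx(1.0, rel=1e-3)

    def test_noncompetitive_signature_nonzero_plateau(self, kin_c3):
        # k'' << k leaves a small but nonzero residual rate at saturation
        ratio = limiting_rate_ratio(kin_c3, 25e-6, 600e-9)
        assert 0.0 < ratio < 0.5

    def test_zero_rate_rejected(self):
        p = _kin(k=0.0, k_prime=0.0, k_dblprime=0.0)
        with pytest.raises(ZeroDivisionError):
            limiting_rate_ratio(p, 25e-6, 600e-9)


class TestIc50:
    def test_logistic_round_trip(self):
        I = np.logspace(-7, -3, 11)
        y = 0.1 + (1.0 - 0.1) / (1.0 + (I / 7e-6) ** 1.3)
        r = estimate_ic50(I, y)
        assert r.ic50 == pytest.approx(7e-6, rel=1e-3)
        assert r.hill == pytest.approx(1.3, rel=1e-3)

    def test_logistic_matches_model_half_rate(self, kin_c3):
        # inhibition curve generated by the mechanistic model: the logistic
        # midpoint should sit within 10% of the exact half-rate concentration
        I = np.logspace(np.log10(2e-7), np.log10(2e-4), 13)
        v = predict_initial_rate(np.full_like(I, 55e-6), I, 600e-9, kin_c3)
        v = np.concatenate([[predict_initial_rate(55e-6, 0.0, 600e-9, kin_c3)], v])
        I = np.concatenate([[0.0], I])
        fit = estimate_ic50(I, v)
        exact = model_ic50(kin_c3)
        assert fit.ic50 == pytest.approx(exact, rel=0.10)

    def test_increasing_response_rejected(self):
        I = np.logspace(-7, -3, 8)
        with pytest.raises(FitQualityError):
            estimate_ic50(I, np.linspace(0.1, 1.0, 8))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            estimate_ic50(np.array([0.0, 1e-6, 1e-5, 1e-4]), np.array([1.0, 0.8, 0.5, 0.2]))


class TestValidation:
    def test_rate_point_bounds(self):
        with pytest.raises(ValueError):
            RatePoint(-1e-6, 0.0, 1e-8)
        with pytest.raises(ValueError):
            RatePoint(1e-6, 0.0, 1e-8, sigma_rel=0.0)

    def test_dataset_design_requirements(self):
        pts = tuple(RatePoint(1e-5, i * 1e-6, 1e-8) for i in range(5))
        ds = KineticDataset(E_mono=600e-9, points=pts)
        with pytest.raises(ValueError):
            ds.require_fittable()

    def test_parameter_positivity(self):
        with pytest.raises(ValueError):
            _kin(K3=0.0)
        with pytest.raises(ValueError):
            _kin(k=-0.1)
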