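"""Mass-action equilibrium core: closed forms, coupled network, thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dimerfit.equilibrium import (
    EquilibriumConstants,
    Totals,
    delta_g_of_k,
    derive_cycle_constants,
    solve_coupled_equilibria,
    solve_dimer_monomer,
)

import oracles


class TestDimerMonomer:
    def test_closed_form_matches_bisection_oracle(self):
        # 600 nM protein, K_D = 80 nM: M ~ 136.2 nM, 77.3% dimeric
        st_ = solve_dimer_monomer(600e-9, 80e-9)
        assert st_.M == pytest.approx(136.2e-9, rel=1e-3)
        assert st_.M2 == pytest.approx(231.9e-9, rel=1e-3)
        assert st_.dimeric_fraction(600e-9) == pytest.approx(0.773, abs=5e-4)
        # independent check: the root satisfies M^2/M2 = K_D
        assert st_.M**2 / st_.M2 == pytest.approx(80e-9, rel=1e-12)

    def test_no_dissociation_limit(self):
        st_ = solve_dimer_monomer(1e-6, 0.0)
        assert st_.M == 0.0
        assert st_.M2 == pytest.approx(0.5e-6)

    def test_dilution_limit(self):
        fracs = [solve_dimer_monomer(e, 80e-9).dimeric_fraction(e) for e in (1e-9, 1e-11, 1e-13)]
        assert fracs[0] > fracs[1] > fracs[2]
        assert fracs[-1] < 1e-3

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_dimer_monomer(-1e-9, 80e-9)
        with pytest.raises(ValueError):
            solve_dimer_monomer(1e-9, -80e-9)

    @given(
        e=st.floats(1e-12, 1e-3), kd=st.floats(1e-12, 1e-3),
    )
    def test_mass_balance_and_equilibrium_hold(self, e, kd):
        st_ = solve_dimer_monomer(e, kd)
        prot, _, _ = st_.mass_balances()
        assert prot == pytest.approx(e, rel=1e-12)
        assert st_.M**2 / st_.M2 == pytest.approx(kd, rel=1e-9)


class TestCoupledNetwork:
    def test_reduces_to_dimer_monomer_without_inhibitor(self, eq_fret):
        a = solve_coupled_equilibria(Totals(600e-9, 0.0), eq_fret)
        b = solve_dimer_monomer(600e-9, eq_fret.K_D)
        assert a.M == pytest.approx(b.M, rel=1e-12)
        assert a.M2 == pytest.approx(b.M2, rel=1e-12)

    def test_non_binder_reduces_to_dimer_monomer(self):
        c = EquilibriumConstants(K_D=80e-9)  # all inhibitor constants infinite
        a = solve_coupled_equilibria(Totals(600e-9, 1e-4), c)
        b = solve_dimer_monomer(600e-9, 80e-9)
        assert a.M == pytest.approx(b.M, rel=1e-10)
        assert a.I == pytest.approx(1e-4)
        assert a.MI == a.M2I == a.M2I2 == 0.0

    def test_destabilizer_against_grid_oracle(self, eq_fret):
        # saturating C3-like inhibitor drops the dimeric fraction to ~0.57
        st_ = solve_coupled_equilibria(Totals(600e-9, 100e-6), eq_fret)
        assert st_.dimeric_fraction(600e-9) == pytest.approx(0.57, abs=0.01)
        ref = oracles.grid_refine_solve(600e-9, 100e-6, eq_fret.K_D, eq_fret.K_I,
                                        eq_fret.K_I1, eq_fret.K_I2)
        for name in ("M", "MI", "M2", "M2I", "M2I2", "I"):
            assert getattr(st_, name) == pytest.approx(ref[name], rel=1e-4)

    def test_conservation_over_random_draws(self, rng):
        # 1e4 random positive parameter/total draws, log-uniform over [1e-10, 1e-2] M;
        # balances recomputed with the independent species formulas
        from dimerfit import _network

        n_sets, n_each = 50, 200
        for _ in range(n_sets):
            kd, ki, ki1, ki2 = 10.0 ** rng.uniform(-10, -2, size=4)
            e = 10.0 ** rng.uniform(-10, -2, n_each)
            i = 10.0 ** rng.uniform(-10, -2, n_each)
            I, S = _network.solve_free(e, i, 0.0, kd, ki, ki1, ki2)
            sp = _network.species_from_free(I, S, e, kd, ki, ki1, ki2)
            rp, ri, _ = oracles.balance_residuals(sp, e, i, 0.0)
            assert np.abs(rp).max() <= 1e-9
            assert np.abs(ri).max() <= 1e-9

    def test_pairwise_equilibrium_relations(self, rng, eq_fret):
        st_ = solve_coupled_equilibria(Totals(3e-7, 2e-5), eq_fret)
        assert st_.M**2 / st_.M2 == pytest.approx(eq_fret.K_D, rel=1e-6)
        assert st_.M * st_.I / st_.MI == pytest.approx(eq_fret.K_I, rel=1e-6)
        assert st_.M2 * st_.I / st_.M2I == pytest.approx(eq_fret.K_I1, rel=1e-6)
        assert st_.M2I * st_.I / st_.M2I2 == pytest.approx(eq_fret.K_I2, rel=1e-6)

    def test_cycle_closure_spanning_tree_invariance(self, rng):
        # re-deriving (K_I1, K_I2) from the cycle-derived (K_D', K_D'') gives
        # the same network, hence the same state
        for _ in range(25):
            kd, ki, ki1, ki2 = 10.0 ** rng.uniform(-9, -3, size=4)
            c1 = EquilibriumConstants(K_D=kd, K_I=ki, K_I1=ki1, K_I2=ki2)
            kdp, kdpp = derive_cycle_constants(c1)
            c2 = EquilibriumConstants(
                K_D=kd, K_I=ki,
                K_I1=kdp * ki / kd,
                K_I2=kdpp * ki * ki / (kd * (kdp * ki / kd)),
            )
            e, i = 10.0 ** rng.uniform(-9, -3, size=2)
            s1 = solve_coupled_equilibria(Totals(e, i), c1)
            s2 = solve_coupled_equilibria(Totals(e, i), c2)
            for name in ("M", "MI", "M2", "M2I", "M2I2", "I"):
                assert getattr(s1, name) == pytest.approx(getattr(s2, name), rel=1e-8)

    def test_monotonicity_in_inhibitor(self, eq_fret):
        I = np.linspace(0, 2e-4, 40)
        frac_dest = [solve_coupled_equilibria(Totals(6e-7, i), eq_fret).dimeric_fraction(6e-7)
                     for i in I]
        assert np.all(np.diff(frac_dest) <= 1e-12)
        # stabilizer (K_D'' < K_D): dimeric fraction non-decreasing
        stab = EquilibriumConstants(K_D=80e-9, K_I=1e-5, K_I1=1e-6, K_I2=1e-6)
        assert stab.K_D_dblprime < stab.K_D
        frac_stab = [solve_coupled_equilibria(Totals(6e-7, i), stab).dimeric_fraction(6e-7)
                     for i in I]
        assert np.all(np.diff(frac_stab) >= -1e-12)

    def test_saturating_inhibitor_limit(self, eq_fret):
        I_sat = 1e4 * max(eq_fret.K_I, eq_fret.K_I1, eq_fret.K_I2)
        a = solve_coupled_equilibria(Totals(6e-7, I_sat), eq_fret).dimeric_fraction(6e-7)
        b = solve_dimer_monomer(6e-7, eq_fret.K_D_dblprime).dimeric_fraction(6e-7)
        assert abs(a - b) <= 1e-4


class TestCycleConstants:
    def test_tenfold_progressive_destabilization(self, eq_kinetics):
        kdp, kdpp = derive_cycle_constants(eq_kinetics)
        assert kdp / eq_kinetics.K_D == pytest.approx(10.0, rel=1e-12)
        assert kdpp / kdp == pytest.approx(10.0, rel=1e-12)

    def test_neutral_binding(self):
        c = EquilibriumConstants(K_D=80e-9, K_I=1e-6, K_I1=1e-6, K_I2=1e-6)
        kdp, _ = derive_cycle_constants(c)
        assert kdp == pytest.approx(c.K_D, rel=1e-15)

    def test_fivefold_saturated_dimer(self, eq_fret):
        _, kdpp = derive_cycle_constants(eq_fret)
        assert kdpp == pytest.approx(400e-9, rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumConstants(K_D=0.0)
        with pytest.raises(ValueError):
            EquilibriumConstants(K_D=80e-9, K_I=-1e-6)
        # infinity is representable
        c = EquilibriumConstants(K_D=80e-9, K_I=np.inf)
        assert math.isinf(c.K_I)


class TestFreeEnergy:
    def test_standard_state_zero(self):
        assert delta_g_of_k(1.0) == 0.0

    def test_dimer_disruption_values(self):
        assert delta_g_of_k(80e-9, 298.15) == pytest.approx(40.5, abs=0.05)
        assert delta_g_of_k(400e-9, 298.15) == pytest.approx(36.5, abs=0.05)

    def test_additivity(self, rng):
        from dimerfit.equilibrium import R_GAS
        for _ in range(20):
            k1, k2 = 10.0 ** rng.uniform(-9, -3, size=2)
            lhs = delta_g_of_k(k2) - delta_g_of_k(k1)
            rhs = -R_GAS * 298.15 * math.log(k2 / k1) / 1000.0
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            delta_g_of_k(0.0)
        with pytest.raises(ValueError):
            delta_g_of_k(80e-9, -1.0)
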