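"""Closed-form model evaluation: worked values, limits, and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sabrefit as sf
from sabrefit.model import ParameterError, SingularMapError

CONC_GRID = 10.0 ** np.arange(-10.0, -2.9, 0.25)

eps_st = st.floats(0.01, 1.0)
eps0_st = st.floats(0.0, 0.9)
gamma_st = st.floats(1.0, 1e4)
logkd_st = st.floats(-9.0, -4.0)
hill_st = st.floats(0.3, 4.0)


class TestSabreResponse:
    @pytest.mark.parametrize(
        "conc, log_kd, eps, gamma, eps_r0, n, expected",
        [
            # Clark half-maximum at L = Kd
            (1e-6, -6.0, 1.0, 1.0, 0.0, 1.0, 0.5),
            # partial agonist with four-fold gain at L = Kd: 2/3.5
            (1e-6, -6.0, 0.5, 4.0, 0.0, 1.0, 2.0 / 3.5),
            # zero ligand, no constitutive activity
            (0.0, -6.0, 0.7, 3.0, 0.0, 1.0, 0.0),
            # zero-ligand baseline: eps_r0*gamma / (eps_r0*gamma - eps_r0 + 1)
            (0.0, -6.0, 0.7, 3.0, 0.2, 1.0, 0.6 / 1.4),
        ],
    )
    def test_pointwise_values(self, conc, log_kd, eps, gamma, eps_r0, n, expected):
        lig = sf.LigandParams(log_kd=log_kd, eps=eps, hill_n=n)
        pw = sf.PathwayParams(gamma=gamma, eps_r0=eps_r0)
        assert sf.sabre_response(conc, lig, pw) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors_name_offender(self):
        lig = sf.LigandParams(log_kd=-6, eps=0.5)
        pw = sf.PathwayParams(gamma=2.0)
        with pytest.raises(ParameterError, match="conc"):
            sf.sabre_response(-1e-9, lig, pw)
        with pytest.raises(ParameterError, match="hill_n"):
            sf.LigandParams(log_kd=-6, eps=0.5, hill_n=0.0)
        with pytest.raises(ParameterError, match="gamma"):
            sf.PathwayParams(gamma=0.5)
        with pytest.raises(ParameterError, match="eps"):
            sf.LigandParams(log_kd=-6, eps=1.5)

    @given(eps=eps_st, eps0=eps0_st, gamma=gamma_st, log_kd=logkd_st)
    def test_monotone_iff_eps_vs_eps_r0(self, eps, eps0, gamma, log_kd):
        lig = sf.LigandParams(log_kd=log_kd, eps=eps)
        pw = sf.PathwayParams(gamma=gamma, eps_r0=eps0)
        grid = 10.0 ** np.linspace(log_kd - 3, log_kd + 3, 40)
        resp = sf.sabre_response(grid, lig, pw)
        diffs = np.diff(resp)
        if eps > eps0 + 1e-9:
            assert np.all(diffs > 0)
        elif eps < eps0 - 1e-9:
            assert np.all(diffs < 0)
        else:
            assert np.allclose(diffs, 0.0, atol=1e-12)

    @given(eps=eps_st, gamma=gamma_st, log_kd=logkd_st, eps0=eps0_st)
    def test_chain_equivalence_activation_then_amplification(self, eps, gamma,
                                                             log_kd, eps0):
        """amplify(fraction_active(L)) reproduces the closed form at n = 1."""
        lig = sf.LigandParams(log_kd=log_kd, eps=eps)
        pw = sf.PathwayParams(gamma=gamma, eps_r0=eps0)
        grid = 10.0 ** np.linspace(log_kd - 3, log_kd + 3, 30)
        composed = sf.amplify(sf.fraction_active(grid, lig, pw), gamma)
        direct = sf.sabre_response(grid, lig, pw)
        np.testing.assert_allclose(composed, direct, rtol=1e-12)


class TestFractionActive:
    def test_limits_and_midpoint(self):
        lig = sf.LigandParams(log_kd=-6, eps=0.5)
        pw = sf.PathwayParams(gamma=1.0, eps_r0=0.1)
        # at L = Kd, half occupancy: arithmetic mean of the two limits
        assert sf.fraction_active(1e-6, lig, pw) == pytest.approx(0.3)
        assert sf.fraction_active(0.0, lig, pw) == pytest.approx(0.1)
        assert sf.fraction_active(1e2, lig, pw) == pytest.approx(0.5, abs=1e-6)

    def test_rejects_hill_slope(self):
        lig = sf.LigandParams(log_kd=-6, eps=0.5, hill_n=2.0)
        with pytest.raises(ParameterError, match="hill_n"):
            sf.fraction_active(1e-6, lig, sf.PathwayParams(gamma=1.0))


class TestAmplify:
    def test_identity_at_unit_gain_and_worked_value(self):
        assert sf.amplify(0.5, 1.0) == pytest.approx(0.5)
        assert sf.amplify(0.5, 4.0) == pytest.approx(0.8)

    def test_saturation_returns_limit(self):
        assert sf.amplify(1.0, 10.0) == 1.0

    @given(f=st.floats(0.001, 0.999), gamma=gamma_st)
    def test_strictly_increasing_in_both_arguments(self, f, gamma):
        step = sf.amplify(min(f + 1e-4, 0.9999), gamma) - sf.amplify(f, gamma)
        assert step > 0
        if gamma > 1:
            assert sf.amplify(f, gamma) > sf.amplify(f, max(1.0, gamma / 2))


class TestDerivedEc50Emax:
    def test_worked_example(self):
        lig = sf.LigandParams(log_kd=-6.0, eps=0.5)
        pw = sf.PathwayParams(gamma=4.0)
        k_obs, f_max = sf.derived_ec50_emax(lig, pw)
        assert k_obs == pytest.approx(4e-7)
        assert f_max == pytest.approx(0.8)

    def test_clark_limit(self):
        lig = sf.LigandParams(log_kd=-6.0, eps=1.0)
        k_obs, f_max = sf.derived_ec50_emax(lig, sf.PathwayParams(gamma=1.0))
        assert k_obs == pytest.approx(1e-6)
        assert f_max == pytest.approx(1.0)

    def test_full_agonist_left_shift_matches_fig5_design(self):
        """gamma = 21.1 shifts a full agonist with log Kd -6.7 to log EC50 ~ -8."""
        lig = sf.LigandParams(log_kd=-6.7, eps=1.0)
        k_obs, _ = sf.derived_ec50_emax(lig, sf.PathwayParams(gamma=21.1))
        assert np.log10(k_obs) == pytest.approx(-6.7 - np.log10(21.1), abs=1e-12)
        assert np.log10(k_obs) == pytest.approx(-8.0, abs=0.05)

    @given(eps=eps_st, gamma=gamma_st, log_kd=logkd_st)
    def test_agrees_with_numerical_plateau_and_half_point(self, eps, gamma, log_kd):
        lig = sf.LigandParams(log_kd=log_kd, eps=eps)
        pw = sf.PathwayParams(gamma=gamma)
        k_obs, f_max = sf.derived_ec50_emax(lig, pw)
        assert sf.sabre_response(1e6, lig, pw) == pytest.approx(f_max, rel=1e-9)
        assert sf.sabre_response(k_obs, lig, pw) == pytest.approx(f_max / 2, rel=1e-9)


class TestOccupancy:
    def test_half_occupancy_at_kd_any_slope(self):
        for n in (0.5, 1.0, 3.0):
            assert sf.occupancy(1e-7, -7.0, n) == pytest.approx(0.5)

    def test_worked_value(self):
        assert sf.occupancy(1e-6, -7.0, 1.0) == pytest.approx(10.0 / 11.0)

    @given(f=st.floats(0.001, 0.999), log_kd=logkd_st, n=hill_st)
    def test_round_trip(self, f, log_kd, n):
        conc = sf.inverse_occupancy(f, log_kd, n)
        assert sf.occupancy(conc, log_kd, n) == pytest.approx(f, rel=1e-9)

    def test_saturation_is_domain_error(self):
        with pytest.raises(ParameterError, match="f_occup"):
            sf.inverse_occupancy(1.0, -7.0)


class TestResponseFromOccupancy:
    @pytest.mark.parametrize(
        "f, eps, gamma, expected",
        [
            (0.0, 0.5, 7.0, 0.0),
            (0.37, 1.0, 1.0, 0.37),  # identity line for a full agonist, no gain
            (0.5, 1.0, 21.1, 10.55 / 11.05),
        ],
    )
    def test_values(self, f, eps, gamma, expected):
        assert sf.response_from_occupancy(f, eps, gamma) == pytest.approx(expected, rel=1e-12)

    @given(f=st.floats(0.001, 0.999), eps=eps_st, gamma=gamma_st, log_kd=logkd_st)
    def test_equals_response_at_inverse_occupancy(self, f, eps, gamma, log_kd):
        lig = sf.LigandParams(log_kd=log_kd, eps=eps)
        pw = sf.PathwayParams(gamma=gamma)
        conc = sf.inverse_occupancy(f, log_kd)
        assert sf.response_from_occupancy(f, eps, gamma) == pytest.approx(
            sf.sabre_response(conc, lig, pw), rel=1e-9
        )


class TestOperationalModel:
    def test_basic_worked_value_and_limit(self):
        p = sf.OperationalParams(log_KD=-7.0, tau=1.0)
        assert sf.operational_response(1e-7, p, "basic") == pytest.approx(1.0 / 3.0)
        assert sf.operational_response(1e3, p, "basic") == pytest.approx(0.5, abs=1e-9)

    def test_unknown_variant(self):
        with pytest.raises(ParameterError, match="variant"):
            sf.operational_response(1e-7, sf.OperationalParams(log_KD=-7, tau=1.0),
                                    "extended")

    def test_slack_hall_zero_ligand_baseline(self):
        p = sf.OperationalParams(log_KD=-7.0, chi=0.5, eps=0.3)
        # at L=0: chi*KD / (KD + chi*KD) = chi/(1+chi)
        assert sf.operational_response(0.0, p, "slack_hall") == pytest.approx(1.0 / 3.0)

    def test_forward_map_worked_values(self):
        p = sf.sabre_to_operational(-6.7, 1.0, 21.1)
        assert p.tau == pytest.approx(20.1)
        assert p.alpha == pytest.approx(21.1 / 20.1)

    def test_reverse_map_worked_values(self):
        log_kd, eps, gamma = sf.operational_to_sabre(
            sf.OperationalParams(log_KD=-7.0, tau=1.0, alpha=2.0))
        assert (eps, gamma) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_singularities_raise(self):
        with pytest.raises(SingularMapError):
            sf.sabre_to_operational(-7.0, 0.5, 1.0)
        with pytest.raises(SingularMapError):
            sf.operational_to_sabre(sf.OperationalParams(log_KD=-7, tau=1.0, alpha=1.0))

    def test_out_of_range_reverse_eps_warns_unclipped(self):
        with pytest.warns(UserWarning, match="outside"):
            _, eps, _ = sf.operational_to_sabre(
                sf.OperationalParams(log_KD=-7, tau=5.0, alpha=2.0))
        assert eps == pytest.approx(5.0)

    @given(eps=eps_st, gamma=st.floats(1.001, 1e4), log_kd=logkd_st)
    def test_round_trip_identity(self, eps, gamma, log_kd):
        back = sf.operational_to_sabre(sf.sabre_to_operational(log_kd, eps, gamma))
        np.testing.assert_allclose(back, (log_kd, eps, gamma), rtol=1e-9)

    @given(eps=eps_st, gamma=st.floats(1.001, 1e4), log_kd=logkd_st)
    def test_scaled_operational_reproduces_sabre_pointwise(self, eps, gamma, log_kd):
        lig = sf.LigandParams(log_kd=log_kd, eps=eps)
        pw = sf.PathwayParams(gamma=gamma)
        p = sf.sabre_to_operational(log_kd, eps, gamma)
        grid = 10.0 ** np.linspace(log_kd - 3, log_kd + 3, 25)
        np.testing.assert_allclose(
            sf.operational_response(grid, p, "scaled"),
            sf.sabre_response(grid, lig, pw), rtol=1e-10)


class TestBiasPlotCurve:
    def test_balanced_ligand_worked_value(self):
        # gamma 4 vs 20, balanced efficacy, f1 = 0.5 -> 10/12
        assert sf.bias_plot_curve(0.5, 0.7, 0.7, 4.0, 20.0) == pytest.approx(10.0 / 12.0)

    def test_zero_and_identity(self):
        assert sf.bias_plot_curve(0.0, 0.5, 0.1, 4.0, 20.0) == 0.0
        f = np.linspace(0, 1, 11)
        np.testing.assert_allclose(sf.bias_plot_curve(f, 0.6, 0.6, 5.0, 5.0), f)

    @given(eps1=eps_st, eps2=eps_st, g1=st.floats(1.0, 100.0), g2=st.floats(1.0, 100.0),
           log_kd=logkd_st)
    def test_matches_parametric_evaluation_through_concentration(self, eps1, eps2,
                                                                 g1, g2, log_kd):
        lig = sf.LigandParams(log_kd=log_kd, eps={"P1": eps1, "P2": eps2})
        pw1 = sf.PathwayParams(gamma=g1, name="P1")
        pw2 = sf.PathwayParams(gamma=g2, name="P2")
        grid = 10.0 ** np.linspace(log_kd - 3, log_kd + 3, 20)
        f1 = sf.sabre_response(grid, lig, pw1)
        f2 = sf.sabre_response(grid, lig, pw2)
        np.testing.assert_allclose(
            sf.bias_plot_curve(f1, eps1, eps2, g1, g2), f2, rtol=1e-9)


class TestLadderReductions:
    """Constrained general form equals each printed reduced formula exactly."""

    GRID = CONC_GRID

    def test_minimal_two_state(self):
        eps, gamma, kd = 0.4, 8.0, 1e-7
        lig = sf.LigandParams(log_kd=-7.0, eps=eps)
        direct = eps * gamma * self.GRID / ((eps * gamma - eps + 1) * self.GRID + kd)
        np.testing.assert_allclose(
            sf.sabre_response(self.GRID, lig, sf.PathwayParams(gamma=gamma)),
            direct, rtol=1e-13)

    def test_emax(self):
        eps, kd = 0.4, 1e-7
        lig = sf.LigandParams(log_kd=-7.0, eps=eps)
        np.testing.assert_allclose(
            sf.sabre_response(self.GRID, lig, sf.PathwayParams(gamma=1.0)),
            eps * self.GRID / (self.GRID + kd), rtol=1e-13)

    def test_clark(self):
        lig = sf.LigandParams(log_kd=-7.0, eps=1.0)
        np.testing.assert_allclose(
            sf.sabre_response(self.GRID, lig, sf.PathwayParams(gamma=1.0)),
            self.GRID / (self.GRID + 1e-7), rtol=1e-13)

    def test_full_model_with_constitutive_activity(self):
        eps, eps0, gamma, kd = 0.6, 0.1, 5.0, 1e-7
        lig = sf.LigandParams(log_kd=-7.0, eps=eps)
        pw = sf.PathwayParams(gamma=gamma, eps_r0=eps0)
        direct = (eps * gamma * self.GRID + eps0 * gamma * kd) / (
            (eps * gamma - eps + 1) * self.GRID + (eps0 * gamma - eps0 + 1) * kd)
        np.testing.assert_allclose(sf.sabre_response(self.GRID, lig, pw),
                                   direct, rtol=1e-13)


class TestModelSpecLadder:
    @pytest.mark.parametrize(
        "level, n_p",
        [("clark", 1), ("emax", 2), ("minimal_two_state", 3),
         ("full", 4), ("full_hill", 5)],
    )
    def test_canonical_levels_and_free_counts(self, level, n_p):
        red = sf.reduce_model(sf.ModelSpec.from_ladder(level))
        assert red.ladder_level == level
        assert red.n_p == n_p

    def test_contradictory_constraints_raise(self):
        spec = sf.ModelSpec.clark()
        bad = dict(spec.rules)
        bad["gamma"] = sf.ParamRule.free("pathway")
        with pytest.raises(ParameterError, match="contradicted"):
            sf.ModelSpec(rules=bad, ladder_level="clark")

    def test_noncanonical_fixed_value_raises(self):
        spec = sf.ModelSpec.clark()
        bad = dict(spec.rules)
        bad["eps"] = sf.ParamRule.fixed(0.5, share="compound_pathway")
        with pytest.raises(ParameterError, match="eps"):
            sf.ModelSpec(rules=bad, ladder_level="clark")

    def test_unknown_level_raises(self):
        with pytest.raises(ParameterError, match="ladder"):
            sf.ModelSpec.from_ladder("operational")
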