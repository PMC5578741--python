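"""Unit tests for the receptor free-energy model and adaptation kinetics."""

import math
import warnings

import numpy as np
import pytest

from thermotax import (
    DomainError,
    InvalidParameterError,
    KineticsParams,
    LigandModel,
    ModelParams,
    ThermalResponseCurve,
    TrimerComposition,
    ensemble_adapted_activity,
    find_inversion_temperature,
    integrate_methylation,
    ligand_free_energy_offset,
    methylation_rate,
    receptor_free_energy,
    solve_steady_state_methylation,
    steady_state_residual,
    thermal_response_curve,
    trimer_activity,
    trimer_mixing_distribution,
)


class TestLigandFreeEnergy:
    @pytest.mark.parametrize(
        "L, expected",
        [
            (0.0, 0.0),
            (100.0, math.log(11.0 / 1.1)),  # = ln 10
            (1e12, math.log(100.0)),        # saturation limit ln(Kon/Koff)
        ],
    )
    def test_binding_formula(self, L, expected):
        lig = LigandModel(f0_zero=0.0, Kon=1000.0, Koff=10.0, L=L)
        assert ligand_free_energy_offset(lig) == pytest.approx(expected, abs=1e-9)

    def test_attractant_monotone_increasing_in_ligand(self):
        offsets = [
            ligand_free_energy_offset(LigandModel(0.5, Kon=1000.0, Koff=10.0, L=L))
            for L in (0.0, 1.0, 10.0, 100.0, 1e4)
        ]
        assert offsets[0] == 0.5
        assert np.all(np.diff(offsets) > 0)

    def test_invalid_dissociation_constants(self):
        with pytest.raises(InvalidParameterError):
            LigandModel(0.0, Kon=-1.0, Koff=10.0, L=0.0)
        with pytest.raises(InvalidParameterError):
            LigandModel(0.0, Kon=10.0, Koff=0.0, L=0.0)


class TestReceptorFreeEnergy:
    @pytest.mark.parametrize(
        "f0, T, m, expected",
        [
            (0.0, 24.0, 4.0, 0.0),   # T = T0 and g0 = 0 kill every term
            (0.0, 30.0, 6.0, 0.0),   # m = f1/g1, the temperature-insensitive level
            (1.5, 27.0, 2.0, 3.9),   # 1.5 + 3*1.2 - 3*0.2*2
        ],
    )
    def test_linear_expansion(self, f0, T, m, expected, params):
        assert receptor_free_energy(f0, T, m, params) == pytest.approx(expected, abs=1e-12)

    def test_methylation_domain_checked(self, params):
        with pytest.raises(DomainError):
            receptor_free_energy(0.0, 30.0, -0.1, params)
        with pytest.raises(DomainError):
            receptor_free_energy(0.0, 30.0, 8.1, params)
        # internal callers may evaluate frozen states outside the box
        assert np.isfinite(receptor_free_energy(0.0, 30.0, 12.0, params, check=False))


class TestTrimerActivity:
    def test_logistic_at_zero_free_energy(self, params, tar_only, no_ligand):
        assert trimer_activity(tar_only, no_ligand, 24.0, 4.0, params) == 0.5

    def test_closed_form_third(self, params, tar_only):
        # F = 3 * f_Tar = ln 2  ->  A = 1/3
        f0 = {"Tar": math.log(2.0) / 3.0, "Tsr": 0.0}
        assert trimer_activity(tar_only, f0, 24.0, 0.0, params) == pytest.approx(1 / 3)

    def test_saturation_without_overflow(self, params, tar_only):
        lo = trimer_activity(tar_only, {"Tar": 500.0, "Tsr": 0.0}, 24.0, 0.0, params)
        hi = trimer_activity(tar_only, {"Tar": -500.0, "Tsr": 0.0}, 24.0, 0.0, params)
        assert lo == pytest.approx(0.0, abs=1e-200)
        assert hi == pytest.approx(1.0, abs=1e-15)


class TestMixingDistribution:
    @pytest.mark.parametrize(
        "p_tar, expected",
        [
            (1.0, (1.0, 0.0, 0.0, 0.0)),
            (0.5, (1 / 8, 3 / 8, 3 / 8, 1 / 8)),
            (0.25, (1 / 64, 9 / 64, 27 / 64, 27 / 64)),
        ],
    )
    def test_binomial_weights(self, p_tar, expected):
        comps = trimer_mixing_distribution(p_tar)
        assert [c.n_tar for c in comps] == [3, 2, 1, 0]
        assert [c.weight for c in comps] == pytest.approx(list(expected), abs=1e-15)
        assert sum(c.weight for c in comps) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            trimer_mixing_distribution(1.5)


class TestMethylationKinetics:
    def test_pure_demethylation_at_full_activity(self):
        p = ModelParams(N0=0.0)
        kin = KineticsParams(gamma_R=0.5, gamma_B=1.3)
        assert methylation_rate(4.0, 1.0, kin, p) == pytest.approx(-1.3)

    def test_boundary_flux_keeps_box_invariant(self, params):
        kin = KineticsParams()
        for A in (0.0, 0.3, 1.0):
            assert methylation_rate(0.0, A, kin, params) >= 0.0
            assert methylation_rate(float(params.mtot), A, kin, params) <= 0.0

    def test_fixed_point_at_set_point_activity(self):
        p = ModelParams(N0=0.0)
        kin = KineticsParams(gamma_R=0.7, gamma_B=2.1)
        A_star = kin.gamma_R / (kin.gamma_R + kin.gamma_B)
        assert methylation_rate(3.0, A_star, kin, p) == pytest.approx(0.0, abs=1e-15)


class TestIntegration:
    def test_fixed_point_stays_constant(self, params, tar_only, no_ligand):
        st = solve_steady_state_methylation(tar_only, no_ligand, 30.0, params, unbounded=False)
        act = lambda m, T: trimer_activity(tar_only, no_ligand, T, m, params)
        _, m = integrate_methylation(st.m_ss, act, 30.0, params=params, t_end=50.0)
        assert np.max(np.abs(m - st.m_ss)) < 1e-6

    def test_converges_to_algebraic_steady_state(self, params, tar_only, no_ligand):
        st = solve_steady_state_methylation(tar_only, no_ligand, 30.0, params, unbounded=False)
        act = lambda m, T: trimer_activity(tar_only, no_ligand, T, m, params)
        _, m = integrate_methylation(0.0, act, 30.0, params=params, t_end=2000.0)
        assert abs(m[-1] - st.m_ss) < 1e-4

    def test_forced_full_activity_linear_decay(self):
        # A = 1, N0 = 0, gamma_B = 1: dm/dt = -1 until m hits 0, then 0
        p = ModelParams(N0=0.0)
        kin = KineticsParams(gamma_R=0.5, gamma_B=1.0)
        t, m = integrate_methylation(2.0, lambda m, T: 1.0, 30.0, kin, p,
                                     t_end=3.0, n_eval=7)
        expected = np.maximum(2.0 - t, 0.0)
        assert np.allclose(m, expected, atol=1e-4)


class TestSteadyState:
    def test_perfect_adaptation_returns_set_point(self, tar_only, no_ligand):
        p = ModelParams(N0=0.0)
        st = solve_steady_state_methylation(tar_only, no_ligand, 30.0, p)
        assert st.A == pytest.approx(1 / 3, abs=1e-12)
        # analytic root of 3*(7.2 - 1.2 m) = ln 2
        assert st.m_ss == pytest.approx((7.2 - math.log(2.0) / 3.0) / 1.2, abs=1e-10)

    def test_asymptotic_methylation_approaches_f1_over_g1(self, params, tar_only, no_ligand):
        m_prev = -np.inf
        for dT in (6.0, 30.0, 100.0, 1000.0):
            st = solve_steady_state_methylation(
                tar_only, no_ligand, params.T0 + dT, params, unbounded=False
            )
            assert st.m_ss < params.f1 / params.g1  # from below
            assert st.m_ss > m_prev                 # monotone in T
            m_prev = st.m_ss
        assert abs(m_prev - params.f1 / params.g1) < 0.05

    def test_interior_root_has_small_residual(self, params, tar_only, no_ligand):
        st = solve_steady_state_methylation(tar_only, no_ligand, 33.0, params, unbounded=False)
        assert not st.boundary
        assert abs(steady_state_residual(st.m_ss, tar_only, no_ligand, 33.0, params)) < 1e-10

    def test_saturated_ligand_pins_boundary_at_reference_temperature(self, params, tar_only):
        # at T = T0 with g0 = 0 activity is ~0 at f0 = 15; methylation pins at mtot
        st = solve_steady_state_methylation(
            tar_only, {"Tar": 15.0, "Tsr": 0.0}, 24.0, params, unbounded=False
        )
        assert st.m_ss == pytest.approx(params.mtot, abs=1e-6)


class TestEnsemble:
    def test_symmetric_ligand_collapses_to_single_trimer(self, params):
        f0 = {"Tar": 0.7, "Tsr": 0.7}
        ens = ensemble_adapted_activity(0.5, f0, 30.0, params)
        activities = [s.A for s in ens.states]
        assert np.ptp(activities) < 1e-12
        assert ens.A_bar == pytest.approx(activities[0])

    def test_perfect_adaptation_average_is_set_point(self):
        p = ModelParams(N0=0.0)
        ens = ensemble_adapted_activity(0.5, {"Tar": 3.0, "Tsr": 0.0}, 30.0, p)
        assert ens.A_bar == pytest.approx(p.A0, abs=1e-12)

    def test_methylation_increases_with_tar_content_under_measp(self, params):
        # Tar-containing trimers adapt near saturation under saturating MeAsp
        ens = ensemble_adapted_activity(0.5, {"Tar": 15.0, "Tsr": 0.0}, 30.0, params)
        m_by_ntar = {s.composition.n_tar: s.m_ss for s in ens.states}
        assert m_by_ntar[0] < m_by_ntar[1] < m_by_ntar[2] < m_by_ntar[3]

    def test_ligand_monotonicity_of_methylation(self, params, tar_only):
        m_vals = [
            solve_steady_state_methylation(
                tar_only, {"Tar": f0, "Tsr": 0.0}, 30.0, params, unbounded=False
            ).m_ss
            for f0 in (0.0, 0.5, 1.5, 2.5, 5.0, 15.0)
        ]
        assert np.all(np.diff(m_vals) >= 0)


class TestThermalResponse:
    def test_single_receptor_curves_keep_constant_sign(self, params):
        signs = {}
        for f0 in (0.0, 0.5, 1.5, 2.5):
            curve = thermal_response_curve(1.0, {"Tar": f0, "Tsr": 0.0}, params=params)
            s = np.sign(curve.R)
            assert np.all(s == s[0]), f"sign change at f0={f0}"
            assert curve.T_inv is None
            signs[f0] = s[0]
        assert signs[0.0] < 0  # no ligand: thermophilic
        assert signs[2.5] > 0  # strong ligand: cryophilic

    def test_mixed_ensemble_inverts_once(self, params):
        curve = thermal_response_curve(0.5, {"Tar": 15.0, "Tsr": 0.0}, params=params)
        flips = np.flatnonzero(curve.R[:-1] * curve.R[1:] < 0)
        assert len(flips) == 1
        assert curve.R[flips[0]] < 0 < curve.R[flips[0] + 1]  # thermophilic -> cryophilic
        assert curve.T_grid[0] < curve.T_inv < curve.T_grid[-1]
        assert curve.classes[0] == "thermophilic"
        assert curve.classes[-1] == "cryophilic"

    def test_perfect_adaptation_removes_inversion(self):
        p = ModelParams(N0=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curve = thermal_response_curve(0.5, {"Tar": 15.0, "Tsr": 0.0}, params=p)
        s = np.sign(curve.R)
        assert np.all(s == s[0])
        assert curve.T_inv is None

    def test_re_adapted_response_vanishes_under_perfect_adaptation(self):
        p = ModelParams(N0=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curve = thermal_response_curve(
                0.5, {"Tar": 15.0, "Tsr": 0.0}, params=p, mode="re_adapted"
            )
        assert np.allclose(curve.R, 0.0, atol=1e-10)

    def test_normalization_is_positive(self, params):
        curve = thermal_response_curve(1.0, {"Tar": 0.0, "Tsr": 0.0}, params=params)
        assert curve.delta_A_norm > 0


class TestInversionTemperature:
    def _curve(self, T, R):
        n = len(T)
        return ThermalResponseCurve(
            T_grid=np.asarray(T, float), R=np.asarray(R, float), delta_A_norm=1.0,
            classes=["none"] * n, A_bar=np.zeros(n), m_ss=np.zeros((n, 4)),
        )

    def test_no_sign_change_gives_none(self):
        assert find_inversion_temperature(self._curve([24, 27, 30], [-0.3, -0.2, -0.1])) is None

    def test_symmetric_crossing_interpolates_midpoint(self):
        assert find_inversion_temperature(
            self._curve([30, 33], [-0.1, 0.1])
        ) == pytest.approx(31.5)
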