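"""Model core: source term, ODE right-hand side, relaxation, integration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ectsim.model import (
    AVOGADRO,
    ModelParameters,
    ModelState,
    SolverConfig,
    derivatives,
    equilibration_ceiling,
    molecules_per_cell,
    permeability_coefficient,
    relax_closed_form,
    renkin_hindrance,
    simulate,
    source_current,
)
from ectsim.waveforms import PulseSegment, PulseTrain, make_monopolar_train


class TestSourceCurrent:
    def test_value_at_conventional_field(self, params):
        # direct evaluation: 1e-6 * 1.4 * 5e-9 * 1.2e5 / (0.258 * 1.062e-10)
        expected = (1e-6 * 1.4 * 5e-9 * 1.2e5) / (258e-3 * 12 * 8.85e-12)
        assert expected == pytest.approx(30.657, rel=1e-4)
        assert source_current(1.2e5, params) == pytest.approx(expected, rel=1e-12)

    def test_zero_field_gives_zero(self, params):
        assert source_current(0.0, params) == 0.0

    @given(E=st.floats(1e3, 1e7), factor=st.floats(0.1, 10))
    def test_linearity_in_field(self, E, factor):
        p = ModelParameters()
        assert source_current(factor * E, p) == pytest.approx(
            factor * source_current(E, p), rel=1e-12
        )

    def test_sign_follows_field(self, params):
        assert source_current(-1e5, params) < 0 < source_current(1e5, params)


class TestDerivatives:
    def test_origin_is_fixed_point(self, params):
        s = ModelState(0.0, 0.0, 0.0, 0.0, 0.0)
        assert np.all(derivatives(s, 0.0, params) == 0.0)

    def test_n_formation_rate_at_unit_voltage(self, params):
        s = ModelState(0.0, 1.0, 0.0, 0.0, 0.0)
        dU, dN, dM, dX = derivatives(s, 0.0, params)
        assert dN == pytest.approx(params.alpha)  # alpha * U^2 with U = 1
        assert dM == 0.0 and dX == 0.0

    def test_voltage_sign_symmetry(self, params):
        s_pos = ModelState(0.0, 2.0, 1e-8, 1e-8, 0.1)
        s_neg = ModelState(0.0, -2.0, 1e-8, 1e-8, 0.1)
        d_pos = derivatives(s_pos, 5.0, params)
        d_neg = derivatives(s_neg, -5.0, params)
        assert d_neg[0] == pytest.approx(-d_pos[0], rel=1e-12)
        np.testing.assert_allclose(d_neg[1:], d_pos[1:], rtol=1e-12)


class TestRelaxClosedForm:
    def test_pure_n_decay_when_m_zero(self, params):
        s0 = ModelState(0.0, 0.0, 1e-6, 0.0, 0.2)
        out = relax_closed_form(s0, 1e7, params)
        assert out.N == pytest.approx(1e-6 * math.exp(-params.beta * 1e7), rel=1e-12)
        assert out.M == 0.0
        assert out.X == pytest.approx(0.2, rel=1e-12)

    def test_infinite_time_plateau(self, params):
        # X(inf) = 1 - exp(-xi * M0 / eta) from X0 = 0
        M0 = 1e-8
        s0 = ModelState(0.0, 0.0, 0.0, M0, 0.0)
        out = relax_closed_form(s0, 1e13, params)
        expected = 1.0 - math.exp(-params.xi * M0 / params.eta)
        assert out.X == pytest.approx(expected, rel=1e-9)

    @given(
        N0=st.floats(0, 1e-6),
        M0=st.floats(0, 1e-6),
        X0=st.floats(0, 0.9),
        dtau=st.floats(1e3, 1e9),
    )
    def test_agrees_with_numeric_integration(self, N0, M0, X0, dtau):
        """Closed form vs adaptive ODE solution of the field-free system."""
        p = ModelParameters()
        s0 = ModelState(0.0, 0.0, N0, M0, X0)
        out = relax_closed_form(s0, dtau, p)
        sol = solve_ivp(
            lambda t, y: derivatives(y, 0.0, p),
            (0.0, dtau),
            [0.0, N0, M0, X0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-16,
        )
        assert sol.success
        np.testing.assert_allclose(
            [out.N, out.M, out.X], sol.y[1:, -1], rtol=1e-6, atol=1e-14
        )

    def test_degenerate_equal_rates(self):
        p = ModelParameters(beta=4e-9, eta=4e-9)
        s0 = ModelState(0.0, 0.0, 1e-7, 1e-7, 0.0)
        dtau = 1e8
        out = relax_closed_form(s0, dtau, p)
        # N' = -beta N + eta M0 e^{-eta tau} with beta == eta
        expected_N = (1e-7 + p.eta * 1e-7 * dtau) * math.exp(-p.beta * dtau)
        assert out.N == pytest.approx(expected_N, rel=1e-9)

    def test_negative_interval_rejected(self, params):
        with pytest.raises(ValueError):
            relax_closed_form(ModelState(0, 0, 0, 0, 0), -1.0, params)


class TestHindranceAndPermeability:
    def test_unhindered_limit(self):
        assert renkin_hindrance(0.0) == pytest.approx(1.0)

    def test_cisplatin_defect_ratio(self):
        # direct polynomial evaluation at lambda = 0.725
        lam = 0.725
        expected = (1 - lam) ** 2 * (1 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)
        assert expected == pytest.approx(6.11e-3, rel=2e-3)
        assert renkin_hindrance(lam) == pytest.approx(expected, rel=1e-12)

    def test_pore_filling_limit(self):
        assert renkin_hindrance(0.999999) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("lam", [-0.1, 1.0, 1.5])
    def test_domain_errors(self, lam):
        with pytest.raises(ValueError):
            renkin_hindrance(lam)

    def test_permeability_from_first_principles(self, params):
        # 3 H(lam) D tau_RC / (r h); close to but not equal to the adopted
        # literature constant 8.45e-4 (see docs on the ~3.5% discrepancy)
        xi = permeability_coefficient(params)
        assert xi == pytest.approx(8.16e-4, rel=1e-2)
        assert xi != params.xi
        assert abs(xi - params.xi) / params.xi < 0.05

    def test_linearity_in_diffusivity(self, params):
        p2 = ModelParameters(D=2 * params.D)
        assert permeability_coefficient(p2) == pytest.approx(
            2 * permeability_coefficient(params), rel=1e-12
        )


class TestMoleculeConversion:
    def test_zero_uptake(self):
        assert molecules_per_cell(0.0, 50e-6, 7.5e-6) == 0.0

    def test_equilibration_ceiling_at_50uM(self, params):
        # full equilibration: X_e * (4/3 pi r^3 in L) * N_A
        vol_L = 4.0 / 3.0 * math.pi * (7.5e-6) ** 3 * 1e3
        expected = 50e-6 * vol_L * AVOGADRO
        assert expected == pytest.approx(5.32e7, rel=1e-3)
        assert equilibration_ceiling(50e-6, params.r) == pytest.approx(
            expected, rel=1e-12
        )

    @given(X=st.floats(0, 1), c=st.floats(0, 1e-4), factor=st.floats(0.1, 5))
    def test_linearity_in_concentration(self, X, c, factor):
        base = molecules_per_cell(X, c, 7.5e-6)
        assert molecules_per_cell(X, factor * c, 7.5e-6) == pytest.approx(
            factor * base, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            molecules_per_cell(1.5, 1e-6, 7.5e-6)
        with pytest.raises(ValueError):
            molecules_per_cell(0.5, -1e-6, 7.5e-6)


class TestSimulate:
    def test_zero_field_train_stays_at_origin(self, params):
        train = PulseTrain("off", (PulseSegment(1e-3, 0.0),))
        traj = simulate(train, params, t_end=10.0)
        f = traj.final
        assert f.U == f.N == f.M == f.X == 0.0

    def test_polarity_symmetry(self, params):
        train = make_monopolar_train(2, 100e-6, 100.0, 1.2e5)
        cfg = SolverConfig(t_end_reference="train_start")
        pos = simulate(train, params, t_end=1.0, solver=cfg).final
        neg = simulate(train.scaled(-1.0), params, t_end=1.0, solver=cfg).final
        assert neg.N == pytest.approx(pos.N, rel=1e-6)
        assert neg.M == pytest.approx(pos.M, rel=1e-6)
        assert neg.X == pytest.approx(pos.X, rel=1e-6)

    def test_hybrid_matches_brute_force_on_short_train(self, params):
        train = make_monopolar_train(3, 100e-6, 10.0, 1.2e5)
        hybrid = simulate(
            train, params, t_end=2.0, solver=SolverConfig(t_end_reference="train_start")
        ).final
        brute = simulate(
            train,
            params,
            t_end=2.0,
            solver=SolverConfig(
                t_end_reference="train_start", use_closed_form_gaps=False
            ),
        ).final
        assert hybrid.X == pytest.approx(brute.X, rel=1e-6)
        assert hybrid.N == pytest.approx(brute.N, rel=1e-6)
        assert hybrid.M == pytest.approx(brute.M, rel=1e-6)

    def test_trajectory_invariants_on_short_train(self, params):
        train = make_monopolar_train(2, 100e-6, 10.0, 1.2e5)
        traj = simulate(train, params, t_end=60.0)
        taus = np.array([s.tau for s in traj.samples])
        X = np.array([s.X for s in traj.samples])
        assert np.all(np.diff(taus) > 0)
        assert np.all(np.diff(X) >= -1e-12)
        for s in traj.samples:
            assert s.N >= 0 and s.M >= 0 and 0.0 <= s.X <= 1.0

    def test_solver_tolerance_convergence(self, params):
        train = make_monopolar_train(2, 100e-6, 10.0, 1.2e5)
        loose = simulate(train, params, t_end=60.0).final.X
        tight = simulate(
            train, params, t_end=60.0, solver=SolverConfig(rtol=5e-9, atol=5e-13)
        ).final.X
        assert tight == pytest.approx(loose, rel=1e-3)

    def test_train_start_reference_shorter_than_train_rejected(self, params):
        train = make_monopolar_train(8, 100e-6, 1.0, 1.2e5)
        with pytest.raises(ValueError):
            simulate(
                train, params, t_end=1.0, solver=SolverConfig(t_end_reference="train_start")
            )

    def test_final_time_matches_request(self, params):
        train = make_monopolar_train(1, 100e-6, 1.0, 1.2e5)
        traj = simulate(train, params, t_end=30.0)
        expected_tau = (train.duration + 30.0) / params.tau_RC
        assert traj.final.tau == pytest.approx(expected_tau, rel=1e-9)

    def test_trajectory_export_columns(self, params):
        train = make_monopolar_train(1, 100e-6, 1.0, 1.2e5)
        df = simulate(train, params, t_end=1.0).to_frame(params.tau_RC)
        assert list(df.columns) == ["t_s", "tau", "U", "N", "M", "X"]
        assert df["t_s"].iloc[-1] == pytest.approx(train.duration + 1.0)


class TestParameterValidation:
    def test_defaults_are_consistent(self):
        p = ModelParameters()
        assert p.lambda_m == pytest.approx(0.725)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(D=0.0)

    def test_radius_ratio_must_be_fractional(self):
        with pytest.raises(ValueError):
            ModelParameters(rho_s=1.0e-9, rho_d=0.8e-9)
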