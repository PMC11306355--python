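"""Decomposition recursion: components, partial sums, conservation, diagnostics."""

import json

import numpy as np
import pytest

from ntdm import (
    BilinearTerm,
    FracSeries,
    Kernel,
    KernelSpec,
    adomian_level,
    rk4_classical,
    solve,
    truncation_diagnostic,
)
from ntdm.engine import FracODESystem, evaluate_solution


class TestSystemValidation:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FracODESystem(("x", "y"), (0.0,), ((0.0, 0.0), (0.0, 0.0)), (), (1.0, 2.0))

    def test_bilinear_index_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FracODESystem(
                ("x",), (0.0,), ((0.0,),), (BilinearTerm(0, 0, 1, 1.0),), (1.0,)
            )

    def test_non_finite_coefficient_rejected(self):
        with pytest.raises(ValueError):
            FracODESystem(("x",), (float("nan"),), ((0.0,),), (), (1.0,))

    def test_unknown_state_name_rejected(self, smoking_system):
        with pytest.raises(KeyError):
            smoking_system.index("Z")


class TestAdomianLevels:
    def test_level_zero_is_product_of_initials(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2)
        a0 = adomian_level(sol.components, 0, 2, 0)  # V*T at level 0
        assert a0.coefficient(0, 0) == pytest.approx(800.0)  # 40 * 20

    def test_level_one_is_cross_convolution(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2)
        v, t = 0, 2
        a1 = adomian_level(sol.components, v, t, 1)
        expect = (
            sol.components[v][0] * sol.components[t][1]
            + sol.components[v][1] * sol.components[t][0]
        )
        assert a1.allclose(expect, rtol=1e-14)

    def test_vanishes_when_level_one_components_are_zero(self):
        system = FracODESystem(
            ("x", "y"), (0.0, 0.0), ((0.0, 0.0), (0.0, 0.0)), (), (1.0, 2.0)
        )
        sol = solve(system, KernelSpec(Kernel.CAPUTO, 0.5), 2)
        assert adomian_level(sol.components, 0, 1, 1).is_zero()

    def test_level_beyond_depth_rejected(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 1)
        with pytest.raises(ValueError):
            adomian_level(sol.components, 0, 2, 2)


# first-order component coefficients obtained by substituting the default
# rates into the assembled right-hand side at the initial point
LEVEL1_COEFS = {"V": -113.0, "G": 111.48, "T": -16.48, "O": 13.4, "W": 1.35}


class TestRecursion:
    @pytest.mark.parametrize("mu", [0.6, 1.0])
    def test_caputo_level_one_coefficients(self, smoking_system, mu):
        from scipy.special import gamma

        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, mu), 1)
        for name, c in LEVEL1_COEFS.items():
            i = smoking_system.index(name)
            comp = sol.components[i][1]
            assert comp.coefficient(0, 1) == pytest.approx(c / gamma(1 + mu), rel=1e-12)

    def test_cf_level_one_carries_affine_bracket(self, smoking_system):
        # W1 = 1.35 * (1 - mu + mu*tau) under the exponential kernel
        mu = 0.8
        sol = solve(smoking_system, KernelSpec(Kernel.CF, mu), 1)
        w1 = sol.components[smoking_system.index("W")][1]
        assert w1.coefficient(0, 0) == pytest.approx(1.35 * (1 - mu))
        assert w1.coefficient(1, 0) == pytest.approx(1.35 * mu)

    def test_all_zero_system_has_empty_higher_levels(self):
        system = FracODESystem(
            ("x", "y"), (0.0, 0.0), ((0.0, 0.0), (0.0, 0.0)), (), (3.0, 4.0)
        )
        sol = solve(system, KernelSpec(Kernel.ABC, 0.7), 4)
        for comps in sol.components:
            assert all(c.is_zero() for c in comps[1:])

    def test_level_zero_equals_initial_constants(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CF, 0.5), 0)
        for i, x0 in enumerate(smoking_system.initial):
            assert sol.components[i][0] == FracSeries.constant(x0)

    def test_component_order_bounds(self, smoking_system):
        """Level-k terms never exceed k operator applications: b <= k for the
        power-law/Mittag-Leffler kernels, a <= k for the exponential kernel."""
        for kern, attr in [(Kernel.CAPUTO, "max_b"), (Kernel.ABC, "max_b"), (Kernel.CF, "max_a")]:
            sol = solve(smoking_system, KernelSpec(kern, 0.8), 3)
            for comps in sol.components:
                for k, comp in enumerate(comps):
                    assert getattr(comp, attr)() <= k

    def test_negative_truncation_order_rejected(self, smoking_system):
        with pytest.raises(ValueError):
            solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), -1)

    def test_unknown_source_mode_rejected(self, smoking_system):
        with pytest.raises(ValueError):
            solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2, source_mode="sometimes")

    def test_determinism_bit_identical(self, smoking_system):
        spec = KernelSpec(Kernel.ABC, 0.83)
        a = solve(smoking_system, spec, 3)
        b = solve(smoking_system, spec, 3)
        for ca, cb in zip(a.components, b.components):
            for x, y in zip(ca, cb):
                assert x.terms == y.terms


class TestPartialSums:
    @pytest.mark.parametrize(
        "kernel,mu,state,tau,expected",
        [
            (Kernel.CAPUTO, 1.0, "V", 0.1, 30.8717),
            (Kernel.CAPUTO, 0.8, "T", 0.1, 17.4502),
            (Kernel.CF, 0.8, "V", 0.1, 39.7982),
            (Kernel.CAPUTO, 1.0, "W", 0.1, 5.1281),
        ],
    )
    def test_reference_values_at_k2(self, smoking_system, kernel, mu, state, tau, expected):
        sol = solve(smoking_system, KernelSpec(kernel, mu), 2)
        assert sol.evaluate(state, tau) == pytest.approx(expected, abs=2e-3)

    def test_k0_partial_sums_are_constant_initials(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CF, 0.6), 0)
        for name, x0 in zip(smoking_system.names, smoking_system.initial):
            for tau in (0.0, 0.25, 0.5):
                assert sol.evaluate(name, tau) == pytest.approx(x0)

    def test_evaluation_at_zero_returns_initial_for_power_law_kernel(self, smoking_system):
        """Only the power-law kernel leaves tau=0 untouched at mu<1: the
        exponential and Mittag-Leffler operators carry a (1-mu)*identity part,
        so their partial sums at tau=0 include nonzero offsets (visible in the
        reference tables' tau=0 rows)."""
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 0.7), 2)
        for name, x0 in zip(smoking_system.names, smoking_system.initial):
            assert sol.evaluate(name, 0.0) == pytest.approx(x0)
        for kern in Kernel:  # at mu=1 all kernels reduce to classical integration
            sol = solve(smoking_system, KernelSpec(kern, 1.0), 2)
            assert sol.evaluate("V", 0.0) == pytest.approx(40.0)
        # the nonsingular kernels shift tau=0 by the (1-mu) parts
        cf = solve(smoking_system, KernelSpec(Kernel.CF, 0.8), 2)
        assert cf.evaluate("V", 0.0) == pytest.approx(34.1735, abs=2e-3)

    def test_upto_k_truncates(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2)
        v0 = evaluate_solution(sol, "V", 0.1, upto_k=0)
        v1 = evaluate_solution(sol, "V", 0.1, upto_k=1)
        assert v0 == pytest.approx(40.0)
        assert v1 == pytest.approx(40.0 - 113.0 * 0.1)
        with pytest.raises(ValueError):
            evaluate_solution(sol, "V", 0.1, upto_k=3)

    def test_mu_one_kernel_coincidence(self, smoking_system):
        sols = [solve(smoking_system, KernelSpec(k, 1.0), 2) for k in Kernel]
        for tau in np.arange(0.0, 0.51, 0.1):
            for name in smoking_system.names:
                vals = [s.evaluate(name, tau) for s in sols]
                assert max(vals) - min(vals) <= 1e-10 * max(1.0, abs(vals[0]))


class TestConservation:
    @pytest.mark.parametrize("kern", list(Kernel))
    @pytest.mark.parametrize("mu", [0.8, 1.0])
    def test_compartment_sum_solves_scalar_total_equation(
        self, smoking_system, scalar_total_system, kern, mu
    ):
        """The contact/transfer terms cancel in the compartment sum, so the
        summed components must match the scalar solution of the total."""
        spec = KernelSpec(kern, mu)
        full = solve(smoking_system, spec, 2)
        scalar = solve(scalar_total_system, spec, 2)
        for k in range(3):
            total = FracSeries.zero()
            for i in range(smoking_system.n):
                total = total + full.components[i][k]
            assert total.allclose(scalar.components[0][k], rtol=1e-10, atol=1e-12)

    def test_level_one_hand_anchor(self, smoking_system):
        # sum of level-1 coefficients = alpha - vartheta * 85 = -3.25 at mu=1
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 1)
        total = sum(sol.components[i][1].coefficient(0, 1) for i in range(5))
        assert total == pytest.approx(-3.25, rel=1e-12)


class TestTaylorProperty:
    def test_mu_one_remainder_shrinks_at_cubic_rate(self, smoking_system):
        """With the source injected only at level 0, the three-term partial sum
        is the quadratic Maclaurin polynomial: |series - RK4| ~ tau^3."""
        sol = solve(
            smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2, source_mode="first_level"
        )
        grid = rk4_classical(smoking_system, 0.05, 1e-3)
        taus = [0.01, 0.02, 0.05]
        errs = [abs(sol.evaluate("V", t) - grid.at(t)[0]) for t in taus]
        slope = np.polyfit(np.log(taus), np.log(errs), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.3)


class TestDiagnosticsAndExport:
    def test_diagnostic_requires_two_components(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 0)
        with pytest.raises(ValueError):
            truncation_diagnostic(sol, [0.1])

    def test_small_tau_flagged_convergent(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2)
        df = truncation_diagnostic(sol, [0.01])
        row = df[(df["state"] == "V") & (df["tau"] == 0.01)].iloc[0]
        assert row["converged"]
        assert row["ratio"] < 0.05

    def test_ratio_monotone_in_tau_for_single_sign_series(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2)
        taus = [0.05, 0.1, 0.2, 0.3, 0.4]
        df = truncation_diagnostic(sol, taus)
        ratios = df[df["state"] == "W"].sort_values("tau")["ratio"].to_numpy()
        assert np.all(np.diff(ratios) >= -1e-12)

    def test_solution_json_round_trips_components(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.ABC, 0.8), 2)
        payload = json.loads(sol.to_json())
        assert payload["kernel"] == "abc"
        for name in smoking_system.names:
            comps = [FracSeries.from_dict(d) for d in payload["states"][name]]
            for orig, loaded in zip(sol.components[smoking_system.index(name)], comps):
                assert orig == loaded

    def test_grid_frame_schema(self, smoking_system):
        sol = solve(smoking_system, KernelSpec(Kernel.CAPUTO, 1.0), 2)
        df = sol.evaluate_grid([0.0, 0.1])
        assert list(df.columns) == ["tau", "state", "value", "kernel", "mu", "K"]
        assert len(df) == 10
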