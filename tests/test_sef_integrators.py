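import numpy as np
import pytest

import sefmd
from sefmd.decoupling import DecouplingSpec
from sefmd.sef_integrators import (
    PhaseState,
    PropagationError,
    SimulationConfig,
    available_schemes,
    check_order_conditions,
    get_scheme,
    perturbed_scheme,
    propagate,
    se_step,
    sef_step,
)


def leapfrog_quadratic(h, q0, p0, dt, n_steps):
    """Independent position-Verlet oracle on V = q^T h q / 2."""
    q, p = np.array(q0, float), np.array(p0, float)
    out = [q.copy()]
    for _ in range(n_steps):
        q = q + 0.5 * dt * p
        p = p - dt * (h @ q)
        q = q + 0.5 * dt * p
        out.append(q.copy())
    return np.array(out)


class TestSchemeRegistry:
    def test_sef2_closed_form(self):
        scheme = get_scheme("SEF2")
        assert scheme.a == (0.5, 0.5)
        assert scheme.b == (0.0, 1.0)
        assert scheme.c == (0.5, 0.5)
        assert scheme.order == 2 and scheme.needs_hessian

    def test_sef4_closed_form(self):
        scheme = get_scheme("SEF4")
        cbrt = 2.0 ** (1 / 3)
        a_outer = (cbrt + 1 / cbrt + 2) / 6
        a_inner = -(cbrt + 1 / cbrt - 1) / 6
        np.testing.assert_allclose(
            scheme.a, (a_outer, a_inner, a_inner, a_outer), rtol=1e-15
        )
        b2 = (2 ** (4 / 3) + 2 ** (2 / 3) + 4) / 6
        b3 = -(2 ** (7 / 3) + 2 ** (5 / 3) + 2) / 6
        np.testing.assert_allclose(scheme.b, (0.0, b2, b3, b2), rtol=1e-15)
        assert scheme.c == scheme.a

    @pytest.mark.parametrize("name", ["SE2", "SE4", "SEF2", "SEF4"])
    def test_sums_are_one(self, name):
        scheme = get_scheme(name)
        assert abs(sum(scheme.a) - 1.0) < 1e-14
        assert abs(sum(scheme.b) - 1.0) < 1e-14
        assert scheme.b[0] == 0.0

    def test_unknown_scheme_lists_available(self):
        with pytest.raises(KeyError, match="SE2"):
            get_scheme("SEF6")
        assert set(available_schemes()) == {"SE2", "SE4", "SEF2", "SEF4"}


class TestSefStep:
    def test_free_particle(self):
        """Zero Hessian, zero initial force: exact free flight."""
        surface = sefmd.build_harmonic_surface(np.zeros((2, 2)), [0.0, 0.0])
        state = PhaseState([1.0, -1.0], [0.3, 0.4], [0.0, 0.0], [1.0, -1.0])
        out = sef_step(state, surface, None, get_scheme("SEF2"), dt=10.0)
        np.testing.assert_allclose(out.q, [1.0 + 3.0, -1.0 + 4.0], rtol=1e-15)
        np.testing.assert_allclose(out.p, [0.3, 0.4], rtol=1e-15)
        np.testing.assert_allclose(out.f_tilde, [0.0, 0.0])

    def test_sef2_equals_leapfrog_on_quadratic(self):
        """With a consistent initial force, SEF2 reproduces leapfrog
        step-for-step on a quadratic surface over 3000 steps."""
        h = np.array([[1.0e-4, 2.0e-5], [2.0e-5, 2.25e-4]])
        surface = sefmd.build_harmonic_surface(h, np.zeros(2))
        q0 = np.array([0.5, -0.3])
        p0 = np.array([0.01, 0.008])
        init = PhaseState(q0, p0, -(h @ q0), q0)
        cfg = SimulationConfig(dt=10.0, n_steps=3000, scheme="SEF2")
        traj = propagate(init, surface, cfg)
        oracle = leapfrog_quadratic(h, q0, p0, 10.0, 3000)
        assert np.max(np.abs(traj.q - oracle)) < 1e-12

    def test_force_estimate_exact_on_quadratic(self):
        """F_n = -h (q_n - q_eq) after every step to machine precision."""
        h = np.array([[2.0e-4, 3.0e-5], [3.0e-5, 1.0e-4]])
        surface = sefmd.build_harmonic_surface(h, np.zeros(2))
        basis = sefmd.dof_normal_modes(surface)
        init = sefmd.site_zpe_state(basis, np.zeros(2))
        for scheme in ("SEF2", "SEF4"):
            cfg = SimulationConfig(dt=10.0, n_steps=500, scheme=scheme)
            traj = propagate(init, surface, cfg)
            resid = traj.f_tilde + traj.q @ h
            assert np.max(np.abs(resid)) < 1e-14

    def test_q_hat_tracks_q_at_step_boundaries(self, coupled_pair):
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        state = init
        for _ in range(5):
            state = sef_step(state, coupled_pair, None, get_scheme("SEF4"), 10.0)
            np.testing.assert_array_equal(state.q, state.q_hat)

    def test_hessian_evaluation_counts(self, coupled_pair):
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        for name, expected in (("SEF2", 2), ("SEF4", 6)):
            coupled_pair.reset_counters()
            sef_step(init, coupled_pair, None, get_scheme(name), 10.0)
            assert coupled_pair.calls["hessian"] == expected
            assert coupled_pair.calls["gradient"] == 0

    def test_rejects_se_scheme(self, coupled_pair):
        init = PhaseState([0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            sef_step(init, coupled_pair, None, get_scheme("SE2"), 10.0)


class TestSeStep:
    def test_harmonic_energy_boundedness(self):
        """SE2 over 100 periods: relative energy error stays < 1e-6."""
        omega = 1.0
        surface = sefmd.build_harmonic_surface([[omega**2]], [0.0])
        period = 2 * np.pi / omega
        dt = period / 1000.0
        state = PhaseState([1.0], [0.0], [0.0], [1.0])
        e0 = 0.5 * omega**2
        scheme = get_scheme("SE2")
        for _ in range(1000):  # 1 period; then check a long run via propagate
            state = se_step(state, surface, scheme, dt)
        e1 = 0.5 * state.p[0] ** 2 + surface.energy_at(state.q)
        assert abs(e1 - e0) / e0 < 1e-6
        cfg = SimulationConfig(dt=dt, n_steps=100_000, scheme="SE2")
        traj = propagate(PhaseState([1.0], [0.0], [0.0], [1.0]), surface, cfg)
        from sefmd.diagnostics import energy_drift

        # the O(dt^2) oscillation is bounded; there is no secular drift
        summary = energy_drift(traj.energies, dt)
        assert abs(summary["drift_slope_per_step"]) < 1e-13
        assert summary["amplitude"] / e0 < 1e-4

    @pytest.mark.parametrize(
        "name, order, tol", [("SE2", 2.0, 0.2), ("SE4", 4.0, 0.3)]
    )
    def test_global_error_slopes_on_morse(self, name, order, tol):
        report = check_order_conditions(get_scheme(name))
        assert report.measured_order == pytest.approx(order, abs=tol)
        assert report.passed


class TestPropagate:
    def test_zero_steps_returns_initial_only(self, harmonic_1dof):
        init = PhaseState([0.2], [0.0], [-0.2 * 1e-4], [0.2])
        cfg = SimulationConfig(dt=10.0, n_steps=0, scheme="SEF2")
        traj = propagate(init, harmonic_1dof, cfg)
        assert traj.q.shape == (1, 1)
        np.testing.assert_array_equal(traj.q[0], init.q)

    def test_discard_steps_select_retained_slice(self, harmonic_1dof):
        basis = sefmd.dof_normal_modes(harmonic_1dof)
        init = sefmd.site_zpe_state(basis, harmonic_1dof.reference_geometry)
        cfg = SimulationConfig(dt=10.0, n_steps=500, discard_steps=200,
                               scheme="SEF2")
        traj = propagate(init, harmonic_1dof, cfg)
        kept = traj.retained()
        assert kept.times[0] == pytest.approx(200 * 10.0)
        assert kept.q.shape[0] == 301
        np.testing.assert_array_equal(kept.q, traj.q[200:])

    def test_non_finite_aborts_with_step_index(self):
        """An inverted-harmonic surface (exponential runaway) overflows and
        the propagation reports the offending step."""
        surface = sefmd.build_harmonic_surface([[-1.0]], [0.0])
        init = PhaseState([1.0], [0.0], [1.0], [1.0])
        cfg = SimulationConfig(dt=100.0, n_steps=200, scheme="SEF2")
        with pytest.raises(PropagationError) as err:
            with np.errstate(over="ignore", invalid="ignore"):
                propagate(init, surface, cfg)
        assert err.value.step is not None

    def test_determinism_bit_identical(self, coupled_pair):
        basis = sefmd.dof_normal_modes(coupled_pair)
        init = sefmd.site_zpe_state(basis, coupled_pair.reference_geometry)
        spec = DecouplingSpec(
            group_pairs=((frozenset({0}), frozenset({1}), 0.5),),
            frame="normal_mode",
        )
        cfg = SimulationConfig(dt=10.0, n_steps=300, scheme="SEF4", spec=spec)
        t1 = propagate(init, coupled_pair, cfg, basis=basis)
        t2 = propagate(init, coupled_pair, cfg, basis=basis)
        assert np.array_equal(t1.q, t2.q)
        assert np.array_equal(t1.p, t2.p)
        assert np.array_equal(t1.f_tilde, t2.f_tilde)


class TestOrderConditions:
    def test_sef2_measured_order_and_unique_solution(self):
        report = check_order_conditions(get_scheme("SEF2"))
        assert report.measured_order == pytest.approx(2.0, abs=0.2)
        assert report.unique_second_order is True
        assert report.passed

    def test_sef4_measured_order(self):
        report = check_order_conditions(get_scheme("SEF4"))
        assert report.measured_order == pytest.approx(4.0, abs=0.3)
        assert report.passed

    def test_perturbed_scheme_drops_to_first_order(self):
        """Shifting a_1 (keeping sum a = 1) breaks the time symmetry: the
        measured order falls to 1 once the O(dt) term dominates."""
        bad = perturbed_scheme(get_scheme("SE2"), 0.05)
        report = check_order_conditions(bad, test_order=1)
        assert report.measured_order == pytest.approx(1.0, abs=0.25)

    def test_sum_violation_reported(self):
        from dataclasses import replace

        bad = replace(get_scheme("SE2"), a=(0.5, 0.6))
        report = check_order_conditions(bad, test_order=1)
        assert any("sum(a)" in msg for msg in report.failures)


def test_sef2_vs_se2_divergence_is_third_order_per_step(morse_unit):
    """At alpha = 1 on an anharmonic surface the SEF2 and SE2 steps differ
    by the locally-harmonic force error, O(dt^3) for a single step."""
    q0, p0 = np.array([0.3]), np.array([0.2])
    diffs = []
    dts = [0.2, 0.1, 0.05]
    for dt in dts:
        init = PhaseState(q0, p0, -morse_unit.gradient_at(q0), q0)
        a = sef_step(init, morse_unit, None, get_scheme("SEF2"), dt)
        b = se_step(PhaseState(q0, p0, [0.0], q0), morse_unit,
                    get_scheme("SE2"), dt)
        diffs.append(np.max(np.abs(np.hstack([a.q - b.q, a.p - b.p]))))
    slope = np.polyfit(np.log(dts), np.log(diffs), 1)[0]
    assert slope >= 2.7  # at least cubic in dt
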