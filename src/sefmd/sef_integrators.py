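"""SEF symplectic maps and reference SE integrators.

The SEF (Symplectic Explicit with Force) maps never evaluate the force
directly: the force estimate ``F`` is propagated by time-integrating the
(pair-decoupled) Hessian along the trajectory,

    dq/dt = p,   dp/dt = F,   dF/dt = -h_tilde(q) p,

which, initialized consistently, reproduces the exact dynamics of the
pair-decoupled Hamiltonian (and of the true Hamiltonian at alpha = 1).
Each time step is a composition of leapfrog sub-steps; within every
drift half-segment the force is updated with one Hessian evaluation at
the *midpoint* of the segment, the discretization of the line integral
``F -> F - h_tilde(q) dq`` that keeps the sub-step time-symmetric (see
docs/methods.md).  SEF2 is a single such sub-step and coincides with
position-Verlet/leapfrog on quadratic surfaces; SEF4 is the symmetric
Forest-Ruth product of three SEF2 sub-steps and is globally fourth
order.  The reference SE2/SE4 maps are the standard kick-drift
compositions using exact gradients.

Everything runs in mass-scaled coordinates with unit mass; masses never
appear in the inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .decoupling import DecouplingSpec, make_hessian_transform
from .model_potentials import PotentialSurface

__all__ = [
    "IntegratorScheme",
    "PhaseState",
    "PropagationError",
    "SimulationConfig",
    "Trajectory",
    "available_schemes",
    "check_order_conditions",
    "get_scheme",
    "propagate",
    "se_step",
    "sef_step",
]


class PropagationError(RuntimeError):
    """Raised when propagation produces a non-finite state."""

    def __init__(self, message: str, step: int | None = None, geometry=None):
        super().__init__(message)
        self.step = step
        self.geometry = geometry


@dataclass
class PhaseState:
    """Phase-space state ``(q, p, F, q_hat)`` at time ``t`` (all au).

    ``f_tilde`` is the propagated force estimate and ``q_hat`` the
    auxiliary position that tracks the force quadrature; for the bundled
    schemes (``c_k = a_k``) ``q_hat`` equals ``q`` at every full-step
    boundary.
    """

    q: np.ndarray
    p: np.ndarray
    f_tilde: np.ndarray
    q_hat: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).reshape(-1)
        self.p = np.asarray(self.p, dtype=float).reshape(-1)
        self.f_tilde = np.asarray(self.f_tilde, dtype=float).reshape(-1)
        self.q_hat = np.asarray(self.q_hat, dtype=float).reshape(-1)
        sizes = {self.q.size, self.p.size, self.f_tilde.size, self.q_hat.size}
        if len(sizes) != 1:
            raise ValueError("q, p, f_tilde and q_hat must have equal length")

    def copy(self) -> "PhaseState":
        return PhaseState(
            self.q.copy(), self.p.copy(), self.f_tilde.copy(), self.q_hat.copy(),
            self.t,
        )


_CBRT2 = 2.0 ** (1.0 / 3.0)
_FR_GAMMA1 = 1.0 / (2.0 - _CBRT2)
_FR_GAMMA2 = -_CBRT2 / (2.0 - _CBRT2)

# Closed-form composite coefficients (sum_k a_k = sum_k b_k = 1, b_1 = 0)
_A4 = (
    (2.0 ** (1 / 3) + 2.0 ** (-1 / 3) + 2.0) / 6.0,
    -(2.0 ** (1 / 3) + 2.0 ** (-1 / 3) - 1.0) / 6.0,
    -(2.0 ** (1 / 3) + 2.0 ** (-1 / 3) - 1.0) / 6.0,
    (2.0 ** (1 / 3) + 2.0 ** (-1 / 3) + 2.0) / 6.0,
)
_B4 = (
    0.0,
    (2.0 ** (4 / 3) + 2.0 ** (2 / 3) + 4.0) / 6.0,
    -(2.0 ** (7 / 3) + 2.0 ** (5 / 3) + 2.0) / 6.0,
    (2.0 ** (4 / 3) + 2.0 ** (2 / 3) + 4.0) / 6.0,
)


@dataclass(frozen=True)
class IntegratorScheme:
    """Named coefficient set defining a symplectic map.

    ``a``/``b``/``c`` are the flat kick/drift/auxiliary-drift coefficients
    of the ``n``-sub-step cycle; ``sub_steps`` are the leapfrog scale
    factors the composition is built from (used by the SEF stepper, whose
    force quadrature subdivides each sub-step's two drift halves).
    """

    name: str
    order: int
    a: tuple[float, ...]
    b: tuple[float, ...]
    c: tuple[float, ...]
    needs_hessian: bool
    sub_steps: tuple[float, ...] = (1.0,)

    @property
    def n_substeps(self) -> int:
        return len(self.a)

    @property
    def hessian_evals_per_step(self) -> int:
        """Hessian evaluations per time step (SEF schemes only)."""
        return 2 * len(self.sub_steps) if self.needs_hessian else 0

    @property
    def gradient_evals_per_step(self) -> int:
        return 0 if self.needs_hessian else sum(1 for bk in self.b if bk != 0.0)


_SCHEMES = {
    "SE2": IntegratorScheme(
        "SE2", 2, (0.5, 0.5), (0.0, 1.0), (0.5, 0.5), False, (1.0,)
    ),
    "SE4": IntegratorScheme(
        "SE4", 4, _A4, _B4, _A4, False, (_FR_GAMMA1, _FR_GAMMA2, _FR_GAMMA1)
    ),
    "SEF2": IntegratorScheme(
        "SEF2", 2, (0.5, 0.5), (0.0, 1.0), (0.5, 0.5), True, (1.0,)
    ),
    "SEF4": IntegratorScheme(
        "SEF4", 4, _A4, _B4, _A4, True, (_FR_GAMMA1, _FR_GAMMA2, _FR_GAMMA1)
    ),
}


def available_schemes() -> tuple[str, ...]:
    return tuple(_SCHEMES)


def get_scheme(name: str) -> IntegratorScheme:
    """Look up a registered scheme by name (case-insensitive)."""
    key = name.upper()
    if key not in _SCHEMES:
        raise KeyError(
            f"unknown scheme {name!r}; available: {', '.join(_SCHEMES)}"
        )
    return _SCHEMES[key]


# ---------------------------------------------------------------------------
# step kernels (operate in place on raw arrays for speed)
# ---------------------------------------------------------------------------


def _sef_cycle(q, p, f, qh, hessian_of, transform, sub_steps, dt) -> None:
    """One SEF time step: composition of leapfrog sub-steps with midpoint
    force quadrature.  Mutates the arrays in place."""
    def drift_half(half):
        nonlocal q, p, f, qh
        # line-integral update of the force: Hessian at the segment midpoint
        hq = hessian_of(qh + 0.5 * half * p)
        if transform is not None:
            hq = transform(hq)
        q += half * p
        f -= half * (hq @ p)
        qh += half * p

    for gamma in sub_steps:
        h = gamma * dt
        drift_half(0.5 * h)
        p += h * f
        drift_half(0.5 * h)


def _se_cycle(q, p, gradient_of, a, b, dt) -> None:
    """One SE time step: plain kick-drift composition with exact forces."""
    for ak, bk in zip(a, b):
        if bk != 0.0:
            p -= (bk * dt) * gradient_of(q)
        if ak != 0.0:
            q += (ak * dt) * p


def sef_step(
    state: PhaseState,
    surface: PotentialSurface,
    spec: DecouplingSpec | None,
    scheme: IntegratorScheme,
    dt: float,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    basis=None,
) -> PhaseState:
    """Advance one SEF time step; the force is never evaluated.

    Exactly ``scheme.hessian_evals_per_step`` Hessian evaluations are
    performed, each at the midpoint of a drift half-segment, and the
    (pair-decoupled) force estimate is updated by the quadrature
    ``F -> F - c dt h_tilde(q_mid) p``.
    """
    if not scheme.needs_hessian:
        raise ValueError(f"{scheme.name} is not an SEF scheme")
    if transform is None:
        transform = make_hessian_transform(spec, basis=basis, n_dof=state.q.size)
    out = state.copy()
    try:
        _sef_cycle(
            out.q, out.p, out.f_tilde, out.q_hat,
            surface.hessian_at, transform, scheme.sub_steps, dt,
        )
    except (FloatingPointError, np.linalg.LinAlgError) as exc:  # pragma: no cover
        raise PropagationError(
            f"Hessian evaluation failed at t={state.t}", geometry=state.q_hat
        ) from exc
    out.t = state.t + dt
    return out


def se_step(
    state: PhaseState,
    surface: PotentialSurface,
    scheme: IntegratorScheme,
    dt: float,
) -> PhaseState:
    """Advance one standard symplectic-explicit step using exact forces."""
    if scheme.needs_hessian:
        raise ValueError(f"{scheme.name} requires the SEF stepper")
    out = state.copy()
    _se_cycle(out.q, out.p, surface.gradient_at, scheme.a, scheme.b, dt)
    out.t = state.t + dt
    return out


# ---------------------------------------------------------------------------
# trajectory propagation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Propagation protocol: time step 10 au and 3000 steps by default;
    runs probing weak decoupling use 5000 steps and discard the first
    2000 (about 0.5 ps) as decorrelation time."""

    dt: float = 10.0
    n_steps: int = 3000
    discard_steps: int = 0
    scheme: str = "SEF2"
    spec: DecouplingSpec | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps > 0 and not (0 <= self.discard_steps < self.n_steps):
            raise ValueError("discard_steps must satisfy 0 <= discard < n_steps")


@dataclass
class Trajectory:
    """Time series of the propagation, stored every step.

    ``energies`` is ``E = |p|^2/2 + V(q)`` on the *fully coupled*
    surface (the quantity monitored even when the dynamics is
    pair-decoupled).  Rows ``q[k]``, ``p[k]`` are the state after ``k``
    steps; row 0 is the initial state.
    """

    times: np.ndarray
    q: np.ndarray
    p: np.ndarray
    f_tilde: np.ndarray
    energies: np.ndarray
    dt: float
    scheme: str
    discard_steps: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    @property
    def dof_count(self) -> int:
        return self.q.shape[1]

    def retained(self) -> "Trajectory":
        """Drop the decorrelation segment (first ``discard_steps`` rows)."""
        s = self.discard_steps
        return Trajectory(
            self.times[s:], self.q[s:], self.p[s:], self.f_tilde[s:],
            self.energies[s:], self.dt, self.scheme, 0, dict(self.meta),
        )

    def final_state(self) -> PhaseState:
        return PhaseState(
            self.q[-1], self.p[-1], self.f_tilde[-1], self.q[-1],
            t=float(self.times[-1]),
        )

    def save_npz(self, path: str) -> None:
        np.savez(
            path,
            times=self.times, q=self.q, p=self.p, f_tilde=self.f_tilde,
            energies=self.energies, dt=self.dt, scheme=self.scheme,
            discard_steps=self.discard_steps,
        )

    @staticmethod
    def load_npz(path: str) -> "Trajectory":
        data = np.load(path, allow_pickle=False)
        return Trajectory(
            times=data["times"], q=data["q"], p=data["p"],
            f_tilde=data["f_tilde"], energies=data["energies"],
            dt=float(data["dt"]), scheme=str(data["scheme"]),
            discard_steps=int(data["discard_steps"]),
        )


def propagate(
    initial: PhaseState,
    surface: PotentialSurface,
    config: SimulationConfig,
    basis=None,
    record_energy: bool = True,
) -> Trajectory:
    """Propagate ``config.n_steps`` steps, applying mode freezing after
    every step and recording ``(t, q, p, F, E)``.

    The propagation is fully deterministic (no randomness anywhere); a
    non-finite state aborts with the offending step index, which flags
    surface-extrapolation blowups.
    """
    scheme = get_scheme(config.scheme)
    spec = config.spec
    transform = make_hessian_transform(spec, basis=basis, n_dof=initial.q.size)
    frozen = (
        np.fromiter(spec.frozen_modes, dtype=int)
        if spec is not None and spec.frozen_modes
        else None
    )

    n = config.n_steps
    dof = initial.q.size
    q = initial.q.copy()
    p = initial.p.copy()
    f = initial.f_tilde.copy()
    qh = initial.q_hat.copy()
    if frozen is not None:
        for arr in (q, p, f, qh):
            arr[frozen] = 0.0

    qs = np.empty((n + 1, dof))
    ps = np.empty((n + 1, dof))
    fs = np.empty((n + 1, dof))
    es = np.empty(n + 1)
    qs[0], ps[0], fs[0] = q, p, f
    es[0] = 0.5 * float(p @ p) + (surface.energy_at(q) if record_energy else np.nan)

    hessian_of = surface.hessian_at
    gradient_of = surface.gradient_at
    for k in range(1, n + 1):
        if scheme.needs_hessian:
            _sef_cycle(q, p, f, qh, hessian_of, transform, scheme.sub_steps, config.dt)
        else:
            _se_cycle(q, p, gradient_of, scheme.a, scheme.b, config.dt)
        if frozen is not None:
            for arr in (q, p, f, qh):
                arr[frozen] = 0.0
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(p))):
            raise PropagationError(
                f"non-finite state at step {k}", step=k, geometry=q.copy()
            )
        qs[k], ps[k], fs[k] = q, p, f
        es[k] = (
            0.5 * float(p @ p) + (surface.energy_at(q) if record_energy else np.nan)
        )

    meta = {
        "alpha_map": [
            (sorted(a), sorted(b), alpha)
            for (a, b, alpha) in (spec.group_pairs if spec else ())
        ],
        "frozen_modes": sorted(spec.frozen_modes) if spec else [],
    }
    return Trajectory(
        times=initial.t + config.dt * np.arange(n + 1),
        q=qs, p=ps, f_tilde=fs, energies=es,
        dt=config.dt, scheme=scheme.name,
        discard_steps=config.discard_steps, meta=meta,
    )


# ---------------------------------------------------------------------------
# order-condition checker
# ---------------------------------------------------------------------------


@dataclass
class OrderConditionReport:
    scheme: str
    test_order: int
    sum_a: float
    sum_b: float
    measured_order: float
    errors: tuple[float, ...]
    dts: tuple[float, ...]
    unique_second_order: bool | None
    failures: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.failures


def _reference_morse_flow(q0: float, p0: float, t_end: float) -> np.ndarray:
    """High-accuracy reference flow of the unit Morse oscillator."""
    from scipy.integrate import solve_ivp

    def rhs(_t, z):
        e = np.exp(-z[0])
        return [z[1], -2.0 * e * (1.0 - e)]

    sol = solve_ivp(
        rhs, (0.0, t_end), [q0, p0], method="DOP853", rtol=1e-13, atol=1e-14
    )
    return sol.y[:, -1]


def check_order_conditions(
    scheme: IntegratorScheme, test_order: int | None = None
) -> OrderConditionReport:
    """Verify a scheme's order algebraically and by Richardson slope.

    Algebraic checks: ``sum_k a_k = sum_k b_k = 1`` (to 1e-14); for
    second-order schemes with ``b_1 = 0`` the unique solution
    ``a = (1/2, 1/2), b = (0, 1)``.  The numerical check measures the
    global-error slope on a nonlinear (Morse) oscillator against a
    high-accuracy reference and compares it with the nominal order.
    """
    from .model_potentials import build_morse_surface

    if test_order is None:
        test_order = scheme.order
    if test_order not in (1, 2, 3, 4):
        raise ValueError("test_order must be in {1, 2, 3, 4}")

    failures: list[str] = []
    sum_a, sum_b = float(sum(scheme.a)), float(sum(scheme.b))
    if abs(sum_a - 1.0) > 1e-14:
        failures.append(f"sum(a) = {sum_a!r} != 1")
    if abs(sum_b - 1.0) > 1e-14:
        failures.append(f"sum(b) = {sum_b!r} != 1")

    unique2: bool | None = None
    if scheme.order == 2 and len(scheme.b) >= 2 and scheme.b[0] == 0.0:
        unique2 = (
            abs(scheme.a[0] - 0.5) < 1e-14
            and abs(scheme.a[1] - 0.5) < 1e-14
            and abs(scheme.b[1] - 1.0) < 1e-14
        )
        if not unique2:
            failures.append("second-order b1=0 solution is not a=(1/2,1/2), b=(0,1)")

    surface = build_morse_surface(1.0, 1.0)
    q0, p0, t_end = 0.4, 0.1, 5.0
    ref = _reference_morse_flow(q0, p0, t_end)
    dts = (0.05, 0.025, 0.0125, 0.00625)
    errs = []
    for dt in dts:
        n = int(round(t_end / dt))
        state = PhaseState([q0], [p0], -surface.gradient_at(np.array([q0])), [q0])
        q, p, f, qh = state.q, state.p, state.f_tilde, state.q_hat
        for _ in range(n):
            if scheme.needs_hessian:
                _sef_cycle(q, p, f, qh, surface.hessian_at, None, scheme.sub_steps, dt)
            else:
                _se_cycle(q, p, surface.gradient_at, scheme.a, scheme.b, dt)
        errs.append(float(np.max(np.abs(np.array([q[0], p[0]]) - ref))))
    slope = float(
        np.polyfit(np.log(dts), np.log(np.maximum(errs, 1e-16)), 1)[0]
    )
    tol = 0.2 if test_order <= 2 else 0.3
    if abs(slope - test_order) > tol:
        failures.append(
            f"measured order {slope:.2f} differs from requested {test_order}"
        )
    return OrderConditionReport(
        scheme=scheme.name,
        test_order=test_order,
        sum_a=sum_a,
        sum_b=sum_b,
        measured_order=slope,
        errors=tuple(errs),
        dts=dts,
        unique_second_order=unique2,
        failures=tuple(failures),
    )


def perturbed_scheme(scheme: IntegratorScheme, da: float) -> IntegratorScheme:
    """Shift ``a_1`` by ``da`` and ``a_2`` by ``-da`` (keeps ``sum a = 1``);
    breaks the time symmetry, so the order of a symmetric scheme drops."""
    a = list(scheme.a)
    a[0] += da
    a[1] -= da
    return replace(scheme, name=scheme.name + "-perturbed", a=tuple(a))
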