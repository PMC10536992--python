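"""Validation measures: energy series, symplecticity, time reversibility.

Three diagnostics certify an integration numerically:

* the total energy ``E(t) = |p|^2/2 + V(q)`` on the fully coupled
  surface, summarized by its oscillation amplitude and linear-drift
  slope;
* the symplecticity deviation ``Y(t) = max | M(t)^T J M(t) - J |`` of
  the monodromy matrix ``M(t) = dz(t)/dz(0)``, computed by central
  finite differences of full auxiliary trajectories;
* the round-trip reversibility deviation: propagate to ``T``, flip the
  momentum sign, propagate another ``T``, and report the RMS displacement
  of the final geometry from the initial one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_potentials import PotentialSurface
from .sef_integrators import (
    PhaseState,
    PropagationError,
    SimulationConfig,
    Trajectory,
    get_scheme,
    propagate,
)

__all__ = [
    "MonodromyTrace",
    "canonical_j",
    "energy_drift",
    "energy_series",
    "monodromy_by_finite_difference",
    "quadratic_decoupled_energy_series",
    "reversibility_deviation",
    "symplectic_deviation",
]


def canonical_j(f: int) -> np.ndarray:
    """Canonical symplectic matrix ``J = [[0, I], [-I, 0]]`` of size 2F."""
    j = np.zeros((2 * f, 2 * f))
    j[:f, f:] = np.eye(f)
    j[f:, :f] = -np.eye(f)
    return j


@dataclass
class MonodromyTrace:
    """Finite-difference monodromy matrices ``M(t)`` along a trajectory.

    ``matrices[k]`` approximates ``dz(t_k)/dz(0)`` with ``z = (q, p)``;
    ``M(0)`` is the identity exactly.  ``converged`` reports whether
    halving the displacement changed the final matrix by less than the
    stated tolerance.
    """

    times: np.ndarray
    matrices: np.ndarray
    displacement_eps: float
    converged: bool | None = None
    convergence_change: float | None = None

    def max_symplectic_deviation(self, norm: str = "max") -> float:
        """Largest ``Y(t)`` over the stored trajectory."""
        return max(symplectic_deviation(m, norm) for m in self.matrices)


def _displaced_initial(initial: PhaseState, transform, surface, delta_q, delta_p):
    """Displace the initial condition consistently.

    A displaced force estimate ``F0' = F0 - h_tilde(q0) dq`` keeps all
    auxiliary trajectories on the *same* pair-decoupled force law (to
    first order), which is what makes the finite-difference map a
    Jacobian of one dynamical system rather than of a family of them.
    """
    out = initial.copy()
    out.q = out.q + delta_q
    out.q_hat = out.q_hat + delta_q
    out.p = out.p + delta_p
    if np.any(delta_q):
        h = surface.hessian_at(initial.q)
        if transform is not None:
            h = transform(h)
        out.f_tilde = out.f_tilde - h @ delta_q
    return out


def monodromy_by_finite_difference(
    initial: PhaseState,
    surface: PotentialSurface,
    config: SimulationConfig,
    eps: float = 1e-6,
    basis=None,
    check_convergence: bool = True,
    convergence_tol: float = 1e-5,
) -> MonodromyTrace:
    """Monodromy matrices from 4F displaced trajectories (central FD).

    Column ``j`` of ``M(t)`` is ``[z(t; z0 + eps e_j) - z(t; z0 - eps e_j)]
    / (2 eps)``.  With ``check_convergence`` the final-time matrix is
    recomputed at ``eps / 2`` and the max-abs change recorded (must stay
    below ``convergence_tol`` to count as converged).
    """
    if eps <= 0:
        raise ValueError("displacement eps must be positive")
    f_dim = initial.q.size
    scheme = get_scheme(config.scheme)
    needs_sef = scheme.needs_hessian
    from .decoupling import make_hessian_transform

    transform = make_hessian_transform(config.spec, basis=basis, n_dof=f_dim)

    def z_series(state: PhaseState) -> np.ndarray:
        try:
            traj = propagate(state, surface, config, basis=basis, record_energy=False)
        except PropagationError as exc:
            raise PropagationError(
                f"auxiliary trajectory diverged ({exc})", step=exc.step,
                geometry=exc.geometry,
            ) from exc
        return np.hstack([traj.q, traj.p])  # (n_steps + 1, 2F)

    def assemble(eps_val: float) -> np.ndarray:
        n_rows = config.n_steps + 1
        m = np.empty((n_rows, 2 * f_dim, 2 * f_dim))
        for j in range(2 * f_dim):
            dq = np.zeros(f_dim)
            dp = np.zeros(f_dim)
            if j < f_dim:
                dq[j] = eps_val
            else:
                dp[j - f_dim] = eps_val
            tfm = transform if needs_sef else None
            plus = z_series(_displaced_initial(initial, tfm, surface, dq, dp))
            minus = z_series(_displaced_initial(initial, tfm, surface, -dq, -dp))
            m[:, :, j] = (plus - minus) / (2.0 * eps_val)
        m[0] = np.eye(2 * f_dim)  # exact at t = 0
        return m

    matrices = assemble(eps)
    converged = None
    change = None
    if check_convergence:
        half = assemble(0.5 * eps)
        change = float(np.max(np.abs(half[-1] - matrices[-1])))
        converged = change < convergence_tol
    times = initial.t + config.dt * np.arange(config.n_steps + 1)
    return MonodromyTrace(
        times=times, matrices=matrices, displacement_eps=eps,
        converged=converged, convergence_change=change,
    )


def symplectic_deviation(m: np.ndarray, norm: str = "max") -> float:
    """Deviation ``Y = |M^T J M - J|`` (max-abs entry by default).

    Returns exactly zero (up to roundoff) for symplectic ``M``.  The
    elementwise max is the most stringent reading; ``norm="fro"`` gives
    the Frobenius norm instead.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 2:
        raise ValueError("M must be square with even dimension")
    j = canonical_j(m.shape[0] // 2)
    resid = m.T @ j @ m - j
    if norm == "max":
        return float(np.max(np.abs(resid)))
    if norm == "fro":
        return float(np.linalg.norm(resid))
    raise ValueError("norm must be 'max' or 'fro'")


def reversibility_deviation(
    initial: PhaseState,
    surface: PotentialSurface,
    config: SimulationConfig,
    t_half: float = 6000.0,
    basis=None,
    to_cartesian=None,
) -> float:
    """Round-trip reversibility: RMS position error after time ``2T``.

    Runs ``T = t_half`` forward, flips the momentum sign exactly (the
    propagated force estimate keeps its current value, so its quadrature
    simply retraces), runs another ``T``, and returns the RMS over the
    geometry components of (final - initial).  With ``to_cartesian`` the
    comparison happens on the F = 3 N_at Cartesian components.
    """
    n_half = t_half / config.dt
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError("t_half must be an integer multiple of dt")
    n_half = int(round(n_half))
    if n_half == 0:
        return 0.0
    cfg = SimulationConfig(
        dt=config.dt, n_steps=n_half, discard_steps=0,
        scheme=config.scheme, spec=config.spec,
    )
    fwd = propagate(initial, surface, cfg, basis=basis, record_energy=False)
    turn = fwd.final_state()
    turn.p = -turn.p
    back = propagate(turn, surface, cfg, basis=basis, record_energy=False)
    q_end, q_start = back.q[-1], initial.q
    if to_cartesian is not None:
        q_end, q_start = to_cartesian(q_end), to_cartesian(q_start)
    diff = q_end - q_start
    return float(np.sqrt(np.mean(diff**2)))


def energy_series(trajectory: Trajectory, surface: PotentialSurface) -> np.ndarray:
    """Total energy ``E(t)`` on the fully coupled surface at every frame."""
    kin = 0.5 * np.sum(trajectory.p**2, axis=1)
    pot = np.array([surface.energy_at(qk) for qk in trajectory.q])
    return kin + pot


def quadratic_decoupled_energy_series(
    trajectory: Trajectory,
    surface: PotentialSurface,
    spec=None,
    basis=None,
    shadow: bool = False,
) -> np.ndarray:
    """Energy of the propagated pair-decoupled Hamiltonian on a *quadratic*
    surface: ``E_tilde = |p|^2/2 + d^T h_tilde d / 2`` with
    ``d = q - q_ref`` and ``h_tilde`` the constant decoupled Hessian.

    This is the quantity the pair-decoupled dynamics conserves; the fully
    coupled ``E`` recorded by propagation oscillates boundedly (by the
    scaled cross terms) whenever ``alpha != 1``.  With ``shadow=True`` the
    exact discrete invariant of the second-order leapfrog composition,
    ``E_tilde - dt^2 p^T h_tilde p / 8``, is returned instead; it is
    conserved to roundoff by SEF2/SE2 on quadratic surfaces.
    """
    from .decoupling import make_hessian_transform

    h = surface.hessian_at(surface.reference_geometry)
    transform = make_hessian_transform(spec, basis=basis, n_dof=h.shape[0])
    if transform is not None:
        h = transform(h)
    d = trajectory.q - surface.reference_geometry
    pot = 0.5 * np.einsum("ki,ij,kj->k", d, h, d)
    kin = 0.5 * np.sum(trajectory.p**2, axis=1)
    e = kin + pot
    if shadow:
        e = e - (trajectory.dt**2 / 8.0) * np.einsum(
            "ki,ij,kj->k", trajectory.p, h, trajectory.p
        )
    return e


def energy_drift(energies: np.ndarray, dt: float = 1.0) -> dict:
    """Oscillation amplitude and linear-drift slope of an energy series.

    The slope comes from a least-squares fit of ``E`` against the step
    index (au/step); the amplitude is ``max - min`` of the series.
    """
    e = np.asarray(energies, dtype=float)
    steps = np.arange(e.size)
    slope = float(np.polyfit(steps, e, 1)[0]) if e.size > 1 else 0.0
    return {
        "amplitude": float(np.max(e) - np.min(e)),
        "drift_slope_per_step": slope,
        "drift_slope_per_au": slope / dt,
        "mean": float(np.mean(e)),
    }
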