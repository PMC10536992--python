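"""Potential-energy-surface contract and bundled analytic model surfaces.

Every surface exposes energy, gradient and Hessian of ``V(q)`` at an
arbitrary geometry ``q`` in *mass-scaled* coordinates and atomic units
(hartree; hartree per mass-scaled bohr; ...), so the kinetic energy is
always ``|p|^2 / 2`` with unit mass.  The bundled surfaces (general
quadratic, Morse, quartic force field) have analytic derivatives and make
the whole package testable without any external download.  Adapters for
externally fitted surfaces that only supply energies and gradients obtain
the Hessian by symmetrized central finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PotentialSurface",
    "QuarticForceField",
    "build_harmonic_surface",
    "build_morse_surface",
    "external_surface_adapter",
    "finite_difference_hessian",
    "load_quartic_ff",
    "quartic_ff_energy_gradient_hessian",
]

_SYM_RTOL = 1e-10


class SurfaceError(ValueError):
    """Raised for invalid surface definitions or evaluation failures."""


class PotentialSurface:
    """Contract providing energy/gradient/Hessian of ``V(q)`` at any geometry.

    Parameters
    ----------
    dof_count:
        Number of (mass-scaled) degrees of freedom.
    reference_geometry:
        The geometry at which the surface was built (typically the
        equilibrium geometry, where the gradient vanishes).
    energy, gradient, hessian:
        Callables evaluating ``V``, ``dV/dq`` and ``d^2V/dq^2``.

    Evaluation counts are kept in :attr:`calls` so workflows can verify
    how many Hessian evaluations an integrator actually performed.
    """

    def __init__(
        self,
        dof_count: int,
        reference_geometry: np.ndarray,
        energy: Callable[[np.ndarray], float],
        gradient: Callable[[np.ndarray], np.ndarray],
        hessian: Callable[[np.ndarray], np.ndarray],
        name: str = "surface",
    ) -> None:
        if dof_count <= 0:
            raise SurfaceError("dof_count must be a positive integer")
        ref = np.asarray(reference_geometry, dtype=float).reshape(-1)
        if ref.size != dof_count:
            raise SurfaceError(
                f"reference_geometry has length {ref.size}, expected {dof_count}"
            )
        self.dof_count = int(dof_count)
        self.reference_geometry = ref
        self.name = name
        self._energy = energy
        self._gradient = gradient
        self._hessian = hessian
        self.calls = {"energy": 0, "gradient": 0, "hessian": 0}

    def energy_at(self, q: np.ndarray) -> float:
        self.calls["energy"] += 1
        return float(self._energy(np.asarray(q, dtype=float)))

    def gradient_at(self, q: np.ndarray) -> np.ndarray:
        self.calls["gradient"] += 1
        return np.asarray(self._gradient(np.asarray(q, dtype=float)), dtype=float)

    def hessian_at(self, q: np.ndarray) -> np.ndarray:
        self.calls["hessian"] += 1
        return np.asarray(self._hessian(np.asarray(q, dtype=float)), dtype=float)

    def reset_counters(self) -> None:
        for key in self.calls:
            self.calls[key] = 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PotentialSurface(name={self.name!r}, dof_count={self.dof_count})"


def build_harmonic_surface(
    hessian: np.ndarray, q_eq: Sequence[float], name: str = "harmonic"
) -> PotentialSurface:
    """General quadratic surface ``V = (q - q_eq)^T H (q - q_eq) / 2``.

    The Hessian is constant in ``q``; the gradient is ``H (q - q_eq)``.
    ``hessian`` must be symmetric (validated to 1e-10 relative tolerance).
    """
    h = np.asarray(hessian, dtype=float)
    q0 = np.asarray(q_eq, dtype=float).reshape(-1)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise SurfaceError("hessian must be a square matrix")
    if h.shape[0] != q0.size:
        raise SurfaceError("hessian and q_eq dimensions do not match")
    scale = max(np.max(np.abs(h)), 1.0)
    if np.max(np.abs(h - h.T)) > _SYM_RTOL * scale:
        raise SurfaceError("hessian must be symmetric")
    h = 0.5 * (h + h.T)

    def energy(q: np.ndarray) -> float:
        d = q - q0
        return 0.5 * float(d @ h @ d)

    return PotentialSurface(
        dof_count=q0.size,
        reference_geometry=q0,
        energy=energy,
        gradient=lambda q: h @ (q - q0),
        hessian=lambda q: h.copy(),
        name=name,
    )


def build_morse_surface(
    depth: float,
    width: float,
    r_eq: float = 0.0,
    *,
    mass_scaled: bool = True,
    mass: float = 1.0,
) -> PotentialSurface:
    """One-dimensional Morse oscillator ``V(r) = D (1 - exp(-a (r - r_eq)))^2``.

    With ``mass_scaled=True`` (default) the coordinate is already the
    mass-scaled one and the dynamics has unit mass.  Otherwise ``mass``
    is used to express the potential in the mass-scaled coordinate
    ``x = sqrt(m) r``, in which the width becomes ``a / sqrt(m)``.

    At the minimum ``V = V' = 0`` and ``V'' = 2 D a^2``; the harmonic
    frequency (unit mass) is ``a sqrt(2 D)``.
    """
    if depth <= 0 or width <= 0:
        raise SurfaceError("Morse depth and width must be positive")
    if mass_scaled:
        a, x0 = float(width), float(r_eq)
    else:
        if mass <= 0:
            raise SurfaceError("mass must be positive")
        a = float(width) / np.sqrt(mass)
        x0 = float(r_eq) * np.sqrt(mass)
    d = float(depth)

    def energy(q: np.ndarray) -> float:
        u = 1.0 - np.exp(-a * (float(q[0]) - x0))
        return d * u * u

    def gradient(q: np.ndarray) -> np.ndarray:
        e = np.exp(-a * (float(q[0]) - x0))
        return np.array([2.0 * d * a * e * (1.0 - e)])

    def hessian(q: np.ndarray) -> np.ndarray:
        e = np.exp(-a * (float(q[0]) - x0))
        return np.array([[2.0 * d * a * a * e * (2.0 * e - 1.0)]])

    return PotentialSurface(1, [x0], energy, gradient, hessian, name="morse")


def finite_difference_hessian(
    surface: PotentialSurface, q: np.ndarray, step: float = 1e-3
) -> np.ndarray:
    """Symmetrized central-difference Hessian from a surface's gradient.

    Column ``j`` is ``[g(q + s e_j) - g(q - s e_j)] / (2 s)``; the result is
    forced symmetric by averaging with its transpose (exact for quadratics
    up to roundoff, O(step^2) otherwise).  If the differences underflow the
    step is enlarged tenfold once before giving up.
    """
    if step <= 0:
        raise SurfaceError("finite-difference step must be positive")
    q = np.asarray(q, dtype=float).reshape(-1)
    n = q.size

    def attempt(s: float) -> np.ndarray:
        cols = np.empty((n, n))
        for j in range(n):
            dq = np.zeros(n)
            dq[j] = s
            cols[:, j] = (surface.gradient_at(q + dq) - surface.gradient_at(q - dq)) / (
                2.0 * s
            )
        return cols

    h = attempt(step)
    gnorm = np.max(np.abs(surface.gradient_at(q)))
    if not np.any(h) and gnorm > 0:
        warnings.warn(
            "finite-difference step too small (differences underflow); "
            "retrying with a 10x larger step",
            RuntimeWarning,
            stacklevel=2,
        )
        h = attempt(10.0 * step)
        if not np.any(h):
            raise SurfaceError("finite-difference Hessian underflowed twice")
    return 0.5 * (h + h.T)


def external_surface_adapter(
    dof_count: int,
    reference_geometry: Sequence[float],
    energy: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray],
    hessian: Callable[[np.ndarray], np.ndarray] | None = None,
    fd_step: float = 1e-3,
    name: str = "external",
) -> PotentialSurface:
    """Wrap an external fitted surface exposing at least energy + gradient.

    This is the contract used for machine-learned surfaces (e.g. a
    gradient-domain model downloaded separately): if no analytic Hessian is
    supplied, it is obtained on demand by :func:`finite_difference_hessian`
    of the supplied gradient.
    """
    if hessian is None:
        inner = PotentialSurface(
            dof_count, reference_geometry, energy, gradient,
            lambda q: np.zeros((dof_count, dof_count)), name=name + "-grad",
        )
        hessian = lambda q: finite_difference_hessian(inner, q, fd_step)  # noqa: E731
    return PotentialSurface(
        dof_count, reference_geometry, energy, gradient, hessian, name=name
    )


# ---------------------------------------------------------------------------
# Quartic force fields in mass-scaled normal coordinates
# ---------------------------------------------------------------------------


def _symmetrize_tensor(t: np.ndarray) -> np.ndarray:
    """Average a rank-3/4 tensor over all index permutations."""
    import itertools

    rank = t.ndim
    acc = np.zeros_like(t)
    perms = list(itertools.permutations(range(rank)))
    for perm in perms:
        acc += np.transpose(t, perm)
    return acc / len(perms)


@dataclass
class QuarticForceField:
    """Quartic force field in mass-scaled normal coordinates.

    ``V(Q) = sum_j w_j^2 Q_j^2 / 2 + (1/6) sum c_ijk Q_i Q_j Q_k
    + (1/24) sum d_ijkl Q_i Q_j Q_k Q_l``

    with ``harmonic_frequencies`` ``w_j`` (au) and dense coefficient
    tensors ``cubic_coeffs``/``quartic_coeffs`` symmetric under index
    permutation (validated).  With zero cubic and quartic tensors the
    energy reduces exactly to the harmonic sum.
    """

    harmonic_frequencies: np.ndarray
    cubic_coeffs: np.ndarray | None = None
    quartic_coeffs: np.ndarray | None = None
    name: str = "quartic_ff"
    _n: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        w = np.asarray(self.harmonic_frequencies, dtype=float).reshape(-1)
        self.harmonic_frequencies = w
        n = w.size
        self._n = n
        if self.cubic_coeffs is None:
            self.cubic_coeffs = np.zeros((n, n, n))
        if self.quartic_coeffs is None:
            self.quartic_coeffs = np.zeros((n, n, n, n))
        c = np.asarray(self.cubic_coeffs, dtype=float)
        d = np.asarray(self.quartic_coeffs, dtype=float)
        if c.shape != (n, n, n) or d.shape != (n, n, n, n):
            raise SurfaceError("coefficient tensor dimensions do not match dof_count")
        for t, label in ((c, "cubic"), (d, "quartic")):
            sym = _symmetrize_tensor(t)
            scale = max(np.max(np.abs(t)), 1.0)
            if np.max(np.abs(t - sym)) > 1e-10 * scale:
                raise SurfaceError(f"{label} coefficient tensor is not symmetric")
        self.cubic_coeffs = c
        self.quartic_coeffs = d

    @property
    def dof_count(self) -> int:
        return self._n

    def as_surface(self) -> PotentialSurface:
        """Expose the force field through the :class:`PotentialSurface` contract."""
        return PotentialSurface(
            self._n,
            np.zeros(self._n),
            lambda q: quartic_ff_energy_gradient_hessian(self, q)[0],
            lambda q: quartic_ff_energy_gradient_hessian(self, q)[1],
            lambda q: quartic_ff_energy_gradient_hessian(self, q)[2],
            name=self.name,
        )


def quartic_ff_energy_gradient_hessian(
    ff: QuarticForceField, Q: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Energy, gradient and Hessian of a quartic force field at ``Q``."""
    q = np.asarray(Q, dtype=float).reshape(-1)
    if q.size != ff.dof_count:
        raise SurfaceError("Q dimension does not match the force field")
    w2 = ff.harmonic_frequencies**2
    c = ff.cubic_coeffs
    d = ff.quartic_coeffs

    cqq = np.einsum("ijk,j,k->i", c, q, q)
    dqqq = np.einsum("ijkl,j,k,l->i", d, q, q, q)
    energy = (
        0.5 * float(w2 @ q**2)
        + float(q @ cqq) / 6.0
        + float(q @ dqqq) / 24.0
    )
    gradient = w2 * q + 0.5 * cqq + dqqq / 6.0
    hessian = (
        np.diag(w2)
        + np.einsum("ijk,k->ij", c, q)
        + 0.5 * np.einsum("ijkl,k,l->ij", d, q, q)
    )
    return energy, gradient, hessian


def load_quartic_ff(path: str) -> QuarticForceField:
    """Read a quartic force field from a plain-text coefficient file.

    One record per nonzero coefficient, 0-based indices, atomic units::

        i i value        # harmonic: value = w_i^2
        i j k value      # cubic third derivative c_ijk
        i j k l value    # quartic fourth derivative d_ijkl

    Records with permuted indices refer to the same coefficient; each
    coefficient is stored under all index permutations.
    """
    records: list[tuple[tuple[int, ...], float]] = []
    n = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4, 5):
                raise SurfaceError(f"{path}:{line_no}: malformed record {line!r}")
            idx = tuple(int(p) for p in parts[:-1])
            records.append((idx, float(parts[-1])))
            n = max(n, max(idx) + 1)
    w2 = np.zeros(n)
    cubic = np.zeros((n, n, n))
    quartic = np.zeros((n, n, n, n))
    import itertools

    for idx, value in records:
        if len(idx) == 2:
            if idx[0] != idx[1]:
                raise SurfaceError(
                    "off-diagonal second-order records are not allowed in "
                    "normal coordinates"
                )
            w2[idx[0]] = value
        elif len(idx) == 3:
            for perm in set(itertools.permutations(idx)):
                cubic[perm] = value
        else:
            for perm in set(itertools.permutations(idx)):
                quartic[perm] = value
    if np.any(w2 < 0):
        raise SurfaceError("negative harmonic w_i^2 in force-field file")
    return QuarticForceField(np.sqrt(w2), cubic, quartic)
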