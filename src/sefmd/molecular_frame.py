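"""Normal-mode machinery and molecular-frame transforms.

Cartesian masses enter only here: propagation everywhere else happens in
mass-scaled coordinates with unit mass.  This module mass-weights the
Cartesian Hessian, projects out rigid translations/rotations (Eckart
frame), diagonalizes, and provides the transforms between Cartesian
geometries and normal coordinates, plus the zero-point-energy initial
conditions used throughout: every vibrational mode starts at its
equilibrium position with momentum ``sqrt(w_j)`` so that its initial
kinetic energy equals the harmonic zero-point energy ``w_j / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_potentials import PotentialSurface

__all__ = [
    "ANGSTROM_TO_BOHR",
    "AMU_TO_ME",
    "MolecularSystem",
    "NormalModeBasis",
    "compute_normal_modes",
    "dof_normal_modes",
    "normal_mode_surface",
    "read_xyz",
    "to_cartesian_coordinates",
    "to_normal_coordinates",
    "write_xyz",
    "zpe_initial_state",
]

ANGSTROM_TO_BOHR = 1.8897259886
AMU_TO_ME = 1822.888486  # atomic mass unit in electron masses

# squared-frequency eigenvalues with |lambda| below this are rigid-body modes
_ZERO_EIG_TOL = 1e-10
# moment-of-inertia eigenvalue (amu * bohr^2) below which a molecule is linear
_LINEAR_TOL = 1e-8


class FrameError(ValueError):
    """Raised for inconsistent molecular-frame inputs."""


@dataclass
class MolecularSystem:
    """Atom labels, per-atom masses (electron masses) and geometry (bohr)."""

    atom_labels: list[str]
    masses: np.ndarray
    equilibrium_geometry: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        self.equilibrium_geometry = np.asarray(
            self.equilibrium_geometry, dtype=float
        ).reshape(-1)
        if np.any(self.masses <= 0):
            raise FrameError("masses must be strictly positive")
        if self.equilibrium_geometry.size % 3 != 0:
            raise FrameError("geometry length must be divisible by 3")
        if self.equilibrium_geometry.size != 3 * self.masses.size:
            raise FrameError("geometry and mass vector sizes are inconsistent")

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def mass_per_dof(self) -> np.ndarray:
        return np.repeat(self.masses, 3)


@dataclass
class NormalModeBasis:
    """Orthogonal normal-mode basis of the mass-weighted Hessian.

    ``mode_matrix`` is the full 3N x 3N (or n x n for plain-DOF systems)
    orthogonal matrix whose columns are eigenvectors of the projected
    mass-weighted Hessian: the first ``n_projected`` columns span the
    removed rigid translations/rotations, the remaining columns are the
    vibrational modes in ascending frequency order.  ``frequencies``
    holds the vibrational ``w_j = sqrt(lambda_j)`` only.  Modes with
    significantly negative eigenvalues are flagged in
    ``imaginary_modes`` (indices into the vibrational block) rather than
    silently dropped; their ``frequencies`` entry is ``sqrt(|lambda|)``.
    """

    frequencies: np.ndarray
    mode_matrix: np.ndarray
    n_projected: int
    imaginary_modes: tuple[int, ...] = ()
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_vibrations(self) -> int:
        return self.frequencies.size

    @property
    def vibrational_modes(self) -> np.ndarray:
        """Columns of ``mode_matrix`` for the vibrational block."""
        return self.mode_matrix[:, self.n_projected :]


def _rigid_body_vectors(system: MolecularSystem) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n_at = system.n_atoms
    sqm = np.sqrt(system.masses)
    x = system.equilibrium_geometry.reshape(n_at, 3)
    com = (system.masses[:, None] * x).sum(axis=0) / system.masses.sum()
    disp = x - com

    vecs = []
    for axis in range(3):  # translations
        v = np.zeros((n_at, 3))
        v[:, axis] = sqm
        vecs.append(v.reshape(-1))
    for axis in range(3):  # rotations about the COM
        e = np.zeros(3)
        e[axis] = 1.0
        v = sqm[:, None] * np.cross(disp, e)
        vecs.append(v.reshape(-1))

    # orthonormalize, dropping null rotations (linear molecules)
    basis: list[np.ndarray] = []
    for v in vecs:
        for b in basis:
            v = v - (b @ v) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.column_stack(basis)


def expected_rigid_modes(system: MolecularSystem) -> int:
    """6 for nonlinear molecules, 5 for linear ones, 3 for a single atom.

    Linearity is detected from the principal moments of inertia: an
    eigenvalue below 1e-8 amu bohr^2 marks a linear molecule.
    """
    if system.n_atoms == 1:
        return 3
    x = system.equilibrium_geometry.reshape(-1, 3)
    m_amu = system.masses / AMU_TO_ME
    com = (m_amu[:, None] * x).sum(axis=0) / m_amu.sum()
    d = x - com
    inertia = np.zeros((3, 3))
    for mi, di in zip(m_amu, d):
        inertia += mi * ((di @ di) * np.eye(3) - np.outer(di, di))
    eigs = np.linalg.eigvalsh(inertia)
    return 5 if eigs[0] < _LINEAR_TOL else 6


def compute_normal_modes(
    system: MolecularSystem, surface: PotentialSurface
) -> NormalModeBasis:
    """Diagonalize the Eckart-projected mass-weighted Hessian at equilibrium.

    ``surface`` must provide the Cartesian Hessian (hartree/bohr^2) at the
    system's equilibrium geometry.  Rigid translations and rotations are
    removed by the complement projector ``P = 1 - sum v v^T`` over the
    orthonormalized rigid-body vectors, and ``P H_mw P`` is diagonalized.
    Eigenvalues of the vibrational block give ``w_j = sqrt(lambda_j)``;
    negative eigenvalues beyond tolerance are flagged as imaginary modes.
    """
    n_dof = 3 * system.n_atoms
    h_cart = surface.hessian_at(system.equilibrium_geometry)
    if h_cart.shape != (n_dof, n_dof):
        raise FrameError("surface Hessian shape does not match 3 * n_atoms")
    inv_sqm = 1.0 / np.sqrt(system.mass_per_dof)
    h_mw = h_cart * np.outer(inv_sqm, inv_sqm)

    rigid = _rigid_body_vectors(system)
    proj = np.eye(n_dof) - rigid @ rigid.T
    h_proj = proj @ h_mw @ proj
    h_proj = 0.5 * (h_proj + h_proj.T)

    eigvals, eigvecs = np.linalg.eigh(h_proj)
    if not np.all(np.isfinite(eigvals)):
        raise FrameError("eigensolve of the projected Hessian did not converge")

    # rigid-body modes: the n_projected eigenvalues closest to zero
    n_projected = rigid.shape[1]
    order = np.argsort(np.abs(eigvals))
    rigid_idx = set(order[:n_projected].tolist())
    vib_idx = [i for i in range(n_dof) if i not in rigid_idx]
    vib_idx.sort(key=lambda i: eigvals[i])

    columns = np.column_stack(
        [eigvecs[:, sorted(rigid_idx)], eigvecs[:, vib_idx]]
    )
    lam = eigvals[vib_idx]
    imag = tuple(int(i) for i, lv in enumerate(lam) if lv < -_ZERO_EIG_TOL)
    freqs = np.sqrt(np.abs(lam))
    return NormalModeBasis(
        frequencies=freqs,
        mode_matrix=columns,
        n_projected=n_projected,
        imaginary_modes=imag,
        eigenvalues=lam,
    )


def dof_normal_modes(surface: PotentialSurface) -> NormalModeBasis:
    """Normal modes of a plain mass-scaled-DOF surface (no rigid-body modes).

    Used for the bundled model systems, which are defined directly in
    mass-scaled coordinates: the Hessian at the reference geometry is
    diagonalized without any projection.
    """
    h = surface.hessian_at(surface.reference_geometry)
    h = 0.5 * (h + h.T)
    eigvals, eigvecs = np.linalg.eigh(h)
    imag = tuple(int(i) for i, lv in enumerate(eigvals) if lv < -_ZERO_EIG_TOL)
    return NormalModeBasis(
        frequencies=np.sqrt(np.abs(eigvals)),
        mode_matrix=eigvecs,
        n_projected=0,
        imaginary_modes=imag,
        eigenvalues=eigvals,
    )


def to_normal_coordinates(
    basis: NormalModeBasis, system: MolecularSystem, cartesian_geometry: np.ndarray
) -> np.ndarray:
    """Full-length normal coordinates ``Q = L^T M^(1/2) (x - x_eq)``.

    The first ``n_projected`` components are the rigid-body coordinates;
    the rest are vibrational.  The equilibrium geometry maps to the zero
    vector, and the round trip through
    :func:`to_cartesian_coordinates` is exact to roundoff.
    """
    x = np.asarray(cartesian_geometry, dtype=float).reshape(-1)
    if x.size != 3 * system.n_atoms:
        raise FrameError("geometry length must be 3 * n_atoms")
    sqm = np.sqrt(system.mass_per_dof)
    return basis.mode_matrix.T @ (sqm * (x - system.equilibrium_geometry))


def to_cartesian_coordinates(
    basis: NormalModeBasis, system: MolecularSystem, normal_coordinates: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`to_normal_coordinates`.

    Accepts either the full coordinate vector or only the vibrational
    block (rigid-body coordinates then assumed zero).
    """
    q = np.asarray(normal_coordinates, dtype=float).reshape(-1)
    n_dof = basis.mode_matrix.shape[0]
    if q.size == basis.n_vibrations and basis.n_projected > 0:
        full = np.zeros(n_dof)
        full[basis.n_projected :] = q
        q = full
    elif q.size != n_dof:
        raise FrameError("normal-coordinate vector has the wrong length")
    inv_sqm = 1.0 / np.sqrt(system.mass_per_dof)
    return system.equilibrium_geometry + inv_sqm * (basis.mode_matrix @ q)


def normal_mode_surface(
    system: MolecularSystem, surface: PotentialSurface, basis: NormalModeBasis
) -> PotentialSurface:
    """Express a Cartesian surface in the vibrational normal coordinates.

    The returned surface has ``dof_count = n_vibrations`` and reference
    geometry 0; energies/gradients/Hessians are obtained by mapping the
    normal coordinates back to Cartesians and rotating the derivatives,
    ``g_nm = L^T M^(-1/2) g_cart`` and ``h_nm = L^T M^(-1/2) H M^(-1/2) L``.
    """
    sqm = np.sqrt(system.mass_per_dof)
    l_vib = basis.vibrational_modes
    t = l_vib / sqm[:, None]  # M^(-1/2) L, shape (3N, n_vib)

    def x_of(qn: np.ndarray) -> np.ndarray:
        return system.equilibrium_geometry + t @ qn

    return PotentialSurface(
        basis.n_vibrations,
        np.zeros(basis.n_vibrations),
        lambda qn: surface.energy_at(x_of(qn)),
        lambda qn: t.T @ surface.gradient_at(x_of(qn)),
        lambda qn: t.T @ surface.hessian_at(x_of(qn)) @ t,
        name=surface.name + "@normal-modes",
    )


def zpe_initial_state(basis: NormalModeBasis, momentum_signs=None):
    """Zero-point-energy initial phase state in the vibrational mode frame.

    Every vibrational mode starts with ``Q_j = 0`` and ``P_j = +sqrt(w_j)``
    (kinetic energy ``w_j / 2`` per mode); the propagated force estimate
    starts at exactly zero.  The sign of each momentum can be overridden
    per mode via ``momentum_signs``.  Raises if imaginary frequencies are
    present, since no zero-point momentum can be assigned to them.
    """
    from .sef_integrators import PhaseState  # local import avoids a cycle

    if basis.imaginary_modes:
        raise FrameError(
            f"cannot assign ZPE momenta: imaginary modes {basis.imaginary_modes}"
        )
    n = basis.n_vibrations
    p = np.sqrt(basis.frequencies)
    if momentum_signs is not None:
        signs = np.asarray(momentum_signs, dtype=float).reshape(-1)
        if signs.size != n:
            raise FrameError("momentum_signs length must equal n_vibrations")
        p = p * np.sign(signs)
    return PhaseState(
        q=np.zeros(n), p=p, f_tilde=np.zeros(n), q_hat=np.zeros(n), t=0.0
    )


# ---------------------------------------------------------------------------
# XYZ I/O (standard XYZ: count line, comment line, element x y z in Angstrom)
# ---------------------------------------------------------------------------


def read_xyz(path: str) -> list[tuple[list[str], np.ndarray, str]]:
    """Read a (multi-frame) XYZ file; coordinates converted to bohr.

    Returns a list of ``(labels, flat_geometry_bohr, comment)`` frames.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        labels, coords = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            labels.append(parts[0])
            coords.extend(float(v) for v in parts[1:4])
        frames.append((labels, np.array(coords) * ANGSTROM_TO_BOHR, comment))
        i += 2 + n
    return frames


def write_xyz(path: str, labels: list[str], geometries, comments=None) -> None:
    """Write one or more flat bohr geometries as standard XYZ (Angstrom)."""
    geometries = np.atleast_2d(np.asarray(geometries, dtype=float))
    if not np.all(np.isfinite(geometries)):
        raise FrameError("refusing to write non-finite coordinates")
    n = len(labels)
    with open(path, "w") as fh:
        for k, geom in enumerate(geometries):
            comment = "" if comments is None else comments[k]
            fh.write(f"{n}\n{comment}\n")
            for label, xyz in zip(labels, geom.reshape(n, 3) / ANGSTROM_TO_BOHR):
                fh.write(f"{label} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
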