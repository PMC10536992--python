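"""Pair-decoupled Hessian construction and mode freezing.

The pair-decoupling idea: off-diagonal Hessian elements coupling two
chosen groups of degrees of freedom are scaled by a coefficient
``alpha`` in [0, 1] (1 = no decoupling, 0 = fully decoupled).  The
diagonal is never touched, so the trace is preserved exactly, and the
scaled matrix stays symmetric.  At ``alpha = 0`` between two groups that
partition all DOFs the Hessian becomes block diagonal and the dynamics
separates into independent subsystems.

Two frames are supported:

* ``normal_mode`` (alias ``direct``): the group indices refer directly
  to the coordinates the propagation runs in, and the Hessian elements
  are scaled in place.
* ``cartesian_atoms``: whole-atom decoupling.  The normal-mode
  Hessian is rotated to (mass-weighted) Cartesian coordinates, whole-atom
  ``(x, y, z)`` index triples are scaled, and the matrix is rotated back.
  Using the *mass-weighted* Cartesian frame keeps the transform
  orthogonal, so symmetry and trace are preserved exactly; a
  plain-Cartesian variant is available behind ``mass_weighted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .molecular_frame import MolecularSystem, NormalModeBasis

__all__ = [
    "DecouplingSpec",
    "apply_mode_freezing",
    "cartesian_atom_decoupled_hessian",
    "make_hessian_transform",
    "scale_hessian_pairs",
]


class DecouplingError(ValueError):
    """Raised for invalid decoupling specifications."""


_FRAMES = {"normal_mode", "direct", "cartesian_atoms"}


@dataclass(frozen=True)
class DecouplingSpec:
    """Which DOF groups are decoupled, with one alpha per group pair.

    ``group_pairs`` is a sequence of ``(group_a, group_b, alpha)``;
    groups are sets of 0-based DOF indices (in ``cartesian_atoms`` frame
    they must be unions of whole-atom ``(3i, 3i+1, 3i+2)`` triples).
    ``frozen_modes`` are normal-mode indices pinned at equilibrium during
    propagation.
    """

    group_pairs: tuple[tuple[frozenset, frozenset, float], ...] = ()
    frame: str = "normal_mode"
    frozen_modes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.frame not in _FRAMES:
            raise DecouplingError(
                f"unknown frame {self.frame!r}; expected one of {sorted(_FRAMES)}"
            )
        pairs = []
        for group_a, group_b, alpha in self.group_pairs:
            a, b = frozenset(group_a), frozenset(group_b)
            if not (0.0 <= alpha <= 1.0):
                raise DecouplingError(f"alpha must be in [0, 1], got {alpha}")
            if a & b:
                raise DecouplingError("decoupled groups must be disjoint")
            if self.frame == "cartesian_atoms":
                for grp in (a, b):
                    atoms = {i // 3 for i in grp}
                    if grp != frozenset(
                        3 * at + k for at in atoms for k in range(3)
                    ):
                        raise DecouplingError(
                            "cartesian_atoms groups must be unions of whole-atom "
                            "(x, y, z) index triples"
                        )
            pairs.append((a, b, float(alpha)))
        object.__setattr__(self, "group_pairs", tuple(pairs))
        object.__setattr__(self, "frozen_modes", frozenset(self.frozen_modes))

    @staticmethod
    def from_atom_pairs(
        atom_pairs: Iterable[tuple[Sequence[int], Sequence[int], float]],
        frozen_modes: Iterable[int] = (),
        one_based: bool = False,
    ) -> "DecouplingSpec":
        """Build a ``cartesian_atoms`` spec from atom-index groups.

        ``one_based=True`` accepts the 1-based atom labels conventional in
        structure figures; DOF indices are always 0-based internally.
        """
        off = 1 if one_based else 0
        pairs = []
        for atoms_a, atoms_b, alpha in atom_pairs:
            dof_a = frozenset(3 * (a - off) + k for a in atoms_a for k in range(3))
            dof_b = frozenset(3 * (b - off) + k for b in atoms_b for k in range(3))
            pairs.append((dof_a, dof_b, alpha))
        return DecouplingSpec(
            group_pairs=tuple(pairs),
            frame="cartesian_atoms",
            frozen_modes=frozenset(frozen_modes),
        )


def _scale_matrix(n: int, spec: DecouplingSpec) -> np.ndarray:
    """Elementwise scale factors; overlapping pairs are an error."""
    scale = np.ones((n, n))
    touched = np.zeros((n, n), dtype=bool)
    for group_a, group_b, alpha in spec.group_pairs:
        ia = np.fromiter(group_a, dtype=int)
        ib = np.fromiter(group_b, dtype=int)
        if ia.size and (ia.max() >= n or ia.min() < 0):
            raise DecouplingError("group index out of range")
        if ib.size and (ib.max() >= n or ib.min() < 0):
            raise DecouplingError("group index out of range")
        sub = touched[np.ix_(ia, ib)]
        if sub.any():
            raise DecouplingError(
                "overlapping group pairs touch the same Hessian element; "
                "no silent override is performed"
            )
        touched[np.ix_(ia, ib)] = True
        touched[np.ix_(ib, ia)] = True
        scale[np.ix_(ia, ib)] = alpha
        scale[np.ix_(ib, ia)] = alpha
    return scale


def scale_hessian_pairs(h: np.ndarray, spec: DecouplingSpec) -> np.ndarray:
    """Scale the Hessian elements that cross each decoupled group pair.

    ``h_ij -> alpha * h_ij`` exactly when ``(i, j)`` crosses a decoupled
    pair, all other elements (including the whole diagonal) untouched.
    The output is symmetric and has the same trace as the input.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise DecouplingError("h must be a square matrix")
    if np.max(np.abs(h - h.T)) > 1e-10 * max(np.max(np.abs(h)), 1.0):
        raise DecouplingError("h must be symmetric")
    if not spec.group_pairs:
        return h.copy()
    return h * _scale_matrix(h.shape[0], spec)


def cartesian_atom_decoupled_hessian(
    h_nm: np.ndarray,
    basis: NormalModeBasis,
    system: MolecularSystem | None,
    spec: DecouplingSpec,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Rotate-scale-rotate: decouple whole atoms of a normal-mode Hessian.

    ``h_nm`` (n_vib x n_vib) is rotated to the (mass-weighted) Cartesian
    frame with the vibrational mode matrix ``L``, the atom-pair elements
    are scaled, and the result is rotated back:
    ``h_out = L^T scale(L h_nm L^T) L``.  With the default mass-weighted
    frame ``L`` is orthonormal-column, so ``alpha = 1`` returns the input
    to machine precision.  ``mass_weighted=False`` performs the scaling
    on the plain-Cartesian Hessian instead (non-orthogonal transform).
    """
    if spec.frame != "cartesian_atoms":
        raise DecouplingError("spec.frame must be 'cartesian_atoms'")
    h_nm = np.asarray(h_nm, dtype=float)
    l_vib = basis.vibrational_modes
    n_cart = l_vib.shape[0]
    if mass_weighted or system is None:
        fwd, back = l_vib, l_vib.T
    else:
        # plain Cartesian: H_cart = M^(1/2) L h_nm L^T M^(1/2) and the
        # inverse rotation uses M^(-1/2) L (exact pair, non-orthogonal)
        sqm = np.sqrt(system.mass_per_dof)
        fwd = l_vib * sqm[:, None]
        back = (l_vib / sqm[:, None]).T
    h_cart = fwd @ h_nm @ fwd.T
    scaled = h_cart * _scale_matrix(n_cart, spec)
    out = back @ scaled @ back.T
    return 0.5 * (out + out.T)


def make_hessian_transform(
    spec: DecouplingSpec | None,
    basis: NormalModeBasis | None = None,
    system: MolecularSystem | None = None,
    n_dof: int | None = None,
) -> Callable[[np.ndarray], np.ndarray] | None:
    """Compile a decoupling spec into a fast ``h -> h_tilde`` callable.

    Returns ``None`` when there is nothing to scale (no spec or no group
    pairs), letting integrators skip the transform entirely.
    """
    if spec is None or not spec.group_pairs:
        return None
    if spec.frame in ("normal_mode", "direct"):
        if n_dof is None and basis is not None:
            n_dof = basis.n_vibrations or basis.mode_matrix.shape[0]
        if n_dof is None:
            raise DecouplingError("n_dof (or basis) required for direct scaling")
        scale = _scale_matrix(n_dof, spec)
        return lambda h: h * scale
    if basis is None:
        raise DecouplingError("cartesian_atoms decoupling needs a NormalModeBasis")
    l_vib = basis.vibrational_modes
    scale = _scale_matrix(l_vib.shape[0], spec)

    def transform(h: np.ndarray) -> np.ndarray:
        h_cart = l_vib @ h @ l_vib.T
        out = l_vib.T @ (h_cart * scale) @ l_vib
        return 0.5 * (out + out.T)

    return transform


def apply_mode_freezing(state, spec: DecouplingSpec | None):
    """Pin frozen modes at equilibrium: zero their coordinate, momentum,
    force estimate and auxiliary position components, leaving everything
    else untouched.  An empty frozen set is a no-op.  The mode indices
    refer to the propagation frame.
    """
    if spec is None or not spec.frozen_modes:
        return state
    idx = np.fromiter(spec.frozen_modes, dtype=int)
    if idx.size and (idx.max() >= state.q.size or idx.min() < 0):
        raise DecouplingError("frozen mode index out of range")
    out = state.copy()
    out.q[idx] = 0.0
    out.p[idx] = 0.0
    out.f_tilde[idx] = 0.0
    out.q_hat[idx] = 0.0
    return out
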