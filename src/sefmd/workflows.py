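"""Configuration-driven end-to-end runs and download-free model systems.

The fixture generator bundles small model systems, defined directly in
mass-scaled coordinates (atomic units), that exercise every scenario
class the integrator family targets: coupled quadratic networks, Morse
anharmonicity, quartic force fields.  Frequencies are placed in the
molecular mid-infrared (roughly 0.005-0.02 au, i.e. 1000-4400 cm^-1)
with inter-site couplings one to two orders of magnitude below the
diagonal force constants — the typical regime of mildly coupled normal
modes.  All randomness (coefficient jitter) flows from a single explicit
seed; propagation itself is seed-free and deterministic.

``run_from_config`` executes the full pipeline (normal modes, ZPE
initial conditions, propagation, diagnostics, spectra) from a YAML
mapping and writes TSV/XYZ/NPZ artifacts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .decoupling import DecouplingSpec
from .diagnostics import energy_drift
from .model_potentials import (
    PotentialSurface,
    QuarticForceField,
    build_harmonic_surface,
)
from .molecular_frame import (
    MolecularSystem,
    NormalModeBasis,
    dof_normal_modes,
    write_xyz,
    to_cartesian_coordinates,
)
from .sef_integrators import (
    PhaseState,
    SimulationConfig,
    Trajectory,
    get_scheme,
    propagate,
)
from .spectra import total_power_spectrum

__all__ = [
    "FIXTURE_NAMES",
    "RunConfig",
    "RunResult",
    "make_fixture",
    "run_from_config",
    "site_zpe_state",
    "write_xyz_trajectory",
]

logger = logging.getLogger("sefmd")

FIXTURE_NAMES = (
    "harmonic_chain_k",
    "triatomic_morse_bend",
    "quartic_toy",
    "coupled_pair_2d",
)


class WorkflowError(ValueError):
    """Raised for invalid run configurations."""


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _chain_hessian(k: int, rng: np.random.Generator) -> np.ndarray:
    """Spring matrix of the k-site harmonic chain.

    Nearest neighbours are connected by springs of constant 1e-4 au
    (frequencies up to 2e-2 au); every non-adjacent pair by a weak
    long-range spring of 5e-6 au, jittered by +-10% from the seed.  Site
    ``i`` additionally feels an on-site spring of 2.5e-5 au so that all
    modes (including the would-be free translation of the chain) are
    bound.  For a spring network, ``H_ii = k_onsite + sum_j k_ij`` and
    ``H_ij = -k_ij``.
    """
    k_nn = 1.0e-4
    k_on = 2.5e-5
    h = np.zeros((k, k))
    for i in range(k):
        h[i, i] += k_on
    for i in range(k - 1):
        for j in range(i + 1, k):
            kij = k_nn if j == i + 1 else 5.0e-6 * (1.0 + 0.1 * rng.uniform(-1, 1))
            h[i, i] += kij
            h[j, j] += kij
            h[i, j] -= kij
            h[j, i] -= kij
    return h


def _triatomic_surface(rng: np.random.Generator) -> PotentialSurface:
    """Two Morse stretches plus a harmonic bend, bilinearly coupled.

    ``V(q) = D (1 - e^(-a q1))^2 + D (1 - e^(-a q2))^2 + w_b^2 q3^2 / 2
    + k12 q1 q2 + k13 q1 q3 + k23 q2 q3`` with D = 0.1 hartree,
    a = 0.04 (mass-scaled au; harmonic stretch frequency
    ``a sqrt(2D) ~ 0.0179 au ~ 3925 cm^-1``), bend ``w_b = 0.007 au``
    (~1536 cm^-1), and couplings of order 1e-5 jittered by the seed.
    The origin is a stationary point for any couplings.
    """
    d_e, a_w, w_b = 0.1, 0.04, 0.007
    k12 = 1.0e-5 * (1.0 + 0.2 * rng.uniform(-1, 1))
    k13 = 8.0e-6 * (1.0 + 0.2 * rng.uniform(-1, 1))
    k23 = 8.0e-6 * (1.0 + 0.2 * rng.uniform(-1, 1))

    def morse(x):
        u = 1.0 - np.exp(-a_w * x)
        return d_e * u * u

    def dmorse(x):
        e = np.exp(-a_w * x)
        return 2.0 * d_e * a_w * e * (1.0 - e)

    def d2morse(x):
        e = np.exp(-a_w * x)
        return 2.0 * d_e * a_w * a_w * e * (2.0 * e - 1.0)

    def energy(q):
        return (
            morse(q[0]) + morse(q[1]) + 0.5 * w_b**2 * q[2] ** 2
            + k12 * q[0] * q[1] + k13 * q[0] * q[2] + k23 * q[1] * q[2]
        )

    def gradient(q):
        return np.array([
            dmorse(q[0]) + k12 * q[1] + k13 * q[2],
            dmorse(q[1]) + k12 * q[0] + k23 * q[2],
            w_b**2 * q[2] + k13 * q[0] + k23 * q[1],
        ])

    def hessian(q):
        return np.array([
            [d2morse(q[0]), k12, k13],
            [k12, d2morse(q[1]), k23],
            [k13, k23, w_b**2],
        ])

    return PotentialSurface(3, np.zeros(3), energy, gradient, hessian,
                            name="triatomic_morse_bend")


def make_fixture(
    name: str, seed: int = 0, **params
) -> tuple[MolecularSystem | None, PotentialSurface]:
    """Deterministic model system for a given (name, seed).

    Supported names: ``harmonic_chain_<k>`` (e.g. ``harmonic_chain_3``),
    ``triatomic_morse_bend``, ``quartic_toy``, ``coupled_pair_2d``
    (optional ``coupling=`` override, au).  The fixtures are plain
    mass-scaled-DOF systems, so the molecular-system slot is ``None``;
    their normal modes come from :func:`~sefmd.molecular_frame.dof_normal_modes`.
    """
    rng = np.random.default_rng(seed)
    if name.startswith("harmonic_chain"):
        try:
            k = int(name.rsplit("_", 1)[1])
        except (IndexError, ValueError):
            raise WorkflowError(f"bad harmonic chain fixture name {name!r}")
        if k < 2:
            raise WorkflowError("harmonic chain needs at least 2 sites")
        h = _chain_hessian(k, rng)
        return None, build_harmonic_surface(h, np.zeros(k), name=name)
    if name == "triatomic_morse_bend":
        return None, _triatomic_surface(rng)
    if name == "quartic_toy":
        omegas = np.array([0.005, 0.01, 0.018]) * (1.0 + 0.05 * rng.uniform(-1, 1, 3))
        n = 3
        cubic = np.zeros((n, n, n))
        quartic = np.zeros((n, n, n, n))
        for idx in [(0, 0, 1), (1, 1, 2), (0, 1, 2)]:
            val = 1.0e-6 * rng.uniform(-1, 1)
            import itertools
            for perm in set(itertools.permutations(idx)):
                cubic[perm] = val
        for j in range(n):
            quartic[j, j, j, j] = 1.0e-7 * rng.uniform(0.5, 1.0)
        ff = QuarticForceField(omegas, cubic, quartic, name="quartic_toy")
        return None, ff.as_surface()
    if name == "coupled_pair_2d":
        coupling = params.get("coupling")
        if coupling is None:
            coupling = 2.0e-5 * (1.0 + 0.1 * rng.uniform(-1, 1))
        w1, w2 = 0.01, 0.015
        h = np.array([[w1**2, float(coupling)], [float(coupling), w2**2]])
        return None, build_harmonic_surface(h, np.zeros(2), name=name)
    raise WorkflowError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )


def site_zpe_state(basis: NormalModeBasis, reference_geometry: np.ndarray) -> PhaseState:
    """ZPE initial conditions expressed in the site (propagation) frame.

    Positions start at the reference geometry; the momentum is the
    mode-frame ZPE momentum ``sqrt(w_j)`` rotated to the site frame,
    ``p0 = L sqrt(w)``.  The initial force estimate is zero.
    """
    if basis.imaginary_modes:
        raise WorkflowError(
            f"cannot assign ZPE momenta: imaginary modes {basis.imaginary_modes}"
        )
    q0 = np.asarray(reference_geometry, dtype=float).reshape(-1)
    p0 = basis.mode_matrix @ np.sqrt(basis.frequencies)
    return PhaseState(q=q0, p=p0, f_tilde=np.zeros_like(q0), q_hat=q0.copy(), t=0.0)


# ---------------------------------------------------------------------------
# configuration-driven runs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of one simulation.

    YAML schema (all decoupling DOF indices 0-based; ``cartesian_atoms``
    groups may use 1-based atom labels via ``atoms_one_based: true``)::

        fixture: harmonic_chain_3      # or system: {xyz: file, surface: ...}
        seed: 1
        scheme: SEF2
        dt: 10.0
        steps: 3000
        discard: 0
        decouple:
          - {frame: normal_mode, groups: [[0], [1, 2]], alpha: 0.0}
        freeze_modes: []
        out:
          trajectory: traj.npz         # .npz or .xyz
          spectrum: spectrum.tsv
          diagnostics: energy.tsv
    """

    fixture: str | None = None
    seed: int = 0
    scheme: str = "SEF2"
    dt: float = 10.0
    steps: int = 3000
    discard: int = 0
    decouple: list = field(default_factory=list)
    freeze_modes: list = field(default_factory=list)
    fixture_params: dict = field(default_factory=dict)
    out: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise WorkflowError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def decoupling_spec(self) -> DecouplingSpec | None:
        if not self.decouple and not self.freeze_modes:
            return None
        pairs = []
        frame = "normal_mode"
        for entry in self.decouple:
            frame = entry.get("frame", "normal_mode")
            groups = entry["groups"]
            if len(groups) != 2:
                raise WorkflowError("each decouple entry needs exactly 2 groups")
            group_a, group_b = (frozenset(int(i) for i in g) for g in groups)
            if frame == "cartesian_atoms" and entry.get("atoms_one_based"):
                group_a = frozenset(
                    3 * (at - 1) + k for at in groups[0] for k in range(3)
                )
                group_b = frozenset(
                    3 * (at - 1) + k for at in groups[1] for k in range(3)
                )
            pairs.append((group_a, group_b, float(entry["alpha"])))
        return DecouplingSpec(
            group_pairs=tuple(pairs),
            frame=frame,
            frozen_modes=frozenset(int(j) for j in self.freeze_modes),
        )


@dataclass
class RunResult:
    trajectory: Trajectory
    basis: NormalModeBasis
    surface: PotentialSurface
    spectrum: object
    energy_summary: dict
    hessian_calls: int
    outputs: dict


def run_from_config(config: RunConfig | str) -> RunResult:
    """Execute propagate -> diagnostics -> spectra for one configuration.

    Logs the scheme, alpha map and the instrumented Hessian-call count
    (``n_steps x scheme.hessian_evals_per_step`` for SEF schemes).
    Partial outputs are removed if any stage fails.
    """
    if isinstance(config, str):
        config = RunConfig.from_yaml(config)
    if config.steps <= 0:
        raise WorkflowError("steps must be positive")
    if config.discard >= config.steps:
        raise WorkflowError("discard must be smaller than steps")
    if config.fixture is None:
        raise WorkflowError("config must name a fixture")

    system, surface = make_fixture(
        config.fixture, config.seed, **config.fixture_params
    )
    basis = dof_normal_modes(surface)
    spec = config.decoupling_spec()
    scheme = get_scheme(config.scheme)
    sim = SimulationConfig(
        dt=config.dt, n_steps=config.steps, discard_steps=config.discard,
        scheme=scheme.name, spec=spec,
    )
    initial = site_zpe_state(basis, surface.reference_geometry)

    surface.reset_counters()
    written: list[str] = []
    try:
        trajectory = propagate(initial, surface, sim, basis=basis)
        hessian_calls = surface.calls["hessian"]
        expected = sim.n_steps * scheme.hessian_evals_per_step
        if scheme.needs_hessian and hessian_calls != expected:
            raise WorkflowError(
                f"Hessian call count {hessian_calls} != expected {expected}"
            )
        energy_summary = energy_drift(trajectory.energies, dt=config.dt)
        spectrum = total_power_spectrum(trajectory, basis=basis)

        outputs = {}
        out = config.out or {}
        if "trajectory" in out:
            path = out["trajectory"]
            if path.endswith(".xyz"):
                if system is None:
                    raise WorkflowError(
                        "xyz output requires a molecular system; use .npz"
                    )
                write_xyz_trajectory(trajectory, system, basis, path)
            else:
                trajectory.save_npz(path)
            written.append(path)
            outputs["trajectory"] = path
        if "spectrum" in out:
            spectrum.write_tsv(out["spectrum"])
            written.append(out["spectrum"])
            outputs["spectrum"] = out["spectrum"]
        if "diagnostics" in out:
            table = np.column_stack([trajectory.times, trajectory.energies])
            np.savetxt(out["diagnostics"], table, delimiter="\t",
                       header="t\tenergy", comments="", fmt="%.12e")
            written.append(out["diagnostics"])
            outputs["diagnostics"] = out["diagnostics"]
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise

    logger.info(
        "run complete: fixture=%s scheme=%s steps=%d hessian_calls=%d alpha_map=%s",
        config.fixture, scheme.name, config.steps, hessian_calls,
        trajectory.meta.get("alpha_map"),
    )
    return RunResult(
        trajectory=trajectory, basis=basis, surface=surface, spectrum=spectrum,
        energy_summary=energy_summary, hessian_calls=hessian_calls,
        outputs=outputs,
    )


AU_TIME_TO_FS = 2.4188843265857e-2


def write_xyz_trajectory(
    trajectory: Trajectory,
    system: MolecularSystem,
    basis: NormalModeBasis,
    path: str,
) -> None:
    """Write a trajectory as multi-frame XYZ (Angstrom, time in fs).

    The stored normal coordinates are mapped back to Cartesian
    geometries; non-finite coordinates refuse to write.
    """
    geoms = np.array([
        to_cartesian_coordinates(basis, system, qk) for qk in trajectory.q
    ])
    comments = [f"t = {t * AU_TIME_TO_FS:.6f} fs" for t in trajectory.times]
    write_xyz(path, system.atom_labels, geoms, comments)
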