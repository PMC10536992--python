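"""Classical vibrational power spectra from mode momentum series.

The power spectrum of the j-th mass-scaled normal mode is the squared
finite-time Fourier transform of its momentum,

    I_j(w) = (1 / 2 pi T) | integral_0^T p_j(t) exp(-i w t) dt |^2,

discretized by an FFT of the retained samples with a rectangular window
(frequency resolution ``dw = 2 pi / T``).  The multidimensional spectrum
is simply the sum of the per-mode spectra.  Peak positions give the
anharmonic vibrational frequencies; the intensities depend only on how
often each mode was visited by this particular trajectory and are *not*
comparable with IR or Raman intensities.  The integral of ``I_j`` over
frequency equals twice the time-averaged kinetic energy of the mode
(discrete Parseval identity), which is what makes intensity differences
between decoupled and normal simulations interpretable as vibrational
energy redistribution.

An initial decorrelation segment (about 0.5 ps for weak decouplings) can
be discarded before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .molecular_frame import NormalModeBasis
from .sef_integrators import Trajectory

__all__ = [
    "HARTREE_TO_CM1",
    "SpectrumResult",
    "mode_power_spectrum",
    "peak_frequencies",
    "total_power_spectrum",
]

HARTREE_TO_CM1 = 219474.63

_MIN_SAMPLES = 64


class SpectrumError(ValueError):
    """Raised for unusable spectral inputs."""


def _periodogram(samples: np.ndarray, dt: float, pad_factor: int = 1):
    """One-sided rectangular-window periodogram of a real series.

    Interior bins are doubled so that ``sum I dw`` equals the mean of
    ``samples**2`` (two-sided Parseval folded onto w >= 0).  ``pad_factor``
    zero-pads the FFT for finer peak readout without changing integrals.
    """
    n = samples.size
    t_span = n * dt
    n_fft = n * pad_factor
    coeffs = np.fft.rfft(samples, n=n_fft)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_fft, d=dt)
    intensity = (dt * dt / (2.0 * np.pi * t_span)) * np.abs(coeffs) ** 2
    fold = np.full(omega.size, 2.0)
    fold[0] = 1.0
    if n_fft % 2 == 0:
        fold[-1] = 1.0
    return omega, intensity * fold


def mode_power_spectrum(
    mode_momentum_series: np.ndarray,
    dt: float,
    discard: int = 0,
    pad_factor: int = 1,
    window: str = "rect",
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum ``I_j(w)`` of one mode momentum series.

    ``discard`` initial samples are dropped (decorrelation time) before
    the FFT.  ``window="hann"`` applies a Hann window (amplitude
    normalized); the default rectangular window matches the resolution
    behaviour of short simulations.
    """
    p = np.asarray(mode_momentum_series, dtype=float).reshape(-1)
    if discard < 0 or discard >= p.size:
        raise SpectrumError("discard must be in [0, len(series))")
    p = p[discard:]
    if p.size < _MIN_SAMPLES:
        raise SpectrumError(
            f"only {p.size} retained samples; at least {_MIN_SAMPLES} required"
        )
    if window == "hann":
        w = np.hanning(p.size)
        p = p * w / np.sqrt(np.mean(w**2))
    elif window != "rect":
        raise SpectrumError("window must be 'rect' or 'hann'")
    return _periodogram(p, dt, pad_factor)


@dataclass
class SpectrumResult:
    """Per-mode and summed power spectra on a common frequency grid.

    ``total_intensity`` is the pointwise sum of the mode rows (frozen
    modes excluded, listed in ``frozen_modes``).  ``omega_fine`` /
    ``mode_intensities_fine`` hold a 4x zero-padded version for sub-bin
    peak readout; integrals are taken on the raw grid.
    """

    omega_au: np.ndarray
    mode_intensities: np.ndarray
    total_intensity: np.ndarray
    t_used: float
    discarded_steps: int
    frozen_modes: tuple[int, ...] = ()
    omega_fine: np.ndarray | None = None
    mode_intensities_fine: np.ndarray | None = None

    @property
    def omega_cm1(self) -> np.ndarray:
        return self.omega_au * HARTREE_TO_CM1

    @property
    def grid_spacing_au(self) -> float:
        return float(self.omega_au[1] - self.omega_au[0])

    @property
    def grid_spacing_cm1(self) -> float:
        return self.grid_spacing_au * HARTREE_TO_CM1

    @property
    def n_modes(self) -> int:
        return self.mode_intensities.shape[0]

    def mode_integral(self, j: int) -> float:
        """``integral I_j(w) dw`` on the raw grid (au)."""
        return float(np.sum(self.mode_intensities[j]) * self.grid_spacing_au)

    def total_integral(self) -> float:
        return float(np.sum(self.total_intensity) * self.grid_spacing_au)

    def write_tsv(self, path: str) -> None:
        header = ["omega_au", "omega_cm1", "I_total"] + [
            f"I_mode_{j}" for j in range(self.n_modes)
        ]
        table = np.column_stack(
            [self.omega_au, self.omega_cm1, self.total_intensity]
            + [self.mode_intensities[j] for j in range(self.n_modes)]
        )
        np.savetxt(path, table, delimiter="\t", header="\t".join(header),
                   comments="", fmt="%.12e")


def total_power_spectrum(
    trajectory: Trajectory,
    basis: NormalModeBasis | None = None,
    discard: int | None = None,
    pad_factor_fine: int = 4,
) -> SpectrumResult:
    """Per-mode spectra and their sum for a whole trajectory.

    If ``basis`` is given, the stored momenta are projected onto the
    vibrational modes (``p_modes = L^T p``); otherwise they are taken to
    be mode momenta already (the propagation frame of molecular runs).
    Frozen modes (from the trajectory metadata) are excluded from the
    total and reported in ``frozen_modes``.
    """
    if discard is None:
        discard = trajectory.discard_steps
    p = trajectory.p
    if basis is not None:
        modes = (
            basis.vibrational_modes
            if basis.mode_matrix.shape[0] == p.shape[1] and basis.n_projected
            else basis.mode_matrix
        )
        if modes.shape[0] != p.shape[1]:
            raise SpectrumError(
                "basis dimension does not match the trajectory momenta"
            )
        p = p @ modes  # columns: mode momenta
    n_modes = p.shape[1]
    frozen = tuple(int(j) for j in trajectory.meta.get("frozen_modes", ()))

    rows, rows_fine = [], []
    omega = omega_fine = None
    for j in range(n_modes):
        omega, intens = mode_power_spectrum(p[:, j], trajectory.dt, discard)
        omega_fine, fine = mode_power_spectrum(
            p[:, j], trajectory.dt, discard, pad_factor=pad_factor_fine
        )
        rows.append(intens)
        rows_fine.append(fine)
    mode_intensities = np.vstack(rows)
    active = [j for j in range(n_modes) if j not in frozen]
    total = mode_intensities[active].sum(axis=0) if active else np.zeros_like(omega)
    n_retained = trajectory.times.size - discard
    return SpectrumResult(
        omega_au=omega,
        mode_intensities=mode_intensities,
        total_intensity=total,
        t_used=n_retained * trajectory.dt,
        discarded_steps=discard,
        frozen_modes=frozen,
        omega_fine=omega_fine,
        mode_intensities_fine=np.vstack(rows_fine),
    )


def peak_frequencies(
    result: SpectrumResult, prominence: float = 0.1
) -> list[tuple[int, float, float]]:
    """Local maxima above ``prominence * global max``, per mode.

    Returns ``(mode_index, omega_cm1, intensity)`` tuples ordered by
    frequency, read off the zero-padded fine grid when available.
    """
    if prominence <= 0:
        raise SpectrumError("prominence must be positive")
    if result.mode_intensities_fine is not None:
        grid = result.omega_fine * HARTREE_TO_CM1
        spectra = result.mode_intensities_fine
    else:
        grid = result.omega_cm1
        spectra = result.mode_intensities
    global_max = float(spectra.max()) if spectra.size else 0.0
    peaks: list[tuple[int, float, float]] = []
    if global_max == 0.0:
        return peaks
    threshold = prominence * global_max
    for j in range(spectra.shape[0]):
        idx, _ = find_peaks(spectra[j], height=threshold)
        for i in idx:
            peaks.append((j, float(grid[i]), float(spectra[j, i])))
    peaks.sort(key=lambda rec: rec[1])
    return peaks
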