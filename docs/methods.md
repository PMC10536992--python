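# Methods

## Pair-decoupled dynamics

The package models the "what if these atoms stopped feeling each other"
experiment by modifying second derivatives only: for a chosen pair of
DOF groups A and B, every Hessian element h_ij with i ∈ A, j ∈ B is
multiplied by α ∈ [0, 1].  The diagonal is never scaled, so the trace
(and therefore the sum of squared frequencies) is preserved exactly, and
the scaled matrix stays symmetric.  At α = 0 between two groups that
partition all DOFs the Hessian is block diagonal and the dynamics
separates exactly into independent subsystems; the implementation
guarantees this at machine precision because a block-diagonal
matrix-vector product contributes exact floating-point zeros across
blocks.

Two frames are supported.  In the *direct* (normal-mode) frame the group
indices refer to the propagation coordinates and the elements are scaled
in place.  In the *Cartesian atom* frame the propagation-frame Hessian is
rotated to mass-weighted Cartesian coordinates with the vibrational mode
matrix L, whole-atom (x, y, z) triples are scaled, and the matrix is
rotated back: h̃ = Lᵀ·scale(L h Lᵀ)·L.  Mass-weighted Cartesians were
chosen because L then has orthonormal columns, making the α = 1 path an
exact identity and preserving symmetry and trace exactly; a
plain-Cartesian variant (non-orthogonal transform) is available behind
`mass_weighted=False`.

Overlapping group pairs (two pairs touching the same (i, j) element) are
rejected outright rather than composed — composition rules for
overlapping α's have no physical definition here.

The pair-decoupled Hessian generally does not correspond to a stationary
point of any potential: the equilibrium geometry of the coupled system
is *not* an equilibrium of the decoupled one, which is why harmonic
analysis of h̃ is not meaningful and a dynamical (spectral) analysis is
required.  No re-optimization is attempted.

## The SEF integrators

Because the decoupled system is defined only through h̃, the force is
propagated rather than evaluated.  The extended ODE

    dq/dt = p,   dp/dt = F̃,   dF̃/dt = −h̃(q) p

reproduces the exact dynamics when F̃(0) = −∇Ṽ(q(0)); the default
protocol starts at the coupled equilibrium with F̃(0) = 0, i.e. treats
the start as if it were a stationary point of the decoupled system as
well.

Each SEF2 step is a position-Verlet cycle on (q, p) with the force
quadrature embedded in the drifts.  Within a drift half-segment of
length h/2 the force update is the discretized line integral

    F̃ ← F̃ − (h/2) · h̃(q̂ + (h/4) p) · p ,

i.e. **one Hessian evaluation at the midpoint of the segment**.  The
midpoint rule is the design decision that matters most in this package:

* With the Hessian at the segment *endpoint* (or start), the per-segment
  quadrature error is O(h²) and accumulates in F̃, which measurably
  degrades the scheme to **first order** on anharmonic surfaces (we
  verified slopes of 1.00 on a Morse oscillator for both 2- and 4-stage
  variants).
* With the *midpoint* rule the two half-segments of a cycle straddle the
  kick symmetrically, the O(h²) terms cancel, and the step becomes
  exactly time-symmetric: Φ₋τ ∘ Φτ = Id on the extended state
  (q, p, F̃).  Measured Richardson slopes: 2.00 for SEF2 and 4.00 for
  SEF4 against a tightly converged reference flow.

A byproduct of the symmetric quadrature is that the SEF round trip
(propagate T, flip p, propagate T) retraces to roundoff on *anharmonic*
surfaces too, not only on quadratic ones where exactness holds by
construction.

SEF4 is the Forest–Ruth symmetric product of three SEF2 sub-steps with
scale factors γ₁ = 1/(2 − 2^{1/3}), γ₂ = −2^{1/3}γ₁, γ₁.  Its flat
kick/drift coefficients are the standard fourth-order composition
values (Σa = Σb = 1, b₁ = 0) exposed on the scheme object.  The force
quadrature subdivides each sub-step's two drift halves, so SEF4 performs
**6 Hessian evaluations per step** (SEF2: 2).  A flat 4-evaluation cycle
was measured to be only second order and was rejected.  Higher-order
compositions, force-gradient (Hessian-in-the-kick) integrators, extended
phase-space methods for non-separable Hamiltonians, and thermostats are
out of scope; the dynamics is NVE only.

Fourth-order coefficient sets that are not symmetric products (and are
not time-reversible by construction) are not registered: the scheme
registry carries SE2, SE4, SEF2 and SEF4, and `get_scheme` reports the
available names on a miss.

On quadratic surfaces with a consistent initial force the propagated
force is exact, F̃ₙ = −h̃ (qₙ − q_eq), after every step to machine
precision, and SEF2 coincides step-for-step with leapfrog — the two
hard oracles that pin the reconstruction.

All propagation happens in mass-scaled coordinates with unit mass, so
masses never appear in the inner loop; they enter only in the molecular
frame transforms.

## Molecular frame and initial conditions

Normal modes come from the Eckart-projected mass-weighted Hessian: six
(five for linear molecules, detected by a principal moment of inertia
below 1e-8 amu·bohr²) orthonormalized rigid-body vectors are projected
out with P = 1 − Σ v vᵀ before diagonalization.  Imaginary frequencies
(eigenvalues below −1e-10) are flagged, never silently dropped, and
block zero-point initialization.  The full eigenvector matrix is kept
orthogonal so coordinate round trips are exact.

Initial conditions follow the zero-point-energy protocol: every
vibrational mode starts at its equilibrium position with momentum
P_j = +√ω_j, so each mode carries its harmonic zero-point kinetic energy
ω_j/2.  The sign of √ω_j is a free choice; all-positive is the
deterministic default, overridable per mode.  F̃(0) = 0.

Frozen modes ("kept at equilibrium") have coordinate, momentum, force
estimate and auxiliary position zeroed after every step; the indices
refer to the propagation frame.

## Diagnostics

*Energy.*  The propagation records E = |p|²/2 + V(q) on the fully
coupled surface at every step — the quantity monitored even when the
dynamics is decoupled.  For α ≠ 1 on quadratic surfaces this E
oscillates boundedly (the scaled cross terms beat at frequency
differences) and is *not* the conserved quantity; the conserved energy
of the propagated pair-decoupled Hamiltonian, Ẽ = |p|²/2 + dᵀh̃d/2, is
provided separately, together with the exact discrete invariant of the
second-order composition, Ẽ − (dt²/8) pᵀh̃p, which SEF2/SE2 conserve to
roundoff on quadratics.  Drift is summarized as the least-squares slope
of the series against the step index; a bounded oscillation contributes
a finite-window artifact to that slope, which is why no-drift assertions
are made on the conserved invariant rather than on the oscillating
coupled E.

*Symplecticity.*  The monodromy matrix M(t) = ∂z(t)/∂z(0), z = (q, p),
is built column-by-column from central finite differences of displaced
trajectories (eps = 1e-6 in mass-scaled au; convergence validated by
halving eps once and requiring the final matrix to change by less than
1e-5).  Displaced initial conditions shift the force estimate
consistently, F̃₀' = F̃₀ − h̃(q₀)·δq, so that all auxiliary trajectories
sample the *same* decoupled force law — without this the FD map is the
Jacobian of a family of systems and is not symplectic even for
quadratics.  The deviation Υ = max |(MᵀJM − J)_ij| uses the elementwise
max (the most stringent norm reading); Frobenius is available behind a
flag.

*Reversibility.*  Propagate to T (default 6000 au, commensurate with
dt), flip the momentum sign exactly — F̃ and q̂ keep their current
values, so the force quadrature simply retraces — propagate another T,
and report the RMS over the geometry components of (final − initial),
in Cartesian components when a transform is supplied.

## Power spectra

I_j(ω) is the squared finite-time Fourier transform of the mode momentum
over the retained span, normalized by 1/(2πT) and folded one-sided so
that the discrete integral ∫I_j dω equals the time average of p_j²
(twice the mean kinetic energy) exactly in the Parseval sense.  A
rectangular window is the default (matching the resolution behaviour of
short runs, Δω = 2π/T ≈ 46 cm⁻¹ for 3000 × 10 au); Hann is available
behind a flag.  Peak readout uses a 4× zero-padded grid (integrals are
always taken on the raw grid, which padding provably leaves unchanged).
Intensities are trajectory-population measures, not IR/Raman
intensities.  Spectra are single-trajectory estimates — the protocol
runs one trajectory from the ZPE initial condition, not a phase-space
average.  A decorrelation segment (2000 steps ≈ 0.5 ps for
weak-decoupling runs) can be discarded before the transform.

## Model systems

The bundled fixtures are defined directly in mass-scaled coordinates
with frequencies placed in the molecular mid-infrared (0.005–0.02 au ≈
1100–4400 cm⁻¹) and couplings one to two orders of magnitude below the
diagonal force constants, the regime of mildly coupled vibrations:

* `harmonic_chain_k` — k sites, nearest-neighbour springs 1e-4 au,
  weak long-range springs 5e-6 au (±10% seed jitter), on-site springs
  2.5e-5 au so all modes are bound; frequencies known from the
  documented spring matrix.
* `triatomic_morse_bend` — two Morse stretches (D = 0.1 hartree,
  a = 0.04, harmonic frequency ≈ 3925 cm⁻¹) plus a harmonic bend
  (≈ 1536 cm⁻¹), bilinearly coupled (≈ 1e-5 au, seed-jittered); the
  origin is stationary for any couplings.
* `quartic_toy` — three modes with synthetic cubic/quartic coefficients
  small enough that ZPE-amplitude motion stays bound.
* `coupled_pair_2d` — two modes (0.010 and 0.015 au) with a 2e-5 au
  bilinear coupling, overridable (coupling = 0 gives the naturally
  separable limit).

All randomness flows from one explicit seed into coefficient jitter;
propagation is seed-free and bit-deterministic.  Quartic force-field
coefficients for specific real molecules are not bundled; the evaluator
accepts arbitrary coefficient files.  External fitted surfaces enter
through an adapter needing only energy + gradient (Hessian by
symmetrized central differences); no machine-learning framework is
imported, so everything here runs without downloads.

What the fixtures do *not* emulate: dissociation and large-amplitude
floppy motion on fitted surfaces (where the SEF locally harmonic force
is least accurate and extrapolation blowups are flagged by the
non-finite abort), rovibrational coupling, and the dense mode spectrum
of real mid-size molecules.  Passing tests certify the integrator
family's mathematical guarantees on these conditions, not quantitative
spectra of any specific molecule.

## Numerical choices and problem sizes

dt = 10 au and 3000 steps (5000 with 2000 discarded for weak
decoupling) are the standard protocol; reversibility uses T = 6000 au.
Hessian symmetry is enforced to 1e-10 relative; rigid-body eigenvalues
below 1e-10 count as zero; FD Hessians symmetrize by transpose
averaging and retry once with a 10× step on underflow.  Order
measurements use a unit Morse oscillator integrated to t = 5 with
dt ∈ {0.05, …, 0.00625} against a DOP853 reference at rtol 1e-13.
Monodromy-based checks run on 2–3 DOF fixtures where 4F auxiliary
trajectories of 3000 steps are cheap.  Non-finite states abort with the
step index and offending geometry attached.

## Known limitations

* SEF accuracy rests on the locally harmonic force; strongly anharmonic
  landscapes show larger energy oscillation (never secular drift in our
  tests) and the method cannot describe free translations/rotations,
  which is why propagation always happens in the projected normal-mode
  frame.
* The decoupled Hessian is recomputed at every quadrature point (2 or 6
  per step), limiting system size exactly as any Hessian-based method.
* `cartesian_atoms` decoupling assumes the mass-weighted frame for
  exactness of the invariants; the plain-Cartesian variant does not
  preserve the normal-mode trace.
* Monodromy matrices by finite differences inherit FD noise ~1e-9; Υ
  below that level is indistinguishable from zero.
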