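# Methods

## Model and ansatz

The electronic structure is a configuration-interaction expansion over a
restricted active space.  Determinants are occupation bitstrings over
2·n_orb spin orbitals (all α, then all β; canonical order is ascending
(α-mask, β-mask), which is total and hash-free).  Each RAS partition
carries a hole limit counted in spin orbitals relative to the filled
partition: the standard setup is core 2p (RAS1, ≤ 1 hole), valence 3d
(RAS2, unrestricted) and optional σ-bonding orbitals (RAS1′, ≤ 1 hole).
Because the spin–orbit triplet operators T̂^x, T̂^y change M_s by ±1, the
space is not restricted to a single S_z sector by default; an optional
`ms2` filter exists for spin-free runs, where the ground energy is
S_z-independent (tested).

The Hamiltonian combines spin-free one- and two-electron integrals
(chemist notation, 8-fold real-orbital symmetry) with the mean-field
Breit–Pauli spin–orbit term Σ_c h^c ⊗ s_c, i.e. a general complex one-body
operator in spin-orbital space.  Matrix elements are assembled by
Slater–Condon rules with that complex one-body matrix and verified, element
by element, against an independent Jordan–Wigner construction on the full
Fock space for every small test system.  Internal units are Hartree; all
user-facing energies are eV (conversion constant 27.211386245988).

## Ground state and degenerate manifolds

Below 2500 determinants the ground state comes from dense Hermitian
diagonalization; a single-vector Lanczos run cannot resolve the
multiplicity of a degenerate level, and degenerate ground manifolds (spin
multiplets, Kramers doublets, orbital degeneracy) are the norm in these
systems.  Above that, ARPACK is used with a deterministic start vector
(unit weight on the lowest-diagonal determinant) and a growing window until
the manifold boundary is resolved.  All states within `degeneracy_tol`
(default 1e-6 Hartree) of the lowest eigenvalue form the ground manifold,
and every spectrum is averaged uniformly over it.  Averaging removes any
dependence on the arbitrary choice of basis within the manifold; computing
from a single member instead is possible but not the default.

## Correction vectors and spectra

For each frequency the spectral quantities need C = (z − Ĥ)⁻¹ X with
Im z = η > 0.  All shifts share the Krylov space of Ĥ built from X, so one
Lanczos recurrence (full reorthogonalization; real symmetric tridiagonal
projection) serves every grid point: the per-shift solution is
V_m (z − T_m)⁻¹ β₀e₁ and the residual norm is available in closed form as
β_m |y_m|.  Iteration continues until the worst relative residual over all
shifts is below the tolerance (default 1e-10), with an explicit post-hoc
residual verification; single-shift GMRES (diagonal preconditioner) and
dense-LU paths exist behind the same contract.  A zero right-hand side
returns zero without a solve; a real shift is rejected.

XAS accumulates (η/π)‖A_λ‖² over the three Cartesian dipole components;
RIXS solves one A_λ per incident polarization at fixed ω_ex (chosen as the
grid argmax of the total XAS inside an L₃ window, ties toward lower
energy), then one loss-grid family of B_ρλ per emission polarization, and
accumulates (η′/π)‖B_ρλ‖².  Only resonant terms are kept; the ρ, λ sums
implement the orientation/polarization average; overall prefactors are
normalized away, so RIXS intensities are relative.  Spectra are reported
per eV: an isolated transition of moment m appears with peak height
m²/(πη).  Default broadenings are η = 0.3 eV and η′ = 0.1 eV; default
grid steps are 0.02 eV (XAS) and 0.01 eV (RIXS loss), which resolve the
η′-limited features.  The energy-loss axis ω_ex − ω_em is the default
RIXS abscissa.

The sum-over-states module evaluates the same quantities from a full dense
diagonalization (capped at 2000 determinants by default) — the resonant
Kramers–Heisenberg double sum for RIXS — and serves purely as the
independent cross-check; the correction-vector route never consults it.

## Deconvolution

*Particle–hole.*  The dipole operator is one-body, so the right-hand side
splits exactly into orbital-pair pieces d_pq Ê_pq|Ψ₀⟩.  Component spectra
are the cross terms (η/π) Re⟨A_ia|A⟩, which sum to the total pointwise by
linearity — the sum rule holds by construction and is asserted against the
*independently computed* total at 1e-8.  On resonance the component
measures the amplitude of the i→a excitation in the final state.  Because
components are interference terms they may be locally negative; the total
is nonnegative.  For RIXS the net transition is valence→valence through the
core: the absorption solve is decomposed by the created (particle) orbital
and the emission solve by the annihilated valence (source) orbital, giving
channels keyed (hole = v, particle = a); everything outside that
core-mediated pattern is aggregated into one flagged channel so the sum
rule stays exact, and the integrated valence-to-valence fraction is
reported.  The elastic channel has hole = particle.  Deconvolution is done
in the natural-orbital basis of the ground-state wave function: the
spin-summed one-particle density matrix of the averaged manifold (its
symmetrized real part; the average over a time-reversal-closed manifold is
real) is diagonalized within each shell block, occupations sorted
descending, sign fixed by making the largest coefficient positive.
Rotating the basis re-expresses the integrals and recomputes the ground
state; totals are invariant (tested).

*Spin.*  Löwdin projectors P_S over all attainable spins of the space
(S from (N mod 2)/2 up to min(N, 2n−N)/2) are applied directly to the
correction vectors; since Σ_S P_S = 1 with orthogonal idempotents, the
channel norms (η/π)‖P_S A‖² sum to the total exactly.  The projector
factors are applied in descending S′ order (bounds intermediate growth;
fixed order for determinism).  Channel percentages integrate each channel
over the full computed grid by the trapezoid rule and divide by the
integrated total; an incomplete channel list is detected by the sum rule
and rejected.

## Ligand-field model generator

The generator emulates a tetrahedral Fe L-edge problem in a minimal active
space.  Defaults (eV): 2p level −710 (puts the L₃ edge near 710), core SOC
ζ = 8 applied as +ζ l·s in the electron convention — the one-particle p
levels sit at +ζ/2 (j = 3/2, 4-fold) and −ζ (j = 1/2, 2-fold), so the
one-hole ground manifold is the 4-fold j = 3/2 level and XAS shows L₃
below L₂ with the statistical 2:1 weight and 3ζ/2 separation; crystal
field 10Dq = 0.65 with the e set (z², x²−y²) below t₂; Kanamori-style
valence interactions U = 4, J = 0.8 (intra-orbital U, inter-orbital U−2J,
exchange and pair-hopping J) producing high-spin ground states; and a
core–valence Coulomb term Q = 5 entering as (ii|aa) repulsion, whose loss
upon core-hole creation binds the excited electron.  Angular structure —
real-harmonic l matrices, p–d dipole factors, and the optional full
Slater–Condon two-electron input (F⁰F²F⁴ for d–d, F⁰F²/G¹G³ for 2p–3d) —
is generated from Gaunt coefficients and transformed to real harmonics;
the d² term spectrum reproduces the closed-form Racah energies exactly in
the tests.  Dipoles couple core↔valence only.

What the fixtures do *not* emulate: ligand-to-metal charge-transfer states
(σ-donor orbitals enter only as a single RAS1′ orbital in the σ fixture),
orbital relaxation, dynamic correlation outside the active space, and any
ab initio radial information (dipole radial integrals are a single scale
factor).  Passing tests therefore demonstrate the correctness of the
machinery — equivalence to the sum over states, exact sum rules, analytic
SOC and crystal-field limits, Kramers pairing, spin selection rules — not
agreement with measured spectra of real complexes.  Reproducing real
systems requires external integrals through the adapter (natural-orbital
coefficients, occupations and full-basis integrals from a mean-field
engine), for which only the file contract and the selection/localization/
transformation logic are in scope here.

Problem sizes: the fixture spaces span 13–1710 determinants, chosen so
that every pipeline result can be compared pointwise against dense
diagonalization; the σ-extended fixture uses one σ orbital for the same
reason.  Test and acceptance grids use coarser steps (0.1–2 eV) than the
production defaults where only pointwise identities are being asserted,
since the sum rules and CV–SOS equivalence are grid-independent.

## Numerical choices and limitations

Tolerances: solver residual 1e-10 (relative), ground-state degeneracy
1e-6 Ha, sum-rule assertion 1e-8, symmetry validation 1e-10–1e-12.
Rounding noise in generated SOC/dipole matrices is chopped at 1e-14 of the
largest element so file round trips are bit-exact.  Deterministic
tie-breaks: ω_ex argmax toward lower energy; natural-orbital sign by
largest coefficient.  The default pipeline contains no randomness; reruns
are bit-identical.

Known limitations: dense diagonalization bounds oracle comparisons (and
the default ground-state path) to a few thousand determinants; the
shifted-Lanczos memory grows with the Krylov dimension times the space
dimension; Pipek-style localization uses caller-provided population
operators and is only as meaningful as those; the adapter does not compute
integrals ab initio.  Non-resonant and absorption–emission interference
terms of the scattering cross section are intentionally out of scope.
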