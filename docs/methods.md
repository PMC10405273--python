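# Methods

This note records the model, the working equations as implemented, the
defaults and why they were chosen, what the bundled fixtures do and do not
probe, and the known limitations.

## Monomer description

Each monomer is described by a spin-compensated RHF or (state-averaged)
CASSCF wave function produced by the built-in backend
(`mrdisp.integrals` + `mrdisp.scf`):

* Gaussian integrals by the McMurchie–Davidson scheme (s/p shells in the
  shipped basis library: STO-3G for H, He, C, N, O and a split-valence "dz"
  set for H and He);
* RHF with DIIS;
* CASSCF: full CI in the active window, orbital optimization by L-BFGS over
  the nonredundant rotations with the analytic generalized-Fock gradient,
  re-expanding exp(K) around the current point whenever the optimizer
  stalls (the near-redundant rotations involving almost fully occupied or
  almost empty active orbitals are otherwise slow); state averaging with
  arbitrary weights, default two equal-weight states for excited-state work.

The resulting `MonomerState` carries natural orbitals (active block of the
one-density diagonalized; inactive/virtual blocks **semicanonicalized**
against the generalized Fock matrix — occupations there are pinned at 1/0,
so this is a free choice that keeps the one-body part of the zeroth-order
Hamiltonian diagonal), occupation numbers n_p ∈ [0, 1] with 2Σn_p = N, and
spin-free 1-/2-RDMs.  Monomers in a dimer are computed in the
**dimer-centered basis** (partner atoms as ghosts), consistent with
counterpoise-corrected supermolecular energies.

Any other electronic-structure source can provide the same data through the
HDF5 interchange format (`write_interchange` / `read_interchange`:
`/monomer_X/{no_coeff, occupations, partition, rdm1, rdm2_active,
hcore_no}` plus `/nuclei` and optional `/cholesky/*`).

## ERPA eigenproblem

With spin-summed excitation operators E_pq and the symmetric/antisymmetric
combinations S_pq = E_pq + E_qp, R_pq = E_pq − E_qp over pairs p > q, the
Hessians are double-commutator expectation values closed over the RDMs:

    A+ = 1/2 <[S, [H, S]]>,   A− = 1/2 <[R, [H, R]]>,
    N_pq = gamma_q − gamma_p = 2(n_q − n_p)   (diagonal metric).

These reduce **exactly** to the singlet TDHF stability matrices 2(A−B) and
2(A+B) for a single determinant; the static response then equals
coupled-perturbed HF, which the tests verify against finite-field SCF.  The
contraction formulas were derived once from the operator algebra and are
unit-tested against exact determinant-space evaluation of
⟨[E_qp,[H,E_rs]]⟩ on random Hamiltonians.

Pair index: subranges (active×inactive), (virtual×inactive),
(active×active), (virtual×active); inactive–inactive and virtual–virtual
pairs carry no metric and are excluded by construction.  Pairs whose
occupation difference n_q − n_p falls below **0.01** (configurable;
`metric_tol` is twice this) are additionally dropped: their ERPA metric is
near-singular, they contribute O((n_q−n_p)²) transition strength, and they
destroy the convergence of the α-expansion while barely moving the direct
result (≈5% of the dispersion energy on the H₂ CAS(2,2) fixture, whose
weakly occupied active natural orbital has n ≈ 0.006).  This mirrors the
occupation thresholds used by production multireference-response codes.

Eigenproblem: in the metric-orthonormal representation
(Ã± = N^(−1/2) A± N^(−1/2)) the squared transition energies are the
eigenvalues of Ã⁺Ã⁻ and the transition-density carriers its right
eigenvectors, normalized by gᵀÃ⁻g = ω (symplectic normalization
FᵀNG = 1, recorded in the solution metadata).  Roots with ω² ≤ 0, complex
ω², or negative symplectic norm are **spurious/negative transitions**: they
are counted, excluded from the sum-over-states dispersion, and their exact
rank-one contribution is *deflated* from the response kernel so that both
dispersion routes describe the same positive-excitation spectrum.  For
ground-state CASSCF references no such roots appear on any fixture (the
orbital Hessian of a variational minimum is positive); for excited-state
references the downward transition shows up here, its non-Casimir–Polder
physics is not modeled, and the deflation keeps the two routes consistent
(the neglected term is ~4·10⁻⁴ relative on the excited-state fixture).

## Response and the α-recursion

The frequency-dependent kernel at imaginary frequency iω is obtained
either directly,

    M(ω) = (Ã⁺Ã⁻ + ω²)⁻¹ Ã⁺      (linear solve; spectral form
                                   Σ_ν ω_ν/(ω_ν²+ω²) g_ν g_νᵀ),

or through the coupling-constant expansion.  The Hessians are split
exactly, A±(α) = A±(0) + α A±(1), where A±(0) is the restriction of A± to a
block layout modeling a group-product zeroth order: one block for all
active–active pairs; one block per inactive (resp. virtual) partner for the
inactive→active (resp. active→virtual) groups; 1×1 blocks for
inactive→virtual.  The largest blocks are of active-space dimension, so the
resolvent Λ(ω) = Ã⁺(0)Ã⁻(0) + ω² is inverted block by block at negligible
cost.  Matching powers of α in (Λ + αB₁ + α²B₂) Z = Ã⁺(α) D̃ gives the
recursion quoted in the module docstring; each step costs one
pair²×N_Chol product — the *m*⁵ bound.  Any exact split converges to the
same α = 1 limit; the split only sets the convergence rate, which the
fixture-suite scan monitors (mean |E(n=8) − E(direct)|/|E| ≈ 2·10⁻⁴ %).
Divergence (three consecutive growing increment norms beyond order 2) is
flagged, not raised.

## Frequency quadrature

The Casimir–Polder integral is discretized on 8 points.  A mapped
Gauss–Legendre rule (ω = ω₀ tan(π(1+t)/4), available as `kind="gl"` and used
for any other point count) cannot reach the 10⁻⁶ relative accuracy this
package demands of the identity (2/π)∫ ab/((a²+ω²)(b²+ω²)) dω = 1/(a+b)
over the transition-energy range of interest — its best error is ≈4·10⁻³
with 8 points.  The default 8-point rule is therefore a **generalized
(minimax) Gauss rule** for the Lorentzian-product family with parameters in
[0.2, 5] hartree, the span of valence transition energies that dominate the
dispersion integrand; its frozen nodes/weights reproduce 1/(a+b) to better
than 10⁻⁶ relative across that whole family (the continuum minimax optimum
for any 8-node positive rule is ≈9·10⁻⁷).  Transitions outside the design
range (e.g. core excitations ~20 hartree in minimal-basis water) are
integrated less accurately, but carry negligible dispersion weight; the
refinement test (16- vs 32-point mapped GL against the 8-point value)
bounds the residual quadrature error on the fixtures at <10⁻⁶ relative.

## Dispersion assembly, induction, SAPT arithmetic

Per node, W^X(ω) = D̃ᵀ M(ω) D̃ with D̃ the metric-dressed projected Cholesky
factors; E_disp = −(2/π) Σ_j w_j Tr[W^A W^B].  The overall sign/prefactor is
fixed by the analytic one-mode Casimir–Polder case and cross-checked against
the sum-over-states expression; both are anchored to physical response
through the finite-field polarizability test.  Internal unit is hartree;
reports use 627.5095 kcal/mol per hartree.

Second-order induction uses the static kernel: E_ind(A←B) = −vᵀC_A(0)v with
v the partner's electrostatic potential over A's pairs; both directions are
summed.  δ_HF = E_int^HF − (elst + exch + ind + exch-ind); δ_CAS scales δ_HF
by the ES/GS ratio of second-order induction energies; exchange components
in a larger basis are estimated by the ratio of their polarization partners.
Table reproduction uses half-away-from-zero rounding to the printed decimals
with a 0.015 kcal/mol tolerance (accumulated two-decimal input rounding);
one shipped row (AcOH–pentane CAS+DISP, ground state) exceeds that bound by
0.06 kcal/mol and is tracked as a known discrepancy, never silently passed.

## Dispersion density

Each pair's share of the frequency-integrated trace is attributed to the
pair's occupied (more occupied) member; Q^X(r) is the share-weighted sum of
occupied natural-orbital densities and Q^AB = (Q^A + Q^B)/2.  The exact
per-orbital weighting is a modeling choice — the grid integral is rescaled
so ∫Q^AB = E_disp holds exactly on the quadrature grid regardless, and the
pre-rescaling error (<1% on the fixture grids, warning above 5%) measures
grid quality.  Cube export in kcal mol⁻¹ Å⁻³; iso-values are reported as the
levels enclosing given fractions of the integrated |density|.

## Fixture suite and what passing means

Five dimers ship as XYZ + YAML: H₂–H₂ (CAS(2,2), split-valence), He–He
(mean field), water dimer (mean field and CAS(4,4), minimal basis), and an
excited-state H₂–H₂ (SA-2 CASSCF S₁ monomer).  They are chosen so the full
*m*⁶ sum over states runs in seconds and every route comparison is exact to
numerical precision.  They emulate weakly correlated, weakly interacting
closed-shell systems in small bases; they do **not** probe large monomers,
diffuse/augmented bases, strong correlation, charge transfer, or the
basis-set convergence of dispersion itself — conclusions from the passing
suite are about internal consistency and scaling structure, not about
quantitative accuracy against experiment.  Synthetic seeded
block-structured response instances exercise the recursion independently of
any electronic structure.

## Numerical defaults

| quantity | default | notes |
| --- | --- | --- |
| Cholesky threshold | 10⁻² (summed residual) | 10⁻⁸ "tight" mode for oracle tests |
| frequency grid | 8-point minimax rule, family [0.2, 5] E_h | mapped GL for other n |
| truncation order n | 8 | μE_h-level on the fixtures |
| pair metric cutoff | n_q − n_p ≥ 0.01 | 0 keeps the formal pair space |
| eigensolver filters | ω² > 10⁻⁸, norm > 0 | discarded roots counted + deflated |
| CASSCF gradient | < 10⁻⁴ | L-BFGS with exp(K) re-expansion |

## Known limitations

* Spin-compensated (even-electron, M_S = 0) monomers only; the backend has
  no UHF/ROHF path.
* The backend's basis library is minimal/split-valence s,p — adequate for
  algorithmic validation, far from basis-set-converged dispersion.
* Exchange-dispersion and exchange-induction are never computed from
  integrals; they enter only as numbers to be scaled/assembled.
* Non-Casimir–Polder (negative-transition) contributions of excited-state
  monomers are deflated, not modeled.
* Per-frequency intermediates are held in memory; no disk streaming is
  implemented (desk-scale systems never need it).
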