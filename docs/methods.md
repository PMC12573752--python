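# Methods

## The model

`dfqmmm` treats a QM/MM system as interacting electronic subsystems in the
subsystem-DFT sense.  The total electron density is a sum of fragment
densities, `rho = rho_QM + rho_MM`, and the total energy is

    E = E[rho_QM] + E[rho_MM] + E_nad[rho_QM, rho_MM]

with the nonadditive coupling

    E_nad = T_s^nad + E_xc^nad
          + ∫∫ rho_QM(r) rho_MM(r') / |r - r'|
          + ∫ rho_MM v_QM + ∫ rho_QM v_MM ,

where `F^nad[a, b] = F[a + b] - F[a] - F[b]` for the kinetic and
exchange-correlation functionals.  The nonadditive kinetic term encodes
Pauli repulsion between fragments; omitting it lets QM electrons collapse
onto the environment sites (the charge spill-out diagnostic reproduces this,
see below).

The MM subsystem has no orbitals.  Its density is synthesized from the force
field's electrostatics ("backward mapping"): each site contributes a
normalized Gaussian of width `sigma_q` scaled by `N - q` (valence electrons
minus permanent charge), and each induced dipole contributes
`-mu . grad g_sigma_mu`, the gradient of a normalized Gaussian.  Nuclei (QM
and MM) are represented by an analytic local pseudopotential

    v_loc(r) = -N erf(r / (sqrt(2) sigma_core)) / r ,

the energy-per-electron potential of a Gaussian core of charge `+N`, which
is grid-friendly and has the correct `-N/r` tail.  The MM *internal* energy
is the classical polarizable force-field energy; the backward-mapped density
enters only the QM-MM coupling.

The QM subsystems are solved with orbital-free DFT: the density is
parametrized as `rho = phi^2` and the energy minimized directly under the
electron-number constraint.  The additive kinetic functional is
von Weizsacker + Thomas-Fermi (`lam = 1`), the standard orbital-free choice
for small fragments; the vW term is evaluated exactly through `phi`
(`T_vW = 1/2 ∫ |grad phi|^2`).  The nonadditive kinetic functional is a GGA
with enhancement factor `F(s) = 1 + mu s^2 / (1 + mu s^2 / kappa)` and
revAPBEk-style parameters (`mu_k = 0.23889`, `kappa_k = 1.245`, stored as
config data).  Exchange-correlation is spin-unpolarized PBE (PW92 local
correlation) both additively and nonadditively.

## Mutual polarization

The outer loop alternates:

1. assemble `rho_MM` from permanent charges and current dipoles;
2. minimize each QM subsystem's density in its ionic potential **plus** the
   environment coupling.  The coupling is part of the inner variational
   objective (its energy and exact functional derivative are evaluated at
   every step in the potential-difference form
   `v_F[rho + rho_env] - v_F[rho]`), so each inner solve is fully
   self-consistent with the frozen environment; the outer loop only has to
   relax the dipoles and the inter-fragment coupling;
3. evaluate the classical part of the QM field, `-grad[v_QM +
   Hartree(rho_QM)]`, at the grid point nearest each MM site (ties broken
   toward the lower index) and re-solve the induced dipoles; the nonadditive
   kinetic/xc contributions to the MM-side field are excluded because
   classical polarizabilities are parametrized for long-range response only;
4. declare convergence when the total energy change per atom, the L2 norm of
   the QM density change, and the dipole update all fall below their
   thresholds (defaults `1e-8 Ha/atom`, `1e-6` electrons, `1e-7 e bohr`).

Damped dipole mixing (default factor 0.5) guards against field/dipole
ping-pong at strong coupling; the fixed point is independent of the mixing
factor, and the faster undamped update is used in the test suite.  The
mutual-polarization fixed point is *not* a joint minimum of the bookkept
total energy (the dipole equation uses the truncated, nearest-grid-point
field), so small uphill energy steps during dipole relaxation are normal;
the cycling detector triggers only on a non-decaying `|dE|` envelope.

With several QM subsystems the nonadditive terms are evaluated in the
telescoped form `F[sum_I rho_I + rho_MM] - sum_I F[rho_I] - F[rho_MM]` — no
pairwise approximation — and each subsystem is minimized in the embedding of
all the others.

## Units, conventions, and numerical choices

* Hartree atomic units internally; Angstrom in XYZ files, kcal/mol at
  reporting boundaries (1 Ha = 627.509 kcal/mol).
* Electron densities are positive; potentials are energy-per-electron.  The
  polarizable module works throughout in the matching "electron convention":
  fields are `-grad` of energy-per-electron potentials (the negative of the
  conventional electric field) and dipole vectors are electron-displacement
  dipoles (physical dipole `= -mu`).  Classical electrostatics is
  sign-symmetric, so all energies are convention-free, and the
  energy-minimizing dipole is literally `alpha` times the field returned by
  the grid — no sign conversions anywhere.
* All Coulomb objects drop the G = 0 component (neutralizing background).
  Individual electrostatic terms then carry Wigner/jelly offsets that cancel
  only in neutral totals; ion-ion terms are therefore evaluated on the same
  grid (Gaussian core densities), never by a bare pairwise formula.
* Grid spacing obeys `h <= pi / sqrt(2 cutoff)` per axis, rounded up to
  2,3,5-smooth FFT sizes.  Gaussian site densities and pseudopotentials are
  synthesized in reciprocal space (exact periodic image sums); widths
  narrower than 1.5 grid spacings raise a resolution error.
* Densities are floored at `1e-12 e/bohr^3` inside quotients.  Band-limited
  synthesis leaves negative ringing of order `1e-8` of the peak, which is
  clipped; values below `-1e-5` of the peak are a domain error.  The mapped
  dipole density can dip genuinely below zero near strongly polarized sites;
  kinetic/xc functionals see the clipped density while Coulomb terms use the
  exact one.
* PBE correlation partials are obtained by complex-step differentiation of
  the analytic energy density (machine precision, no subtractive
  cancellation); all other functional derivatives are analytic.
* The orbital-free minimizer uses projected, preconditioned
  (`1/(1 + G^2/g0^2)`, `g0^2 = 10`) nonlinear conjugate gradients with
  curvilinear steps on the constraint sphere and a parabolic line search
  whose accepted-energy sequence is non-increasing.
* Breakdown bookkeeping reuses the additive components evaluated by the
  minimizer itself: the phi-form and rho-form von Weizsacker energies differ
  at grid level, and the reported decomposition must match the variational
  objective.

## Built-in water model

Production many-body water potentials are external software; the bundled model is
the smallest polarizable force field that exercises every code path: rigid
3-site monomers (r_OH = 0.9572 A, HOH = 104.52 deg), TIP3P-like charges
(O -0.834 e, H +0.417 e), AMOEBA-style isotropic atomic polarizabilities
(O 0.837 A^3 = 5.650 bohr^3, H 0.496 A^3 = 3.348 bohr^3), Thole exponential
damping (a = 0.39), 1-2/1-3 intramolecular permanent-field exclusions, and
minimum-image real-space Coulomb for MM-MM terms.  Default backward-mapping
widths are declared, not fitted: `sigma_q` O 1.1 / H 0.9 bohr, `sigma_mu`
O 1.0 / H 0.8 bohr, `sigma_core = sigma_q / 2`.  The dipole self-energy is
`|mu|^2 / (2 alpha)` plus the interface correction `k_SE |mu - mu'|^2`
relative to the isolated-MM dipoles `mu'`; `k_SE` defaults to 0 and can be
included in the calibration parameter vector.

## Width calibration and the partition statistic

`fit_widths` minimizes squared deviations of model interaction energies from
reference energies by bounded trust-region least squares.  The bundled
evaluator freezes the vacuum QM density and its induced MM dipoles (both
width-independent) and re-evaluates only the width-dependent interaction
terms, making each objective evaluation a handful of grid operations.  Fit
configurations scan the fragment separation (0.9-1.3x) while rotating the MM
monomer, so that the residuals are sensitive to all four water widths
(sigma_q and sigma_mu for O and H); without the rotations the oxygen dipole
width is nearly flat in the objective.

For an n-molecule cluster, every way of promoting k molecules to the QM
level should ideally give the same interaction energy.  `partition_rmse`
computes the spread of the binomial(n, k) member energies about their mean,
regresses it through the origin against `sqrt(binomial(n, k))`, and reports
`slope * sqrt(pi/2)` as the average error per QM/MM boundary — the
half-normal mean/RMS relation, validated in the tests by direct Monte Carlo
rather than taken on faith.

## What the synthetic fixtures do and do not show

Geometry generators (dimer scans, an inversion-symmetric dimer, tetrahedral
pentamers, a prism-like hexamer, seeded random water boxes with a 2.4 A
minimum O-O distance) are structurally analogous stand-ins, not published
coordinates.  The orbital-free TF+vW water fragment is considerably more
diffuse than a Kohn-Sham water molecule, which makes the toy dimer
net-repulsive near 2.9 A O-O separation: Pauli repulsion from the overlapping
diffuse densities outweighs electrostatics there.  Passing tests therefore
demonstrate the correctness and internal consistency of the embedding
machinery — exact labeling symmetry, variational consistency, spill-out
behavior, parameter recovery — not the quantitative energetics of real
water, which require a Kohn-Sham engine and a production force field.

## Problem sizes

The suite and the acceptance script run on one CPU with cells of 12.5-50
bohr and cutoffs of 6-30 Ha (grids 24^3 to 96^3), chosen as the smallest
sizes at which every resolvability constraint of the default water model is
met and the checked identities are far above discretization noise.  The
box-size convergence check uses 22 vs 44 bohr cells because of the diffuse
orbital-free tails.

QM-size scans (`qm_size_scan`) report, alongside the energies, whether the
last two QM sizes agree within the configured convergence band
(`scan_convergence_band`, default +-2 kcal/mol — the conventional target
window for QM/MM convergence studies), for both the polarizable and the
charge-only variant.

## Known limitations

* Orbital-free QM: no shell structure; quantitative molecular energetics
  are out of scope by design.
* Single shared cell and grid for QM and MM; Gamma point only; no separate
  QM cell reduction.
* Charges and dipoles only in the backward mapping (no higher multipoles,
  no off-atom sites); rigid monomers; isotropic polarizabilities.
* No nuclear forces, no dynamics, no dispersion correction.
* Charged total systems are rejected by default (`declared_charge`); the
  background convention makes individual charged-fragment terms
  cell-size-dependent.
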