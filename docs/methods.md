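# Methods

## Model

Charged hard spheres in a dielectric continuum (restricted primitive
model). Salt ions are free beads; polymers are linear chains of bonded
beads. Each bead *i* has a hard-core radius *a_i* (default 0.5 σ for every
species, the RPM's defining symmetry; per-species overrides are allowed)
and a valence *z_i* ∈ {−1, 0, +1}. The configurational energy is

    U = 1/2 Σ_{i≠j} [U_HS(r_ij) + U_ES(r_ij)] + Σ_chains Σ_j [U_B(r_j,j+1) + U_θ(θ_j)]

* `U_HS`: infinite below contact `a_i + a_j`, zero above (minimum-image).
* `U_ES/k_BT = l_B z_i z_j / r_ij` under cubic periodic boundary
  conditions, evaluated by Ewald summation with conducting (tin-foil)
  boundaries.
* `U_B = k_b (r − r_0)²` and `U_θ = k_θ (θ − θ_0)²`, both harmonic. The
  defaults are `k_b = 200 k_BT/σ²`, `r_0 = 1 σ` (a stiff, nearly
  tangent-bead chain) and `k_θ = 0` (freely jointed); both constants are
  configuration-exposed so any published parameterization can be dropped
  in. Harmonic forms are the minimal choice compatible with the model
  class; they are a declared convention, not a fitted one.

### Reduced units and the single conversion scalar

Lengths are in bead diameters σ, energies in k_BT. One scalar — the
physical bead diameter `sigma_nm` — maps reduced number densities to molar
concentrations (`c[mM] = ρ σ⁻³ / (N_A σ³)`) and sets the reduced Bjerrum
length `l_B = 0.7114 nm / sigma_nm` (water, 25 °C). The default is
`sigma_nm = 0.3` (l_B = 2.37 σ), i.e. a compact, high-charge-density
monomer with a contact coupling of ≈ 2.4 k_BT between unit charges. The
value was chosen so that the baseline phenomenon — robust complexation and
coacervation with a critical salt concentration on the few-hundred-mM
scale — exists for the chain lengths and box sizes this package simulates;
at weaker couplings (σ ≳ 0.35 nm) the measured excess free energy stays
convex in these small systems and no coacervation occurs at all. The
sequence comparison itself was not an input to this choice.

### Ewald details

Real-space part: `l_B q_i q_j erfc(α r)/r` with minimum image and cutoff
`r_c ≤ L/2`. Reciprocal part: half-space integer wave vectors with
coefficients `4π l_B/V · e^{−k²/4α²}/k²` applied to the squared structure
factor; self term `−l_B α/√π Σ q²`. Given a target tolerance `ε_tol`
(default 1e-5 k_BT per charge; production campaigns use 1e-4, far below
thermal noise), `α = erfc⁻¹(ε_tol)/r_c` and
`k_max = ⌈erfc⁻¹(ε_tol)·αL/π⌉`. Structure factors are updated
incrementally per Monte Carlo move; the bookkept energy agrees with full
recomputation to ~1e-13 relative (tested).

## NVT Metropolis sampling

A sweep is `N_tot` attempted moves drawn from {single-bead displacement,
whole-chain translation, crankshaft (interior-bead rotation about the axis
through its bonded neighbours; end beads rotate about a random axis through
their single neighbour), reptation}. Default mix 0.70/0.10/0.15/0.05.
Reptation slides bead positions along the contour (charges stay with their
indices, so patterned sequences are preserved); the new end bead is drawn
uniformly in a ball around the old end, and the move is rejected up front
when the broken bond would not fit the reverse proposal ball (detailed
balance). Reptation is disabled automatically for chains with non-uniform
radii, where the contour-slide is not a valid configuration map. Step sizes
are tuned toward ~40 % acceptance during equilibration only and frozen for
production. Initial states come from self-avoiding chain growth plus random
ion insertion; a failure to place beads after a bounded number of attempts
reports a too-high density. All randomness flows from one master seed
through named SeedSequence-derived streams; identical inputs give
bit-identical trajectories (tested).

## Excess chemical potentials

Charged species are inserted as electroneutral groups, keeping every
insertion Ewald-valid: salt as +/− pairs; a test chain together with its
neutralizing counterions. Single-ion values follow from the ± symmetry of
the model (μ₊ = μ₋ = μ_pair/2).

The estimator is sequential Monte Carlo rather than plain Rosenbluth
growth: a population (default 16–32) of partial insertions is grown bead by
bead, with systematic resampling between stages; the product of stage-mean
weights is an unbiased estimator of ⟨e^{−βΔU}⟩. Two further variance
controls matter at liquid-like densities: counterions are interleaved with
the charged monomers they neutralize, so the partial group stays
near-neutral during growth, and free counterions use a mixture proposal
(half uniform in the box, half uniform in spheres around placed opposite
charges) with the exact 1/(Vp) importance-weight correction. Bonded beads
draw trial bond lengths from the tabulated bond Boltzmann distribution
(that factor then cancels from the weight) and treat angle energy as
external. The reciprocal-space and self Ewald terms of the completed
insertion enter as a final reweighting stage. Plain Rosenbluth growth was
measured to be badly weight-degenerate here (seed-to-seed spreads of tens
of k_BT for 48-bead groups at coacervate densities); the population
estimator reduces this to the ~1 k_BT level at the campaign's densities.

## Excess free energy and phase coexistence

`f_exc(ρ_P, ρ_S)` (k_BT per σ³; ρ_P counts all polymer monomers, ρ_S salt
pairs) is built by thermodynamic integration along dilution rays of fixed
polymer:salt ratio, using the charge-balanced chain unit (2 polycations +
1 polyanion) and the salt pair as the integration species. Cumulative
trapezoid quadrature starts from zero density (salt μ → 0; the chain-unit μ
is continued by its first node — the resulting error is linear in density
and cancels exactly from phase coexistence).

The scattered f_exc samples are fitted with a small electrostatic basis:
linear terms, a Debye–Hückel-like −A·I^{3/2} term in the ionic strength
I = f_q ρ_P + 2ρ_S, and local quadratic corrections (x², xs, s²). Two
identifiability measures make the sequence comparison well-conditioned:

1. the linear (dilute-limit self-energy) coefficient of each sequence is
   measured *exactly* by ghost insertion of its chain unit into an empty
   periodic box of the same edge length, and pinned in the fit — along a
   dilution ray the linear and I^{3/2} columns are otherwise nearly
   collinear and the τ signal aliases into the coexistence-irrelevant
   linear term;
2. all sequences share the curvature coefficients (they share ions,
   packing and solvent physics), leaving the sequence effect in one
   amplitude A_τ per pattern. Because everything else is shared, the
   binodal — and hence the critical salt concentration — is a monotone
   function of A_τ.

Mixing entropy uses a Flory–Huggins lattice with site volume σ³: polymer
translational entropy per chain (1/N per monomer), salt ions and solvent
per particle, `f₀ = Σ (φ_k/N_k) ln φ_k + (1−φ_P−φ_S) ln(1−φ_P−φ_S)`.
The free energy of a two-phase split, `ΔF = v f(I) + (1−v) f(II) − f(φ̄)`,
is minimized over one phase's composition and volume fraction (the other
follows from the lever rule) by multi-start Nelder–Mead from
supernatant-rich and coacervate-rich corners; coexistence is recorded when
the split lowers ΔF by more than 1e-4 with a polymer gap above 0.02. The
CSC is the binodal apex in the salt direction, refined by bisection on the
salt level at the apex composition. The polymer is treated at mean-field
level; accuracy very close to the critical point is explicitly out of
scope. No extrapolation outside the sampled surface domain is permitted
(a 2 % slack absorbs boundary roundoff).

## Counterion census and the 1D adsorption entropy

On a dilute single-chain trajectory, a counterion (small ion of sign
opposite to the chain's net charge; switchable) is *condensed* in a frame
when it lies within r_CC of any monomer — closed boundary, exactly r_CC
counts — and is assigned to its nearest monomer only, so per frame the
assignments sum to the number of condensed ions (tested invariant). The
default r_CC = 2 σ is twice the contact distance of oppositely charged
beads and is configuration-exposed.

The reference census runs the same topology and radii with all polymer
charges zeroed. Zeroing the charges removes the counterions' raison
d'être, so exact "same ion content" would break electroneutrality; the
implemented convention keeps the *counted* counterion species at the same
count as the charged run and balances with co-ions. `ε̃_i =
−ln(⟨n_i⟩/⟨n_i⁰⟩)`; monomers with zero counts in either census are flagged
and excluded, never imputed.

The entropy of the 1D independent-site model is evaluated exactly as

    S/k_B = Σ_i [ ln(1 + e^{−(ε̃_i − μ̃)}) + ε̃_i · e^{−(ε̃_i−μ̃)}/(1 + e^{−(ε̃_i−μ̃)}) ]

with log1p/overflow-guarded arithmetic. The energy-weighting factor uses
ε̃_i in the second term; the textbook grand-canonical variant (weighting by
ε̃_i − μ̃) is available behind `energy_factor="shifted"` — the printed form
is the default and is what every reported number uses. The shared reservoir
chemical potential μ̃ (one value for all sequences and sites at a given
salt concentration) defaults to the coverage-matching fit: the μ̃ at which
the model's total occupancy Σ 1/(1+e^{ε̃_i−μ̃}) reproduces the censused
number of condensed counterions pooled over all sequences. An external
calibration route (`fit_mu`, least squares against supplied −TΔS values)
is also provided. Release convention: ΔS = S(ε̃=0; μ̃) − S(ε̃_sim; μ̃),
per mole of charged monomer, with −TΔS reported in kJ/mol at 298.15 K.

## Structural correlations

g_ij(r): minimum-image distance histograms normalized by
`N_i ρ_j 4πr²Δr` per frame, half-open bins, truncated at L/2. The energy
functional `U_i = 2π Σ_j ρ_j ∫ r² v_ij g_ij dr` uses trapezoidal
quadrature on the g(r) grid (no silent resampling; mismatched grids are an
error) with bare-Coulomb `v_ij = l_B z_i z_j/r`; truncation at L/2 relies
on the charge-neutrality cancellation of the r·(g→1) tails across the
species sum.

C1/C2: anchors are (charged polycation monomer, charged polyanion monomer)
pairs within r_C (default 1.5 σ, 1.5× the charged-contact distance); both
contours are walked by Δs. C1(Δs) = P(within r_C | both charged), C2(Δs) =
P(both charged | within r_C); offsets past a chain end leave the
denominators. By default the matched directions (+,+)/(−,−) are pooled
with the antiparallel ones (chain orientation is arbitrary); the
`directions="parallel"` switch restricts to matched walks, under which the
two-chain ladder fixture gives the exact identity C1 = C2 = 1. Δs = 0 is
counted once per anchor, so C1(0) = C2(0) = 1 by construction. Undefined
bins are flagged, never zero-filled.

## Study conditions (the compact campaign)

The acceptance-facing studies run at a deliberately compact scale chosen so
the full set completes in well under half an hour on one CPU core, while
keeping the physical conditions of the studied system: chain length N = 48,
f = 1/2 polycations against fully charged homopolyanions at 2:1
stoichiometry, and a 25 mM salt background for all dilute-phase analyses.

* Phase campaign: box L = 10 σ; two dilution rays per sequence (endpoints
  2 chain units with 6 and with 24 salt pairs; nodes at half and full
  density) plus a shared salt-only ray (10–40 pairs); 500 equilibration +
  500 production sweeps, 20 frames; 2 400 chain-group and 20 000 salt-pair
  insertions per state point; three replicate seeds pooled per state point.
  Seeds are keyed by state point and replicate — not by sequence — so
  cross-τ comparisons benefit from common random numbers. The τ = 24
  pattern completes a full period only on N ≥ 48 chains, and the
  density-dependent sequence signal grows strongly with chain length, so
  the campaign keeps the full chain length and economizes on box size and
  ray resolution instead.
* Census runs: one chain in an L = 16 σ box with neutralizing counterions
  plus 25 mM salt; 6 000 production sweeps sampled every 10; standard
  errors by 20-block averaging (consecutive frames are correlated).
* Energy-of-coacervation runs: matched 25 mM backgrounds, a dense point
  (2 units in the campaign box) against a dilute one (1 unit, L = 16 σ),
  three common-random-number replicates averaged.

At this scale the *trends* are the deliverable: the CSC ordering across τ
and the entropy ordering are resolved (and tested), while amplitudes (the
CSC ratio between the blockiest and the alternating sequence, the absolute
span of −TΔS) remain strongly scale-suppressed relative to a full-size
campaign, and the g(r)-functional energy change carries ~0.1 kT-per-charge
statistical noise. The test suite asserts exactly what this scale can
support and no more.

## What the generated data does and does not emulate

The simulated systems are the model's own ground truth: phase behavior,
condensation statistics and correlations emerge from the RPM Hamiltonian,
not from injected effect sizes. They do not emulate solvent structure,
Hofmeister-specific ion identities, dielectric inhomogeneity, chain-length
or charge-fraction polydispersity, or pH-dependent (annealed) charging —
in particular, quantitative agreement with any specific experimental
polymer chemistry is not claimed, only the sequence-level physics. Passing
tests therefore demonstrate internal correctness of the estimators and the
reproducibility of the sequence trends within this model family.

## Numerical choices and degenerate inputs

* Hard-sphere contact uses a strict `r < a_i + a_j − 1e-12` overlap test;
  exact contact is allowed.
* Nelder–Mead tolerances 1e-7 (x) / 1e-12 (f); ties between minimizer
  starts resolve to the lowest ΔF.
* Zero-charge systems short-circuit the Ewald machinery; empty boxes are
  valid insertion targets (used for the dilute-limit anchors).
* Chains of length 1 contribute no bonded energy; salt-free compositions
  carry zero salt entropy by the x ln x → 0 limit.
* Zero-weight (all-overlap) insertion batches raise, with the remedy named.

## Known limitations

* Mean-field polymer treatment: no fluctuation corrections near the
  critical point; binodal branches close to the apex are smoothed by the
  parametric surface.
* The excess-surface basis is a low-order parametric form; with two
  polymer rays per sequence it interpolates rather than resolves fine
  structure in (ρ_P, ρ_S).
* SMC insertion at the densest state points retains a residual heavy-tail
  bias that common random numbers only partially cancel; absolute chemical
  potentials there are good to ~1 k_BT, differences across sequences
  better.
* The 1D adsorption model treats sites as independent; cooperative
  condensation along a block enters only through the measured ε̃ profile.
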