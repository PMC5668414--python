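# coacervseq

Monte Carlo toolkit for **sequence-defined complex coacervation**: how the
1D pattern of charged monomers along a polycation controls the
liquid–liquid phase separation it undergoes with a homopolyanion and salt.

Complex coacervation is the associative demixing of oppositely charged
polyelectrolytes into a polymer-dense *coacervate* and a polymer-dilute
*supernatant* phase. For a polycation of length *N* with charged fraction
*f* = 1/2, the charge pattern is set by a periodicity *τ*: each period of τ
monomers starts with a block of τ/2 charges (τ = 2 alternates, τ = 16 is
eight charges then eight neutrals). Blockier sequences (larger τ) widen the
two-phase region and raise the critical salt concentration (CSC), and the
driving force is entropic: counterions condensed along a blocky chain in
the supernatant are additionally confined *along the contour* near the
charged blocks, so their release on coacervation gains more entropy.

The package implements, for charged hard spheres in a dielectric continuum
(the restricted primitive model):

- **`patterns`** — τ-periodic charge patterns and charge-balanced box
  compositions;
- **`model`** — the configurational energy
  `U = Σ[U_HS + U_ES] + Σ[U_B + U_θ]` with Ewald-summed electrostatics
  (`U_ES/kT = l_B z_i z_j / r_ij`, tin-foil boundary conditions) and
  harmonic bonds/angles, in reduced units (bead diameter σ, k_BT);
- **`mc`** — NVT Metropolis sampling (bead displacement, chain translation,
  crankshaft, reptation) with incremental Ewald bookkeeping;
- **`free_energy`** — excess chemical potentials by sequential-Monte-Carlo
  Widom insertion of electroneutral groups (salt pairs; chains with their
  counterions), thermodynamic integration along dilution rays to the excess
  free energy f_exc(ρ_P, ρ_S), and a Flory–Huggins construction
  (ΔF = F₀ + F_EXC − F_HOM minimized under the lever rule) for binodals,
  tie lines and the CSC;
- **`structure`** — pair correlations g_ij(r), the energy functional
  `U_i = 2π Σ_j ρ_j ∫ r² v_ij(r) g_ij(r) dr`, and the along-contour looping
  (C1) and sequence-alignment (C2) conditional probabilities;
- **`entropy`** — the condensed-counterion census (cutoff r_CC, nearest
  monomer assignment), effective site energies
  `ε̃_i = −ln(⟨n_i⟩/⟨n_i⁰⟩)`, and the 1D adsorption-model entropy

  `S/k_B = Σ_i [ ln(1 + e^{−(ε̃_i−μ̃)}) + ε̃_i e^{−(ε̃_i−μ̃)} / (1 + e^{−(ε̃_i−μ̃)}) ]`

  from which the counterion-release contribution −TΔS per sequence follows;
- **`campaign`** — the end-to-end study drivers, and a `coacervseq` CLI
  (`pattern`, `simulate`, `widom`, `analyze gr|align`, `census`, `entropy`,
  `phase-diagram`, `pipeline`).

## Worked example

The sequence dependence in one picture: two ε̃ profiles with the same mean
binding but different 1D arrangement, evaluated with the adsorption model
at a shared reservoir chemical potential μ̃:

```python
import numpy as np
from coacervseq import make_periodic_pattern
from coacervseq.entropy import adsorption_entropy
from coacervseq.units import entropy_to_kJ_per_mol

pat = make_periodic_pattern(N=48, tau=16, f=0.5, sign=+1)
print(pat.to_string())

eps_blocky = np.where(pat.as_array() != 0, -2.0, 0.4)   # wells on the blocks
eps_uniform = np.full(48, eps_blocky.mean())            # same mean depth
for name, eps in [("blocky", eps_blocky), ("uniform", eps_uniform)]:
    s_bound = adsorption_entropy(eps, mu=-2.7)
    s_free = adsorption_entropy(np.zeros_like(eps), mu=-2.7)
    tds = -entropy_to_kJ_per_mol((s_free - s_bound) / 24)
    print(f"{name:8s} S_bound={s_bound:6.3f} kB  S_free={s_free:6.3f} kB  "
          f"-TdS={tds:6.3f} kJ/mol")
```

prints

```
++++++++00000000++++++++00000000++++++++00000000
blocky   S_bound=-4.779 kB  S_free= 3.122 kB  -TdS=-0.816 kJ/mol
uniform  S_bound= 1.694 kB  S_free= 3.122 kB  -TdS=-0.147 kJ/mol
```

Confining the same number of counterions onto blocks (deep wells on half
the sites) lowers the bound-state entropy, so releasing them on
coacervation is worth several times more free energy than for the uniform
profile — the mechanism behind the τ dependence of the phase diagram. The
full simulation pipeline produces the ε̃ profiles that replace these
synthetic ones:

```sh
coacervseq entropy --seed 1 --taus 2,8,16 --out tds.csv
coacervseq phase-diagram --seed 1 --taus 2,8,24 --out binodal.csv
```

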