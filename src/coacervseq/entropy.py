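"""Counterion condensation census and the 1D adsorption entropy model.

In the dilute (supernatant) phase, counterions condense along a charged
chain.  A counterion is condensed when it lies within a cutoff r_CC of ANY
monomer (closed boundary: exactly r_CC counts), and is assigned to its
NEAREST monomer only, giving a per-monomer average occupancy <n_i>.  The
same census on an uncharged chain of identical topology gives the purely
geometric reference <n_i^0>; their ratio defines the effective per-site
binding energy

    eps_i = -ln(<n_i> / <n_i^0>)            (in k_BT)

The chain contour is then treated as a 1D lattice of independent adsorption
sites in contact with an ion reservoir at chemical potential mu.  The model
entropy, as implemented here,

    S/k_B = sum_i [ ln(1 + e^{-(eps_i - mu)})
                    + eps_i * e^{-(eps_i - mu)} / (1 + e^{-(eps_i - mu)}) ]

couples the occupancy to the site energy; a variant whose energy-weighting
factor uses (eps_i - mu) instead of eps_i (the textbook two-state
grand-canonical entropy) is available behind ``energy_factor="shifted"``.
Blockier sequences confine condensed counterions near the charged blocks;
releasing a more confined counterion gains more entropy, which is the
sequence dependence of the coacervation driving force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .mc import Trajectory
from .patterns import ChargePattern
from .units import ROOM_T, entropy_to_kJ_per_mol

__all__ = [
    "AdsorptionProfile",
    "EntropyResult",
    "condensation_census",
    "reference_census",
    "effective_energy",
    "adsorption_entropy",
    "coacervation_entropy",
    "fit_mu",
]


@dataclass
class AdsorptionProfile:
    """Per-monomer condensed-counterion statistics for one chain."""

    n_mean: np.ndarray  # <n_i>, charged-chain census
    n0_mean: np.ndarray | None = None  # <n_i^0>, uncharged-chain reference
    eps: np.ndarray | None = None  # -ln(n/n0) where defined
    defined: np.ndarray | None = None
    r_CC: float = 0.0
    pattern: ChargePattern | None = None
    n_se: np.ndarray | None = None
    n0_se: np.ndarray | None = None
    n_frames: int = 0

    @property
    def N(self) -> int:
        return len(self.n_mean)


def _census_counts(
    trajectory: Trajectory, r_CC: float, ion_sel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame condensed counts assigned to nearest monomers.

    Returns (counts[frames, N], per-monomer mean)."""
    tmpl = trajectory.template
    if len(tmpl.chains) != 1:
        raise ValueError(
            f"condensation census is a dilute single-chain analysis; got "
            f"{len(tmpl.chains)} chains"
        )
    (cs, cl), = tmpl.chains
    L = tmpl.box_length
    counts = np.zeros((trajectory.n_frames, cl))
    ions = np.where(ion_sel)[0]
    if len(ions) == 0:
        return counts, counts.mean(axis=0)
    for f in range(trajectory.n_frames):
        pos = trajectory.frames[f]
        d = pos[ions][:, None, :] - pos[cs : cs + cl][None, :, :]
        d -= L * np.rint(d / L)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        dmin = dist.min(axis=1)
        condensed = dmin <= r_CC  # closed boundary: exactly r_CC counts
        nearest = dist.argmin(axis=1)
        np.add.at(counts[f], nearest[condensed], 1.0)
    return counts, counts.mean(axis=0)


def _block_se(counts: np.ndarray, n_blocks: int = 20) -> np.ndarray:
    """Standard error of per-monomer means by block averaging over frames
    (consecutive frames are correlated; blocks tame that)."""
    nf = len(counts)
    nb = min(n_blocks, nf)
    if nb < 2:
        return np.full(counts.shape[1], np.inf)
    edges = np.linspace(0, nf, nb + 1, dtype=int)
    means = np.array([counts[a:b].mean(axis=0) for a, b in zip(edges, edges[1:])])
    return means.std(axis=0, ddof=1) / math.sqrt(nb)


def _counterion_mask(trajectory: Trajectory, counterion_charge: float | None):
    tmpl = trajectory.template
    if len(tmpl.chains) != 1:
        raise ValueError(
            f"condensation census is a dilute single-chain analysis; got "
            f"{len(tmpl.chains)} chains"
        )
    (cs, cl), = tmpl.chains
    in_chain = np.zeros(tmpl.n_beads, dtype=bool)
    in_chain[cs : cs + cl] = True
    if counterion_charge is None:
        chain_net = tmpl.charges[cs : cs + cl].sum()
        if chain_net == 0:
            raise ValueError(
                "chain carries no net charge; specify counterion_charge explicitly"
            )
        counterion_charge = -math.copysign(1.0, chain_net)
    return (~in_chain) & (np.sign(tmpl.charges) == np.sign(counterion_charge)), counterion_charge


def condensation_census(
    trajectory: Trajectory,
    r_CC: float = 2.0,
    counterion_charge: float | None = None,
    pattern: ChargePattern | None = None,
) -> AdsorptionProfile:
    """<n_i> census on a dilute single-chain trajectory.

    Counterions are all small ions whose charge opposes the chain's net
    charge (override with ``counterion_charge``).  Each condensed counterion
    increments exactly one monomer per frame (census conservation).
    """
    sel, _ = _counterion_mask(trajectory, counterion_charge)
    counts, mean = _census_counts(trajectory, r_CC, sel)
    se = _block_se(counts)
    return AdsorptionProfile(
        n_mean=mean, r_CC=r_CC, pattern=pattern, n_se=se, n_frames=len(counts)
    )


def reference_census(
    trajectory: Trajectory,
    r_CC: float,
    profile: AdsorptionProfile,
    counterion_charge: float,
) -> AdsorptionProfile:
    """<n_i^0> census on an uncharged-chain trajectory, paired with a
    charged-chain profile.

    The reference run must share the chain topology and radii of the charged
    run; ``counterion_charge`` selects the same ion species counted there.
    """
    tmpl = trajectory.template
    (cs, cl), = tmpl.chains
    if cl != profile.N:
        raise ValueError(
            f"reference chain length {cl} does not match paired profile ({profile.N})"
        )
    if np.any(tmpl.charges[cs : cs + cl] != 0):
        raise ValueError("reference trajectory must have an uncharged chain")
    sel, _ = _counterion_mask(trajectory, counterion_charge)
    counts, mean = _census_counts(trajectory, r_CC, sel)
    se = _block_se(counts)
    out = AdsorptionProfile(
        n_mean=profile.n_mean,
        n0_mean=mean,
        r_CC=r_CC,
        pattern=profile.pattern,
        n_se=profile.n_se,
        n0_se=se,
        n_frames=profile.n_frames,
    )
    return effective_energy(out)


def effective_energy(profile: AdsorptionProfile) -> AdsorptionProfile:
    """eps_i = -ln(<n_i>/<n_i^0>) elementwise; zero-count monomers are
    flagged undefined, never imputed."""
    if profile.n0_mean is None:
        raise ValueError("profile lacks the uncharged-chain reference census")
    n = profile.n_mean
    n0 = profile.n0_mean
    defined = (n > 0) & (n0 > 0)
    eps = np.full(profile.N, np.nan)
    eps[defined] = -np.log(n[defined] / n0[defined])
    profile.eps = eps
    profile.defined = defined
    return profile


def adsorption_entropy(
    eps: np.ndarray,
    mu: float,
    energy_factor: str = "printed",
    return_sites: bool = False,
):
    """Entropy (in k_B) of the 1D independent-site adsorption model.

    ``energy_factor="printed"`` weights the occupancy term by eps_i;
    "shifted" uses (eps_i - mu), which equals S = beta<E> - beta*Omega - ...
    of the two-state grand-canonical site.  NaN entries must be filtered by
    the caller.
    """
    eps = np.asarray(eps, dtype=float)
    if np.isnan(eps).any():
        raise ValueError("eps contains undefined (NaN) sites; exclude them first")
    x = -(eps - mu)
    lnterm = np.logaddexp(0.0, x)  # ln(1 + e^x), stable for both signs
    occ = special.expit(x)  # e^x / (1 + e^x), overflow-safe
    if energy_factor == "printed":
        w = eps
    elif energy_factor == "shifted":
        w = eps - mu
    else:
        raise ValueError("energy_factor must be 'printed' or 'shifted'")
    per_site = lnterm + w * occ
    if return_sites:
        return float(per_site.sum()), per_site
    return float(per_site.sum())


@dataclass
class EntropyResult:
    """Counterion-release entropies per sequence at a shared reservoir mu."""

    mu: float
    taus: list
    S_initial: list  # condensed state, simulated eps (k_B per chain)
    S_released: list  # released state, eps = 0 at the same mu
    dS_per_charge: list  # (S_released - S_initial)/n_charged (k_B)
    minus_TdS_kJ_per_mol: list
    n_excluded: list  # undefined sites dropped from each sum
    T: float = ROOM_T


def coacervation_entropy(
    profiles: dict,
    mu: float,
    energy_factor: str = "printed",
    T: float = ROOM_T,
) -> EntropyResult:
    """Counterion-release entropy -T*dS per sequence.

    ``profiles`` maps tau -> AdsorptionProfile (all at one salt
    concentration; the reservoir mu is shared across sequences and sites).
    Release convention: the initial state evaluates the model at the
    simulated eps profile; the final state at eps = 0 (free sites at the
    same mu).  dS is reported per mole of charged monomer and -T*dS in
    kJ/mol at T = 298.15 K.
    """
    taus = sorted(profiles)
    res = EntropyResult(
        mu=mu, taus=taus, S_initial=[], S_released=[], dS_per_charge=[],
        minus_TdS_kJ_per_mol=[], n_excluded=[], T=T,
    )
    for tau in taus:
        p = profiles[tau]
        if p.eps is None:
            raise ValueError(f"profile for tau={tau} lacks effective energies")
        eps = p.eps[p.defined]
        n_excl = int(p.N - p.defined.sum())
        s_init = adsorption_entropy(eps, mu, energy_factor)
        s_rel = adsorption_entropy(np.zeros_like(eps), mu, energy_factor)
        n_charged = p.pattern.n_charged if p.pattern is not None else p.N
        ds = (s_rel - s_init) / n_charged
        res.S_initial.append(s_init)
        res.S_released.append(s_rel)
        res.dS_per_charge.append(ds)
        res.minus_TdS_kJ_per_mol.append(-entropy_to_kJ_per_mol(ds, T))
        res.n_excluded.append(n_excl)
    return res


def fit_mu_coverage(profiles: dict) -> float:
    """Single reservoir mu reproducing the observed condensation coverage.

    Solves sum over all sequences and sites of the model occupancy
    1/(1 + e^{eps_i - mu}) equal to the censused sum of <n_i>, giving a
    data-driven shared mu with no external calibration.
    """
    if not profiles:
        raise ValueError("no adsorption profiles supplied")
    eps_all = []
    target = 0.0
    for p in profiles.values():
        if p.eps is None:
            raise ValueError("profiles must carry effective energies")
        eps_all.append(p.eps[p.defined])
        target += float(p.n_mean[p.defined].sum())
    eps_all = np.concatenate(eps_all)
    if target <= 0:
        raise ValueError("census recorded no condensed counterions")
    if target >= len(eps_all):
        raise ValueError("mean coverage exceeds one counterion per site; the "
                         "single-occupancy lattice model does not apply")

    def gap(mu):
        return float((1.0 / (1.0 + np.exp(np.clip(eps_all - mu, -500, 500)))).sum()
                     - target)

    return float(optimize.brentq(gap, -50.0, 50.0, xtol=1e-12))


def fit_mu(
    profiles: dict,
    calibration: list,
    energy_factor: str = "printed",
    bracket: tuple[float, float] = (-20.0, 5.0),
) -> tuple[float, float]:
    """Least-squares fit of the single reservoir mu to calibration values.

    ``calibration`` is a list of (tau, -T*dS in kJ/mol) pairs; the same mu
    applies to every sequence.  Returns (mu, residual sum of squares).
    """
    if not profiles:
        raise ValueError("no adsorption profiles supplied")
    if not calibration:
        raise ValueError("at least one calibration point is required")
    taus = [t for t, _ in calibration]
    targets = np.array([v for _, v in calibration])
    for t in taus:
        if t not in profiles:
            raise ValueError(f"no profile for calibration tau={t}")

    def sse(mu):
        res = coacervation_entropy({t: profiles[t] for t in taus}, mu, energy_factor)
        pred = np.array(
            [res.minus_TdS_kJ_per_mol[res.taus.index(t)] for t in taus]
        )
        return float(((pred - targets) ** 2).sum())

    # the objective can be multimodal in mu: coarse scan, then local refine
    grid = np.linspace(bracket[0], bracket[1], 400)
    best = min(grid, key=sse)
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        sse, bounds=(best - span, best + span), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(
            f"mu fit did not converge in bracket {bracket}: {res.message}"
        )
    return float(res.x), float(res.fun)
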