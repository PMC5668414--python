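"""Excess free energy and phase coexistence.

The route follows the standard Monte Carlo construction for coacervate phase
diagrams: excess chemical potentials of electroneutral insertion groups are
measured by (Rosenbluth-)Widom insertion along dilution rays, integrated
thermodynamically to an excess free-energy surface f_exc(rho_P, rho_S), and
combined with Flory-Huggins ideal mixing entropy.  Two-phase coexistence is
found by minimizing the total free energy of a two-phase split under the
lever rule; the critical salt concentration (CSC) is the binodal apex in the
salt direction.

Charged species are inserted as neutral groups (salt ion pairs; a test chain
together with its neutralizing counterions) so every insertion is Ewald
valid.  Single-ion chemical potentials follow from the symmetry of the
restricted primitive model (mu_+ = mu_- = mu_pair / 2).

Conventions: ``rho_P`` is the total monomer number density of both polymers
(charged plus neutral monomers, per sigma^3), ``rho_S`` the added-salt pair
density.  Volume fractions use a site volume of one cubic bead diameter,
phi = rho * sigma^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _kernels as _k
from .mc import Trajectory, bond_length_quantiles
from .model import EnergyParams
from .patterns import ChargePattern

__all__ = [
    "widom_mu_excess",
    "StatePointMu",
    "FreeEnergySurface",
    "thermo_integrate",
    "total_free_energy",
    "BinodalResult",
    "solve_binodal",
]


# ---------------------------------------------------------------------------
# Widom insertion
# ---------------------------------------------------------------------------


def _insertion_group(species, trajectory: Trajectory, bead_radius: float):
    """Build (parent indices, charges, radii) arrays for an insertion group.

    Chains are interleaved with their neutralizing counterions (each free
    counterion directly follows a charged monomer), which keeps the partial
    group near-neutral during Rosenbluth growth.
    """
    if isinstance(species, ChargePattern):
        z = species.as_array().astype(float)
        ncounter = int(abs(z.sum()))
        counter_sign = -math.copysign(1.0, z.sum()) if ncounter else 0.0
        gq, gprev = [], []
        prev_chain = -1
        remaining = ncounter
        for zi in z:
            gprev.append(prev_chain)
            prev_chain = len(gq)
            gq.append(float(zi))
            if zi != 0 and remaining > 0:
                gprev.append(-1)
                gq.append(counter_sign)
                remaining -= 1
        for _ in range(remaining):
            gprev.append(-1)
            gq.append(counter_sign)
        gq = np.asarray(gq)
        return np.asarray(gprev, dtype=np.int64), gq, np.full(len(gq), bead_radius)
    if species == "salt_pair":
        return (
            np.array([-1, -1], dtype=np.int64),
            np.array([1.0, -1.0]),
            np.full(2, bead_radius),
        )
    if species == "hard_sphere":
        return np.array([-1], dtype=np.int64), np.array([0.0]), np.array([bead_radius])
    if species in ("polycation", "polyanion"):
        comp = trajectory.template.composition
        pat = getattr(comp, species, None) if comp is not None else None
        if pat is None:
            pat = _pattern_from_template(trajectory.template, species)
        return _insertion_group(pat, trajectory, bead_radius)
    raise ValueError(f"unknown insertion species {species!r}")


def _pattern_from_template(tmpl, species: str) -> ChargePattern:
    """Recover a chain's charge pattern from the configuration itself (used
    for trajectories read from disk, which carry no composition object)."""
    want = 1 if species == "polycation" else -1
    for s, ln in tmpl.chains:
        z = tmpl.charges[s : s + ln]
        if np.sign(z.sum()) == want:
            return ChargePattern.from_string(
                "".join("+" if q > 0 else "-" if q < 0 else "0" for q in z)
            )
    raise ValueError(f"trajectory contains no {species} chain")


def widom_mu_excess(
    trajectory: Trajectory,
    species,
    n_insertions: int = 2000,
    seed: int = 0,
    k_trial: int = 8,
    bead_radius: float = 0.5,
    n_particles: int = 16,
    ion_mix_R: float = 2.0,
) -> tuple[float, float]:
    """Excess chemical potential (and standard error) of an insertion group.

    ``species`` is "salt_pair", "hard_sphere", "polycation", "polyanion" or a
    ChargePattern (the latter three are inserted with neutralizing
    counterions; the returned value is the whole neutral group's mu_exc).
    mu_exc = -ln <W> over ``n_insertions`` ghost insertions spread across all
    frames; overlapping insertions contribute zero weight.
    """
    gprev, gq, grad = _insertion_group(species, trajectory, bead_radius)
    params: EnergyParams = trajectory.metadata["params"]
    tmpl = trajectory.template
    L = tmpl.box_length
    ew = params.resolve(L)
    bond_rq = bond_length_quantiles(params)
    per_frame = max(1, n_insertions // max(trajectory.n_frames, 1))
    weights = []
    rng = np.random.default_rng(seed)
    for fi in range(trajectory.n_frames):
        pos = np.ascontiguousarray(trajectory.frames[fi])
        Sre, Sim = _k.calc_structure_factor(pos, tmpl.charges, L, ew.kmax, ew.kint)
        w = _k.widom_group(
            pos, tmpl.charges, tmpl.radii, L,
            params.bjerrum_length, ew.alpha, ew.rcut,
            ew.kmax, ew.kint, ew.kcoef, Sre, Sim,
            gprev, gq, grad,
            params.angle_k, params.angle_theta0, bond_rq,
            per_frame, k_trial, int(rng.integers(0, 2**31 - 1)),
            ion_mix_R, n_particles,
        )
        weights.append(w)
    logw = np.concatenate(weights)  # kernel returns log-weights
    if not np.isfinite(logw).any():
        raise RuntimeError(
            "all ghost insertions overlapped (zero total weight); use more "
            "insertions or a lower density"
        )
    shift = logw[np.isfinite(logw)].max()
    w = np.exp(np.maximum(logw - shift, -745.0))
    w[~np.isfinite(logw)] = 0.0
    mean = w.mean()
    mu = -(shift + math.log(mean))
    stderr = w.std(ddof=1) / (math.sqrt(len(w)) * mean) if len(w) > 1 else math.inf
    return float(mu), float(stderr)


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatePointMu:
    """Measured group chemical potentials at one state point on a ray.

    ``rho_P`` counts all polymer monomers per sigma^3, ``rho_S`` salt pairs
    per sigma^3.  ``mu`` maps group name -> (mu_exc, stderr); expected groups
    are "polycation_group", "polyanion_group" and "salt_pair".
    """

    rho_P: float
    rho_S: float
    mu: dict


@dataclass
class FreeEnergySurface:
    """Smooth excess free energy f_exc(rho_P, rho_S) in kT per sigma^3.

    Carries the scattered thermodynamic-integration samples (provenance) and
    a fitted parametric form used for evaluation; f_exc(0, 0) = 0 by
    construction (every basis term vanishes at the origin faster than
    linearly, so the ideal limit is also recovered in the chemical
    potentials).
    """

    samples: np.ndarray  # (n, 4): rho_P, rho_S, f_exc, stderr
    coef: np.ndarray
    charged_fraction: float = 2.0 / 3.0
    rho_P_max: float = field(default=0.0)
    rho_S_max: float = field(default=0.0)
    _function: object = None

    @classmethod
    def from_function(cls, fn, rho_P_max=1.0, rho_S_max=1.0):
        """Wrap an analytic f_exc(rho_P, rho_S); used for closed-form tests."""
        return cls(
            samples=np.zeros((0, 4)), coef=np.zeros(0),
            rho_P_max=rho_P_max, rho_S_max=rho_S_max, _function=fn,
        )

    def _basis(self, x, s):
        # linear terms absorb the dilute-limit (self-energy) part of the
        # chain chemical potentials; they do not affect phase coexistence.
        # Curvature lives in the Debye-Hueckel-like I^{3/2} term and local
        # quadratic corrections.
        ionic = self.charged_fraction * x + 2.0 * s
        return np.stack(
            [
                x,
                s,
                -(ionic**1.5),
                x * x,
                x * s,
                s * s,
            ],
            axis=-1,
        )

    def f_exc(self, rho_P, rho_S):
        if self._function is not None:
            return self._function(rho_P, rho_S)
        b = self._basis(np.asarray(rho_P, dtype=float), np.asarray(rho_S, dtype=float))
        return b @ self.coef

    def in_domain(self, rho_P, rho_S, slack: float = 1.0) -> bool:
        return (
            -1e-12 <= rho_P <= self.rho_P_max * slack
            and -1e-12 <= rho_S <= self.rho_S_max * slack
        )


def thermo_integrate(
    rays: list[list[StatePointMu]],
    chain_length: int,
    polycation_charges: int,
    polyanion_charges: int,
    charged_fraction: float | None = None,
) -> FreeEnergySurface:
    """Integrate group chemical potentials along dilution rays.

    Each ray is a list of state points with fixed polymer:salt ratio ordered
    by increasing density from near-dilution; mu at zero density is taken as
    0 for salt and as the first node's value for the chain unit (the
    resulting error is linear in density and cancels from phase coexistence).
    The integrated f_exc samples from all rays are fitted with a small
    electrostatic basis (leading Debye-Hueckel-like I^{3/2} term plus local
    polynomial corrections) by weighted least squares.

    Chain chemical potentials are recovered from the measured neutral groups
    via RPM ion symmetry: mu(chain) = mu(chain + counterions) -
    n_counter * mu_pair / 2.  The integration variable for the polymers is
    the density of the charge-balanced chain unit (2 polycations + 1
    polyanion for the half-charged pattern studied here).
    """
    samples = []
    n_cc = polycation_charges  # counterions per polycation
    n_ca = polyanion_charges
    for ray in rays:
        pts = sorted(ray, key=lambda p: p.rho_P + p.rho_S)
        if not pts:
            continue
        for a, b in zip(pts, pts[1:]):
            da = (a.rho_P + a.rho_S)
            db = (b.rho_P + b.rho_S)
            if db <= da:
                raise ValueError("ray state points must be strictly increasing")
            ra = a.rho_P / (a.rho_P + a.rho_S) if da > 0 else 0.0
            rb = b.rho_P / (b.rho_P + b.rho_S)
            if abs(ra - rb) > 1e-3 and da > 0:
                raise ValueError("state points of one ray must share a composition ratio")
        # unit = 2 polycations + 1 polyanion (3 chains, 3*N monomers)
        end = pts[-1]
        rho_u_end = end.rho_P / (3.0 * chain_length)
        rho_s_end = end.rho_S
        t = np.array([0.0] + [(p.rho_P + p.rho_S) / (end.rho_P + end.rho_S) for p in pts])

        def mu_unit(p: StatePointMu) -> tuple[float, float]:
            mpc, spc = p.mu["polycation_group"]
            mpa, spa = p.mu["polyanion_group"]
            mps, sps = p.mu["salt_pair"]
            ncounter = 2 * n_cc + n_ca
            m = 2.0 * mpc + mpa - ncounter * mps / 2.0
            s = math.sqrt(4 * spc**2 + spa**2 + (ncounter / 2.0 * sps) ** 2)
            return m, s

        mu_u = np.array([mu_unit(pts[0])[0]] + [mu_unit(p)[0] for p in pts])
        se_u = np.array([mu_unit(pts[0])[1]] + [mu_unit(p)[1] for p in pts])
        mu_s = np.array([0.0] + [p.mu["salt_pair"][0] for p in pts])
        se_s = np.array([0.0] + [p.mu["salt_pair"][1] for p in pts])

        # cumulative trapezoid: f_exc(t) = rho_u_end*int mu_u dt + rho_s_end*int mu_s dt
        for i in range(1, len(t)):
            fi = rho_u_end * np.trapezoid(mu_u[: i + 1], t[: i + 1])
            fi += rho_s_end * np.trapezoid(mu_s[: i + 1], t[: i + 1])
            se = math.sqrt(
                (rho_u_end * np.max(se_u[: i + 1]) * t[i]) ** 2
                + (rho_s_end * np.max(se_s[: i + 1]) * t[i]) ** 2
            )
            samples.append((t[i] * end.rho_P, t[i] * end.rho_S, fi, max(se, 1e-12)))
    if not samples:
        raise ValueError("no state points supplied")
    arr = np.array(samples)
    cf = (
        charged_fraction
        if charged_fraction is not None
        else (2 * n_cc + n_ca) / (3.0 * chain_length)
    )
    surf = FreeEnergySurface(
        samples=arr,
        coef=np.zeros(6),
        charged_fraction=cf,
        rho_P_max=float(arr[:, 0].max()),
        rho_S_max=float(arr[:, 1].max()),
    )
    B = surf._basis(arr[:, 0], arr[:, 1])
    w = 1.0 / np.maximum(arr[:, 3], np.percentile(arr[:, 3], 25) + 1e-12)
    A = B * w[:, None]
    y = arr[:, 2] * w
    ridge = 1e-8 * np.eye(B.shape[1])
    surf.coef = np.linalg.solve(A.T @ A + ridge, A.T @ y)
    return surf


# ---------------------------------------------------------------------------
# Flory-Huggins-like total free energy
# ---------------------------------------------------------------------------


def _xlogx(x):
    x = np.maximum(x, 1e-300)
    return x * np.log(x)


def free_energy_density(
    phi_P: float,
    phi_S: float,
    surface: FreeEnergySurface,
    N: int,
    polymer_split=((2.0 / 3.0, None), (1.0 / 3.0, None)),
    solvent_length: int = 1,
) -> float:
    """f = ideal mixing + f_exc, in kT per site volume (sigma^3).

    Polymer translational entropy is per chain (1/N per monomer); salt ions
    and solvent count per particle.  ``polymer_split`` divides phi_P among
    polymer species as (fraction, chain length or None for N).
    """
    if phi_P < -1e-12 or phi_S < -1e-12 or phi_P + phi_S > 1.0:
        raise ValueError("compositions must satisfy 0 <= phi_P + phi_S <= 1")
    f = 0.0
    for frac, n in polymer_split:
        if frac <= 0:
            continue
        nn = n if n is not None else N
        f += _xlogx(frac * phi_P) / nn
    f += 2.0 * _xlogx(phi_S / 2.0)
    f += _xlogx(1.0 - phi_P - phi_S) / solvent_length
    # surface is parameterized by monomer density and salt-pair density
    f += surface.f_exc(phi_P, phi_S / 2.0)
    return float(f)


def total_free_energy(
    phi_P: float,
    phi_S: float,
    surface: FreeEnergySurface,
    N: int,
    overall: tuple[float, float] | None = None,
    **kwargs,
) -> float:
    """Delta F density relative to the homogeneous state at ``overall``.

    With ``overall`` omitted (or equal to the argument composition) the
    reference is the composition itself and Delta F = 0.
    """
    if not surface.in_domain(phi_P, phi_S / 2.0, slack=1.05) and surface._function is None:
        raise ValueError(
            f"composition ({phi_P:g}, {phi_S:g}) outside the sampled surface domain; "
            "no extrapolation"
        )
    ref = overall if overall is not None else (phi_P, phi_S)
    return free_energy_density(phi_P, phi_S, surface, N, **kwargs) - free_energy_density(
        ref[0], ref[1], surface, N, **kwargs
    )


# ---------------------------------------------------------------------------
# Binodal construction
# ---------------------------------------------------------------------------


@dataclass
class BinodalResult:
    """Coexistence data: per tie line the supernatant and coacervate
    compositions (phi_P, phi_S), the phase volume fraction of the
    supernatant, and the overall composition that produced it."""

    supernatant: list  # (phi_P, phi_S)
    coacervate: list
    tie_lines: list  # (overall, supernatant, coacervate, v_supernatant, dF)
    csc_phi_S: float  # binodal apex in the salt direction (volume fraction)

    @property
    def n_tie_lines(self) -> int:
        return len(self.tie_lines)


def _split_objective(x, overall, surface, N, kwargs):
    po, so = overall
    if len(x) == 3:
        p1, s1, v = x
    else:  # salt-free binary system
        p1, v = x
        s1 = 0.0
    if not (1e-4 <= v <= 1 - 1e-4):
        return 1e6
    p2 = (po - v * p1) / (1.0 - v)
    s2 = (so - v * s1) / (1.0 - v)
    eps = 1e-9
    for p, s in ((p1, s1), (p2, s2)):
        if p < eps or s < -1e-15 or (s < eps and so > eps) or p + s > 0.95:
            return 1e6
        if not surface.in_domain(p, s / 2.0, slack=1.02) and surface._function is None:
            return 1e6
    try:
        f1 = free_energy_density(p1, s1, surface, N, **kwargs)
        f2 = free_energy_density(p2, s2, surface, N, **kwargs)
    except ValueError:
        return 1e6
    return v * f1 + (1.0 - v) * f2


def solve_binodal(
    surface: FreeEnergySurface,
    N: int,
    overall_compositions,
    split_tol: float = 1e-4,
    gap_tol: float = 0.02,
    **kwargs,
) -> BinodalResult:
    """Two-phase minimization of Delta F with lever-rule mass balance.

    For each overall composition (phi_P, phi_S) the free energy of a
    two-phase split is minimized over one phase's composition and its volume
    fraction (the other phase follows from the lever rule), from multiple
    starts biased toward supernatant-rich and coacervate-rich corners.
    Coexistence is recorded when the split lowers the free energy by more
    than ``split_tol`` and the polymer gap exceeds ``gap_tol``.
    """
    sup, coa, ties = [], [], []
    for overall in overall_compositions:
        po, so = overall
        try:
            f_hom = free_energy_density(po, so, surface, N, **kwargs)
        except ValueError:
            continue
        best = None
        if so > 1e-12:
            starts = [
                (po * 0.05, so * 0.95, 0.4),
                (po * 0.02, so * 0.8, 0.6),
                (po * 0.3, so * 1.0, 0.3),
                (po * 0.01, so * 1.1, 0.5),
            ]
        else:
            starts = [(po * 0.05, 0.4), (po * 0.3, 0.3), (po * 0.01, 0.6)]
        for x0 in starts:
            res = optimize.minimize(
                _split_objective,
                x0,
                args=(overall, surface, N, kwargs),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        dF = best.fun - f_hom
        if len(best.x) == 3:
            p1, s1, v = best.x
        else:
            (p1, v), s1 = best.x, 0.0
        p2 = (po - v * p1) / (1.0 - v)
        s2 = (so - v * s1) / (1.0 - v)
        if dF < -split_tol and abs(p2 - p1) > gap_tol:
            lo, hi = ((p1, s1), (p2, s2)) if p1 < p2 else ((p2, s2), (p1, s1))
            v_sup = v if p1 < p2 else 1.0 - v
            sup.append(lo)
            coa.append(hi)
            ties.append((tuple(overall), lo, hi, v_sup, dF))
    csc = max((max(a[1], b[1]) for a, b in zip(sup, coa)), default=0.0)
    return BinodalResult(supernatant=sup, coacervate=coa, tie_lines=ties, csc_phi_S=csc)
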