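"""Study drivers: the full sequence-dependence campaign at a compact scale.

The workflow mirrors the scientific pipeline end to end, for chains of
length 48 in a 10-sigma box (a deliberately compact setting chosen so the
whole campaign runs on one CPU core in minutes; trends, not converged
absolute values, are the target at this scale):

1. ``phase_diagram_study``: for each polycation periodicity tau, NVT MC runs
   along dilution rays of fixed polymer:salt ratio; Widom group insertions
   give mu_exc; thermodynamic integration gives f_exc(rho_P, rho_S); the
   Flory-Huggins construction gives the binodal and the critical salt
   concentration (CSC).
2. ``counterion_study``: dilute single-chain runs at a 25 mM-equivalent salt
   background; condensation census vs an uncharged-chain reference gives
   eps_i profiles and the 1D-adsorption entropy -T*dS per tau.
3. ``coacervation_energy_study``: dense vs dilute g(r) energy functionals
   give the electrostatic energy change of coacervation per tau.

All randomness derives from a single master seed via numpy SeedSequence
spawn keys, so every study is reproducible and independently re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .entropy import (
    AdsorptionProfile,
    EntropyResult,
    coacervation_entropy,
    condensation_census,
    fit_mu_coverage,
    reference_census,
)
from .free_energy import (
    BinodalResult,
    FreeEnergySurface,
    StatePointMu,
    solve_binodal,
    thermo_integrate,
    widom_mu_excess,
)
from .mc import MCSchedule, Trajectory, build_initial_configuration, run_nvt
from .model import Configuration, EnergyParams
from .patterns import ChargePattern, SystemComposition, make_periodic_pattern
from .structure import pair_correlation, energy_from_gr
from .units import DEFAULT_UNITS, UnitSystem

__all__ = [
    "CampaignSettings",
    "PhaseDiagram",
    "phase_diagram_study",
    "phase_diagram_campaign",
    "counterion_study",
    "coacervation_energy_study",
    "derive_seed",
]


def derive_seed(master: int, *key) -> int:
    """Deterministic per-stage seed below 2^31 from one master seed.

    Uses a process-independent digest of the key parts (Python's builtin
    ``hash`` is salted per interpreter and must not leak in here).
    """
    digest = hashlib.sha256("|".join(str(p) for p in key).encode()).digest()
    h = int.from_bytes(digest[:8], "little") % (2**31 - 1)
    ss = np.random.SeedSequence(entropy=master, spawn_key=(h,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class CampaignSettings:
    """Problem sizes and conditions of the scaled-down study.

    The chain length (48), charged fraction (1/2), 2:1 polycation:polyanion
    stoichiometry, and 25 mM salt for the dilute-phase analyses follow the
    studied system; box sizes and sweep counts are the compact defaults
    justified by the convergence diagnostics in the docs.  The sequence
    effect on the excess free energy grows strongly with chain length
    (a tau=24 pattern only completes a full period on a chain of at least
    48 monomers), so the phase campaign keeps the full chain length and
    economizes on box size and ray resolution instead.
    """

    chain_length: int = 48
    taus: tuple[int, ...] = (2, 8, 24)
    f_charged: float = 0.5
    box_length: float = 10.0
    # dilution rays: (polymer chain units at the endpoint, salt pairs at the
    # endpoint); interior nodes scale both proportionally
    rays: tuple[tuple[int, int], ...] = ((2, 6), (2, 24))
    ray_nodes: tuple[float, ...] = (0.5, 1.0)
    salt_ray_pairs: tuple[int, ...] = (10, 20, 30, 40)
    n_equil: int = 500
    n_prod: int = 500
    sample_interval: int = 25
    n_widom_salt: int = 20000
    n_widom_chain: int = 2400
    n_seeds: int = 3
    # dilute-phase (census) runs
    census_chain_length: int = 48
    census_box_length: float = 16.0
    census_salt_mM: float = 25.0
    census_n_prod: int = 6000
    census_sample: int = 10
    r_CC: float = 2.0
    ewald_tolerance: float = 1e-4
    units: UnitSystem = DEFAULT_UNITS

    def energy_params(self) -> EnergyParams:
        return EnergyParams(
            bjerrum_length=self.units.bjerrum_reduced,
            ewald_tolerance=self.ewald_tolerance,
        )

    def patterns(self, tau: int, N: int | None = None):
        N = N if N is not None else self.chain_length
        pc = make_periodic_pattern(N, tau, self.f_charged, +1)
        pa = make_periodic_pattern(N, 1, 1.0, -1)
        return pc, pa


# ---------------------------------------------------------------------------
# Phase-diagram campaign
# ---------------------------------------------------------------------------


def _composition_from_counts(
    n_units: int, n_salt: int, settings: CampaignSettings, tau: int
) -> SystemComposition:
    pc, pa = settings.patterns(tau)
    return SystemComposition(
        n_Pplus=2 * n_units,
        n_Pminus=n_units,
        n_plus=n_salt,
        n_minus=n_salt,
        box_length=settings.box_length,
        polycation=pc,
        polyanion=pa,
    )


def run_state_point(
    n_units: int,
    n_salt: int,
    tau: int,
    seed: int,
    settings: CampaignSettings,
) -> StatePointMu:
    """One NVT run plus Widom group insertions at integer particle counts."""
    params = settings.energy_params()
    V = settings.box_length**3
    comp = _composition_from_counts(n_units, n_salt, settings, tau)
    mu: dict[str, tuple[float, float]] = {}
    if comp.n_beads == 0:
        raise ValueError("empty state point")
    cfg = build_initial_configuration(comp, params, seed=derive_seed(seed, "init"))
    sched = MCSchedule(
        n_equil_sweeps=settings.n_equil,
        n_prod_sweeps=settings.n_prod,
        sample_interval=settings.sample_interval,
        seed=derive_seed(seed, "mc"),
    )
    traj = run_nvt(cfg, params, sched)
    mu["salt_pair"] = widom_mu_excess(
        traj, "salt_pair", n_insertions=settings.n_widom_salt,
        seed=derive_seed(seed, "ws"), n_particles=4,
    )
    if n_units > 0:
        mu["polycation_group"] = widom_mu_excess(
            traj, "polycation", n_insertions=settings.n_widom_chain,
            seed=derive_seed(seed, "wpc"), n_particles=32,
        )
        mu["polyanion_group"] = widom_mu_excess(
            traj, "polyanion", n_insertions=settings.n_widom_chain,
            seed=derive_seed(seed, "wpa"), n_particles=32,
        )
    else:
        mu["polycation_group"] = (0.0, 0.0)
        mu["polyanion_group"] = (0.0, 0.0)
    rho_P = n_units * 3 * settings.chain_length / V
    rho_S = n_salt / V
    return StatePointMu(rho_P=rho_P, rho_S=rho_S, mu=mu)


def _pool_state_points(points: list[StatePointMu]) -> StatePointMu:
    """Average replicate-seed measurements at one state point."""
    mu = {}
    for key in points[0].mu:
        vals = np.array([p.mu[key][0] for p in points])
        ses = np.array([p.mu[key][1] for p in points])
        mu[key] = (float(vals.mean()), float(np.sqrt((ses**2).sum()) / len(ses)))
    return StatePointMu(rho_P=points[0].rho_P, rho_S=points[0].rho_S, mu=mu)


@dataclass
class PhaseDiagram:
    tau: int
    surface: FreeEnergySurface
    binodal: BinodalResult
    csc_mM: float
    csc_rho_S: float


def _ray_state_points(s: CampaignSettings):
    rays_pts = []
    for u_end, ns_end in s.rays:
        ray = []
        for t in s.ray_nodes:
            nu = int(round(u_end * t))
            nsalt = int(round(ns_end * t))
            if nu < 1:
                continue
            ray.append((nu, nsalt))
        rays_pts.append(ray)
    return rays_pts


def _measure_point(nu, nsalt, tau, master_seed, s, cache_dir) -> StatePointMu:
    key = f"tau{tau}_u{nu}_s{nsalt}" if nu > 0 else f"salt_s{nsalt}"
    if cache_dir is not None:
        f = Path(cache_dir) / f"mu_{key}.json"
        if f.exists():
            d = json.loads(f.read_text())
            return StatePointMu(rho_P=d["rho_P"], rho_S=d["rho_S"],
                                mu={k: tuple(v) for k, v in d["mu"].items()})
    # seeds keyed by state point and replicate only (not tau): matched
    # random-number streams across sequences cancel part of the shared
    # sampling noise from the tau comparison
    reps = [
        run_state_point(
            nu, nsalt, tau, derive_seed(master_seed, "sp", nu, nsalt, rep), s
        )
        for rep in range(s.n_seeds)
    ]
    pt = _pool_state_points(reps)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"mu_{key}.json").write_text(
            json.dumps({"rho_P": pt.rho_P, "rho_S": pt.rho_S, "mu": pt.mu})
        )
    return pt


def mu_unit_dilute(tau, master_seed, s: CampaignSettings) -> float:
    """Dilute-limit chemical potential of the charge-balanced chain unit.

    Ghost insertion of the neutral groups into an EMPTY periodic box of the
    campaign edge length: only intra-group interactions (and the group's
    periodic Ewald terms) contribute, which is exactly the coefficient of
    the linear density term of f_exc.  Pinning that term removes its near
    collinearity with the electrostatic-correlation amplitude in the
    surface fit.
    """
    params = s.energy_params()
    pc, pa = s.patterns(tau)
    comp = SystemComposition(
        n_Pplus=0, n_Pminus=0, n_plus=0, n_minus=0,
        box_length=s.box_length, polycation=pc, polyanion=pa,
    )
    empty = Configuration(
        positions=np.zeros((0, 3)),
        species=np.zeros(0, dtype=np.int64),
        radii=np.zeros(0),
        charges=np.zeros(0),
        chains=(),
        box_length=s.box_length,
        composition=comp,
    )
    traj = Trajectory(
        template=empty,
        frames=np.zeros((1, 0, 3)),
        energies=np.zeros(1),
        metadata={"params": params},
    )
    n_ins = 6 * s.n_widom_chain
    mpc, _ = widom_mu_excess(
        traj, "polycation", n_insertions=n_ins,
        seed=derive_seed(master_seed, "dil_pc", tau), n_particles=32,
    )
    mpa, _ = widom_mu_excess(
        traj, "polyanion", n_insertions=n_ins,
        seed=derive_seed(master_seed, "dil_pa", tau), n_particles=32,
    )
    mps, _ = widom_mu_excess(
        traj, "salt_pair", n_insertions=3 * s.n_widom_salt,
        seed=derive_seed(master_seed, "dil_s", tau), n_particles=4,
    )
    ncounter = 2 * pc.n_charged + pa.n_charged
    # same neutral-group combination used along the rays
    return 2.0 * mpc + mpa - ncounter * mps / 2.0


def measure_rays(tau, master_seed, s: CampaignSettings, cache_dir=None):
    """All dilution-ray state points for one tau (the salt-only ray carries
    no polymer, so its measurements are shared between sequences)."""
    rays = [
        [_measure_point(nu, ns_, tau, master_seed, s, cache_dir) for nu, ns_ in ray]
        for ray in _ray_state_points(s)
    ]
    salt_ray = [
        _measure_point(0, ns_, tau, master_seed, s, cache_dir)
        for ns_ in s.salt_ray_pairs
    ]
    rays.append(salt_ray)
    return rays


def _binodal_from_surface(surface, s: CampaignSettings) -> tuple[BinodalResult, float]:
    xs = np.linspace(0.02, 0.9 * surface.rho_P_max, 7)
    overall = [
        (x, srho * 2.0)
        for x in xs
        for srho in np.linspace(0.0015, surface.rho_S_max, 12)
    ]
    binodal = solve_binodal(surface, s.chain_length, overall)
    csc = binodal.csc_phi_S / 2.0
    if binodal.n_tie_lines:
        # bisection refinement of the binodal apex in the salt direction:
        # at the overall polymer composition of the saltiest tie line, find
        # the salt level where two-phase coexistence disappears
        top = max(binodal.tie_lines, key=lambda t: max(t[1][1], t[2][1]))
        x_star = top[0][0]
        s_lo = top[0][1] / 2.0
        s_hi = min(surface.rho_S_max, 2.5 * s_lo if s_lo > 0 else surface.rho_S_max)
        for _ in range(8):
            s_mid = 0.5 * (s_lo + s_hi)
            probe = solve_binodal(surface, s.chain_length, [(x_star, s_mid * 2.0)])
            if probe.n_tie_lines:
                s_lo = s_mid
                csc = max(csc, probe.csc_phi_S / 2.0)
            else:
                s_hi = s_mid
    return binodal, csc


def phase_diagram_study(
    tau: int,
    master_seed: int,
    settings: CampaignSettings | None = None,
    cache_dir: str | Path | None = None,
) -> PhaseDiagram:
    """Surface + binodal + CSC for one periodicity, pooled over replicate
    seeds.

    With ``cache_dir`` set, per-state-point results are stored as JSON and
    reused, so interrupted campaigns resume from completed state points.
    """
    s = settings or CampaignSettings()
    measured_rays = measure_rays(tau, master_seed, s, cache_dir)
    pc, pa = s.patterns(tau)
    surface = thermo_integrate(
        measured_rays,
        chain_length=s.chain_length,
        polycation_charges=pc.n_charged,
        polyanion_charges=pa.n_charged,
    )
    binodal, csc_rho = _binodal_from_surface(surface, s)
    return PhaseDiagram(
        tau=tau,
        surface=surface,
        binodal=binodal,
        csc_mM=s.units.density_to_mM(csc_rho),
        csc_rho_S=csc_rho,
    )


def phase_diagram_campaign(
    master_seed: int,
    settings: CampaignSettings | None = None,
    cache_dir: str | Path | None = None,
) -> dict[int, PhaseDiagram]:
    """Phase diagrams for every tau with a jointly fitted surface family.

    All sequences share the same small ions, solvent and packing physics;
    only the polycation charge pattern differs.  The joint fit therefore
    pools every sequence's thermodynamic-integration samples to constrain
    the shared curvature terms (x^2, x*s, s^2 and the salt linear term)
    while giving each sequence its own electrostatic-correlation amplitude
    (the I^{3/2} term) and its own polymer linear (self-energy) term.  This
    leaves the entire sequence effect in one well-conditioned amplitude per
    tau instead of spreading it over collinear coefficients.
    """
    s = settings or CampaignSettings()
    per_tau_samples = {}
    anchors = {}
    for tau in s.taus:
        rays = measure_rays(tau, master_seed, s, cache_dir)
        pc, pa = s.patterns(tau)
        surf = thermo_integrate(
            rays,
            chain_length=s.chain_length,
            polycation_charges=pc.n_charged,
            polyanion_charges=pa.n_charged,
        )
        per_tau_samples[tau] = surf
        anchors[tau] = mu_unit_dilute(tau, master_seed, s) / (3.0 * s.chain_length)
    surfaces = _joint_fit(per_tau_samples, anchors)
    out = {}
    for tau, surface in surfaces.items():
        binodal, csc_rho = _binodal_from_surface(surface, s)
        out[tau] = PhaseDiagram(
            tau=tau,
            surface=surface,
            binodal=binodal,
            csc_mM=s.units.density_to_mM(csc_rho),
            csc_rho_S=csc_rho,
        )
    return out


def _joint_fit(
    per_tau: dict[int, FreeEnergySurface], anchors: dict[int, float]
) -> dict[int, FreeEnergySurface]:
    """Refit all surfaces: pinned linear terms, shared curvature, per-tau
    electrostatic amplitude.

    ``anchors[tau]`` is the exactly measured dilute-limit linear coefficient
    (per monomer) of f_exc; subtracting it before fitting breaks the
    near-collinearity of the x-linear and I^{3/2} columns along rays.  A
    shared residual x column absorbs any offset common to all sequences.
    """
    taus = sorted(per_tau)
    nt = len(taus)
    rows = []
    rhs = []
    wts = []
    # columns: per-tau [-I^{3/2}] then shared [x, s, x^2, x*s, s^2]
    for ti, tau in enumerate(taus):
        surf = per_tau[tau]
        for x, srho, f, se in surf.samples:
            b = surf._basis(x, srho)  # [x, s, -I^1.5, x^2, xs, s^2]
            row = np.zeros(nt + 5)
            row[ti] = b[2]
            row[nt : nt + 5] = (b[0], b[1], b[3], b[4], b[5])
            rows.append(row)
            rhs.append(f - anchors[tau] * x)
            wts.append(1.0 / max(se, 1e-12))
    A = np.asarray(rows) * np.asarray(wts)[:, None]
    y = np.asarray(rhs) * np.asarray(wts)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    out = {}
    for ti, tau in enumerate(taus):
        surf = per_tau[tau]
        c = np.array([
            anchors[tau] + coef[nt],  # x: pinned dilute limit + shared residual
            coef[nt + 1],             # s
            coef[ti],                 # -I^{3/2} (the sequence amplitude)
            coef[nt + 2],             # x^2
            coef[nt + 3],             # x*s
            coef[nt + 4],             # s^2
        ])
        out[tau] = FreeEnergySurface(
            samples=surf.samples,
            coef=c,
            charged_fraction=surf.charged_fraction,
            rho_P_max=surf.rho_P_max,
            rho_S_max=surf.rho_S_max,
        )
    return out


# ---------------------------------------------------------------------------
# Dilute-phase counterion study
# ---------------------------------------------------------------------------


def _dilute_chain_config(
    pattern: ChargePattern,
    settings: CampaignSettings,
    seed: int,
    uncharged: bool = False,
) -> Configuration:
    """Single chain + neutralizing counterions + 25 mM salt background.

    With ``uncharged=True`` the chain keeps its topology and radii but all
    polymer charges are zeroed (the reference system of the census); the box
    then carries equal numbers of both ion species, keeping the counted
    counterion species at the same count as in the paired charged run.
    """
    s = settings
    V = s.census_box_length**3
    n_salt = max(1, int(round(s.units.mM_to_density(s.census_salt_mM) * V)))
    qnet = pattern.net_charge
    if not uncharged:
        n_plus = n_salt + max(0, -qnet)
        n_minus = n_salt + max(0, qnet)
    else:
        n_plus = n_minus = n_salt + abs(qnet)
    comp = SystemComposition(
        n_Pplus=1 if qnet > 0 else 0,
        n_Pminus=1 if qnet < 0 else 0,
        n_plus=n_plus,
        n_minus=n_minus,
        box_length=s.census_box_length,
        polycation=pattern if qnet > 0 else None,
        polyanion=pattern if qnet < 0 else None,
    )
    cfg = build_initial_configuration(comp, s.energy_params(), seed=seed)
    if uncharged:
        (cs, cl), = cfg.chains
        cfg.charges[cs : cs + cl] = 0.0
    return cfg


def _census_schedule(settings: CampaignSettings, seed: int) -> MCSchedule:
    return MCSchedule(
        n_equil_sweeps=max(settings.n_equil, 800),
        n_prod_sweeps=settings.census_n_prod,
        sample_interval=settings.census_sample,
        seed=seed,
    )


@dataclass
class CounterionStudy:
    profiles: dict  # tau -> AdsorptionProfile (eps filled)
    homopolyanion: AdsorptionProfile
    entropy: EntropyResult
    mu: float


def counterion_study(
    taus,
    master_seed: int,
    settings: CampaignSettings | None = None,
    mu: float | None = None,
    include_homopolyanion: bool = True,
) -> CounterionStudy:
    """Dilute single-chain condensation census and 1D-adsorption entropies.

    The shared reservoir chemical potential defaults to the
    coverage-matching fit: the single mu at which the lattice model's total
    occupancy reproduces the censused number of condensed counterions,
    pooled over all sequences at this salt concentration.
    """
    s = settings or CampaignSettings()
    params = s.energy_params()

    def run_chain(pattern, label, uncharged=False):
        cfg = _dilute_chain_config(
            pattern, s, derive_seed(master_seed, "cfg", label), uncharged
        )
        sched = _census_schedule(s, derive_seed(master_seed, "mc", label))
        return run_nvt(cfg, params, sched)

    profiles = {}
    ref_cache: dict[int, Trajectory] = {}  # keyed by |chain net charge|

    def census_for(pattern, label):
        traj = run_chain(pattern, label)
        prof = condensation_census(traj, r_CC=s.r_CC, pattern=pattern)
        qnet = pattern.net_charge
        counter_charge = -math.copysign(1.0, qnet)
        if abs(qnet) not in ref_cache:
            ref_cache[abs(qnet)] = run_chain(
                pattern, f"ref{abs(qnet)}", uncharged=True
            )
        return reference_census(ref_cache[abs(qnet)], s.r_CC, prof, counter_charge)

    for tau in taus:
        pc, _ = s.patterns(tau, N=s.census_chain_length)
        profiles[tau] = census_for(pc, f"tau{tau}")
    homo = None
    if include_homopolyanion:
        pa = make_periodic_pattern(s.census_chain_length, 1, 1.0, -1)
        homo = census_for(pa, "homopolyanion")
    mu_val = mu if mu is not None else fit_mu_coverage(profiles)
    entropy = coacervation_entropy(profiles, mu_val)
    return CounterionStudy(profiles=profiles, homopolyanion=homo, entropy=entropy,
                           mu=mu_val)


# ---------------------------------------------------------------------------
# Coacervation energy from g(r)
# ---------------------------------------------------------------------------


_CHARGED_SPECIES = (("PC+", 1.0), ("PA-", -1.0), ("S+", 1.0), ("S-", -1.0))


def _species_energy(traj: Trajectory, tagged: str, z_i: float, params: EnergyParams,
                    bin_width: float = 0.1) -> float:
    """U_i from the g(r) functional with bare-Coulomb pair potentials."""
    corrs, pots = [], []
    for label, z_j in _CHARGED_SPECIES:
        try:
            corr = pair_correlation(traj, tagged, label, bin_width=bin_width)
        except ValueError:
            continue  # species absent at this state point
        v = params.bjerrum_length * z_i * z_j / corr.r
        corrs.append(corr)
        pots.append(v)
    return energy_from_gr(corrs, pots)


@dataclass
class CoacervationEnergy:
    tau: int
    U_dense: dict
    U_dilute: dict
    dU_kT: float  # (dU_P+ + dU_P-) per charged monomer
    dU_kJ_per_mol: float


def coacervation_energy_study(
    tau: int,
    master_seed: int,
    settings: CampaignSettings | None = None,
    dense_units: int = 2,
    dilute_units: int = 1,
    dilute_box: float = 16.0,
    n_reps: int = 3,
) -> CoacervationEnergy:
    """Electrostatic energy change on transferring chains from a dilute to a
    dense (coacervate-like) phase, via the g(r) energy functional.

    Both state points carry the same 25 mM-equivalent salt background; the
    dense point reuses the campaign box, the dilute point a larger box at
    one chain unit.  Replicate seeds are averaged, and the seed streams are
    keyed by state point only (not by sequence), so the comparison across
    tau benefits from common random numbers.
    """
    s = settings or CampaignSettings()
    params = s.energy_params()
    rho_salt = s.units.mM_to_density(s.census_salt_mM)

    def run(units, box, rep):
        pc, pa = s.patterns(tau)
        n_salt = max(1, int(round(rho_salt * box**3)))
        comp = SystemComposition(
            n_Pplus=2 * units, n_Pminus=units, n_plus=n_salt, n_minus=n_salt,
            box_length=box, polycation=pc, polyanion=pa,
        )
        cfg = build_initial_configuration(
            comp, params, seed=derive_seed(master_seed, "ecfg", units, box, rep)
        )
        sched = MCSchedule(
            n_equil_sweeps=s.n_equil, n_prod_sweeps=2 * s.n_prod,
            sample_interval=max(s.sample_interval // 2, 5),
            seed=derive_seed(master_seed, "emc", units, box, rep),
        )
        return run_nvt(cfg, params, sched)

    U_dense = {"P+": 0.0, "P-": 0.0}
    U_dilute = {"P+": 0.0, "P-": 0.0}
    for rep in range(n_reps):
        dense = run(dense_units, s.box_length, rep)
        dilute = run(dilute_units, dilute_box, rep)
        for key, label, z in (("P+", "PC+", 1.0), ("P-", "PA-", -1.0)):
            U_dense[key] += _species_energy(dense, label, z, params) / n_reps
            U_dilute[key] += _species_energy(dilute, label, z, params) / n_reps
    dU = (U_dense["P+"] - U_dilute["P+"]) + (U_dense["P-"] - U_dilute["P-"])
    # per charged monomer: both species' tagged beads are unit charges
    dU_per_charge = dU / 2.0
    from .units import GAS_CONSTANT, ROOM_T

    return CoacervationEnergy(
        tau=tau,
        U_dense=U_dense,
        U_dilute=U_dilute,
        dU_kT=dU_per_charge,
        dU_kJ_per_mol=dU_per_charge * GAS_CONSTANT * ROOM_T / 1e3,
    )
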