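"""NVT Metropolis Monte Carlo driver.

``run_nvt`` wraps the compiled MC loop: an equilibration stage with
step-size auto-tuning toward ~40% acceptance, then a production stage with
frozen step sizes (tuning during production would break detailed balance).
A sweep is N_tot attempted moves; the move set is single-bead displacement,
whole-chain translation, crankshaft/end rotation and reptation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as _k
from .model import (
    ANION,
    CATION,
    PA_MINUS,
    PA_NEUTRAL,
    PC_NEUTRAL,
    PC_PLUS,
    Configuration,
    EnergyParams,
    total_energy,
)
from .patterns import ChargePattern, SystemComposition

__all__ = ["MCSchedule", "Trajectory", "run_nvt", "build_initial_configuration"]


@dataclass(frozen=True)
class MCSchedule:
    """Sweep counts, sampling interval, move mix and step sizes."""

    n_equil_sweeps: int = 500
    n_prod_sweeps: int = 1000
    sample_interval: int = 20
    move_mix: tuple[float, float, float, float] = (0.7, 0.1, 0.15, 0.05)
    max_bead_displacement: float = 0.4
    max_chain_displacement: float = 0.4
    crank_max_angle: float = math.pi
    reptation_radius: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        w = np.asarray(self.move_mix, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("move weights must be >= 0 with positive sum")

    def cumulative_weights(self, with_chain_moves: bool) -> np.ndarray:
        w = np.asarray(self.move_mix, dtype=float).copy()
        if not with_chain_moves:
            w[1:] = 0.0
        if w.sum() <= 0:
            w[0] = 1.0
        wc = np.cumsum(w / w.sum())
        wc[-1] = 1.1  # guard against roundoff in the selection loop
        return wc


@dataclass
class Trajectory:
    """Sampled frames sharing one topology, with bookkept energies.

    ``frames`` is (n_frames, n_beads, 3); ``template`` carries species,
    charges, radii, chains and box.
    """

    template: Configuration
    frames: np.ndarray
    energies: np.ndarray  # bookkept ES+bonded total per frame (k_BT)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Configuration:
        return self.template.with_positions(self.frames[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def _uniform_radii(config: Configuration) -> bool:
    for s, l in config.chains:
        r = config.radii[s : s + l]
        if np.ptp(r) > 1e-12:
            return False
    return True


def _mc_args(config: Configuration, params: EnergyParams):
    ew = params.resolve(config.box_length)
    cs, cl, bc = config.chain_arrays()
    return ew, cs, cl, bc


def run_nvt(
    config: Configuration,
    params: EnergyParams,
    schedule: MCSchedule,
) -> Trajectory:
    """Sample the RPM system; returns production-stage frames.

    The input configuration must be overlap-free.  With the same
    (configuration, parameters, schedule, seed) the trajectory is
    bit-for-bit reproducible.
    """
    if _k.any_overlap(config.positions, config.radii, config.box_length):
        raise ValueError("initial configuration has hard-sphere overlaps")
    if abs(config.net_charge) > 1e-9 and np.any(config.charges):
        raise ValueError("system must be electroneutral for Ewald sampling")

    work = config.copy()
    ew, cs, cl, bc = _mc_args(work, params)
    has_chains = len(work.chains) > 0
    schedule_eff = schedule
    if has_chains and not _uniform_radii(work):
        # reptation slides bead identities along the contour, which is only a
        # valid configuration map when the chain's radii are uniform
        w = list(schedule.move_mix)
        w[3] = 0.0
        schedule_eff = replace(schedule, move_mix=tuple(w))
    wcum = schedule_eff.cumulative_weights(has_chains)
    dmax = np.array(
        [schedule_eff.max_bead_displacement, schedule_eff.max_chain_displacement]
    )

    common = dict(
        L=work.box_length,
        bjerrum=params.bjerrum_length,
        alpha=ew.alpha,
        rcut=ew.rcut,
        kmax=ew.kmax,
        kint=ew.kint,
        kcoef=ew.kcoef,
    )
    if schedule_eff.n_equil_sweeps > 0:
        _k.mc_run(
            work.positions, work.charges, work.radii,
            common["L"], common["bjerrum"], common["alpha"], common["rcut"],
            common["kmax"], common["kint"], common["kcoef"],
            cs, cl, bc,
            params.bond_k, params.bond_r0, params.angle_k, params.angle_theta0,
            schedule_eff.n_equil_sweeps, max(schedule_eff.n_equil_sweeps, 1),
            False, True,
            wcum, dmax, schedule_eff.crank_max_angle, schedule_eff.reptation_radius,
            (schedule_eff.seed * 2 + 1) % 2**31,
        )
    frames, utrace, att, acc, dmax = _k.mc_run(
        work.positions, work.charges, work.radii,
        common["L"], common["bjerrum"], common["alpha"], common["rcut"],
        common["kmax"], common["kint"], common["kcoef"],
        cs, cl, bc,
        params.bond_k, params.bond_r0, params.angle_k, params.angle_theta0,
        schedule_eff.n_prod_sweeps, schedule_eff.sample_interval,
        True, False,
        wcum, dmax, schedule_eff.crank_max_angle, schedule_eff.reptation_radius,
        (schedule_eff.seed * 2 + 2) % 2**31,
    )
    move_names = ("displace", "translate", "crankshaft", "reptation")
    acceptance = {
        name: (int(acc[i]), int(att[i])) for i, name in enumerate(move_names)
    }
    return Trajectory(
        template=config,
        frames=frames,
        energies=utrace,
        metadata={
            "params": params,
            "schedule": schedule_eff,
            "acceptance": acceptance,
            "tuned_dmax": tuple(float(d) for d in dmax),
            "seed": schedule_eff.seed,
        },
    )


def bond_length_quantiles(params: EnergyParams, n: int = 512) -> np.ndarray:
    """Equally probable bond lengths under p(r) ~ r^2 exp(-k_b (r - r0)^2).

    Used as the trial bond-length table for Rosenbluth chain growth (drawing
    a uniformly random entry samples the bond Boltzmann distribution).
    """
    width = 6.0 / math.sqrt(max(params.bond_k, 1e-6))
    r = np.linspace(max(1e-6, params.bond_r0 - width), params.bond_r0 + width, 4096)
    p = r**2 * np.exp(-params.bond_k * (r - params.bond_r0) ** 2)
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    u = (np.arange(n) + 0.5) / n
    return np.interp(u, cdf, r)


def _pattern_species(pattern: ChargePattern, polymer: str) -> np.ndarray:
    if polymer == "polycation":
        return np.where(pattern.as_array() != 0, PC_PLUS, PC_NEUTRAL)
    return np.where(pattern.as_array() != 0, PA_MINUS, PA_NEUTRAL)


def build_initial_configuration(
    composition: SystemComposition,
    params: EnergyParams,
    seed: int,
    bead_radius: float = 0.5,
    max_attempts: int = 20000,
) -> Configuration:
    """Overlap-free starting state: self-avoiding chain growth + random ions.

    Deterministic for a given seed.  Raises if an overlap-free placement
    cannot be constructed in ``max_attempts`` tries per bead, which signals a
    density too close to packing.
    """
    rng = np.random.default_rng(seed)
    L = composition.box_length
    species: list[int] = []
    charges: list[float] = []
    chains: list[tuple[int, int]] = []
    chain_specs: list[ChargePattern] = []
    for _ in range(composition.n_Pplus):
        chain_specs.append(composition.polycation)
    for _ in range(composition.n_Pminus):
        chain_specs.append(composition.polyanion)
    is_cation = [True] * composition.n_plus + [False] * composition.n_minus

    n_total = sum(p.N for p in chain_specs) + len(is_cation)
    positions = np.empty((n_total, 3))
    radii = np.full(n_total, bead_radius)
    idx = 0
    for ci, pat in enumerate(chain_specs):
        polymer = "polycation" if ci < composition.n_Pplus else "polyanion"
        chains.append((idx, pat.N))
        species.extend(_pattern_species(pat, polymer).tolist())
        charges.extend(float(z) for z in pat.charges)
        for m in range(pat.N):
            placed = False
            for _ in range(max_attempts):
                if m == 0:
                    cand = rng.random(3) * L
                else:
                    vec = rng.normal(size=3)
                    vec *= params.bond_r0 / np.linalg.norm(vec)
                    cand = (positions[idx - 1] + vec) % L
                if _free_of_overlap(cand, positions[:idx], radii[:idx], bead_radius, L):
                    positions[idx] = cand
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place polymer bead without overlap after "
                    f"{max_attempts} attempts; lower the density or enlarge the box"
                )
            idx += 1
    for cat in is_cation:
        species.append(CATION if cat else ANION)
        charges.append(1.0 if cat else -1.0)
        placed = False
        for _ in range(max_attempts):
            cand = rng.random(3) * L
            if _free_of_overlap(cand, positions[:idx], radii[:idx], bead_radius, L):
                positions[idx] = cand
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place ion without overlap after {max_attempts} attempts; "
                "lower the density or enlarge the box"
            )
        idx += 1

    return Configuration(
        positions=positions,
        species=np.array(species),
        radii=radii,
        charges=np.array(charges),
        chains=tuple(chains),
        box_length=L,
        composition=composition,
    )


def _free_of_overlap(cand, pos, rad, r_new, L) -> bool:
    if len(pos) == 0:
        return True
    d = pos - cand
    d -= L * np.rint(d / L)
    return bool((np.einsum("ij,ij->i", d, d) >= (rad + r_new) ** 2 - 1e-12).all())
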