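"""Structural correlations: g(r), the g(r) energy functional, and the
looping (C1) / sequence-alignment (C2) along-chain correlations.

C1 and C2 start from an anchor pair: a charged polycation monomer and a
charged polyanion monomer within a spatial cutoff r_C of each other.  Both
chains' contours are then walked by the same offset Delta-s;

  C1(Ds) = P(new pair within r_C | both new monomers charged)   "looping"
  C2(Ds) = P(both new monomers charged | new pair within r_C)   "alignment"

Offsets past a chain end are excluded from the denominators.  By default the
two matched walk directions (+,+) and (-,-) are pooled together with the
antiparallel pairs (+,-) and (-,+), since chain orientation is arbitrary;
this is switchable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mc import Trajectory
from .model import ANION, CATION, PA_MINUS, PA_NEUTRAL, PC_NEUTRAL, PC_PLUS, SPECIES_CODE

__all__ = [
    "PairCorrelation",
    "AlignmentCorrelation",
    "pair_correlation",
    "energy_from_gr",
    "alignment_correlations",
]

_SPECIES_GROUPS = {
    "polycation": (PC_PLUS, PC_NEUTRAL),
    "polyanion": (PA_MINUS, PA_NEUTRAL),
    "polycation_charged": (PC_PLUS,),
    "polyanion_charged": (PA_MINUS,),
    "cation": (CATION,),
    "anion": (ANION,),
    "salt": (CATION, ANION),
}


def _species_codes(spec) -> tuple[int, ...]:
    if isinstance(spec, str):
        if spec in _SPECIES_GROUPS:
            return _SPECIES_GROUPS[spec]
        if spec in SPECIES_CODE:
            return (SPECIES_CODE[spec],)
        raise ValueError(f"unknown species selector {spec!r}")
    if isinstance(spec, int):
        return (spec,)
    return tuple(int(s) for s in spec)


@dataclass
class PairCorrelation:
    """Radial distribution function between two species groups."""

    species_i: tuple[int, ...]
    species_j: tuple[int, ...]
    r: np.ndarray  # bin centers
    g: np.ndarray
    rho_j: float  # number density of group j
    n_frames: int
    bin_width: float


def _min_image_dists(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= L * np.rint(d / L)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def pair_correlation(
    trajectory: Trajectory, species_i, species_j, bin_width: float = 0.05
) -> PairCorrelation:
    """Standard radial distribution function from minimum-image distances.

    Histogram counts are normalized by the ideal-gas shell expectation
    N_i * rho_j * 4 pi r^2 dr per frame; distances beyond half the box edge
    are excluded.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    tmpl = trajectory.template
    L = tmpl.box_length
    ci = _species_codes(species_i)
    cj = _species_codes(species_j)
    sel_i = np.where(np.isin(tmpl.species, ci))[0]
    sel_j = np.where(np.isin(tmpl.species, cj))[0]
    if len(sel_i) == 0 or len(sel_j) == 0:
        raise ValueError("both species groups must be present in the system")
    rmax = L / 2.0
    nbins = int(rmax / bin_width)
    edges = np.arange(nbins + 1) * bin_width
    hist = np.zeros(nbins)
    same = set(sel_i.tolist()) == set(sel_j.tolist())
    for f in range(trajectory.n_frames):
        pos = trajectory.frames[f]
        d = _min_image_dists(pos[sel_i], pos[sel_j], L)
        if same:
            np.fill_diagonal(d, np.inf)
        else:
            # mask any shared beads between overlapping groups
            shared = np.intersect1d(sel_i, sel_j)
            for s in shared:
                ii = np.searchsorted(sel_i, s)
                jj = np.searchsorted(sel_j, s)
                d[ii, jj] = np.inf
        h, _ = np.histogram(d.ravel(), bins=edges)
        hist += h
    rho_j = len(sel_j) / L**3
    shell = 4.0 * np.pi * ((edges[1:] ** 3 - edges[:-1] ** 3) / 3.0)
    norm = trajectory.n_frames * len(sel_i) * rho_j * shell
    g = hist / norm
    r = 0.5 * (edges[1:] + edges[:-1])
    return PairCorrelation(
        species_i=ci, species_j=cj, r=r, g=g, rho_j=rho_j,
        n_frames=trajectory.n_frames, bin_width=bin_width,
    )


def energy_from_gr(
    correlations: list[PairCorrelation],
    potentials: list[np.ndarray],
    densities: list[float] | None = None,
) -> float:
    """Mean interaction energy of one tagged species from its g(r)s:

        U_i = 2 pi sum_j rho_j int_0^rmax r^2 v_ij(r) g_ij(r) dr   (k_BT)

    Each potential must be tabulated on its correlation's r grid (no silent
    resampling); the integral is trapezoidal and truncated at the g(r) range
    (half the box edge).  For charge-neutral systems with bare-Coulomb v_ij
    the truncated tail cancels across the species sum.
    """
    if densities is None:
        densities = [c.rho_j for c in correlations]
    if not (len(correlations) == len(potentials) == len(densities)):
        raise ValueError("correlations, potentials and densities must align")
    U = 0.0
    for corr, v, rho in zip(correlations, potentials, densities):
        v = np.asarray(v, dtype=float)
        if v.shape != corr.r.shape:
            raise ValueError(
                f"potential grid ({v.shape}) does not match g(r) grid "
                f"({corr.r.shape}); resample explicitly"
            )
        U += 2.0 * np.pi * rho * np.trapezoid(corr.r**2 * v * corr.g, corr.r)
    return float(U)


@dataclass
class AlignmentCorrelation:
    """C1/C2 along-chain conditional probabilities on a Delta-s grid.

    Bins whose denominator is zero are flagged in ``defined`` and hold NaN.
    """

    r_C: float
    ds: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    n_C1: np.ndarray  # C1 denominators (charged-pair counts)
    n_C2: np.ndarray  # C2 denominators (within-r_C counts)
    defined: np.ndarray


def alignment_correlations(
    trajectory: Trajectory,
    r_C: float = 1.5,
    max_ds: int | None = None,
    directions: str = "pooled",
) -> AlignmentCorrelation:
    """Looping (C1) and sequence-alignment (C2) correlations.

    ``directions`` is "pooled" (matched (+,+)/(-,-) plus antiparallel
    (+,-)/(-,+)) or "parallel" (matched only).
    """
    tmpl = trajectory.template
    L = tmpl.box_length
    pc_chains = []
    pa_chains = []
    for s, ln in tmpl.chains:
        codes = tmpl.species[s : s + ln]
        if np.isin(codes, (PC_PLUS, PC_NEUTRAL)).all():
            pc_chains.append((s, ln))
        elif np.isin(codes, (PA_MINUS, PA_NEUTRAL)).all():
            pa_chains.append((s, ln))
    if not pc_chains or not pa_chains:
        raise ValueError("need at least one polycation and one polyanion chain")
    if directions not in ("pooled", "parallel"):
        raise ValueError("directions must be 'pooled' or 'parallel'")
    dirpairs = [(1, 1), (-1, -1)]
    if directions == "pooled":
        dirpairs += [(1, -1), (-1, 1)]

    nds = max_ds if max_ds is not None else max(ln for _, ln in pc_chains) - 1
    num1 = np.zeros(nds + 1)
    den1 = np.zeros(nds + 1)
    num2 = np.zeros(nds + 1)
    den2 = np.zeros(nds + 1)

    charged = tmpl.charges != 0

    for f in range(trajectory.n_frames):
        pos = trajectory.frames[f]
        for cs, cl in pc_chains:
            ch_pc = charged[cs : cs + cl]
            for as_, al in pa_chains:
                ch_pa = charged[as_ : as_ + al]
                # full monomer-monomer proximity matrix for this chain pair
                dall = _min_image_dists(pos[cs : cs + cl], pos[as_ : as_ + al], L)
                within_all = dall <= r_C
                anc = np.argwhere(within_all & np.outer(ch_pc, ch_pa))
                if len(anc) == 0:
                    continue
                i0 = anc[:, 0]
                j0 = anc[:, 1]
                for ds in range(0, nds + 1):
                    for d1, d2 in dirpairs:
                        if ds == 0 and (d1, d2) != (1, 1):
                            continue  # count Ds=0 once per anchor
                        i1 = i0 + d1 * ds
                        j1 = j0 + d2 * ds
                        ok = (i1 >= 0) & (i1 < cl) & (j1 >= 0) & (j1 < al)
                        if not ok.any():
                            continue
                        i1 = i1[ok]
                        j1 = j1[ok]
                        both = ch_pc[i1] & ch_pa[j1]
                        near = within_all[i1, j1]
                        den1[ds] += int(both.sum())
                        num1[ds] += int((both & near).sum())
                        den2[ds] += int(near.sum())
                        num2[ds] += int((near & both).sum())
    defined1 = den1 > 0
    defined2 = den2 > 0
    C1 = np.full(nds + 1, np.nan)
    C2 = np.full(nds + 1, np.nan)
    C1[defined1] = num1[defined1] / den1[defined1]
    C2[defined2] = num2[defined2] / den2[defined2]
    return AlignmentCorrelation(
        r_C=r_C,
        ds=np.arange(nds + 1),
        C1=C1,
        C2=C2,
        n_C1=den1,
        n_C2=den2,
        defined=defined1 & defined2,
    )
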