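"""Deterministic analytic test configurations.

These geometries have closed-form expectations and back the oracle tests:
an ideal gas (uniform, non-interacting), a rock-salt lattice (Madelung
energy), two parallel fully charged chains (a "ladder" whose C1/C2
correlations are identically 1), and a bonded dimer.
"""

from __future__ import annotations

import numpy as np

from .model import ANION, CATION, PA_MINUS, PC_PLUS, Configuration

__all__ = ["make_fixture"]


def make_fixture(kind: str, seed: int = 0, **params) -> Configuration:
    """Build a named fixture configuration; deterministic given the seed."""
    if kind == "ideal_gas":
        return _ideal_gas(seed, **params)
    if kind == "rocksalt_lattice":
        return _rocksalt(**params)
    if kind == "two_chain_ladder":
        return _ladder(**params)
    if kind == "dimer":
        return _dimer(**params)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _ideal_gas(seed, n: int = 100, box_length: float = 10.0) -> Configuration:
    rng = np.random.default_rng(seed)
    return Configuration(
        positions=rng.random((n, 3)) * box_length,
        species=np.full(n, CATION),
        radii=np.zeros(n),
        charges=np.zeros(n),
        chains=(),
        box_length=box_length,
    )


def _rocksalt(n_cells: int = 2, spacing: float = 1.0, radius: float = 0.45) -> Configuration:
    """Alternating +-1 charges on a cubic lattice; 2*n_cells ions per edge."""
    m = 2 * n_cells
    idx = np.arange(m)
    i, j, k = np.meshgrid(idx, idx, idx, indexing="ij")
    pos = np.stack([i, j, k], axis=-1).reshape(-1, 3) * spacing
    q = (-1.0) ** (i + j + k).reshape(-1)
    return Configuration(
        positions=pos.astype(float),
        species=np.where(q > 0, CATION, ANION),
        radii=np.full(len(q), radius),
        charges=q,
        chains=(),
        box_length=m * spacing,
    )


def _ladder(
    N: int = 10,
    separation: float = 1.0,
    bond_length: float = 1.0,
    box_length: float | None = None,
    radius: float = 0.45,
) -> Configuration:
    """Two straight parallel chains: a fully charged polycation at
    separation ``separation`` from a fully charged polyanion, rung-aligned
    (index offset zero)."""
    L = box_length if box_length is not None else max(4.0 * separation, 2.0 * N * bond_length)
    x = np.arange(N) * bond_length + L / 4.0
    pc = np.stack([x, np.full(N, L / 2), np.full(N, L / 2)], axis=1)
    pa = pc.copy()
    pa[:, 1] += separation
    pos = np.vstack([pc, pa])
    species = np.concatenate([np.full(N, PC_PLUS), np.full(N, PA_MINUS)])
    charges = np.concatenate([np.ones(N), -np.ones(N)])
    return Configuration(
        positions=pos,
        species=species,
        radii=np.full(2 * N, radius),
        charges=charges,
        chains=((0, N), (N, N)),
        box_length=L,
    )


def _dimer(
    bond_length: float = 1.0, box_length: float = 10.0, radius: float = 0.0
) -> Configuration:
    pos = np.array(
        [
            [box_length / 2, box_length / 2, box_length / 2],
            [box_length / 2 + bond_length, box_length / 2, box_length / 2],
        ]
    )
    return Configuration(
        positions=pos,
        species=np.array([PC_PLUS, PC_PLUS]),
        radii=np.full(2, radius),
        charges=np.zeros(2),
        chains=((0, 2),),
        box_length=box_length,
    )
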