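"""RPM energies against independent electrostatic oracles."""

import math

import numpy as np
import pytest

from coacervseq.fixtures import make_fixture
from coacervseq.model import (
    Configuration,
    EnergyParams,
    bonded_energy,
    electrostatic_energy,
    hard_sphere_energy,
    total_energy,
)

PARAMS = EnergyParams()


def pair_config(sep, radius=0.5, L=12.0, charges=(1.0, -1.0)):
    pos = np.array([[L / 2, L / 2, L / 2], [L / 2 + sep, L / 2, L / 2]])
    return Configuration(
        positions=pos,
        species=np.array([4, 5]),
        radii=np.full(2, radius),
        charges=np.array(charges),
        chains=(),
        box_length=L,
    )


class TestHardSphere:
    def test_overlap_below_contact(self):
        assert hard_sphere_energy(pair_config(0.95)) == math.inf

    def test_free_above_contact(self):
        assert hard_sphere_energy(pair_config(1.05)) == 0.0

    def test_periodic_image_overlap(self):
        # beads far apart in the box but overlapping through the boundary
        L = 10.0
        cfg = Configuration(
            positions=np.array([[0.2, 5.0, 5.0], [L - 0.3, 5.0, 5.0]]),
            species=np.array([4, 5]),
            radii=np.full(2, 0.5),
            charges=np.zeros(2),
            chains=(),
            box_length=L,
        )
        assert hard_sphere_energy(cfg) == math.inf


class TestElectrostatics:
    def test_zero_charges(self):
        cfg = pair_config(1.5, charges=(0.0, 0.0))
        assert electrostatic_energy(cfg, PARAMS) == 0.0

    def test_isolated_pair_coulomb_limit(self):
        # +/- pair at r << L: the Ewald sum approaches -l_B / r
        cfg = pair_config(1.0, L=40.0)
        u = electrostatic_energy(cfg, PARAMS)
        expected = -PARAMS.bjerrum_length / 1.0
        assert abs(u - expected) / abs(expected) < 1e-4

    def test_rocksalt_madelung(self):
        # oracle: Evjen-weighted direct lattice sum over expanding neutral
        # cubes, an independent route to the Madelung constant
        R = 14
        idx = np.arange(-R, R + 1)
        ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
        sign = (-1.0) ** (ii + jj + kk)
        r = np.sqrt(ii**2 + jj**2 + kk**2)
        w = np.ones_like(sign)
        for ax in (ii, jj, kk):
            w *= np.where(np.abs(ax) == R, 0.5, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = sign * w / r
        terms[R, R, R] = 0.0
        madelung = -terms.sum()  # ~1.7476

        cfg = make_fixture("rocksalt_lattice", n_cells=2, spacing=1.0)
        u = electrostatic_energy(cfg, PARAMS)
        per_pair = u / (cfg.n_beads / 2)
        expected = -madelung * PARAMS.bjerrum_length
        assert abs(per_pair - expected) / abs(expected) < 1e-3

    def test_non_neutral_rejected(self):
        cfg = pair_config(1.5, charges=(1.0, 0.0))
        with pytest.raises(ValueError, match="electroneutral"):
            electrostatic_energy(cfg, PARAMS)

    def test_alpha_kmax_sweep_invariance(self):
        # raising alpha (sharper real-space screening) with kmax scaled to
        # keep the reciprocal truncation converged must not move the energy;
        # a factor-2 sweep spans the useful splitting range at fixed cutoff
        cfg = make_fixture("rocksalt_lattice", n_cells=2)
        ew0 = PARAMS.resolve(cfg.box_length)
        u0 = electrostatic_energy(cfg, PARAMS)
        for fac in (1.4, 2.0):
            p = EnergyParams(
                ewald_alpha=ew0.alpha * fac,
                ewald_kmax=int(math.ceil(ew0.kmax * fac)) + 1,
            )
            u = electrostatic_energy(cfg, p)
            assert abs(u - u0) < 1e-4 * cfg.n_beads

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        cfg = _random_valid_config(rng, n_free=20)
        u0 = electrostatic_energy(cfg, PARAMS)
        shifted = cfg.with_positions((cfg.positions + [1.7, -2.3, 0.9]) % cfg.box_length)
        u1 = electrostatic_energy(shifted, PARAMS)
        assert abs(u1 - u0) <= 1e-8 * max(abs(u0), 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        cfg = _random_valid_config(rng, n_free=20)
        perm = rng.permutation(cfg.n_beads)
        swapped = Configuration(
            positions=cfg.positions[perm],
            species=cfg.species[perm],
            radii=cfg.radii[perm],
            charges=cfg.charges[perm],
            chains=(),
            box_length=cfg.box_length,
        )
        u0 = electrostatic_energy(cfg, PARAMS)
        u1 = electrostatic_energy(swapped, PARAMS)
        assert abs(u1 - u0) <= 1e-9 * max(abs(u0), 1.0)


class TestBonded:
    def _chain(self, positions, L=20.0):
        n = len(positions)
        return Configuration(
            positions=np.asarray(positions, dtype=float),
            species=np.full(n, 1),
            radii=np.zeros(n),
            charges=np.zeros(n),
            chains=((0, n),),
            box_length=L,
        )

    def test_minimum_is_zero(self):
        p = EnergyParams(angle_k=3.0)
        cfg = self._chain([[5, 5, 5], [6, 5, 5], [7, 5, 5]])
        assert bonded_energy(cfg, p) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond(self):
        delta = 0.13
        cfg = self._chain([[5, 5, 5], [6 + delta, 5, 5]])
        assert bonded_energy(cfg, PARAMS) == pytest.approx(
            PARAMS.bond_k * delta**2, rel=1e-12
        )

    def test_collinear_angle_zero(self):
        p = EnergyParams(angle_k=5.0, angle_theta0=math.pi)
        cfg = self._chain([[2, 5, 5], [3, 5, 5], [4, 5, 5]])
        _, ua = bonded_energy(cfg, p, split=True)
        assert ua == pytest.approx(0.0, abs=1e-12)

    def test_right_angle(self):
        p = EnergyParams(angle_k=5.0, angle_theta0=math.pi)
        cfg = self._chain([[2, 5, 5], [3, 5, 5], [3, 6, 5]])
        _, ua = bonded_energy(cfg, p, split=True)
        assert ua == pytest.approx(5.0 * (math.pi / 2 - math.pi) ** 2, rel=1e-12)

    def test_single_bead_chain_contributes_zero(self):
        cfg = self._chain([[5, 5, 5]])
        assert bonded_energy(cfg, PARAMS) == 0.0


def _random_valid_config(rng, n_free=20, L=10.0, radius=0.45):
    """Random non-overlapping, neutral set of charged beads."""
    pos = []
    while len(pos) < n_free:
        cand = rng.random(3) * L
        if all(
            np.linalg.norm(
                (np.array(p) - cand) - L * np.rint((np.array(p) - cand) / L)
            )
            >= 2 * radius
            for p in pos
        ):
            pos.append(cand)
    q = np.tile([1.0, -1.0], n_free // 2)
    return Configuration(
        positions=np.array(pos),
        species=np.where(q > 0, 4, 5),
        radii=np.full(n_free, radius),
        charges=q,
        chains=(),
        box_length=L,
    )


class TestTotalEnergy:
    def test_ideal_gas_all_zero(self):
        cfg = make_fixture("ideal_gas", n=50, seed=1)
        e = total_energy(cfg, PARAMS)
        assert all(e[k] == 0.0 for k in ("HS", "ES", "bond", "angle", "total"))

    def test_decomposition_sums(self):
        rng = np.random.default_rng(7)
        cfg = _random_valid_config(rng)
        e = total_energy(cfg, PARAMS)
        assert e["total"] == pytest.approx(
            e["HS"] + e["ES"] + e["bond"] + e["angle"], rel=1e-12
        )

    def test_against_brute_force_oracle(self):
        """Independent O(N^2) + dense-k Ewald implementation (numpy, no
        recursion tricks) must agree on a small random system."""
        rng = np.random.default_rng(11)
        cfg = _random_valid_config(rng, n_free=24)
        ew = PARAMS.resolve(cfg.box_length)
        u = electrostatic_energy(cfg, PARAMS)

        L, lB, alpha = cfg.box_length, PARAMS.bjerrum_length, ew.alpha
        pos, q = cfg.positions, cfg.charges
        # real space, naive double loop
        u_real = 0.0
        for i in range(cfg.n_beads):
            for j in range(i + 1, cfg.n_beads):
                d = pos[i] - pos[j]
                d -= L * np.rint(d / L)
                r = np.linalg.norm(d)
                if r < ew.rcut:
                    u_real += lB * q[i] * q[j] * math.erfc(alpha * r) / r
        # reciprocal space, dense full-sphere k sum
        kmax = ew.kmax
        ns = np.array(
            [
                (nx, ny, nz)
                for nx in range(-kmax, kmax + 1)
                for ny in range(-kmax, kmax + 1)
                for nz in range(-kmax, kmax + 1)
                if (nx, ny, nz) != (0, 0, 0)
                and nx * nx + ny * ny + nz * nz <= kmax * kmax
            ]
        )
        kv = 2 * np.pi / L * ns
        k2 = (kv**2).sum(axis=1)
        sk = (q[None, :] * np.exp(1j * kv @ pos.T)).sum(axis=1)
        u_rec = (
            2 * np.pi * lB / L**3
            * (np.exp(-k2 / (4 * alpha**2)) / k2 * np.abs(sk) ** 2).sum()
        )
        u_self = -lB * alpha / math.sqrt(math.pi) * (q**2).sum()
        assert u == pytest.approx(u_real + u_rec + u_self, rel=1e-10)
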