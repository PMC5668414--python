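"""g(r), the g(r) energy functional, and C1/C2 alignment correlations."""

import math

import numpy as np
import pytest

from coacervseq.fixtures import make_fixture
from coacervseq.mc import MCSchedule, Trajectory, run_nvt
from coacervseq.model import Configuration, EnergyParams, PA_MINUS, PC_PLUS
from coacervseq.structure import (
    PairCorrelation,
    alignment_correlations,
    energy_from_gr,
    pair_correlation,
)

PARAMS = EnergyParams()


def _still_trajectory(cfg, n_frames=1):
    return Trajectory(
        template=cfg,
        frames=np.repeat(cfg.positions[None], n_frames, axis=0),
        energies=np.zeros(n_frames),
        metadata={"params": PARAMS},
    )


class TestPairCorrelation:
    def test_ideal_gas_is_unity(self):
        cfg = make_fixture("ideal_gas", n=400, seed=3, box_length=8.0)
        traj = run_nvt(
            cfg, PARAMS,
            MCSchedule(n_equil_sweeps=5, n_prod_sweeps=60, sample_interval=2, seed=4),
        )
        corr = pair_correlation(traj, "cation", "cation", bin_width=0.25)
        sel = corr.r > 0.5  # skip tiny-count innermost bins
        mean = corr.g[sel].mean()
        sem = corr.g[sel].std() / math.sqrt(sel.sum())
        assert abs(mean - 1.0) < 3 * max(sem, 0.01)

    def test_hard_spheres_zero_below_contact(self):
        cfg = make_fixture("ideal_gas", n=60, seed=5, box_length=8.0)
        cfg.radii[:] = 0.5
        cfg = cfg.with_positions(_respace(cfg.positions, cfg.box_length))
        traj = run_nvt(
            cfg, PARAMS,
            MCSchedule(n_equil_sweeps=20, n_prod_sweeps=100, sample_interval=5, seed=6),
        )
        corr = pair_correlation(traj, "cation", "cation", bin_width=0.05)
        assert np.all(corr.g[corr.r < 0.99] == 0.0)

    def test_two_particle_fixed_distance_bin_height(self):
        # a single pair at separation d: one occupied bin whose height is
        # the hand-normalized single-pair count
        L, d, bw = 10.0, 2.0, 0.1
        cfg = Configuration(
            positions=np.array([[1.0, 5.0, 5.0], [1.0 + d, 5.0, 5.0]]),
            species=np.array([4, 5]),
            radii=np.zeros(2),
            charges=np.zeros(2),
            chains=(),
            box_length=L,
        )
        corr = pair_correlation(_still_trajectory(cfg), "cation", "anion", bin_width=bw)
        k = int(d / bw)
        shell = 4 * np.pi / 3 * ((bw * (k + 1)) ** 3 - (bw * k) ** 3)
        expected = 1.0 / (1 * (1 / L**3) * shell)
        occupied = corr.g > 0
        assert occupied.sum() == 1
        assert corr.g[k] == pytest.approx(expected, rel=1e-12)

    def test_bad_bin_width(self):
        cfg = make_fixture("ideal_gas", n=10, seed=1)
        with pytest.raises(ValueError):
            pair_correlation(_still_trajectory(cfg), "cation", "cation", bin_width=0.0)

    def test_sum_rule_counts_neighbors(self):
        """Integrating rho_j g(r) 4 pi r^2 over the minimum-image sphere
        recovers the expected neighbor count (within a few % for an ideal
        gas; the r > L/2 corners are excluded by construction)."""
        cfg = make_fixture("ideal_gas", n=500, seed=8, box_length=10.0)
        traj = _still_trajectory(cfg)
        corr = pair_correlation(traj, "cation", "cation", bin_width=0.1)
        integral = (
            corr.rho_j * (4 * np.pi * corr.r**2 * corr.g * corr.bin_width).sum()
        )
        expected = corr.rho_j * 4 * np.pi / 3 * (cfg.box_length / 2) ** 3
        assert integral == pytest.approx(expected, rel=0.02)


class TestEnergyFromGr:
    def _flat_corr(self, rho=0.1, L=10.0, bw=0.05):
        r = np.arange(int((L / 2) / bw)) * bw + bw / 2
        return PairCorrelation(
            species_i=(4,), species_j=(5,), r=r, g=np.ones_like(r),
            rho_j=rho, n_frames=1, bin_width=bw,
        )

    def test_zero_potential(self):
        corr = self._flat_corr()
        assert energy_from_gr([corr], [np.zeros_like(corr.r)]) == 0.0

    def test_screened_coulomb_closed_form(self):
        # v = A exp(-kappa r)/r with g = 1: integral of r^2 v dr has a
        # closed form; quadrature must match to < 1e-4
        corr = self._flat_corr(rho=0.2, bw=0.01)
        A, kappa = 1.7, 2.0
        v = A * np.exp(-kappa * corr.r) / corr.r
        r0, r1 = corr.r[0], corr.r[-1]
        closed = (
            A / kappa**2
            * ((1 + kappa * r0) * np.exp(-kappa * r0) - (1 + kappa * r1) * np.exp(-kappa * r1))
        )
        expected = 2 * np.pi * corr.rho_j * closed
        got = energy_from_gr([corr], [v])
        assert got == pytest.approx(expected, rel=1e-4)

    def test_hard_sphere_zero(self):
        corr = self._flat_corr()
        corr.g[corr.r < 1.0] = 0.0
        v = np.zeros_like(corr.r)  # HS potential is zero outside contact
        assert energy_from_gr([corr], [v]) == 0.0

    def test_additivity_over_species(self):
        c1, c2 = self._flat_corr(rho=0.1), self._flat_corr(rho=0.3)
        v = 1.0 / c1.r
        both = energy_from_gr([c1, c2], [v, v])
        assert both == pytest.approx(
            energy_from_gr([c1], [v]) + energy_from_gr([c2], [v]), rel=1e-12
        )

    def test_grid_mismatch_rejected(self):
        corr = self._flat_corr()
        with pytest.raises(ValueError, match="grid"):
            energy_from_gr([corr], [np.zeros(len(corr.r) - 1)])


class TestAlignment:
    def test_ladder_perfectly_aligned(self):
        # matched-direction walks on rung-aligned straight chains stay on
        # rungs, so looping and alignment probabilities are exactly 1
        cfg = make_fixture("two_chain_ladder", N=10, separation=0.9)
        ac = alignment_correlations(
            _still_trajectory(cfg), r_C=1.0, max_ds=9, directions="parallel"
        )
        assert np.all(ac.C1[ac.defined] == 1.0)
        assert np.all(ac.C2[ac.defined] == 1.0)
        assert ac.defined[: 10 - 1].all()

    def test_anchor_definition_c1_at_zero(self):
        cfg = make_fixture("two_chain_ladder", N=6, separation=0.5)
        ac = alignment_correlations(_still_trajectory(cfg), r_C=1.0)
        assert ac.C1[0] == 1.0 and ac.C2[0] == 1.0

    def test_alternating_pattern_has_no_charged_neighbor(self):
        """With a tau=2 polycation, one contour step away from a charged
        monomer is always neutral: C2(1) = 0 whenever defined."""
        cfg = make_fixture("two_chain_ladder", N=10, separation=0.9)
        # impose the alternating pattern on the polycation
        cfg.charges[:10:2] = 1.0
        cfg.charges[1:10:2] = 0.0
        cfg.species[:10] = np.where(cfg.charges[:10] != 0, PC_PLUS, 1)
        ac = alignment_correlations(_still_trajectory(cfg), r_C=1.0, max_ds=4)
        assert ac.n_C2[1] > 0
        assert ac.C2[1] == 0.0

    def test_end_offsets_excluded_from_denominator(self):
        cfg = make_fixture("two_chain_ladder", N=4, separation=0.5)
        ac = alignment_correlations(
            _still_trajectory(cfg), r_C=1.0, max_ds=10, directions="parallel"
        )
        assert not ac.defined[5:].any()  # beyond the contour: undefined
        assert np.isnan(ac.C1[5:]).all()

    def test_no_anchors_all_flagged(self):
        cfg = make_fixture("two_chain_ladder", N=5, separation=3.0)
        ac = alignment_correlations(_still_trajectory(cfg), r_C=1.0)
        assert not ac.defined.any()

    def test_requires_both_polymers(self):
        cfg = make_fixture("ideal_gas", n=10, seed=0)
        with pytest.raises(ValueError, match="polycation"):
            alignment_correlations(_still_trajectory(cfg), r_C=1.0)


def _respace(pos, L):
    """Spread points to remove overlaps (simple lattice jitter)."""
    n = len(pos)
    side = math.ceil(n ** (1 / 3))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    )[:n]
    return (grid + 0.5) * (L / side)
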