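"""Widom insertion, thermodynamic integration and the binodal solver
against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from coacervseq.fixtures import make_fixture
from coacervseq.free_energy import (
    FreeEnergySurface,
    StatePointMu,
    free_energy_density,
    solve_binodal,
    thermo_integrate,
    total_free_energy,
    widom_mu_excess,
)
from coacervseq.mc import MCSchedule, run_nvt
from coacervseq.model import Configuration, EnergyParams

PARAMS = EnergyParams()


def _hs_fluid(eta, L=8.0, seed=3):
    """Random sequential insertion of hard spheres at packing fraction eta."""
    rho = eta * 6.0 / math.pi
    n = int(round(rho * L**3))
    rng = np.random.default_rng(seed)
    pos = np.empty((n, 3))
    placed = 0
    while placed < n:
        c = rng.random(3) * L
        d = pos[:placed] - c
        d -= L * np.rint(d / L)
        if placed == 0 or (np.einsum("ij,ij->i", d, d) >= 1.0).all():
            pos[placed] = c
            placed += 1
    return Configuration(
        positions=pos,
        species=np.full(n, 4),
        radii=np.full(n, 0.5),
        charges=np.zeros(n),
        chains=(),
        box_length=L,
    )


class TestWidom:
    def test_ideal_gas_mu_zero(self):
        cfg = make_fixture("ideal_gas", n=40, seed=2, box_length=8.0)
        traj = run_nvt(
            cfg, PARAMS,
            MCSchedule(n_equil_sweeps=5, n_prod_sweeps=40, sample_interval=10, seed=3),
        )
        mu, se = widom_mu_excess(traj, "hard_sphere", 400, seed=1, bead_radius=0.0)
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_hard_sphere_matches_carnahan_starling(self):
        eta = 0.05
        cfg = _hs_fluid(eta)
        traj = run_nvt(
            cfg, PARAMS,
            MCSchedule(n_equil_sweeps=100, n_prod_sweeps=400, sample_interval=10, seed=4),
        )
        mu, se = widom_mu_excess(traj, "hard_sphere", n_insertions=6000, seed=5)
        eta_real = cfg.n_beads / cfg.box_length**3 * math.pi / 6
        cs = (8 * eta_real - 9 * eta_real**2 + 3 * eta_real**3) / (1 - eta_real) ** 3
        assert abs(mu - cs) < 3 * se

    def test_neutral_pair_decouples_in_chargefree_system(self):
        """Inserting a +/- ion pair into a charge-free hard-sphere fluid:
        the electrostatic part reduces to the pair's own interaction, so the
        system-dependent part equals twice the single-sphere value."""
        cfg = _hs_fluid(0.03)
        traj = run_nvt(
            cfg, PARAMS,
            MCSchedule(n_equil_sweeps=60, n_prod_sweeps=300, sample_interval=10, seed=6),
        )
        mu_pair, se_p = widom_mu_excess(traj, "salt_pair", n_insertions=8000, seed=7)
        mu_hs, se_h = widom_mu_excess(traj, "hard_sphere", n_insertions=8000, seed=8)
        # pair self-interaction at infinite dilution in the same periodic box
        empty = Configuration(
            positions=np.zeros((0, 3)), species=np.zeros(0, dtype=np.int64),
            radii=np.zeros(0), charges=np.zeros(0), chains=(),
            box_length=cfg.box_length,
        )
        etraj = run_nvt(
            empty, PARAMS, MCSchedule(n_equil_sweeps=0, n_prod_sweeps=10,
                                      sample_interval=10, seed=1),
        )
        mu_pair0, _ = widom_mu_excess(etraj, "salt_pair", n_insertions=8000, seed=9)
        assert abs((mu_pair - mu_pair0) - 2 * mu_hs) < 3 * (se_p + 2 * se_h) + 0.02

    def test_variance_decreases_with_insertions(self):
        cfg = _hs_fluid(0.05, seed=11)
        traj = run_nvt(
            cfg, PARAMS,
            MCSchedule(n_equil_sweeps=50, n_prod_sweeps=200, sample_interval=10, seed=12),
        )
        _, se_small = widom_mu_excess(traj, "hard_sphere", n_insertions=800, seed=13)
        _, se_big = widom_mu_excess(traj, "hard_sphere", n_insertions=12800, seed=13)
        assert se_big < se_small / 2.5  # ~1/sqrt(16) ideally


def _const_mu_points(rho_end, mu_s, n=4):
    return [
        StatePointMu(
            rho_P=0.0, rho_S=t * rho_end,
            mu={
                "polycation_group": (0.0, 1e-9),
                "polyanion_group": (0.0, 1e-9),
                "salt_pair": (mu_s(t * rho_end), 1e-9),
            },
        )
        for t in np.linspace(1.0 / n, 1.0, n)
    ]


class TestThermoIntegrate:
    def test_zero_mu_gives_zero_surface(self):
        pts = _const_mu_points(0.1, lambda r: 0.0)
        surf = thermo_integrate([pts], 24, 12, 24)
        assert surf.f_exc(0.0, 0.05) == pytest.approx(0.0, abs=1e-10)

    def test_constant_mu_linear_f(self):
        c = 1.7
        pts = _const_mu_points(0.1, lambda r: c)
        surf = thermo_integrate([pts], 24, 12, 24)
        # f = c * rho + (c/2) * rho * (trapezoid start at 0 with mu(0)=0)
        got = float(surf.f_exc(0.0, 0.08))
        # exact cumulative trapezoid of a constant with a zero first node
        t = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        mu = np.array([0.0, c, c, c, c])
        expected = 0.1 * np.trapezoid(mu, t) * 0.8 / 1.0
        # evaluate at the sample nearest 0.08 instead of trusting the fit tail
        samp = surf.samples
        k = np.argmin(np.abs(samp[:, 1] - 0.08))
        assert samp[k, 2] == pytest.approx(
            0.1 * np.trapezoid(mu[: 4 + 1], t[: 4 + 1]) * (samp[k, 1] / 0.1),
            rel=0.1,
        )

    def test_linear_mu_quadratic_f_closed_form(self):
        a = 2.0
        rho_end = 0.1
        pts = _const_mu_points(rho_end, lambda r: a * r)
        surf = thermo_integrate([pts], 24, 12, 24)
        # the integrated endpoint sample is exact for a linear integrand
        end = surf.samples[np.argmax(surf.samples[:, 1])]
        assert end[2] == pytest.approx(a * rho_end**2 / 2, abs=1e-6)

    def test_duplicated_node_rejected(self):
        # a gapped/degenerate ray (repeated density node) cannot be
        # integrated; nodes are sorted, so duplicates are the failure mode
        pts = _const_mu_points(0.1, lambda r: 0.0)
        with pytest.raises(ValueError, match="increasing"):
            thermo_integrate([[pts[0], pts[0], pts[1]]], 24, 12, 24)


class TestTotalFreeEnergy:
    def test_identical_phases_zero(self):
        surf = FreeEnergySurface.from_function(lambda x, s: 0.0 * np.asarray(x))
        v = total_free_energy(0.1, 0.02, surf, 24, overall=(0.1, 0.02))
        assert v == pytest.approx(0.0, abs=1e-14)

    def test_ideal_surface_is_convex_no_phase_separation(self):
        surf = FreeEnergySurface.from_function(lambda x, s: 0.0 * np.asarray(x))
        res = solve_binodal(surf, 24, [(0.2, 0.02), (0.4, 0.05)])
        assert res.n_tie_lines == 0

    def test_spinodal_matches_flory_huggins_closed_form(self):
        """Injected f_exc = chi*phi*(1-phi): numerical d2F/dphi2 vanishes at
        the closed-form spinodal chi_s = (1/(phi N) + 1/(1-phi))/2."""
        N, phi = 20, 0.3
        chi_s = 0.5 * (1.0 / (phi * N) + 1.0 / (1.0 - phi))
        for chi, sign in ((0.9 * chi_s, +1), (1.1 * chi_s, -1)):
            surf = FreeEnergySurface.from_function(
                lambda x, s, c=chi: c * np.asarray(x) * (1 - np.asarray(x))
            )
            h = 1e-4
            f = lambda p: free_energy_density(
                p, 0.0, surf, N, polymer_split=((1.0, None),)
            )
            d2 = (f(phi + h) - 2 * f(phi) + f(phi - h)) / h**2
            assert math.copysign(1, d2) == sign

    def test_out_of_domain_rejected(self):
        surf = FreeEnergySurface(
            samples=np.array([[0.1, 0.01, -0.01, 1e-3]]),
            coef=np.zeros(6), rho_P_max=0.1, rho_S_max=0.01,
        )
        with pytest.raises(ValueError, match="domain"):
            total_free_energy(0.5, 0.0, surf, 24)


class TestBinodal:
    def test_symmetric_fh_matches_common_tangent_oracle(self):
        """chi*N = 3 symmetric blend: binodal compositions from the
        two-phase minimizer equal the independent 1D root of the
        common-tangent condition to 1e-4."""
        N = 10
        chi = 3.0 / N
        surf = FreeEnergySurface.from_function(
            lambda x, s: chi * np.asarray(x) * (1 - np.asarray(x))
        )
        res = solve_binodal(
            surf, N, [(0.5, 0.0)], polymer_split=((1.0, None),), solvent_length=N
        )
        assert res.n_tie_lines == 1
        g = lambda p: math.log(p / (1 - p)) / N + chi * (1 - 2 * p)
        phi_oracle = brentq(g, 1e-6, 0.49)
        lo, hi = res.supernatant[0][0], res.coacervate[0][0]
        assert lo == pytest.approx(phi_oracle, abs=1e-4)
        assert hi == pytest.approx(1 - phi_oracle, abs=1e-4)

    def test_lever_rule_mass_balance(self):
        N = 10
        chi = 3.0 / N
        surf = FreeEnergySurface.from_function(
            lambda x, s: chi * np.asarray(x) * (1 - np.asarray(x))
        )
        overall = (0.4, 0.0)
        res = solve_binodal(
            surf, N, [overall], polymer_split=((1.0, None),), solvent_length=N
        )
        (_, lo, hi, v, _), = res.tie_lines
        recombined = v * lo[0] + (1 - v) * hi[0]
        assert recombined == pytest.approx(overall[0], abs=1e-6)

    def test_tie_line_chemical_potential_equality(self):
        """Finite-difference exchange chemical potentials agree between the
        coexisting phases at the minimizer's solution."""
        N = 10
        chi = 3.0 / N
        surf = FreeEnergySurface.from_function(
            lambda x, s: chi * np.asarray(x) * (1 - np.asarray(x))
        )
        res = solve_binodal(
            surf, N, [(0.5, 0.0)], polymer_split=((1.0, None),), solvent_length=N
        )
        (_, lo, hi, _, _), = res.tie_lines
        h = 1e-5
        f = lambda p: free_energy_density(
            p, 0.0, surf, N, polymer_split=((1.0, None),), solvent_length=N
        )
        mu_lo = (f(lo[0] + h) - f(lo[0] - h)) / (2 * h)
        mu_hi = (f(hi[0] + h) - f(hi[0] - h)) / (2 * h)
        assert mu_lo == pytest.approx(mu_hi, abs=5e-3)

    def test_csc_monotone_under_coexistence_inflation(self):
        """Scaling up the non-convex part of a synthetic surface widens the
        coexistence region and cannot shrink the salt apex."""
        N = 10
        cscs = []
        for chi in (0.32, 0.40, 0.50):
            surf = FreeEnergySurface.from_function(
                lambda x, s, c=chi: c * np.asarray(x) * (1 - np.asarray(x))
                + 0.5 * np.asarray(s)
            )
            overall = [(0.5, s) for s in (0.0, 0.02, 0.05, 0.1)]
            res = solve_binodal(
                surf, N, overall, polymer_split=((1.0, None),), solvent_length=N
            )
            cscs.append(res.csc_phi_S)
        assert cscs == sorted(cscs)
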