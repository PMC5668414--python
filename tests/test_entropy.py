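"""Condensation census and the 1D adsorption entropy model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coacervseq.entropy import (
    AdsorptionProfile,
    adsorption_entropy,
    coacervation_entropy,
    condensation_census,
    effective_energy,
    fit_mu,
    fit_mu_coverage,
    reference_census,
)
from coacervseq.mc import Trajectory
from coacervseq.model import ANION, CATION, Configuration, EnergyParams
from coacervseq.patterns import make_periodic_pattern


def _chain_with_ions(ion_positions, ion_charges, N=5, L=20.0, chain_charge=1.0):
    """Straight chain along x starting at (5,5,5) plus ions at given spots."""
    chain = np.stack(
        [5.0 + np.arange(N), np.full(N, 5.0), np.full(N, 5.0)], axis=1
    )
    pos = np.vstack([chain, np.asarray(ion_positions, dtype=float)])
    n_ions = len(ion_positions)
    species = np.concatenate(
        [np.full(N, 0), [CATION if q > 0 else ANION for q in ion_charges]]
    )
    charges = np.concatenate([np.full(N, chain_charge), ion_charges])
    return Configuration(
        positions=pos,
        species=species,
        radii=np.zeros(N + n_ions),
        charges=charges,
        chains=((0, N),),
        box_length=L,
    )


def _traj(cfg, frames=None):
    f = frames if frames is not None else cfg.positions[None]
    return Trajectory(
        template=cfg, frames=np.asarray(f), energies=np.zeros(len(f)), metadata={}
    )


class TestCensus:
    def test_no_ions_in_range(self):
        cfg = _chain_with_ions([[15.0, 15.0, 15.0]], [-1.0])
        prof = condensation_census(_traj(cfg), r_CC=2.0)
        assert np.all(prof.n_mean == 0.0)

    def test_nearest_monomer_assignment(self):
        # ion at 0.8*r_CC from monomer 3 and further from monomer 4:
        # counted once, for monomer 3 only
        r_cc = 2.0
        ion = [5.0 + 2.0 + 0.4, 5.0 + 1.52, 5.0]  # closer to monomer idx 2
        cfg = _chain_with_ions([ion], [-1.0])
        prof = condensation_census(_traj(cfg), r_CC=r_cc)
        assert prof.n_mean.sum() == 1.0
        assert prof.n_mean[2] == 1.0

    def test_closed_boundary_at_r_cc(self):
        r_cc = 2.0
        cfg = _chain_with_ions([[5.0, 5.0 + r_cc, 5.0]], [-1.0])
        prof = condensation_census(_traj(cfg), r_CC=r_cc)
        assert prof.n_mean[0] == 1.0  # exactly at the cutoff counts
        just_out = _chain_with_ions([[5.0, 5.0 + r_cc + 1e-9, 5.0]], [-1.0])
        assert condensation_census(_traj(just_out), r_CC=r_cc).n_mean.sum() == 0.0

    def test_census_conservation(self):
        rng = np.random.default_rng(0)
        ions = 5.0 + rng.random((40, 3)) * 6.0
        cfg = _chain_with_ions(ions, [-1.0] * 40, N=8)
        prof = condensation_census(_traj(cfg), r_CC=2.0)
        d = ions[:, None, :] - cfg.positions[:8][None]
        d -= 20.0 * np.rint(d / 20.0)
        manual = (np.linalg.norm(d, axis=2).min(axis=1) <= 2.0).sum()
        assert prof.n_mean.sum() == manual

    def test_counts_only_counterions(self):
        # a co-ion (same sign as the chain) inside r_CC is not condensed
        cfg = _chain_with_ions([[5.0, 6.0, 5.0], [7.0, 6.0, 5.0]], [+1.0, -1.0])
        prof = condensation_census(_traj(cfg), r_CC=2.0)
        assert prof.n_mean.sum() == 1.0

    def test_multiple_chains_rejected(self):
        cfg = _chain_with_ions([[5.0, 6.0, 5.0]], [-1.0], N=6)
        cfg = Configuration(
            positions=cfg.positions,
            species=cfg.species,
            radii=cfg.radii,
            charges=cfg.charges,
            chains=((0, 3), (3, 3)),
            box_length=cfg.box_length,
        )
        with pytest.raises(ValueError, match="single-chain"):
            condensation_census(_traj(cfg), r_CC=2.0)


class TestReferenceAndEps:
    def test_self_reference_gives_zero_eps(self):
        rng = np.random.default_rng(1)
        ions = 5.0 + rng.random((30, 3)) * 5.0
        charged = _chain_with_ions(ions, [-1.0] * 30, N=6)
        prof = condensation_census(_traj(charged), r_CC=2.0)
        uncharged = _chain_with_ions(ions, [-1.0] * 30, N=6, chain_charge=0.0)
        out = reference_census(_traj(uncharged), 2.0, prof, counterion_charge=-1.0)
        assert np.allclose(out.eps[out.defined], 0.0)

    def test_reference_requires_uncharged_chain(self):
        cfg = _chain_with_ions([[5.0, 6.0, 5.0]], [-1.0])
        prof = condensation_census(_traj(cfg), r_CC=2.0)
        with pytest.raises(ValueError, match="uncharged"):
            reference_census(_traj(cfg), 2.0, prof, counterion_charge=-1.0)

    def test_length_mismatch_rejected(self):
        cfg = _chain_with_ions([[5.0, 6.0, 5.0]], [-1.0], N=5)
        prof = condensation_census(_traj(cfg), r_CC=2.0)
        other = _chain_with_ions([[5.0, 6.0, 5.0]], [-1.0], N=7, chain_charge=0.0)
        with pytest.raises(ValueError, match="does not match"):
            reference_census(_traj(other), 2.0, prof, counterion_charge=-1.0)

    @pytest.mark.parametrize(
        "ratio, expected", [(1.0, 0.0), (math.e, -1.0), (1 / math.e, 1.0)]
    )
    def test_eps_definition(self, ratio, expected):
        prof = AdsorptionProfile(
            n_mean=np.array([ratio]), n0_mean=np.array([1.0]), r_CC=2.0
        )
        out = effective_energy(prof)
        assert out.eps[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_counts_flagged_not_imputed(self):
        prof = AdsorptionProfile(
            n_mean=np.array([0.0, 1.0]), n0_mean=np.array([1.0, 0.0]), r_CC=2.0
        )
        out = effective_energy(prof)
        assert not out.defined.any()
        assert np.isnan(out.eps).all()


class TestAdsorptionEntropy:
    def test_uniform_zero_eps_gives_M_ln2(self):
        M = 17
        assert adsorption_entropy(np.zeros(M), mu=0.0) == pytest.approx(
            M * math.log(2.0), rel=1e-12
        )

    def test_empty_site_limit(self):
        s = adsorption_entropy(np.zeros(10), mu=-60.0)
        assert 0.0 <= s < 1e-20

    def test_overflow_guarded(self):
        s = adsorption_entropy(np.array([-800.0, 800.0]), mu=0.0)
        assert np.isfinite(s)

    @given(
        eps=st.lists(st.floats(-6, 6), min_size=1, max_size=10),
        mu=st.floats(-6, 4),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_grand_canonical_site_oracle(self, eps, mu):
        """Independent per-site assembly: x = e^{-(eps-mu)}, beta*Omega =
        -ln(1+x), <n> = x/(1+x), S = beta<E> - beta*Omega with the energy
        term weighted by eps."""
        eps = np.array(eps)
        total, sites = adsorption_entropy(eps, mu, return_sites=True)
        for e, s_site in zip(eps, sites):
            x = math.exp(-(e - mu))
            omega = -math.log1p(x)
            n = x / (1.0 + x)
            oracle = e * n - omega
            assert s_site == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    def test_shifted_variant_is_textbook_entropy(self):
        eps, mu = np.array([1.3]), -0.4
        x = math.exp(-(eps[0] - mu))
        n = x / (1 + x)
        # Gibbs entropy of the two-state site
        s_exact = -(n * math.log(n) + (1 - n) * math.log(1 - n))
        assert adsorption_entropy(eps, mu, energy_factor="shifted") == pytest.approx(
            s_exact, rel=1e-10
        )

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            adsorption_entropy(np.array([np.nan]), 0.0)


def _profile(eps, pattern=None):
    n0 = np.ones_like(eps)
    p = AdsorptionProfile(
        n_mean=np.exp(-np.asarray(eps, dtype=float)), n0_mean=n0, r_CC=2.0,
        pattern=pattern,
    )
    return effective_energy(p)


class TestCoacervationEntropy:
    def test_identical_eps_identical_entropy(self):
        profs = {2: _profile(np.zeros(8)), 16: _profile(np.zeros(8))}
        res = coacervation_entropy(profs, mu=-1.0)
        assert res.minus_TdS_kJ_per_mol[0] == pytest.approx(
            res.minus_TdS_kJ_per_mol[1], rel=1e-12
        )

    def test_deeper_wells_release_more_entropy(self):
        # numeric scan: uniformly deeper eps at fixed mu increases the
        # magnitude of the (negative) -T*dS of release
        mu = -1.0
        vals = []
        for depth in (0.0, -1.0, -2.0, -3.0):
            res = coacervation_entropy({1: _profile(np.full(10, depth))}, mu=mu)
            vals.append(res.minus_TdS_kJ_per_mol[0])
        assert all(b < a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0

    def test_mu_recovery_from_synthetic_profiles(self):
        mu_true = -1.37
        rng = np.random.default_rng(5)
        profs = {
            tau: _profile(rng.normal(-1.0, 0.7, 12)) for tau in (2, 4, 8)
        }
        target = coacervation_entropy(profs, mu_true)
        calib = list(zip(target.taus, target.minus_TdS_kJ_per_mol))
        mu_fit, resid = fit_mu(profs, calib)
        assert mu_fit == pytest.approx(mu_true, abs=1e-6)
        assert resid < 1e-12

    def test_inconsistent_calibration_reports_residual(self):
        profs = {2: _profile(np.full(6, -1.0)), 4: _profile(np.full(6, -1.0))}
        mu_fit, resid = fit_mu(profs, [(2, -1.0), (4, -3.0)])
        assert resid > 0.1  # identical profiles cannot satisfy both targets

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            fit_mu({}, [(2, -1.0)])
        with pytest.raises(ValueError):
            fit_mu_coverage({})

    def test_coverage_fit_reproduces_total_occupancy(self):
        rng = np.random.default_rng(9)
        eps = rng.normal(-1.5, 0.5, 24)
        mu_true = -0.8
        occ = 1.0 / (1.0 + np.exp(eps - mu_true))
        p = AdsorptionProfile(n_mean=occ, n0_mean=np.ones(24), r_CC=2.0)
        p.eps = eps
        p.defined = np.ones(24, dtype=bool)
        assert fit_mu_coverage({1: p}) == pytest.approx(mu_true, abs=1e-9)
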