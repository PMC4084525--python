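"""Stochastic bond kinetics: rate laws, Monte Carlo update, steric rules."""

import numpy as np
import pytest
from scipy import stats

from platesim.adhesion import (
    BondState,
    KineticParams,
    LigandField,
    bell_off_rate,
    binding_probabilities,
    bond_force,
    check_rules,
    dembo_on_rate,
    mc_update,
    wall_repulsion,
)
from platesim.config import PhysicalParams


@pytest.fixture(scope="module")
def kp():
    return KineticParams.from_physical(PhysicalParams())


class TestBellLaw:
    def test_unstressed_rate(self, kp):
        assert bell_off_rate(0.0, kp) == pytest.approx(3.45)

    def test_doubling_force(self, kp):
        F = kp.kBT * np.log(2.0) / kp.gamma_rc
        assert bell_off_rate(F, kp) == pytest.approx(2 * kp.koff0, rel=1e-12)

    def test_e_squared_amplification(self, kp):
        F = 2.0 * kp.kBT / kp.gamma_rc
        assert bell_off_rate(F, kp) == pytest.approx(kp.koff0 * np.e ** 2,
                                                     rel=1e-12)


class TestDemboLaw:
    def test_maximal_at_equilibrium_length(self, kp):
        assert dembo_on_rate(kp.l_b, kp) == pytest.approx(kp.kon0)
        d = 5e-9
        assert dembo_on_rate(kp.l_b + d, kp) < kp.kon0

    def test_half_rate_length(self, kp):
        d = np.sqrt(2.0 * kp.kBT * np.log(2.0) / kp.sigma_bond)
        assert dembo_on_rate(kp.l_b + d, kp) == pytest.approx(kp.kon0 / 2,
                                                              rel=1e-12)

    def test_symmetric_in_deviation(self, kp):
        for d in (1e-9, 7e-9, 30e-9):
            assert dembo_on_rate(kp.l_b + d, kp) == pytest.approx(
                dembo_on_rate(kp.l_b - d, kp), rel=1e-12)


class TestProbabilities:
    def test_zero_rate_zero_probability(self):
        pf, pr = binding_probabilities(0.0, 0.0, 1e-4)
        assert pf == 0.0 and pr == 0.0

    def test_ln2_gives_half(self):
        pf, _ = binding_probabilities(np.log(2.0) / 1e-4, 0.0, 1e-4)
        assert pf == pytest.approx(0.5, rel=1e-12)

    def test_small_rate_linearization(self):
        _, pr = binding_probabilities(0.0, 3.45, 1e-4)
        assert pr == pytest.approx(3.4494e-4, rel=1e-4)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            binding_probabilities(1.0, 1.0, 0.0)


class TestBondForce:
    def test_zero_at_equilibrium_length(self, kp):
        r = np.array([[0.0, 0.0, kp.l_b]])
        l = np.array([[0.0, 0.0, 0.0]])
        f, x, mag = bond_force(r, l, kp)
        assert np.abs(f).max() < 1e-30
        assert x[0] == pytest.approx(kp.l_b)

    def test_hooke_magnitude_and_direction(self, kp):
        # 10 nm stretch at sigma = 1 pN/nm -> 10 pN toward the ligand
        strong = KineticParams(kon0=1.0, koff0=1.0, gamma_rc=kp.gamma_rc,
                               sigma_bond=1e-3, l_b=kp.l_b,
                               bind_radius=kp.bind_radius, kBT=kp.kBT)
        r = np.array([[0.0, 0.0, strong.l_b + 10e-9]])
        l = np.array([[0.0, 0.0, 0.0]])
        f, _, mag = bond_force(r, l, strong)
        assert mag[0] == pytest.approx(10e-12, rel=1e-12)
        assert f[0, 2] == pytest.approx(-10e-12, rel=1e-12)  # pulls down

    def test_mirror_symmetry(self, kp):
        r = np.array([[50e-9, 20e-9, 200e-9]])
        l = np.array([[0.0, 0.0, 0.0]])
        f1, _, _ = bond_force(r, l, kp)
        f2, _, _ = bond_force(r * [-1, 1, 1], l, kp)
        assert f1[0, 0] == pytest.approx(-f2[0, 0])
        assert f1[0, 1] == pytest.approx(f2[0, 1])


class TestWallRepulsion:
    def test_algebraic_identity_at_ln2(self):
        F0, tau = 5e-19, 2e9
        eps = np.log(2.0) / tau  # 0.35 nm: below the default contact clamp
        assert wall_repulsion(eps, F0, tau, eps_min=1e-12) == pytest.approx(
            F0 * tau, rel=1e-12)

    def test_monotone_decay(self):
        F0, tau = 5e-19, 2e9
        eps = np.linspace(1.5e-9, 20e-9, 50)
        f = wall_repulsion(eps, F0, tau)
        assert np.all(np.diff(f) < 0)
        assert wall_repulsion(1.0e-6, F0, tau) < 1e-30 * F0 * tau

    def test_two_over_tau_value(self):
        F0, tau = 1.0, 1.0
        ref = np.exp(-2.0) / (1.0 - np.exp(-2.0))
        assert wall_repulsion(2.0, F0, tau, eps_min=1e-12) == pytest.approx(
            ref, rel=1e-12)
        assert ref == pytest.approx(0.1565, rel=1e-3)

    def test_contact_clamped(self):
        F0, tau = 5e-19, 2e9
        assert wall_repulsion(-1e-9, F0, tau) == wall_repulsion(1e-9, F0, tau)


def _accelerated(kp, kon0=1e4, koff0=10.0):
    return KineticParams(kon0=kon0, koff0=koff0, gamma_rc=kp.gamma_rc,
                         sigma_bond=kp.sigma_bond, l_b=kp.l_b,
                         bind_radius=kp.bind_radius, kBT=kp.kBT)


class TestMonteCarlo:
    def test_out_of_range_never_binds(self, kp):
        acc = _accelerated(kp)
        bonds = BondState(20)
        sites = np.zeros((20, 3))
        sites[:, 2] = 1e-6  # 1 um above the wall >> 128 nm
        ligands = LigandField.uniform(2e-6, 2e-6, 25e12, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            mc_update(bonds, sites, ligands, acc, 1e-3, rng)
        assert bonds.n_bonds == 0

    def test_saturated_ligand_refuses_fifth_site(self, kp):
        acc = _accelerated(kp, kon0=1e9)  # P_f ~ 1
        ligands = LigandField(positions=np.zeros((1, 3)))
        sites = np.zeros((6, 3))
        sites[:, 2] = kp.l_b  # all within reach, at equilibrium length
        bonds = BondState(6)
        rng = np.random.default_rng(1)
        mc_update(bonds, sites, ligands, acc, 1.0, rng)
        assert bonds.n_bonds == 4  # rule (ii)
        check_rules(bonds, ligands)

    def test_site_binds_single_ligand(self, kp):
        acc = _accelerated(kp, kon0=1e9)
        ligands = LigandField(positions=np.array([[0, 0, 0], [10e-9, 0, 0.0]]))
        sites = np.array([[0.0, 0.0, kp.l_b]])
        bonds = BondState(1)
        rng = np.random.default_rng(2)
        mc_update(bonds, sites, ligands, acc, 1.0, rng)
        assert bonds.n_bonds == 1  # rule (i): one vWF per site
        check_rules(bonds, ligands)

    def test_determinism_same_seed_same_history(self, kp):
        acc = _accelerated(kp)

        def run(seed):
            rng = np.random.default_rng(seed)
            bonds = BondState(50)
            ligands = LigandField.uniform(2e-6, 2e-6, 100e12, seed=5)
            sites = np.zeros((50, 3))
            sites[:, 0] = np.linspace(0, 2e-6, 50)
            sites[:, 2] = kp.l_b
            log: list = []
            for k in range(100):
                mc_update(bonds, sites, ligands, acc, 1e-3, rng,
                          t=k * 1e-3, event_log=log)
            return bonds.site_bond.copy(), log

        b1, l1 = run(9)
        b2, l2 = run(9)
        assert np.array_equal(b1, b2)
        assert l1 == l2

    def test_rule_invariants_hold_throughout(self, kp):
        acc = _accelerated(kp, kon0=1e5, koff0=100.0)
        rng = np.random.default_rng(4)
        bonds = BondState(200)
        ligands = LigandField.uniform(3e-6, 3e-6, 50e12, seed=6)
        sites = rng.random((200, 3)) * np.array([3e-6, 3e-6, 100e-9])
        for k in range(100):
            mc_update(bonds, sites, ligands, acc, 1e-3, rng)
            check_rules(bonds, ligands)

    def test_bond_lifetimes_follow_bell_law(self, kp):
        """Survival of bonds under constant force matches exp(-koff(F) t)."""
        F = 10e-12
        koff = bell_off_rate(F, kp)
        dt = 0.005 / koff            # koff * dt = 0.005 << 0.01
        n = 4000
        # each site pre-bonded to its own distant ligand; stretch sets force
        stretch = F / kp.sigma_bond
        spacing = 2.5 * kp.bind_radius
        ligands = LigandField(
            positions=np.column_stack([np.arange(n) * spacing,
                                       np.zeros(n), np.zeros(n)]))
        sites = ligands.positions + [0.0, 0.0, kp.l_b + stretch]
        bonds = BondState(n, site_bond=np.arange(n),
                          formation_time=np.zeros(n))
        ligands.bound_count[:] = 1
        rng = np.random.default_rng(2024)
        lifetimes = np.full(n, np.nan)
        t = 0.0
        max_steps = 1500
        for step in range(max_steps):
            before = bonds.site_bond >= 0
            mc_update(bonds, sites, ligands, kp, dt, rng, t=t)
            died = before & (bonds.site_bond < 0)
            lifetimes[died] = t + dt
            t += dt
            if bonds.n_bonds == 0:
                break
        done = np.isfinite(lifetimes)
        assert done.mean() > 0.99
        T = max_steps * dt
        # conditional-on-completion distribution is truncated exponential
        cdf = lambda x: (1 - np.exp(-koff * x)) / (1 - np.exp(-koff * T))
        res = stats.kstest(lifetimes[done], cdf)
        assert res.pvalue > 0.01
        # mean lifetime consistent with 1/koff within 3 standard errors
        mean = lifetimes[done].mean()
        se = lifetimes[done].std() / np.sqrt(done.sum())
        assert abs(mean - 1.0 / koff) < 3 * se + dt
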