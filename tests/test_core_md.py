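"""mW potential evaluation and integrator contracts."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, norm

from mwnuc import core_md as cm


# --------------------------------------------------------------------------
# Scalar potential terms
# --------------------------------------------------------------------------


def scalar_pair_oracle(r, p=cm.MWParams()):
    """Independent direct evaluation of the Stillinger-Weber pair formula."""
    if r >= p.a * p.sigma:
        return 0.0
    return (p.A * p.epsilon *
            (p.B * (p.sigma / r) ** p.p - (p.sigma / r) ** p.q) *
            math.exp(p.sigma / (r - p.a * p.sigma)))


def scalar_triplet_oracle(rij, rik, cos_t, p=cm.MWParams()):
    rc = p.a * p.sigma
    if rij >= rc or rik >= rc:
        return 0.0
    return (p.lam * p.epsilon * (cos_t - p.cos_theta0) ** 2 *
            math.exp(p.gamma * p.sigma / (rij - rc)) *
            math.exp(p.gamma * p.sigma / (rik - rc)))


class TestPairEnergy:
    def test_zero_at_and_beyond_cutoff(self, mw_params):
        rc = mw_params.cutoff
        assert cm.pair_energy(rc) == 0.0
        assert cm.pair_energy(10 * rc) == 0.0

    def test_value_at_sigma_matches_oracle(self, mw_params):
        v = cm.pair_energy(mw_params.sigma)
        assert v == pytest.approx(scalar_pair_oracle(mw_params.sigma),
                                  rel=1e-12)
        assert v == pytest.approx(-4.972, abs=5e-4)

    def test_continuous_at_cutoff(self, mw_params):
        rc = mw_params.cutoff
        assert abs(cm.pair_energy(rc - 1e-8)) < 1e-6

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            cm.pair_energy(0.0)
        with pytest.raises(ValueError):
            cm.pair_energy(-1.0)


class TestTripletEnergy:
    def test_zero_at_ideal_angle(self):
        assert cm.triplet_energy(2.4, 2.5, -1.0 / 3.0) == 0.0

    def test_decays_to_zero_at_cutoff(self, mw_params):
        rc = mw_params.cutoff
        assert cm.triplet_energy(rc - 1e-9, 2.4, 0.5) < 1e-6
        assert cm.triplet_energy(rc + 0.1, 2.4, 0.5) == 0.0

    def test_equilateral_matches_oracle(self, mw_params):
        v = cm.triplet_energy(mw_params.sigma, mw_params.sigma, 0.5)
        assert v == pytest.approx(
            scalar_triplet_oracle(mw_params.sigma, mw_params.sigma, 0.5),
            rel=1e-12)


def test_reduced_temperature_conversion():
    assert cm.reduced_to_kelvin(0.07) == pytest.approx(218.0, abs=0.05)
    assert cm.reduced_to_kelvin(0.065) == pytest.approx(202.4, abs=0.05)
    assert cm.reduced_to_kelvin(0.0) == 0.0


# --------------------------------------------------------------------------
# Full evaluation: forces, virial, invariances
# --------------------------------------------------------------------------


class TestEvaluate:
    def test_isolated_pair_beyond_cutoff(self):
        cfg = cm.Configuration([[1.0, 1.0, 1.0], [7.0, 1.0, 1.0]],
                               [20.0, 20.0, 20.0])
        U, F, W = cm.evaluate(cfg)
        assert U == 0.0
        assert np.all(F == 0.0)

    def test_forces_match_finite_differences(self, random_small_config):
        U, F, _ = cm.evaluate(random_small_config)
        pos = random_small_config.positions
        h = 1e-5
        rng = np.random.default_rng(1)
        for i in rng.choice(30, size=6, replace=False):
            for d in range(3):
                pp = pos.copy()
                pp[i, d] += h
                Up, _, _ = cm.evaluate(
                    cm.Configuration(pp, random_small_config.box))
                pm = pos.copy()
                pm[i, d] -= h
                Um, _, _ = cm.evaluate(
                    cm.Configuration(pm, random_small_config.box))
                fd = -(Up - Um) / (2 * h)
                assert fd == pytest.approx(F[i, d], rel=1e-6, abs=1e-8)

    def test_newtons_third_law(self, random_small_config):
        _, F, _ = cm.evaluate(random_small_config)
        assert np.abs(F.sum(axis=0)).max() < 1e-9

    def test_translation_invariance(self, random_small_config):
        U0, _, _ = cm.evaluate(random_small_config)
        shifted = cm.Configuration(random_small_config.positions + 2.37,
                                   random_small_config.box)
        U1, _, _ = cm.evaluate(shifted)
        assert abs(U1 - U0) < 1e-10

    def test_rotation_invariance_isolated_cluster(self):
        rng = np.random.default_rng(3)
        cl = rng.normal(0.0, 1.3, (9, 3))
        big = [60.0, 60.0, 60.0]
        U0, _, _ = cm.evaluate(cm.Configuration(cl + 30.0, big))
        th = 0.9
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        U1, _, _ = cm.evaluate(cm.Configuration(cl @ R.T + 30.0, big))
        assert U1 == pytest.approx(U0, abs=1e-9)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError):
            cm.evaluate(cm.Configuration([[0.0, 0.0, 0.0]], [5.0, 5.0, 5.0]))

    def test_virial_matches_volume_derivative(self, random_small_config):
        """W = -3V dU/dV under affine isotropic scaling."""
        _, _, W = cm.evaluate(random_small_config)
        eps = 1e-6
        pos, box = (random_small_config.positions,
                    np.asarray(random_small_config.box))
        Up, _, _ = cm.evaluate(cm.Configuration(pos * (1 + eps),
                                                box * (1 + eps)))
        Um, _, _ = cm.evaluate(cm.Configuration(pos * (1 - eps),
                                                box * (1 - eps)))
        V = float(np.prod(box))
        dUdV = (Up - Um) / (V * ((1 + eps) ** 3 - (1 - eps) ** 3))
        assert W == pytest.approx(-3.0 * V * dUdV, rel=1e-4, abs=1e-6)


class TestNeighborList:
    def test_matches_brute_force(self, random_small_config):
        nl = cm.neighbor_list(random_small_config, 4.0, 0.5)
        pairs = {tuple(p) for p in nl.pairs()}
        pos = random_small_config.positions
        box = random_small_config.box
        brute = set()
        for i in range(30):
            for j in range(i + 1, 30):
                d = pos[j] - pos[i]
                d -= box * np.floor(d / box + 0.5)
                if np.linalg.norm(d) < 4.5:
                    brute.add((i, j))
        assert pairs == brute

    def test_distance_just_beyond_list_radius(self):
        cfg = cm.Configuration([[1.0, 1.0, 1.0], [1.0 + 4.51, 1.0, 1.0]],
                               [20.0, 20.0, 20.0])
        nl = cm.neighbor_list(cfg, 4.0, 0.5)
        assert len(nl.pairs()) == 0

    def test_diamond_coordination(self, cubic_lattice):
        from mwnuc.synthetic import LatticeSpec, nearest_neighbor_distance
        nn = nearest_neighbor_distance(LatticeSpec(density=0.98))
        nl = cm.neighbor_list(cubic_lattice, nn * 1.1, 0.0)
        counts = np.zeros(cubic_lattice.n, dtype=int)
        for i, j in nl.pairs():
            counts[i] += 1
            counts[j] += 1
        assert np.all(counts == 4)

    def test_cutoff_too_large(self, random_small_config):
        with pytest.raises(ValueError):
            cm.neighbor_list(random_small_config, 7.0)

    def test_rebuild_trigger(self, random_small_config):
        nl = cm.neighbor_list(random_small_config, 4.0, 1.0)
        moved = random_small_config.positions.copy()
        assert not nl.needs_rebuild(moved)
        moved[0] += [0.35, 0.35, 0.35]   # euclidean 0.61 > skin/2
        assert nl.needs_rebuild(moved)


# --------------------------------------------------------------------------
# Velocities
# --------------------------------------------------------------------------


class TestDrawVelocities:
    def test_zero_temperature(self, random_small_config):
        out = cm.draw_velocities(random_small_config, 0.0, 1)
        assert np.all(out.velocities == 0.0)

    def test_component_variance(self):
        cfg = cm.Configuration(np.zeros((10 ** 5, 3)), [1e4, 1e4, 1e4])
        out = cm.draw_velocities(cfg, 250.0, 7)
        target = cm.KB * 250.0 / (cm.MWParams.mass * cm.MVSQ_TO_KCAL)
        assert out.velocities.var() == pytest.approx(target, rel=0.01)

    def test_seed_determinism(self, random_small_config):
        a = cm.draw_velocities(random_small_config, 218.0, 3)
        b = cm.draw_velocities(random_small_config, 218.0, 3)
        c = cm.draw_velocities(random_small_config, 218.0, 4)
        assert np.array_equal(a.velocities, b.velocities)
        assert not np.array_equal(a.velocities, c.velocities)


# --------------------------------------------------------------------------
# Integrators
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def equilibrated_216(liquid_218):
    cfg = cm.draw_velocities(liquid_218, 218.0, 9)
    st = cm.make_state(cfg)
    return cm.integrate_nvt(st, 2500, 4.0, 218.0, damping=0.5, seed=10)


class TestNVE:
    def test_time_advances(self, equilibrated_216):
        out = cm.integrate_nve(equilibrated_216, 5, 4.0)
        assert out.t - equilibrated_216.t == pytest.approx(0.02)

    def test_isolated_static_particles_stay(self):
        cfg = cm.Configuration([[2.0, 2.0, 2.0], [10.0, 10.0, 10.0]],
                               [20.0, 20.0, 20.0],
                               np.zeros((2, 3)))
        st = cm.make_state(cfg)
        out = cm.integrate_nve(st, 100, 4.0)
        assert np.allclose(out.config.positions, cfg.positions)

    def test_energy_drift(self, equilibrated_216):
        """Secular drift below 1e-4 kcal/mol/particle per 1000 steps; the
        shadow-Hamiltonian oscillation is excluded by fitting a slope."""
        st = equilibrated_216
        energies = []
        for _ in range(10):
            st = cm.integrate_nve(st, 100, 4.0)
            energies.append((st.U + st.K) / st.config.n)
        slope = np.polyfit(np.arange(10) * 100, energies, 1)[0] * 1000
        assert abs(slope) < 1e-4


class TestNVT:
    def test_mean_temperature(self, equilibrated_216):
        out = cm.integrate_nvt(equilibrated_216, 8000, 4.0, 270.9,
                               damping=0.2, seed=3, log_stride=20)
        mean_T = out.log[3 * len(out.log) // 4:, 1].mean()
        assert mean_T == pytest.approx(270.9, rel=0.02)

    def test_infinite_damping_recovers_nve(self, equilibrated_216):
        nve = cm.integrate_nve(equilibrated_216, 50, 4.0)
        nvt = cm.integrate_nvt(equilibrated_216, 50, 4.0, 218.0,
                               damping=math.inf, seed=1)
        assert np.allclose(nve.config.positions, nvt.config.positions)

    def test_velocity_distribution_maxwellian(self, equilibrated_216):
        out = cm.integrate_nvt(equilibrated_216, 3000, 4.0, 218.0,
                               damping=0.2, seed=4)
        v = out.config.velocities.ravel()
        sigma = math.sqrt(cm.KB * 218.0 /
                          (cm.MWParams.mass * cm.MVSQ_TO_KCAL))
        edges = np.linspace(-4 * sigma, 4 * sigma, 13)
        obs, _ = np.histogram(v, bins=edges)
        p = norm.cdf(edges[1:], 0, sigma) - norm.cdf(edges[:-1], 0, sigma)
        mask = p * v.size > 5
        _, pval = chisquare(obs[mask],
                            p[mask] / p[mask].sum() * obs[mask].sum())
        assert pval > 0.01


class TestNPT:
    def test_ideal_gas_density(self):
        rng = np.random.default_rng(0)
        free = cm.MWParams(A=0.0, lam=0.0)
        cfg = cm.Configuration(rng.uniform(0, 40, (64, 3)),
                               [40.0, 40.0, 40.0])
        cfg = cm.draw_velocities(cfg, 300.0, 1)
        st = cm.make_state(cfg, free)
        out = cm.integrate_npt(st, 25000, 4.0, 300.0, 200.0, seed=2,
                               params=free, log_stride=50,
                               piston_modulus=400.0)
        log = out.log[len(out.log) // 2:]
        rho_sim = 64 / log[:, 4].mean()
        rho_ideal = (200.0 / cm.KCAL_PER_A3_TO_BAR) / (cm.KB * 300.0)
        assert rho_sim == pytest.approx(rho_ideal, rel=0.08)

    def test_infinite_piston_period_freezes_volume(self, equilibrated_216):
        out = cm.integrate_npt(equilibrated_216, 50, 4.0, 218.0, 1.0,
                               piston_period=math.inf, seed=1)
        assert np.allclose(out.config.box, equilibrated_216.config.box)

    def test_liquid_density_stationary(self, equilibrated_216):
        """No monotone drift of the density over the trailing half."""
        out = cm.integrate_npt(equilibrated_216, 15000, 4.0, 218.0, 1.0,
                               seed=5, log_stride=100)
        v = out.log[len(out.log) // 2:, 4]
        thirds = np.array_split(v, 3)
        means = [t.mean() for t in thirds]
        spread = max(means) - min(means)
        assert spread / np.mean(v) < 0.02
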