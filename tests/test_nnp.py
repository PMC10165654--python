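"""Neural-network potential: descriptors, gradients, training machinery."""

import math

import numpy as np
import pytest

from mwnuc import core_md as cm
from mwnuc import nnp
from mwnuc.core_md import Configuration, MWPotential


@pytest.fixture(scope="module")
def random_model():
    return nnp.NNPModel(weights=nnp.init_network(seed=3))


@pytest.fixture(scope="module")
def random_config():
    rng = np.random.default_rng(1)
    return Configuration(rng.uniform(0, 11, (20, 3)), [11.0, 11.0, 11.0])


# --------------------------------------------------------------------------
# Descriptors
# --------------------------------------------------------------------------


class TestComputeAFs:
    def test_isolated_particle_zero_row(self, random_model):
        cfg = Configuration([[5.0, 5.0, 5.0], [25.0, 25.0, 25.0]],
                            [50.0, 50.0, 50.0])
        G = nnp.compute_afs(cfg, random_model)
        assert np.all(G == 0.0)

    def test_rotation_invariance(self, random_model):
        rng = np.random.default_rng(4)
        cl = rng.normal(0, 1.4, (8, 3))
        big = [60.0, 60.0, 60.0]
        G1 = nnp.compute_afs(Configuration(cl + 20, big), random_model)
        th = 0.8
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        G2 = nnp.compute_afs(Configuration(cl @ R.T + 30, big),
                             random_model)
        assert np.abs(G1 - G2).max() < 1e-10

    def test_permutation_invariance(self, random_model, random_config):
        G1 = nnp.compute_afs(random_config, random_model)
        perm = np.random.default_rng(0).permutation(20)
        G2 = nnp.compute_afs(
            Configuration(random_config.positions[perm],
                          random_config.box), random_model)
        assert np.abs(G1[perm] - G2).max() < 1e-12

    def test_descriptor_gradients_match_finite_differences(self,
                                                           random_model):
        """d(sum G)/dx via the autodiff graph vs central differences."""
        from mwnuc import autodiff as ad
        from mwnuc.autodiff import Var

        rng = np.random.default_rng(2)
        pos0 = rng.uniform(0, 10, (8, 3))
        box = np.array([10.0, 10.0, 10.0])

        def total(pos_arr):
            return nnp.compute_afs(Configuration(pos_arr, box),
                                   random_model).sum()

        cfg = Configuration(pos0, box)
        params = {k: Var(v) for k, v in random_model.trainable().items()}
        pos = Var(cfg.wrapped())
        G, _ = nnp._descriptor_graph(pos, cfg, random_model, params)
        g, = ad.grad(ad.sum_all(G), [pos])
        h = 1e-6
        for i in (0, 3):
            for d in range(3):
                pp = pos0.copy()
                pp[i, d] += h
                pm = pos0.copy()
                pm[i, d] -= h
                fd = (total(pp) - total(pm)) / (2 * h)
                assert fd == pytest.approx(g.v[i, d], rel=1e-5, abs=1e-9)


# --------------------------------------------------------------------------
# Evaluation contract
# --------------------------------------------------------------------------


class TestNNPEvaluate:
    def test_forces_match_finite_differences(self, random_model,
                                             random_config):
        U, F, _ = nnp.nnp_evaluate(random_config, random_model)
        pos = random_config.positions
        h = 1e-5
        for i in (0, 7, 13):
            for d in range(3):
                pp = pos.copy()
                pp[i, d] += h
                pm = pos.copy()
                pm[i, d] -= h
                Up, _, _ = nnp.nnp_evaluate(
                    Configuration(pp, random_config.box), random_model)
                Um, _, _ = nnp.nnp_evaluate(
                    Configuration(pm, random_config.box), random_model)
                fd = -(Up - Um) / (2 * h)
                assert fd == pytest.approx(F[i, d], rel=1e-6, abs=1e-8)

    def test_translation_invariance(self, random_model, random_config):
        U0, _, _ = nnp.nnp_evaluate(random_config, random_model)
        U1, _, _ = nnp.nnp_evaluate(
            Configuration(random_config.positions + 1.7,
                          random_config.box), random_model)
        assert U1 == pytest.approx(U0, abs=1e-9)

    def test_extensivity_2x2x2(self, random_model, random_config):
        U0, _, _ = nnp.nnp_evaluate(random_config, random_model)
        pos = random_config.positions
        box = np.asarray(random_config.box)
        rep = np.concatenate([pos + box * np.array([i, j, k])
                              for i in range(2) for j in range(2)
                              for k in range(2)])
        U8, _, _ = nnp.nnp_evaluate(Configuration(rep, box * 2),
                                    random_model)
        assert U8 == pytest.approx(8 * U0, rel=1e-8)

    def test_virial_matches_volume_derivative(self, random_model,
                                              random_config):
        _, _, W = nnp.nnp_evaluate(random_config, random_model)
        eps = 1e-6
        pos, box = random_config.positions, np.asarray(random_config.box)
        Up, _, _ = nnp.nnp_evaluate(
            Configuration(pos * (1 + eps), box * (1 + eps)), random_model)
        Um, _, _ = nnp.nnp_evaluate(
            Configuration(pos * (1 - eps), box * (1 - eps)), random_model)
        V = float(np.prod(box))
        dUdV = (Up - Um) / (V * ((1 + eps) ** 3 - (1 - eps) ** 3))
        assert W == pytest.approx(-3 * V * dUdV, rel=1e-4, abs=1e-8)

    def test_cutoff_exceeding_half_box_rejected(self, random_model):
        with pytest.raises(ValueError):
            nnp.nnp_evaluate(Configuration([[0.0, 0.0, 0.0]],
                                           [8.0, 8.0, 8.0]), random_model)


# --------------------------------------------------------------------------
# Corpus
# --------------------------------------------------------------------------


class TestCorpus:
    def test_small_corpus_shapes_and_decorrelation(self, small_corpus):
        assert all(e.F.shape == (216, 3) for e in small_corpus)
        u = np.array([e.U for e in small_corpus])
        ac = nnp._lag1_autocorr(u)
        assert abs(ac) < 0.5

    def test_builder_counts(self):
        corpus = nnp.build_training_corpus(
            seed=3, n_per_state=2, n_particles=64,
            state_points=((0.95, 270.9),), stride_steps=200)
        assert len(corpus) == 2
        assert corpus[0].config.n == 64
        assert np.isfinite(corpus[0].U)


# --------------------------------------------------------------------------
# Training machinery
# --------------------------------------------------------------------------


class TestSchedules:
    def test_restart_epochs_log_spaced_and_bounded(self):
        r = nnp.restart_schedule(4000, 6)
        assert np.all(np.diff(r) > 0)
        assert r.max() < 4000
        ratios = r[1:] / r[:-1].astype(float)
        assert ratios.min() > 1.2   # roughly geometric

    def test_lr_anneals_and_restarts(self):
        cfg = nnp.TrainConfig(n_epochs=1000, lr_max=1e-3, lr_min=1e-5)
        restarts = nnp.restart_schedule(1000, 4)
        lr_before = nnp.lr_at(int(restarts[1]) - 1, cfg, restarts)
        lr_after = nnp.lr_at(int(restarts[1]), cfg, restarts)
        assert lr_after > lr_before       # warm restart spikes the rate
        assert nnp.lr_at(0, cfg, restarts) == pytest.approx(1e-3)


class TestSelectBestModel:
    def make(self, de, dp):
        n = len(de)
        hist = nnp.TrainHistory(
            epochs=np.arange(n), train_loss=np.zeros(n),
            val_loss=np.zeros(n), delta_eps=np.asarray(de, float),
            delta_f=np.linspace(1, 0.1, n), delta_P=np.asarray(dp, float),
            restart_epochs=np.zeros(0), lr=np.zeros(n))
        ckpts = [nnp.Checkpoint(e, {"w": np.array([float(e)])})
                 for e in range(n)]
        return hist, ckpts

    def test_monotone_decreasing_takes_last(self):
        hist, ck = self.make(np.linspace(1, 0.1, 8),
                             np.linspace(9, 2, 8))
        best = nnp.select_best_model(hist, ck, tail_fraction=1.0)
        assert best.epoch == 7

    def test_shared_interior_minimum(self):
        de = [5, 4, 1, 4, 5, 6, 7, 8.0]
        dp = [50, 40, 10, 40, 50, 60, 70, 80.0]
        hist, ck = self.make(de, dp)
        best = nnp.select_best_model(hist, ck, tail_fraction=1.0)
        assert best.epoch == 2

    def test_rank_fallback_matches_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        # strictly decreasing-with-jitter: no joint interior minimum likely
        de = rng.permutation(16).astype(float)
        dp = rng.permutation(16).astype(float)
        hist, ck = self.make(de, dp)
        best = nnp.select_best_model(hist, ck, tail_fraction=1.0)

        def is_min(s, i):
            lo = s[i - 1] if i > 0 else np.inf
            hi = s[i + 1] if i < len(s) - 1 else np.inf
            return s[i] <= lo and s[i] <= hi

        joint = [i for i in range(16) if is_min(de, i) and is_min(dp, i)]
        if not joint:
            re = np.argsort(np.argsort(de))
            rp = np.argsort(np.argsort(dp))
            expected = int(np.argmin(np.maximum(re, rp)))
            assert best.epoch == expected

    def test_deterministic(self):
        hist, ck = self.make(np.linspace(1, 0.2, 10),
                             np.linspace(8, 1, 10))
        a = nnp.select_best_model(hist, ck)
        b = nnp.select_best_model(hist, ck)
        assert a.epoch == b.epoch

    def test_empty_checkpoints(self):
        hist, _ = self.make([1.0, 0.5], [2.0, 1.0])
        with pytest.raises(ValueError):
            nnp.select_best_model(hist, [])


class TestErrorMetrics:
    def test_reference_model_gives_zero(self, small_corpus):
        mw = MWPotential()
        em = nnp.error_metrics(mw, small_corpus[:3])
        assert em.delta_eps == pytest.approx(0.0, abs=1e-10)
        assert em.delta_f == pytest.approx(0.0, abs=1e-10)
        assert em.delta_P == pytest.approx(0.0, abs=1e-8)

    def test_constant_energy_offset(self, small_corpus):
        class Offset:
            def evaluate(self, config):
                mw = MWPotential()
                U, F, W = mw.evaluate(config)
                return U + 0.25 * config.n, F, W

        em = nnp.error_metrics(Offset(), small_corpus[:3])
        assert em.delta_eps == pytest.approx(0.25, rel=1e-9)
        assert em.delta_f == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_set(self):
        cfg = Configuration([[1.0, 1.0, 1.0], [4.0, 1.0, 1.0]],
                            [20.0, 20.0, 20.0])
        entries = [
            nnp.CorpusEntry(cfg, 1.0, np.zeros((2, 3)), 0.0),
            nnp.CorpusEntry(cfg, 3.0, np.ones((2, 3)), 0.0),
        ]

        class Fixed:
            def evaluate(self, config):
                return 2.0, np.zeros((2, 3)), 0.0

        em = nnp.error_metrics(Fixed(), entries)
        # energy errors per particle: 0.5 and -0.5 -> RMS 0.5
        assert em.delta_eps == pytest.approx(0.5)
        # force errors: 0 and 1 on each of 12 components -> RMS sqrt(1/2)
        assert em.delta_f == pytest.approx(10.0 * math.sqrt(0.5))


class TestTraining:
    def test_self_consistency_zero_loss(self, random_model, small_corpus):
        """Training data generated by the model itself is fit immediately:
        the initial loss is already ~ 0 and stays there."""
        model = random_model.copy()
        entries = []
        for e in small_corpus[:4]:
            U, F, W = nnp.nnp_evaluate(e.config, model)
            entries.append(nnp.CorpusEntry(e.config, U, F, W))
        cfg = nnp.TrainConfig(n_epochs=3, seed=0, lr_max=1e-7, lr_min=1e-8,
                              metrics_stride=1, checkpoint_stride=1,
                              train_fraction=0.75)
        _, hist, _ = nnp.train(entries, cfg, model=model.copy())
        assert hist.train_loss[-1] < 1e-8

    def test_pair_potential_learnability(self):
        """A descriptor network trained on a pair-only reference reaches a
        force error below 10% of the force scale (miniature corpus and
        schedule; the optimizer settings are scaled for the short run)."""
        from mwnuc.synthetic import generate_liquid
        pair_params = cm.MWParams(lam=0.0)
        pot = MWPotential(pair_params)
        base = generate_liquid(48, 0.95, 270.9, seed=2, chunk_steps=1000)
        cfg = cm.draw_velocities(base, 150.0, 3)
        stt = cm.make_state(cfg, pair_params)
        corpus = []
        for k in range(12):
            stt = cm.integrate_nvt(stt, 400, 4.0, 150.0, damping=0.5,
                                   seed=30 + k, params=pair_params)
            snap = stt.config.copy()
            snap.velocities = None
            U, F, W = pot.evaluate(snap)
            corpus.append(nnp.CorpusEntry(snap, U, F, W))
        tc = nnp.TrainConfig(n_epochs=400, seed=1, metrics_stride=40,
                             checkpoint_stride=40, n_restarts=4,
                             batch_size=3, lr_max=3e-3, lr_min=3e-5)
        model, hist, _ = nnp.train(corpus, tc)
        em = nnp.error_metrics(model, corpus[-3:])
        f_rms = 10.0 * np.sqrt(np.mean(np.concatenate(
            [c.F.ravel() ** 2 for c in corpus[-3:]])))
        assert em.delta_f < 0.1 * f_rms
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_distillation_error_decreases_with_corpus_size(self):
        """Test-set energy error improves as the liquid training corpus
        grows (miniature corpora; the gain saturates at the largest size,
        which is only required not to regress beyond noise)."""
        from mwnuc.synthetic import generate_liquid
        base = generate_liquid(48, 0.95, 270.9, seed=2, chunk_steps=1000)
        mw = MWPotential()
        stt = cm.make_state(cm.draw_velocities(base, 270.9, 3))
        pool, test = [], []
        for k in range(46):
            stt = cm.integrate_nvt(stt, 300, 4.0, 270.9, damping=0.5,
                                   seed=100 + k)
            snap = stt.config.copy()
            snap.velocities = None
            U, F, W = mw.evaluate(snap)
            (pool if k < 40 else test).append(
                nnp.CorpusEntry(snap, U, F, W))
        means = {}
        for size in (5, 15, 35):
            errs = []
            for seed in (1, 2):
                tc = nnp.TrainConfig(n_epochs=100, seed=seed,
                                     metrics_stride=50,
                                     checkpoint_stride=50, n_restarts=3,
                                     batch_size=3, lr_max=3e-3,
                                     lr_min=3e-5)
                model, _, _ = nnp.train(pool[:size], tc)
                errs.append(nnp.error_metrics(model, test).delta_eps)
            means[size] = np.mean(errs)
        assert means[15] < means[5]
        assert means[35] < means[5]
        assert means[35] < means[15] * 1.2

    def test_divergence_detection(self, small_corpus):
        """A non-finite loss (here from a corrupted reference energy)
        aborts with a diagnostic instead of training on garbage."""
        bad = [nnp.CorpusEntry(e.config, float("nan"), e.F, e.W)
               for e in small_corpus[:5]]
        cfg = nnp.TrainConfig(n_epochs=5, seed=0, metrics_stride=5,
                              checkpoint_stride=5)
        with pytest.raises(RuntimeError, match="diverg"):
            nnp.train(bad, cfg)


class TestEnergyErrorMap:
    def test_reference_model_map_near_zero(self):
        """With the reference evaluator standing in for the network the
        energy map vanishes within sampling error."""
        mw = MWPotential()
        em = nnp.energy_error_map(
            mw, temperatures=np.array([260.0]),
            densities=np.array([0.98]), n_particles=48, n_steps=6000,
            sample_stride=30, seed=5)
        assert em.energy_map.shape == (1, 1)
        assert em.energy_map[0, 0] < 0.1


class TestPersistence:
    def test_save_load_round_trip(self, random_model, random_config,
                                  tmp_path):
        p = tmp_path / "model.npz"
        random_model.save(str(p))
        loaded = nnp.NNPModel.load(str(p))
        U0, F0, _ = nnp.nnp_evaluate(random_config, random_model)
        U1, F1, _ = nnp.nnp_evaluate(random_config, loaded)
        assert U1 == pytest.approx(U0, abs=1e-12)
        assert np.allclose(F0, F1)
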