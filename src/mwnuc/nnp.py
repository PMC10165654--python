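"""Descriptor-based neural-network potential distilled from the mW model.

Each particle's local environment is encoded by 10 smooth, trainable atomic
fingerprints — 5 two-body (Gaussians in neighbor distance, trainable center
and width) and 5 three-body (Gaussians in the bond angle cosine and in the
two bond lengths, trainable angular offset, angular sharpness and radial
decay) — all multiplied by a cosine cutoff so they vanish smoothly at the
descriptor cutoff.  A small feed-forward network maps the 10-vector to a
per-particle energy; the total energy is the sum over particles, which makes
the model permutation-invariant and extensive by construction.  Forces and
the virial follow from exact differentiation through the descriptors
(reverse-mode autodiff), and training minimises a weighted energy + force
loss with Adam under a cosine-annealing learning rate with warm restarts at
logarithmically spaced epochs.  The virial-pressure error is monitored but
never trained on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Var
from .core_md import (KB, KCAL_PER_A3_TO_BAR, Configuration, MWParams,
                      MWPotential, draw_velocities, integrate_nvt,
                      make_state, neighbor_list)

N_TWO_BODY = 5
N_THREE_BODY = 5
DEFAULT_CUTOFF = 4.5  # Å; covers the first two coordination shells


# --------------------------------------------------------------------------
# Trainable atomic fingerprints
# --------------------------------------------------------------------------


@dataclass
class AFSet:
    """Trainable descriptor parameters.

    two-body G_k(i) = sum_j exp(-(r_ij - Rs_k)^2 / w2_k^2) fc(r_ij)
    three-body G_k(i) = sum_{j<l} exp(-(cos t_jil - a3_k)^2 / s3_k^2)
                         * exp(-(r_ij^2 + r_il^2) / w3_k^2) fc(r_ij) fc(r_il)
    with fc the cosine cutoff fc(r) = 0.5 (1 + cos(pi r / r_cut)).
    """

    Rs: np.ndarray = field(default_factory=lambda: np.linspace(2.2, 4.2, 5))
    w2: np.ndarray = field(default_factory=lambda: np.full(5, 0.6))
    a3: np.ndarray = field(
        default_factory=lambda: np.array([-0.9, -1.0 / 3.0, 0.1, 0.5, 0.9]))
    s3: np.ndarray = field(default_factory=lambda: np.full(5, 0.5))
    w3: np.ndarray = field(default_factory=lambda: np.full(5, 3.0))
    r_cut: float = DEFAULT_CUTOFF

    def copy(self) -> "AFSet":
        return AFSet(self.Rs.copy(), self.w2.copy(), self.a3.copy(),
                     self.s3.copy(), self.w3.copy(), self.r_cut)


_AF_KEYS = ("Rs", "w2", "a3", "s3", "w3")
_NET_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3")


def init_network(hidden: Tuple[int, int] = (25, 25), seed: int = 0
                 ) -> Dict[str, np.ndarray]:
    """Xavier-initialised feed-forward weights: 10 -> h1 -> h2 -> 1."""
    rng = np.random.default_rng(seed)
    sizes = (N_TWO_BODY + N_THREE_BODY,) + tuple(hidden) + (1,)
    w: Dict[str, np.ndarray] = {}
    for k, (nin, nout) in enumerate(zip(sizes[:-1], sizes[1:]), start=1):
        w[f"W{k}"] = rng.normal(0.0, math.sqrt(2.0 / (nin + nout)),
                                size=(nin, nout))
        w[f"b{k}"] = np.zeros((1, nout))
    return w


@dataclass
class NNPModel:
    """Atomic-fingerprint parameters + network weights + normalisation.

    ``evaluate(config)`` has the same contract as the mW evaluator:
    total energy (kcal/mol), forces (-grad U) and virial W such that the
    pressure is (2K/3 + W/3)/V.
    """

    af: AFSet = field(default_factory=AFSet)
    weights: Dict[str, np.ndarray] = field(default_factory=init_network)
    g_mean: np.ndarray = field(default_factory=lambda: np.zeros(10))
    g_std: np.ndarray = field(default_factory=lambda: np.ones(10))
    e_shift: float = 0.0            # per-particle energy offset, kcal/mol
    mass: float = MWParams.mass

    @property
    def cutoff(self) -> float:
        return self.af.r_cut

    # -- parameter bookkeeping -------------------------------------------
    def trainable(self) -> Dict[str, np.ndarray]:
        out = {k: np.asarray(getattr(self.af, k), dtype=float)
               for k in _AF_KEYS}
        out.update({k: self.weights[k] for k in self.weights})
        return out

    def set_trainable(self, params: Dict[str, np.ndarray]) -> None:
        for k in _AF_KEYS:
            setattr(self.af, k, np.asarray(params[k], dtype=float))
        for k in self.weights:
            self.weights[k] = np.asarray(params[k], dtype=float)

    def copy(self) -> "NNPModel":
        return NNPModel(self.af.copy(),
                        {k: v.copy() for k, v in self.weights.items()},
                        self.g_mean.copy(), self.g_std.copy(),
                        self.e_shift, self.mass)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, config: Configuration):
        return nnp_evaluate(config, self)

    def per_particle_energies(self, config: Configuration) -> np.ndarray:
        e, _, _ = _forward(config, self, need_graph=False)
        return e

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        header = {
            "af": {k: np.asarray(getattr(self.af, k)).tolist()
                   for k in _AF_KEYS},
            "r_cut": self.af.r_cut,
            "layers": {k: v.shape for k, v in self.weights.items()},
            "g_mean": self.g_mean.tolist(),
            "g_std": self.g_std.tolist(),
            "e_shift": self.e_shift,
            "mass": self.mass,
        }
        np.savez(path, header=json.dumps(header),
                 **{k: v for k, v in self.weights.items()})

    @classmethod
    def load(cls, path: str) -> "NNPModel":
        dat = np.load(path, allow_pickle=False)
        header = json.loads(str(dat["header"]))
        af = AFSet(**{k: np.asarray(header["af"][k]) for k in _AF_KEYS},
                   r_cut=header["r_cut"])
        weights = {k: dat[k] for k in dat.files if k != "header"}
        return cls(af, weights, np.asarray(header["g_mean"]),
                   np.asarray(header["g_std"]), header["e_shift"],
                   header["mass"])


# --------------------------------------------------------------------------
# Pair / triplet tables (constant topology for one evaluation)
# --------------------------------------------------------------------------


def _pair_table(config: Configuration, rc: float):
    """Directed pairs (i -> j) within rc and the constant image shift so
    that the minimum-image displacement is pos[j] + shift - pos[i]."""
    nl = neighbor_list(config, rc, 0.0)
    up = nl.pairs()
    if len(up) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros((0, 3))
    pos = config.wrapped()
    box = config.box
    raw = pos[up[:, 1]] - pos[up[:, 0]]
    shift = -box[None, :] * np.floor(raw / box[None, :] + 0.5)
    idx_i = np.concatenate([up[:, 0], up[:, 1]])
    idx_j = np.concatenate([up[:, 1], up[:, 0]])
    shifts = np.concatenate([shift, -shift])
    return idx_i, idx_j, shifts


def _triplet_table(idx_i: np.ndarray):
    """Row indices (p, q) into the directed-pair table forming unordered
    triplets j-i-l around each center i (p < q within the center's group)."""
    order = np.argsort(idx_i, kind="stable")
    ps: List[np.ndarray] = []
    qs: List[np.ndarray] = []
    start = 0
    sorted_i = idx_i[order]
    for stop in np.flatnonzero(np.r_[np.diff(sorted_i) != 0, True]) + 1:
        grp = order[start:stop]
        k = len(grp)
        if k >= 2:
            pi, qi = np.triu_indices(k, 1)
            ps.append(grp[pi])
            qs.append(grp[qi])
        start = stop
    if not ps:
        z = np.zeros(0, dtype=np.int64)
        return z, z
    return np.concatenate(ps), np.concatenate(qs)


# --------------------------------------------------------------------------
# Differentiable forward pass
# --------------------------------------------------------------------------


def _tables(config: Configuration, rc: float):
    """Pair and triplet index tables; cached on the configuration object
    (topology is fixed for a given set of positions)."""
    cache = getattr(config, "_nnp_tables", None)
    if cache is not None and cache[0] == rc:
        return cache[1]
    idx_i, idx_j, shifts = _pair_table(config, rc)
    tp, tq = _triplet_table(idx_i)
    tables = (idx_i, idx_j, shifts, tp, tq)
    try:
        config._nnp_tables = (rc, tables)
    except AttributeError:
        pass
    return tables


def _descriptor_graph(pos: Var, config: Configuration, model: NNPModel,
                      params: Dict[str, Var]):
    """Build the N x 10 descriptor matrix as an autodiff graph.

    Returns ``(G, d)`` where d is the directed pair-displacement Var (the
    virial is -sum d * dU/dd).  All five fingerprints of each body order are
    evaluated in one broadcasted expression.
    """
    n = config.n
    rc = model.af.r_cut
    idx_i, idx_j, shifts, tp, tq = _tables(config, rc + 0.1)
    if len(idx_i) == 0:
        return Var(np.zeros((n, 10))), Var(np.zeros((0, 3)))
    d = ad.gather(pos, idx_j) - ad.gather(pos, idx_i) + Var(shifts)
    r2 = ad.sum_axis(d * d, 1)
    r = r2 ** 0.5
    in_range = (r.v < rc)[:, None]
    rcol = ad.reshape(r, (len(idx_i), 1))
    fc = ad.where_const(in_range,
                        0.5 * (1.0 + ad.vcos(rcol * (math.pi / rc))))
    rs = ad.reshape(params["Rs"], (1, N_TWO_BODY))
    w2 = ad.reshape(params["w2"], (1, N_TWO_BODY))
    dr = rcol - rs
    g2 = ad.scatter_add(ad.vexp(-(dr * dr) / (w2 * w2)) * fc, idx_i, n)
    if len(tp):
        dp = ad.gather(d, tp)
        dq = ad.gather(d, tq)
        rp = ad.gather(rcol, tp)
        rq = ad.gather(rcol, tq)
        fcp = ad.gather(fc, tp)
        fcq = ad.gather(fc, tq)
        cos_t = ad.reshape(ad.sum_axis(dp * dq, 1), (len(tp), 1)) / (rp * rq)
        rsq = rp * rp + rq * rq
        a3 = ad.reshape(params["a3"], (1, N_THREE_BODY))
        s3 = ad.reshape(params["s3"], (1, N_THREE_BODY))
        w3 = ad.reshape(params["w3"], (1, N_THREE_BODY))
        dc = cos_t - a3
        t3 = ad.vexp(-(dc * dc) / (s3 * s3)) * ad.vexp(-rsq / (w3 * w3)) * \
            (fcp * fcq)
        g3 = ad.scatter_add(t3, idx_i[tp], n)
    else:
        g3 = Var(np.zeros((n, N_THREE_BODY)))
    return ad.concat_cols(g2, g3), d


def _forward(config: Configuration, model: NNPModel, need_graph: bool = True):
    """Per-particle energies; with ``need_graph`` returns Vars for autodiff,
    otherwise plain numpy.  Returns ``(e or e Var (N,1), pos Var, d Var)``."""
    params = {k: Var(v) for k, v in model.trainable().items()}
    pos = Var(config.wrapped())
    G, d = _descriptor_graph(pos, config, model, params)
    Gn = (G - Var(model.g_mean[None, :])) / Var(model.g_std[None, :])
    h = ad.vtanh(Gn @ params["W1"] + params["b1"])
    h = ad.vtanh(h @ params["W2"] + params["b2"])
    e = h @ params["W3"] + params["b3"] + Var(np.full((1, 1), model.e_shift))
    if need_graph:
        return e, pos, d
    return e.v[:, 0], None, None


def compute_afs(config: Configuration, model_or_af) -> np.ndarray:
    """N x 10 descriptor matrix (un-normalised)."""
    model = model_or_af if isinstance(model_or_af, NNPModel) \
        else NNPModel(af=model_or_af)
    params = {k: Var(v) for k, v in model.trainable().items()}
    pos = Var(config.wrapped())
    G, _ = _descriptor_graph(pos, config, model, params)
    return G.v


def nnp_evaluate(config: Configuration, model: NNPModel):
    """Total energy, forces and virial of the neural-network potential."""
    if model.af.r_cut > 0.5 * float(np.min(config.box)):
        raise ValueError("descriptor cutoff exceeds half the smallest "
                         "box edge")
    e, pos, d = _forward(config, model)
    U = ad.sum_all(e)
    g_pos, g_d = ad.grad(U, [pos, d])
    F = -g_pos.v
    W = -float(np.sum(d.v * g_d.v))
    return float(U.v), F, W


# --------------------------------------------------------------------------
# Training corpus
# --------------------------------------------------------------------------

#: Liquid state points (density g/cm^3, temperature K) used to build the
#: training corpus.
STATE_POINTS = ((0.92, 221.1), (0.92, 270.9), (1.15, 270.9))


@dataclass
class CorpusEntry:
    config: Configuration
    U: float
    F: np.ndarray
    W: float
    state_point: Tuple[float, float] = (float("nan"), float("nan"))


def build_training_corpus(params: MWParams = MWParams(), seed: int = 0,
                          n_per_state: int = 70, n_particles: int = 1000,
                          state_points=STATE_POINTS,
                          stride_steps: int = 1000, dt: float = 4.0
                          ) -> List[CorpusEntry]:
    """NVT mW sampling at the liquid state points: ``n_per_state``
    decorrelated configurations per point, each stored with its reference
    energy, forces and virial."""
    from .synthetic import generate_liquid

    mw = MWPotential(params)
    corpus: List[CorpusEntry] = []
    for sp_idx, (rho, T) in enumerate(state_points):
        cfg = generate_liquid(n_particles, rho, T, params,
                              seed=seed + 1000 * sp_idx)
        cfg = draw_velocities(cfg, T, seed + 1000 * sp_idx + 1,
                              mass=params.mass)
        state = make_state(cfg, params)
        u_series = []
        for k in range(n_per_state):
            state = integrate_nvt(state, stride_steps, dt, T, damping=1.0,
                                  seed=seed + 1000 * sp_idx + 2 + k,
                                  params=params)
            snap = state.config.copy()
            snap.velocities = None
            U, F, W = mw.evaluate(snap)
            u_series.append(U)
            corpus.append(CorpusEntry(snap, U, F, W, (rho, T)))
        if n_per_state >= 8:
            u = np.asarray(u_series)
            ac = _lag1_autocorr(u)
            if ac > 0.5:
                raise RuntimeError(
                    f"sampling stride too short at (rho={rho}, T={T}): "
                    f"lag-1 energy autocorrelation {ac:.2f}")
    return corpus


def _lag1_autocorr(u: np.ndarray) -> float:
    u = u - u.mean()
    denom = float(np.sum(u * u))
    if denom == 0:
        return 0.0
    return float(np.sum(u[1:] * u[:-1]) / denom)


def split_corpus(corpus: Sequence[CorpusEntry], train_fraction: float,
                 seed: int):
    """Seeded random split by whole configuration."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(corpus))
    n_train = int(round(train_fraction * len(corpus)))
    return ([corpus[i] for i in idx[:n_train]],
            [corpus[i] for i in idx[n_train:]])


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    n_epochs: int = 4000
    train_fraction: float = 0.8
    w_energy: float = 1.0        # per (kcal/mol/particle)^2
    w_force: float = 0.1         # per (kcal/mol/Å)^2 component
    lr_max: float = 1e-3
    lr_min: float = 1e-5
    n_restarts: int = 6          # warm restarts at log-spaced epochs
    hidden: Tuple[int, int] = (25, 25)
    batch_size: int = 8          # configurations per Adam step
    seed: int = 0
    checkpoint_stride: int = 1
    metrics_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class TrainHistory:
    epochs: np.ndarray
    train_loss: np.ndarray
    val_loss: np.ndarray
    delta_eps: np.ndarray    # kcal/mol per particle
    delta_f: np.ndarray      # kcal/mol/nm
    delta_P: np.ndarray      # bar
    restart_epochs: np.ndarray
    lr: np.ndarray


@dataclass
class Checkpoint:
    epoch: int
    params: Dict[str, np.ndarray]


def restart_schedule(n_epochs: int, n_restarts: int) -> np.ndarray:
    """Epochs at which the learning rate warm-restarts, logarithmically
    spaced over the run."""
    if n_restarts < 1 or n_epochs < 4:
        return np.zeros(0, dtype=np.int64)
    first = max(4, n_epochs // (2 ** n_restarts))
    pts = np.unique(np.round(np.geomspace(first, n_epochs,
                                          n_restarts)).astype(np.int64))
    return pts[pts < n_epochs]


def lr_at(epoch: int, cfg: TrainConfig, restarts: np.ndarray) -> float:
    """Cosine annealing from lr_max to lr_min within each restart period."""
    bounds = np.concatenate([[0], restarts, [cfg.n_epochs]])
    k = int(np.searchsorted(bounds, epoch, side="right") - 1)
    lo, hi = bounds[k], bounds[k + 1]
    frac = (epoch - lo) / max(1, hi - lo)
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * \
        (1.0 + math.cos(math.pi * frac))


def _config_loss(entry: CorpusEntry, model: NNPModel, cfg: TrainConfig,
                 params: Dict[str, Var]):
    """Weighted energy + force loss Var of one configuration."""
    n = entry.config.n
    pos = Var(entry.config.wrapped())
    G, d = _descriptor_graph(pos, entry.config, model, params)
    Gn = (G - Var(model.g_mean[None, :])) / Var(model.g_std[None, :])
    h = ad.vtanh(Gn @ params["W1"] + params["b1"])
    h = ad.vtanh(h @ params["W2"] + params["b2"])
    e = h @ params["W3"] + params["b3"] + Var(np.full((1, 1), model.e_shift))
    U = ad.sum_all(e)
    loss = cfg.w_energy * ((U - entry.U) * (1.0 / n)) ** 2.0
    if cfg.w_force > 0:
        gp, = ad.grad(U, [pos])
        F = ad.neg(gp)
        dF = F - Var(entry.F)
        loss = loss + cfg.w_force * ad.sum_all(dF * dF) * (1.0 / (3 * n))
    return loss


def _adam_step(params, grads, m, v, lr, step, b1=0.9, b2=0.999, eps=1e-8):
    for k in params:
        m[k] = b1 * m[k] + (1 - b1) * grads[k]
        v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
        mh = m[k] / (1 - b1 ** step)
        vh = v[k] / (1 - b2 ** step)
        params[k] = params[k] - lr * mh / (np.sqrt(vh) + eps)


def train(corpus: Sequence[CorpusEntry], cfg: TrainConfig = TrainConfig(),
          model: Optional[NNPModel] = None
          ) -> Tuple[NNPModel, TrainHistory, List[Checkpoint]]:
    """Train the potential on a corpus; returns the best model (per the
    selection criterion), the full history, and the retained checkpoints."""
    train_set, test_set = split_corpus(corpus, cfg.train_fraction, cfg.seed)
    if not train_set or not test_set:
        raise ValueError("corpus too small for the requested split")
    if model is None:
        model = NNPModel(weights=init_network(cfg.hidden, cfg.seed))
        # normalisation and energy offset from the training set
        gs = np.concatenate([compute_afs(e.config, model) for e in train_set])
        model.g_mean = gs.mean(axis=0)
        model.g_std = np.maximum(gs.std(axis=0), 1e-8)
        model.e_shift = float(np.mean([e.U / e.config.n for e in train_set]))
    params = {k: v.copy() for k, v in model.trainable().items()}
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    restarts = restart_schedule(cfg.n_epochs, cfg.n_restarts)

    hist = {k: [] for k in ("epochs", "train_loss", "val_loss", "delta_eps",
                            "delta_f", "delta_P", "lr")}
    checkpoints: List[Checkpoint] = []
    step = 0
    rng = np.random.default_rng(cfg.seed + 1)
    bs = max(1, min(cfg.batch_size, len(train_set)))
    for epoch in range(cfg.n_epochs):
        lr = lr_at(epoch, cfg, restarts)
        order = rng.permutation(len(train_set))
        total = 0.0
        for lo in range(0, len(order), bs):
            batch = [train_set[i] for i in order[lo:lo + bs]]
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for entry in batch:
                pvars = {k: Var(v) for k, v in params.items()}
                loss = _config_loss(entry, model, cfg, pvars)
                gs = ad.grad(loss, list(pvars.values()))
                for k, g in zip(pvars.keys(), gs):
                    grads[k] += g.v / len(batch)
                total += float(loss.v) / len(train_set)
            step += 1
            _adam_step(params, grads, m, v2, lr, step)
        if not math.isfinite(total):
            raise RuntimeError(f"training loss diverged at epoch {epoch}")
        model.set_trainable(params)

        if epoch % cfg.metrics_stride == 0 or epoch == cfg.n_epochs - 1:
            val = 0.0
            for entry in test_set:
                pv = {k: Var(v) for k, v in params.items()}
                val += float(_config_loss(entry, model, cfg, pv).v) / \
                    len(test_set)
            em = error_metrics(model, test_set)
            hist["epochs"].append(epoch)
            hist["train_loss"].append(total)
            hist["val_loss"].append(val)
            hist["delta_eps"].append(em.delta_eps)
            hist["delta_f"].append(em.delta_f)
            hist["delta_P"].append(em.delta_P)
            hist["lr"].append(lr)
        if epoch % cfg.checkpoint_stride == 0 or epoch == cfg.n_epochs - 1:
            checkpoints.append(Checkpoint(
                epoch, {k: v.copy() for k, v in params.items()}))

    history = TrainHistory(
        epochs=np.asarray(hist["epochs"]),
        train_loss=np.asarray(hist["train_loss"]),
        val_loss=np.asarray(hist["val_loss"]),
        delta_eps=np.asarray(hist["delta_eps"]),
        delta_f=np.asarray(hist["delta_f"]),
        delta_P=np.asarray(hist["delta_P"]),
        restart_epochs=restarts,
        lr=np.asarray(hist["lr"]))
    best = select_best_model(history, checkpoints)
    final = model.copy()
    final.set_trainable(best.params)
    return final, history, checkpoints


def select_best_model(history: TrainHistory,
                      checkpoints: Sequence[Checkpoint],
                      tail_fraction: float = 0.25) -> Checkpoint:
    """Model-selection criterion: among the checkpoints in the trailing
    (lowest-force-error) part of training, pick a simultaneous local minimum
    of the energy error and of the pressure error; if none exists, the
    checkpoint minimising the worse of the two error ranks."""
    if not checkpoints:
        raise ValueError("no checkpoints retained")
    epochs = np.asarray(history.epochs)
    start_epoch = epochs[-1] - tail_fraction * (epochs[-1] - epochs[0]) \
        if len(epochs) > 1 else epochs[0]
    cand = [c for c in checkpoints if c.epoch >= start_epoch
            and c.epoch in set(epochs.tolist())]
    if not cand:
        cand = list(checkpoints)
    pos = {e: i for i, e in enumerate(epochs.tolist())}
    ide = [pos[c.epoch] for c in cand if c.epoch in pos]
    cand = [c for c in cand if c.epoch in pos]
    de = history.delta_eps
    dp = history.delta_P

    def is_local_min(series, i):
        lo = series[i - 1] if i > 0 else np.inf
        hi = series[i + 1] if i < len(series) - 1 else np.inf
        return series[i] <= lo and series[i] <= hi

    joint = [c for c, i in zip(cand, ide)
             if is_local_min(de, i) and is_local_min(dp, i)]
    if joint:
        # tie-break between several joint minima: normalized error sum
        vals = [de[pos[c.epoch]] / max(de.max(), 1e-300) +
                dp[pos[c.epoch]] / max(dp.max(), 1e-300) for c in joint]
        return joint[int(np.argmin(vals))]
    re = np.argsort(np.argsort([de[i] for i in ide]))
    rp = np.argsort(np.argsort([dp[i] for i in ide]))
    worst = np.maximum(re, rp)
    return cand[int(np.argmin(worst))]


# --------------------------------------------------------------------------
# Error metrics
# --------------------------------------------------------------------------


@dataclass
class ErrorMetrics:
    delta_eps: float             # RMS energy error per particle, kcal/mol
    delta_f: float               # RMS force-component error, kcal/mol/nm
    delta_P: float               # RMS virial-pressure error, bar
    energy_map: Optional[np.ndarray] = None   # |<e>_ref - <e>_model| grid
    map_T: Optional[np.ndarray] = None
    map_rho: Optional[np.ndarray] = None


def error_metrics(model, test_set: Sequence[CorpusEntry]) -> ErrorMetrics:
    """RMS errors of a model against stored reference energies, forces and
    virial pressures.  ``model`` is anything with ``evaluate(config)``."""
    if not test_set:
        raise ValueError("empty test set")
    de2 = df2 = dp2 = 0.0
    nf = 0
    for entry in test_set:
        U, F, W = model.evaluate(entry.config)
        n = entry.config.n
        de2 += ((U - entry.U) / n) ** 2
        df2 += float(np.sum((F - entry.F) ** 2))
        nf += F.size
        vol = entry.config.volume
        dp2 += ((W - entry.W) / 3.0 / vol * KCAL_PER_A3_TO_BAR) ** 2
    return ErrorMetrics(
        delta_eps=math.sqrt(de2 / len(test_set)),
        delta_f=math.sqrt(df2 / nf) * 10.0,   # kcal/mol/Å -> kcal/mol/nm
        delta_P=math.sqrt(dp2 / len(test_set)))


def energy_error_map(model, params: MWParams = MWParams(),
                     temperatures: Optional[np.ndarray] = None,
                     densities: Optional[np.ndarray] = None,
                     n_particles: int = 216, n_steps: int = 4000,
                     sample_stride: int = 50, seed: int = 0,
                     dt: float = 4.0) -> ErrorMetrics:
    """Map of |<e>_mW - <e>_model| over a (T, rho) grid.

    For each state point both potentials are run in the NVT ensemble from
    the same equilibrated liquid and the ensemble-averaged total energy per
    particle is compared.  The default grid spans 6 densities in
    [0.92, 1.22] g/cm^3 and 8 temperatures in [221.1, 373.7] K (48 cells);
    size and run length are configurable because the full map is a
    long-running computation.
    """
    from .synthetic import generate_liquid

    if temperatures is None:
        temperatures = np.linspace(221.1, 373.7, 8)
    if densities is None:
        densities = np.linspace(0.92, 1.22, 6)
    mw = MWPotential(params)
    grid = np.zeros((len(temperatures), len(densities)))
    from .core_md import integrate_nvt_generic
    for a, T in enumerate(temperatures):
        for b, rho in enumerate(densities):
            cfg = generate_liquid(n_particles, rho, T, params,
                                  seed=seed + 101 * a + 7 * b)
            means = []
            for pot_idx, pot in enumerate((mw, model)):
                c = draw_velocities(cfg, T, seed + 11 * a + b + pot_idx,
                                    mass=params.mass)
                if isinstance(pot, MWPotential):
                    st = make_state(c, params)
                    st = integrate_nvt(st, n_steps, dt, T, damping=1.0,
                                       seed=seed + 13 * a + b,
                                       params=params, log_stride=sample_stride)
                    u = st.log[len(st.log) // 2:, 3]
                else:
                    _, _, _, samples = integrate_nvt_generic(
                        c, pot, n_steps, dt, T, damping=1.0,
                        seed=seed + 13 * a + b, sample_stride=sample_stride)
                    u = samples[len(samples) // 2:, 0]
                means.append(float(np.mean(u)) / n_particles)
            grid[a, b] = abs(means[0] - means[1])
    return ErrorMetrics(delta_eps=float("nan"), delta_f=float("nan"),
                        delta_P=float("nan"), energy_map=grid,
                        map_T=np.asarray(temperatures),
                        map_rho=np.asarray(densities))
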