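"""Umbrella sampling of the nucleation barrier with a CNT-shaped bias.

The bias added to the Hamiltonian is the negative of a classical-nucleation-
theory free-energy curve in the largest-cluster size n,

    eta(n) = kB T [ dmu n - (3/2) dmu n_b^{1/3} n^{2/3} ],

whose single adjustable parameter n_b sets the size at which the underlying
CNT barrier would peak; if CNT were exact the biased landscape would be flat
and one simulation would span the whole barrier.  Because n is not a smooth
function of coordinates, sampling uses hybrid Monte Carlo: short NVE segments
accepted with a Metropolis rule on Delta(K + U + eta), with Maxwell-Boltzmann
velocities redrawn after every move, plus occasional isobaric volume moves.
The unbiased free energy is recovered from the visited-n histogram as
beta DG(n) = -ln P_biased(n) - beta eta(n) + const.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .core_md import (KB, KCAL_PER_A3_TO_BAR, MVSQ_TO_KCAL, Configuration,
                      beta_of, draw_velocities, kinetic_energy)
from .structure import OrderParamConfig, largest_cluster_size

# --------------------------------------------------------------------------
# Bias potential
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasSpec:
    """CNT-form bias parameters: the chemical-potential difference per
    particle between crystal and liquid (in units of kB T) and the bias
    critical size.  Defaults are the production values for mW at 218 K and
    ambient pressure."""

    delta_mu: float = 0.57   # kB T units
    n_b: float = 90.0

    def __post_init__(self) -> None:
        if self.delta_mu <= 0:
            raise ValueError("delta_mu must be positive")
        if self.n_b < 1:
            raise ValueError("n_b must be at least 1")


def bias_potential(n: float, spec: BiasSpec, T: float) -> float:
    """eta(n) in kcal/mol; eta(0) = 0, stationary at n = n_b where
    eta(n_b) = -(1/2) dmu n_b kB T."""
    if n < 0:
        raise ValueError("cluster size must be non-negative")
    return KB * T * (spec.delta_mu * n -
                     1.5 * spec.delta_mu * spec.n_b ** (1.0 / 3.0) *
                     float(n) ** (2.0 / 3.0))


def bias_array(n_grid: np.ndarray, spec: BiasSpec, T: float) -> np.ndarray:
    n = np.asarray(n_grid, dtype=float)
    return KB * T * (spec.delta_mu * n -
                     1.5 * spec.delta_mu * spec.n_b ** (1.0 / 3.0) *
                     n ** (2.0 / 3.0))


# --------------------------------------------------------------------------
# Hybrid Monte Carlo and volume moves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HMCConfig:
    """One HMC move = segment_time ps of NVE at timestep dt fs, accepted on
    Delta(K + U + eta); velocities are redrawn from Maxwell--Boltzmann after
    every move.  Volume moves (uniform in ln V, max step max_dlnv) follow
    each HMC move with probability p_volume."""

    T: float = 218.0
    P: float = 1.0                 # bar
    segment_time: float = 0.02     # ps
    dt: float = 4.0                # fs
    p_volume: float = 0.01
    max_dlnv: float = 0.02
    seed: int = 0

    @property
    def segment_steps(self) -> int:
        steps = self.segment_time * 1000.0 / self.dt
        n = int(round(steps))
        if n < 1 or abs(steps - n) > 1e-9:
            raise ValueError("segment length must be a positive multiple "
                             "of the timestep")
        return n


@dataclass
class SamplerState:
    """Current point of the biased Markov chain."""

    config: Configuration
    U: float
    n: int
    eta: float


def _nve_segment(config: Configuration, potential, n_steps: int, dt: float):
    """Velocity-Verlet NVE for an arbitrary evaluate() potential (pure
    Python; segments are a handful of steps)."""
    pos = config.positions.copy()
    vel = config.velocities.copy()
    mass = getattr(potential, "mass", 18.015)
    inv_m = 1.0 / (mass * MVSQ_TO_KCAL)
    work = Configuration(pos, config.box.copy(), vel)
    U, F, W = potential.evaluate(work)
    for _ in range(n_steps):
        vel += 0.5 * dt * F * inv_m
        pos += dt * vel
        work = Configuration(pos, config.box.copy(), vel)
        U, F, W = potential.evaluate(work)
        vel += 0.5 * dt * F * inv_m
    return Configuration(pos, config.box.copy(), vel), U


def order_parameter_fn(op: OrderParamConfig) -> Callable[[Configuration], int]:
    return lambda cfg: largest_cluster_size(cfg, op)


def hmc_move(state: SamplerState, potential, bias: BiasSpec,
             cfg: HMCConfig, op: OrderParamConfig, rng: np.random.Generator
             ) -> Tuple[SamplerState, bool]:
    """One hybrid Monte Carlo move.

    Draw fresh Maxwell--Boltzmann velocities, run an NVE segment, recompute
    the order parameter on the trial frame and accept with
    min(1, exp(-beta [Delta K + Delta U + Delta eta])).  On rejection the
    pre-move configuration is restored exactly.
    """
    T = cfg.T
    mass = getattr(potential, "mass", 18.015)
    start = draw_velocities(state.config, T, int(rng.integers(2 ** 31)),
                            mass=mass)
    K0 = kinetic_energy(start.velocities, mass)
    try:
        trial, U1 = _nve_segment(start, potential, cfg.segment_steps, cfg.dt)
        n1 = largest_cluster_size(trial, op)
    except Exception:
        return state, False
    K1 = kinetic_energy(trial.velocities, mass)
    eta1 = bias_potential(n1, bias, T)
    dE = (K1 - K0) + (U1 - state.U) + (eta1 - state.eta)
    if dE <= 0 or rng.random() < math.exp(-beta_of(T) * dE):
        trial.velocities = None
        return SamplerState(trial, U1, n1, eta1), True
    return state, False


def volume_move(state: SamplerState, potential, bias: BiasSpec,
                cfg: HMCConfig, op: OrderParamConfig,
                rng: np.random.Generator) -> Tuple[SamplerState, bool]:
    """Isobaric move: uniform step in ln V with affine rescaling, accepted
    with min(1, exp(-beta [dU + P dV + d eta] + (N+1) d ln V))."""
    T, P = cfg.T, cfg.P
    old = state.config
    dlnv = rng.uniform(-cfg.max_dlnv, cfg.max_dlnv)
    s = math.exp(dlnv / 3.0)
    trial = Configuration(old.positions * s, old.box * s)
    try:
        U1, _, _ = potential.evaluate(trial)
        n1 = largest_cluster_size(trial, op)
    except Exception:
        return state, False
    eta1 = bias_potential(n1, bias, T)
    V0 = old.volume
    dV = trial.volume - V0
    P_int = P / KCAL_PER_A3_TO_BAR
    arg = -beta_of(T) * ((U1 - state.U) + P_int * dV + (eta1 - state.eta)) \
        + (old.n + 1) * dlnv
    if arg >= 0 or rng.random() < math.exp(arg):
        return SamplerState(trial, U1, n1, eta1), True
    return state, False


# --------------------------------------------------------------------------
# Sampler driver and histogram
# --------------------------------------------------------------------------


@dataclass
class BiasedHistogram:
    counts: np.ndarray         # counts over n = 0..len-1
    total_moves: int
    accept_hmc: float
    accept_volume: float
    n_series: np.ndarray       # n after every move
    bias: Optional[BiasSpec] = None
    T: float = float("nan")
    move_log: Optional[np.ndarray] = None  # move, type(0 hmc/1 vol), n, acc, U, V


class AcceptanceError(RuntimeError):
    pass


def run_cntus(initial: Configuration, potential, bias: BiasSpec,
              cfg: HMCConfig, n_moves: int,
              op: OrderParamConfig = OrderParamConfig(),
              min_acceptance: float = 0.01,
              acceptance_window: int = 500) -> BiasedHistogram:
    """Biased sampling run: HMC moves, each followed with probability
    ``p_volume`` by an isobaric move; records n after every move.

    Aborts with a tuning diagnostic when the HMC acceptance over a trailing
    window falls below ``min_acceptance``.
    """
    rng = np.random.default_rng(cfg.seed)
    U0, _, _ = potential.evaluate(initial)
    n0 = largest_cluster_size(initial, op)
    state = SamplerState(initial.copy(), U0, n0,
                         bias_potential(n0, bias, cfg.T))
    ns = np.zeros(n_moves, dtype=np.int64)
    log = np.zeros((n_moves, 6))
    acc_h = tried_h = acc_v = tried_v = 0
    recent: List[int] = []
    for m in range(n_moves):
        state, ok = hmc_move(state, potential, bias, cfg, op, rng)
        tried_h += 1
        acc_h += ok
        recent.append(int(ok))
        if len(recent) > acceptance_window:
            recent.pop(0)
            if sum(recent) / len(recent) < min_acceptance:
                raise AcceptanceError(
                    f"HMC acceptance below {min_acceptance:.0%} over the "
                    f"last {acceptance_window} moves; reduce the timestep "
                    f"or segment length")
        mtype = 0
        if rng.random() < cfg.p_volume:
            state, okv = volume_move(state, potential, bias, cfg, op, rng)
            tried_v += 1
            acc_v += okv
            mtype = 1
        ns[m] = state.n
        log[m] = (m, mtype, state.n, ok, state.U, state.config.volume)
    counts = np.bincount(ns)
    return BiasedHistogram(
        counts=counts, total_moves=n_moves,
        accept_hmc=acc_h / max(1, tried_h),
        accept_volume=acc_v / max(1, tried_v) if tried_v else float("nan"),
        n_series=ns, bias=bias, T=cfg.T, move_log=log)


# --------------------------------------------------------------------------
# Free-energy reconstruction
# --------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    n: np.ndarray              # cluster-size grid
    beta_dG: np.ndarray        # dimensionless, min set to 0
    interpolated: np.ndarray   # bool mask of filled-in bins
    barrier_height: float      # beta DG*
    n_c: int                   # argmax of the profile


def histogram_from_samples(samples: np.ndarray,
                           n_max: Optional[int] = None) -> np.ndarray:
    samples = np.asarray(samples, dtype=np.int64)
    length = (int(n_max) if n_max is not None else int(samples.max())) + 1
    return np.bincount(samples, minlength=length)


def reconstruct_barrier(hist, bias: Optional[BiasSpec] = None,
                        T: float = float("nan"),
                        beta_eta: Optional[np.ndarray] = None,
                        max_gap: int = 5) -> FreeEnergyProfile:
    """Unbiased free-energy profile beta DG(n) = -ln P(n) - beta eta(n) + C.

    ``hist`` is a BiasedHistogram or a raw count array over n = 0, 1, ....
    The bias can be given as a BiasSpec with a temperature, or directly as a
    dimensionless beta*eta array on the same grid (pass ``beta_eta=0`` array
    or leave all bias arguments unset for unbiased counts).  Empty interior
    bins are linearly interpolated and flagged; a run of more than
    ``max_gap`` empty interior bins means the barrier was not bridged and is
    an error.
    """
    if isinstance(hist, BiasedHistogram):
        counts = hist.counts.astype(float)
        if bias is None:
            bias = hist.bias
        if math.isnan(T):
            T = hist.T
    else:
        counts = np.asarray(hist, dtype=float)
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram needs at least two non-empty bins")
    n = np.arange(len(counts))
    if beta_eta is None:
        if bias is not None:
            if math.isnan(T):
                raise ValueError("temperature required with a BiasSpec bias")
            beta_eta = bias_array(n, bias, T) * beta_of(T)
        else:
            beta_eta = np.zeros(len(counts))
    beta_eta = np.asarray(beta_eta, dtype=float)

    nz = np.flatnonzero(counts > 0)
    lo, hi = nz[0], nz[-1]
    interior = np.arange(lo, hi + 1)
    empty = counts[interior] == 0
    if empty.any():
        # longest run of consecutive empties
        run = 0
        longest = 0
        for e in empty:
            run = run + 1 if e else 0
            longest = max(longest, run)
        if longest > max_gap:
            raise ValueError(
                f"histogram support is disconnected (gap of {longest} bins); "
                f"the barrier region was not bridged")
    with np.errstate(divide="ignore"):
        g = -np.log(counts) - beta_eta
    mask = counts == 0
    gi = g[interior].copy()
    if empty.any():
        ok = ~empty
        gi[empty] = np.interp(interior[empty], interior[ok], gi[ok])
    gi -= gi.min()
    return FreeEnergyProfile(
        n=interior, beta_dG=gi, interpolated=empty,
        barrier_height=float(gi.max()), n_c=int(interior[int(np.argmax(gi))]))
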