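"""Self-generated fixtures: crystals, liquids, and stochastic surrogates.

Everything the pipeline needs is generated here rather than downloaded:

* periodic cubic-diamond and hexagonal-diamond (lonsdaleite, ideal c/a)
  lattices at a requested mass density, optionally perturbed by Gaussian
  noise — the ground truth for the crystallinity classifier;
* equilibrated liquid configurations of the mW model at a state point,
  produced by random insertion followed by Langevin equilibration until the
  potential energy shows no trend;
* one-dimensional birth--death nucleation walks on a prescribed free-energy
  profile, whose mean first passage times are exactly computable by the
  standard recursive summation — the independent oracle for the MFPT fit;
* a Metropolis sampler of a 1-D landscape under a bias, for end-to-end
  validation of the barrier reconstruction without any MD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from . import core_md
from .core_md import (KB, Configuration, MDState, MWParams,
                      density_to_volume, draw_velocities, make_state)

# --------------------------------------------------------------------------
# Diamond lattices
# --------------------------------------------------------------------------

# conventional cubic-diamond cell: fcc + (1/4,1/4,1/4) basis, 8 atoms
_CUBIC_FRAC = np.array([
    [0.00, 0.00, 0.00], [0.00, 0.50, 0.50], [0.50, 0.00, 0.50],
    [0.50, 0.50, 0.00], [0.25, 0.25, 0.25], [0.25, 0.75, 0.75],
    [0.75, 0.25, 0.75], [0.75, 0.75, 0.25],
])

# orthohexagonal lonsdaleite cell (a, sqrt(3) a, c), ideal c/a = sqrt(8/3),
# 8 atoms: two wurtzite-topology hexagonal cells
_HEX_FRAC = np.array([
    [0.0, 1.0 / 3.0, 0.0], [0.0, 1.0 / 3.0, 3.0 / 8.0],
    [0.5, 1.0 / 6.0, 0.5], [0.5, 1.0 / 6.0, 7.0 / 8.0],
    [0.5, 5.0 / 6.0, 0.0], [0.5, 5.0 / 6.0, 3.0 / 8.0],
    [0.0, 2.0 / 3.0, 0.5], [0.0, 2.0 / 3.0, 7.0 / 8.0],
])


@dataclass(frozen=True)
class LatticeSpec:
    polymorph: str = "cubic-diamond"      # or "hexagonal-diamond"
    cells: Tuple[int, int, int] = (3, 3, 3)
    density: float = 0.98                 # g/cm^3
    noise: float = 0.0                    # Gaussian displacement amplitude, Å
    mass: float = MWParams.mass
    seed: int = 0


def nearest_neighbor_distance(spec: LatticeSpec) -> float:
    """Ideal tetrahedral bond length of the lattice at the spec density."""
    vol_per_atom = spec.mass * core_md.MASS_PER_A3_TO_GCC / spec.density
    if spec.polymorph == "cubic-diamond":
        a = (8.0 * vol_per_atom) ** (1.0 / 3.0)
        return math.sqrt(3.0) * a / 4.0
    a = (8.0 * vol_per_atom / math.sqrt(8.0)) ** (1.0 / 3.0)
    return math.sqrt(3.0 / 8.0) * a


def build_lattice(spec: LatticeSpec) -> Configuration:
    """Periodic diamond lattice at the requested density.

    Cubic diamond uses the 8-atom conventional cell; hexagonal diamond the
    8-atom orthohexagonal lonsdaleite cell with the ideal c/a ratio.
    """
    if min(spec.cells) < 2:
        raise ValueError("need at least 2 unit cells per axis for a valid "
                         "periodic crystal")
    vol_per_atom = spec.mass * core_md.MASS_PER_A3_TO_GCC / spec.density
    if spec.polymorph == "cubic-diamond":
        a = (8.0 * vol_per_atom) ** (1.0 / 3.0)
        cell = np.array([a, a, a])
        frac = _CUBIC_FRAC
    elif spec.polymorph == "hexagonal-diamond":
        a = (8.0 * vol_per_atom / math.sqrt(8.0)) ** (1.0 / 3.0)
        cell = np.array([a, math.sqrt(3.0) * a, math.sqrt(8.0 / 3.0) * a])
        frac = _HEX_FRAC
    else:
        raise ValueError(f"unknown polymorph {spec.polymorph!r}")
    if nearest_neighbor_distance(spec) < 1.0:
        raise ValueError("density implies overlapping particles")
    nx, ny, nz = spec.cells
    shifts = np.array([[i, j, k] for i in range(nx)
                       for j in range(ny) for k in range(nz)], dtype=float)
    pos = ((frac[None, :, :] + shifts[:, None, :]).reshape(-1, 3)) * cell
    box = cell * np.array(spec.cells, dtype=float)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        pos = pos + rng.normal(0.0, spec.noise, size=pos.shape)
    return Configuration(pos, box)


# --------------------------------------------------------------------------
# Equilibrated liquid surrogate
# --------------------------------------------------------------------------


class EquilibrationError(RuntimeError):
    pass


def energy_trend_ok(u: np.ndarray) -> bool:
    """True when the linear trend of the trailing half of ``u`` is within two
    standard errors of zero (stationarity test)."""
    tail = u[len(u) // 2:]
    if len(tail) < 8:
        return False
    x = np.arange(len(tail), dtype=float)
    slope, intercept = np.polyfit(x, tail, 1)
    resid = tail - (slope * x + intercept)
    se = np.sqrt(np.sum(resid ** 2) / max(1, len(tail) - 2) /
                 np.sum((x - x.mean()) ** 2))
    return bool(abs(slope) < 2.0 * se)


def random_insertion(n: int, box: np.ndarray, min_dist: float,
                     seed: int, max_attempts: int = 2000) -> np.ndarray:
    """Sequential random insertion with overlap rejection."""
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    placed = 0
    attempts = 0
    while placed < n:
        trial = rng.uniform(0.0, 1.0, 3) * box
        d = pos[:placed] - trial[None, :]
        d -= box[None, :] * np.floor(d / box[None, :] + 0.5)
        if placed == 0 or np.min(np.sum(d * d, axis=1)) > min_dist ** 2:
            pos[placed] = trial
            placed += 1
            attempts = 0
        else:
            attempts += 1
            if attempts > max_attempts:
                min_dist *= 0.95
                attempts = 0
    return pos


def generate_liquid(n: int, rho: float, T: float,
                    params: MWParams = MWParams(), seed: int = 0,
                    dt: float = 4.0, chunk_steps: int = 2000,
                    max_chunks: int = 25) -> Configuration:
    """Equilibrated mW liquid at density ``rho`` (g/cm^3) and temperature
    ``T`` (K): random insertion, then NVT chunks until the potential-energy
    trend test passes."""
    vol = density_to_volume(n, params.mass, rho)
    box = np.full(3, vol ** (1.0 / 3.0))
    pos = random_insertion(n, box, 2.2, seed)
    cfg = Configuration(pos, box)
    cfg = draw_velocities(cfg, T, seed + 1, mass=params.mass)
    state = make_state(cfg, params)
    u_hist: List[float] = []
    for chunk in range(max_chunks):
        state = cm_nvt(state, chunk_steps, dt, T, seed=seed + 2 + chunk,
                       params=params)
        u_hist.append(state.U / n)
        if len(u_hist) >= 8 and energy_trend_ok(np.array(u_hist)):
            out = state.config.copy()
            out.positions = np.mod(out.positions, out.box[None, :])
            out.temperature = T
            return out
    raise EquilibrationError(
        f"liquid at rho={rho} g/cm^3, T={T} K not equilibrated within "
        f"{max_chunks * chunk_steps} steps")


def cm_nvt(state: MDState, n_steps, dt, T, seed, params):
    return core_md.integrate_nvt(state, n_steps, dt, T, damping=0.5,
                                 seed=seed, params=params)


# --------------------------------------------------------------------------
# Birth--death nucleation walks with an exact MFPT oracle
# --------------------------------------------------------------------------


@dataclass
class WalkSpec:
    """1-D continuous-time birth--death surrogate for the largest-cluster
    dynamics: attachment rate k_plus (size-independent), detachment rate
    fixed by detailed balance against the profile beta_G."""

    beta_G: np.ndarray            # free-energy profile over n = 0..n_max
    k_plus: float = 100.0         # attachment rate, ns^-1
    n_traj: int = 100
    seed: int = 0
    t_max: float = np.inf         # ns, safety cap per trajectory


@dataclass
class NSeries:
    """Piecewise-constant order-parameter time series: n(t) = n[i] for
    t in [times[i], times[i+1])."""

    times: np.ndarray   # ns (synthetic walks) or ps (MD analyses)
    n: np.ndarray

    def first_time_at(self, level: int) -> float:
        """Earliest time the series reaches >= level; nan if never."""
        hit = np.flatnonzero(self.n >= level)
        return float(self.times[hit[0]]) if hit.size else float("nan")


def detachment_rates(beta_G: np.ndarray, k_plus: float) -> np.ndarray:
    """k_minus(n) for n = 1..n_max, from detailed balance:
    exp(-G(n-1)) k_plus = exp(-G(n)) k_minus(n)."""
    dG = np.diff(beta_G)   # G(n) - G(n-1)
    return k_plus * np.exp(dG)


def mfpt_exact(beta_G: np.ndarray, k_plus: float, target: int,
               start: int = 0) -> float:
    """Exact mean first passage time (ns) from ``start`` to first reaching
    ``target`` for the birth--death walk, by the standard recursive
    summation: T = sum_{j=start}^{target-1} (1/(k+ pi_j)) sum_{i<=j} pi_i,
    with pi_i the stationary weights and a reflecting boundary at 0."""
    if target <= start:
        return 0.0
    pi = np.exp(-(beta_G - beta_G.min()))
    t = 0.0
    cum = np.cumsum(pi)
    for j in range(start, target):
        t += cum[j] / (k_plus * pi[j])
    return t


@njit(cache=False)
def _gillespie_walk(beta_G, k_plus, n_max, t_max, seed):
    """First time each level 0..n_max is reached (inf if never within t_max).

    The full jump record of a barrier-crossing walk is enormous (the walk
    recrosses the basin ~exp(beta G*) times); only the running-maximum first
    hits are retained, which is exactly what first-passage analysis uses.
    """
    np.random.seed(seed)
    first_hit = np.full(n_max + 1, np.inf)
    first_hit[0] = 0.0
    n = 0
    hi = 0
    t = 0.0
    while hi < n_max and t < t_max:
        # no attachment into an infinitely unfavorable state
        kp = k_plus if math.isfinite(beta_G[n + 1]) else 0.0
        if n > 0 and math.isfinite(beta_G[n]):
            km = k_plus * math.exp(beta_G[n] - beta_G[n - 1])
        else:
            km = 0.0
        ktot = kp + km
        if ktot == 0.0:
            break
        t += -math.log(np.random.random()) / ktot
        if np.random.random() < kp / ktot:
            n += 1
        else:
            n -= 1
        if n > hi:
            hi = n
            first_hit[hi] = t
    return first_hit


def simulate_walks(spec: WalkSpec) -> List[NSeries]:
    """Ensemble of birth--death trajectories, absorbing at the top level.

    Each trajectory is returned as its running-maximum skeleton: the series
    jumps to level m at the first time m is reached.  First passage times
    computed from it are identical to those of the full jump record.
    """
    if spec.k_plus <= 0:
        raise ValueError("k_plus must be positive")
    n_max = len(spec.beta_G) - 1
    out = []
    bg = np.ascontiguousarray(spec.beta_G, dtype=np.float64)
    for k in range(spec.n_traj):
        fh = _gillespie_walk(bg, spec.k_plus, n_max, spec.t_max,
                             (spec.seed + 7919 * k) & 0x7FFFFFFF)
        ok = np.isfinite(fh)
        levels = np.flatnonzero(ok)
        out.append(NSeries(fh[ok], levels.astype(np.int64)))
    return out


# --------------------------------------------------------------------------
# 1-D landscape Metropolis sampler (sampler-validation surrogate)
# --------------------------------------------------------------------------


@njit(cache=False)
def _metropolis_1d(total_beta_g, n_moves, seed):
    np.random.seed(seed)
    m = len(total_beta_g)
    samples = np.empty(n_moves, dtype=np.int64)
    x = 0
    for i in range(n_moves):
        prop = x + 1 if np.random.random() < 0.5 else x - 1
        if 0 <= prop < m:
            dg = total_beta_g[prop] - total_beta_g[x]
            if dg <= 0.0 or np.random.random() < math.exp(-dg):
                x = prop
        samples[i] = x
    return samples


def sample_landscape_1d(beta_G: np.ndarray,
                        beta_eta: Optional[np.ndarray] = None,
                        n_moves: int = 100000, seed: int = 0) -> np.ndarray:
    """Metropolis samples of P(n) ∝ exp(-beta_G(n) - beta_eta(n)) on the
    integer grid 0..len(beta_G)-1, with ±1 proposals and reflecting edges."""
    g = np.asarray(beta_G, dtype=np.float64)
    if beta_eta is not None:
        g = g + np.asarray(beta_eta, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("profile must be finite")
    return _metropolis_1d(g, int(n_moves), int(seed) & 0x7FFFFFFF)


def cnt_profile(n_max_grid: int, beta_dmu: float, n_barrier: float
                ) -> np.ndarray:
    """Classical-nucleation-theory profile beta G(n) = -dmu n + (3/2) dmu
    n_b^{1/3} n^{2/3}, with its maximum (height dmu n_b / 2) at n_barrier."""
    n = np.arange(n_max_grid + 1, dtype=float)
    return -beta_dmu * n + 1.5 * beta_dmu * n_barrier ** (1.0 / 3.0) * \
        n ** (2.0 / 3.0)


# --------------------------------------------------------------------------
# Harmonic toy system (for sampler validation)
# --------------------------------------------------------------------------


class HarmonicTrap:
    """Independent 3-D harmonic wells, one per particle: U = k/2 sum r_i^2.

    A toy potential with an exactly known canonical distribution, used to
    validate the hybrid Monte Carlo machinery.  Implements the same
    ``evaluate`` contract as the mW and NNP evaluators.
    """

    def __init__(self, k: float = 1.0, mass: float = MWParams.mass):
        self.k = k
        self.mass = mass
        self.cutoff = 0.0

    def evaluate(self, config: Configuration):
        # harmonic wells anchored at the box center
        d = config.positions - 0.5 * config.box[None, :]
        U = 0.5 * self.k * float(np.sum(d * d))
        F = -self.k * d
        W = float(np.sum(d * F))
        return U, F, W
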