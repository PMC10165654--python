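"""Molecular dynamics core for the mW monatomic water model.

The mW model represents a water molecule as a single particle interacting
through a Stillinger--Weber-form potential: a short-ranged pair term plus a
three-body term that penalises deviations from the tetrahedral angle
(cos θ0 = -1/3).  This module evaluates energies, forces and the virial
under orthorhombic periodic boundary conditions and integrates the equations
of motion in the NVE, NVT (BAOAB Langevin) and NPT (Langevin-piston)
ensembles.

Unit system: kcal/mol (energy), Å (length), fs (time inside integrators,
ps in reported elapsed time), K (temperature), bar (pressure), g/mol (mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# Physical constants and unit conversions
# --------------------------------------------------------------------------

KB = 0.0019872041  # Boltzmann constant, kcal mol^-1 K^-1
AVOGADRO = 6.02214076e23
#: kcal/mol obtained from  m [g/mol] * v^2 [Å^2/fs^2]
MVSQ_TO_KCAL = 1.0e7 / 4184.0
#: bar obtained from 1 kcal mol^-1 Å^-3
KCAL_PER_A3_TO_BAR = 4184.0 / AVOGADRO * 1.0e30 / 1.0e5
#: g/cm^3 obtained from  (N * m [g/mol]) / V [Å^3]
MASS_PER_A3_TO_GCC = 1.0e24 / AVOGADRO


def density_to_volume(n: int, mass: float, rho: float) -> float:
    """Volume (Å^3) of ``n`` particles of ``mass`` g/mol at ``rho`` g/cm^3."""
    return n * mass * MASS_PER_A3_TO_GCC / rho


def volume_to_density(n: int, mass: float, volume: float) -> float:
    """Mass density (g/cm^3) of ``n`` particles in ``volume`` Å^3."""
    return n * mass * MASS_PER_A3_TO_GCC / volume


def beta_of(T: float) -> float:
    """Inverse thermal energy 1/(kB T) in mol/kcal."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB * T)


# --------------------------------------------------------------------------
# Model parameters and state containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MWParams:
    """Stillinger--Weber parameter set; defaults are the published mW water
    constants (Molinero & Moore's monatomic water model)."""

    epsilon: float = 6.189          # kcal/mol
    sigma: float = 2.3925           # Å
    A: float = 7.049556277
    B: float = 0.6022245584
    p: float = 4.0
    q: float = 0.0
    a: float = 1.8                  # cutoff multiplier: r_c = a * sigma
    gamma: float = 1.2
    lam: float = 23.15
    cos_theta0: float = -1.0 / 3.0
    mass: float = 18.015            # g/mol

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.a <= 1:
            raise ValueError("cutoff multiplier a must exceed 1")

    @property
    def cutoff(self) -> float:
        return self.a * self.sigma


@dataclass
class Configuration:
    """Particle positions in an orthorhombic periodic box with a state point.

    Positions may be stored unwrapped; the minimum-image convention is applied
    wherever distances are computed.  ``velocities`` are in Å/fs.
    """

    positions: np.ndarray
    box: np.ndarray
    velocities: Optional[np.ndarray] = None
    temperature: Optional[float] = None
    pressure: Optional[float] = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be N x 3")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.velocities is not None:
            self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def density(self, mass: float = MWParams.mass) -> float:
        return volume_to_density(self.n, mass, self.volume)

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into [0, L) along each axis."""
        return np.mod(self.positions, self.box[None, :])

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.box.copy(),
            None if self.velocities is None else self.velocities.copy(),
            self.temperature, self.pressure,
        )


@dataclass
class Trajectory:
    """Strided record of an MD run; positions are unwrapped."""

    times: np.ndarray       # ps
    positions: np.ndarray   # frames x N x 3, Å
    boxes: np.ndarray       # frames x 3, Å

    def __len__(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> Configuration:
        return Configuration(self.positions[i].copy(), self.boxes[i].copy())


@dataclass
class MDState:
    """Instantaneous thermodynamic state of an MD run."""

    config: Configuration
    U: float = 0.0   # potential energy, kcal/mol
    K: float = 0.0   # kinetic energy, kcal/mol
    W: float = 0.0   # virial  sum_ij r_ij . f_ij, kcal/mol
    t: float = 0.0   # elapsed time, ps
    trajectory: Optional[Trajectory] = None
    log: Optional[np.ndarray] = None  # columns: t/ps, T/K, P/bar, U, V

    @property
    def kinetic_temperature(self) -> float:
        n = self.config.n
        return 2.0 * self.K / (3.0 * n * KB)

    @property
    def pressure(self) -> float:
        """Instantaneous virial pressure in bar."""
        v = self.config.volume
        return (2.0 * self.K / 3.0 + self.W / 3.0) / v * KCAL_PER_A3_TO_BAR


class IntegrationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Scalar potential terms (shared by the jitted kernels and the public API)
# --------------------------------------------------------------------------


@njit(cache=False)
def _phi2(r, A, B, p, q, eps, sig, rc):
    if r >= rc:
        return 0.0
    sr = sig / r
    return A * eps * (B * sr ** p - sr ** q) * math.exp(sig / (r - rc))


@njit(cache=False)
def _dphi2(r, A, B, p, q, eps, sig, rc):
    """d phi2 / d r for r < rc."""
    if r >= rc:
        return 0.0
    sr = sig / r
    e = math.exp(sig / (r - rc))
    poly = B * sr ** p - sr ** q
    dpoly = (-p * B * sr ** p + q * sr ** q) / r
    return A * eps * e * (dpoly - poly * sig / (r - rc) ** 2)


@njit(cache=False)
def _h3(rij, rik, cos_t, lam, eps, gam, sig, rc, c0):
    if rij >= rc or rik >= rc:
        return 0.0
    d = cos_t - c0
    return lam * eps * d * d * math.exp(gam * sig / (rij - rc)) * math.exp(
        gam * sig / (rik - rc))


def pair_energy(r: float, params: MWParams = MWParams()) -> float:
    """Stillinger--Weber two-body energy at separation ``r`` (Å)."""
    if r <= 0:
        raise ValueError("separation must be positive")
    return _phi2(r, params.A, params.B, params.p, params.q,
                 params.epsilon, params.sigma, params.cutoff)


def triplet_energy(r_ij: float, r_ik: float, cos_theta: float,
                   params: MWParams = MWParams()) -> float:
    """Three-body energy of a triplet with ``i`` central; zero beyond cutoff."""
    if r_ij <= 0 or r_ik <= 0:
        raise ValueError("separations must be positive")
    return _h3(r_ij, r_ik, cos_theta, params.lam, params.epsilon,
               params.gamma, params.sigma, params.cutoff, params.cos_theta0)


# --------------------------------------------------------------------------
# Neighbor list
# --------------------------------------------------------------------------

_MAX_NEIGH = 96


@njit(cache=False)
def _build_nlist(pos, box, rlist, maxn):
    n = pos.shape[0]
    idx = np.full((n, maxn), -1, dtype=np.int64)
    cnt = np.zeros(n, dtype=np.int64)
    r2 = rlist * rlist
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * math.floor(dx / box[0] + 0.5)
            dy -= box[1] * math.floor(dy / box[1] + 0.5)
            dz -= box[2] * math.floor(dz / box[2] + 0.5)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < r2:
                idx[i, cnt[i]] = j
                idx[j, cnt[j]] = i
                cnt[i] += 1
                cnt[j] += 1
    return idx, cnt


@dataclass
class NeighborList:
    """Symmetric Verlet list with a skin; valid while no particle has moved
    more than skin/2 since the list was built."""

    idx: np.ndarray
    cnt: np.ndarray
    cutoff: float
    skin: float
    ref_positions: np.ndarray

    def pairs(self) -> np.ndarray:
        """Unique (i, j) pairs with i < j."""
        out = []
        for i in range(self.idx.shape[0]):
            for k in range(self.cnt[i]):
                j = self.idx[i, k]
                if j > i:
                    out.append((i, j))
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    def needs_rebuild(self, positions: np.ndarray) -> bool:
        disp = positions - self.ref_positions
        d2 = np.max(np.sum(disp * disp, axis=1))
        return bool(d2 > (0.5 * self.skin) ** 2)


def neighbor_list(config: Configuration, cutoff: float,
                  skin: float = 0.0) -> NeighborList:
    """All pairs with minimum-image distance < cutoff + skin."""
    if cutoff > 0.5 * float(np.min(config.box)):
        raise ValueError("cutoff exceeds half the smallest box edge")
    pos = config.positions
    idx, cnt = _build_nlist(pos, config.box, cutoff + skin, _MAX_NEIGH)
    if np.max(cnt) >= _MAX_NEIGH:
        raise RuntimeError("neighbor overflow; density too high for list size")
    return NeighborList(idx, cnt, cutoff, skin, pos.copy())


# --------------------------------------------------------------------------
# Force kernel
# --------------------------------------------------------------------------


@njit(cache=False)
def _mw_forces(pos, box, idx, cnt, A, B, p, q, eps, sig, rc, gam, lam, c0):
    """Energy, forces and virial of the mW potential from a neighbor list.

    Pairs are counted once (j > i); each three-body term is counted once with
    its central particle.  Virial is sum over interactions of f . r with the
    displacement taken from the central/first particle.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    U = 0.0
    W = 0.0
    # scratch for the neighbors of one particle
    dxs = np.empty(_MAX_NEIGH)
    dys = np.empty(_MAX_NEIGH)
    dzs = np.empty(_MAX_NEIGH)
    rs = np.empty(_MAX_NEIGH)
    gs = np.empty(_MAX_NEIGH)
    dgs = np.empty(_MAX_NEIGH)
    js = np.empty(_MAX_NEIGH, dtype=np.int64)
    for i in range(n):
        m = 0
        for k in range(cnt[i]):
            j = idx[i, k]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * math.floor(dx / box[0] + 0.5)
            dy -= box[1] * math.floor(dy / box[1] + 0.5)
            dz -= box[2] * math.floor(dz / box[2] + 0.5)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r >= rc:
                continue
            dxs[m] = dx
            dys[m] = dy
            dzs[m] = dz
            rs[m] = r
            g = math.exp(gam * sig / (r - rc))
            gs[m] = g
            dgs[m] = -g * gam * sig / ((r - rc) * (r - rc))
            js[m] = j
            m += 1
            # pair term, counted once
            if j > i:
                U += _phi2(r, A, B, p, q, eps, sig, rc)
                dp = _dphi2(r, A, B, p, q, eps, sig, rc)
                fx = dp * dx / r
                fy = dp * dy / r
                fz = dp * dz / r
                # force on i is +dp*dhat, on j is -dp*dhat
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
                W -= dp * r
        # three-body terms centered on i
        for aj in range(m):
            ru = rs[aj]
            ux, uy, uz = dxs[aj], dys[aj], dzs[aj]
            for ak in range(aj + 1, m):
                rv = rs[ak]
                vx, vy, vz = dxs[ak], dys[ak], dzs[ak]
                c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
                d = c - c0
                pref = lam * eps
                h = pref * d * d * gs[aj] * gs[ak]
                U += h
                # gradient wrt u (displacement to j)
                cu = 2.0 * pref * d * gs[aj] * gs[ak]
                hu = pref * d * d * dgs[aj] * gs[ak]
                hv = pref * d * d * gs[aj] * dgs[ak]
                # dc/du = v/(ru rv) - c u / ru^2
                gux = cu * (vx / (ru * rv) - c * ux / (ru * ru)) + hu * ux / ru
                guy = cu * (vy / (ru * rv) - c * uy / (ru * ru)) + hu * uy / ru
                guz = cu * (vz / (ru * rv) - c * uz / (ru * ru)) + hu * uz / ru
                gvx = cu * (ux / (ru * rv) - c * vx / (rv * rv)) + hv * vx / rv
                gvy = cu * (uy / (ru * rv) - c * vy / (rv * rv)) + hv * vy / rv
                gvz = cu * (uz / (ru * rv) - c * vz / (rv * rv)) + hv * vz / rv
                j = js[aj]
                k2 = js[ak]
                F[j, 0] -= gux
                F[j, 1] -= guy
                F[j, 2] -= guz
                F[k2, 0] -= gvx
                F[k2, 1] -= gvy
                F[k2, 2] -= gvz
                F[i, 0] += gux + gvx
                F[i, 1] += guy + gvy
                F[i, 2] += guz + gvz
                W -= gux * ux + guy * uy + guz * uz
                W -= gvx * vx + gvy * vy + gvz * vz
    return U, F, W


def evaluate(config: Configuration, params: MWParams = MWParams()):
    """Total mW energy, forces (-grad U) and virial of a configuration.

    Returns ``(U, forces, W)`` with the virial defined so that the pressure is
    ``(2K/3 + W/3)/V``.
    """
    rc = params.cutoff
    if 2.0 * rc > float(np.min(config.box)):
        raise ValueError("box edge smaller than twice the cutoff")
    nl = neighbor_list(config, rc, 0.0)
    U, F, W = _mw_forces(config.positions, config.box, nl.idx, nl.cnt,
                         params.A, params.B, params.p, params.q,
                         params.epsilon, params.sigma, rc,
                         params.gamma, params.lam, params.cos_theta0)
    if not np.isfinite(U) or not np.all(np.isfinite(F)):
        raise IntegrationError("non-finite energy or force (overlap?)")
    return U, F, W


class MWPotential:
    """mW evaluator with the generic ``evaluate(config)`` interface shared by
    the neural-network potential."""

    def __init__(self, params: MWParams = MWParams()):
        self.params = params
        self.cutoff = params.cutoff
        self.mass = params.mass

    def evaluate(self, config: Configuration):
        return evaluate(config, self.params)


# --------------------------------------------------------------------------
# Velocities and thermodynamic helpers
# --------------------------------------------------------------------------


def draw_velocities(config: Configuration, T: float, seed: int,
                    mass: float = MWParams.mass,
                    zero_momentum: bool = False) -> Configuration:
    """Maxwell--Boltzmann velocities: each component ~ N(0, kB T / m)."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    rng = np.random.default_rng(seed)
    sig = math.sqrt(KB * T / (mass * MVSQ_TO_KCAL)) if T > 0 else 0.0
    v = rng.normal(0.0, sig, size=config.positions.shape) if sig > 0 else \
        np.zeros_like(config.positions)
    if zero_momentum and config.n > 0:
        v -= v.mean(axis=0, keepdims=True)
    out = config.copy()
    out.velocities = v
    out.temperature = T
    return out


def kinetic_energy(velocities: np.ndarray, mass: float = MWParams.mass) -> float:
    return 0.5 * mass * MVSQ_TO_KCAL * float(np.sum(velocities ** 2))


def reduced_to_kelvin(t_star: float, params: MWParams = MWParams()) -> float:
    """Convert a temperature in mW internal units (epsilon = 1) to kelvin."""
    if t_star < 0:
        raise ValueError("reduced temperature must be non-negative")
    return t_star * params.epsilon / KB


# --------------------------------------------------------------------------
# Integrators (single jitted driver: NVE / BAOAB-Langevin NVT / Langevin-piston NPT)
# --------------------------------------------------------------------------


@njit(cache=False)
def _run_md(pos, vel, box, nsteps, dt, mode, Tset, gamma_fs, Pset_int,
            piston_w, piston_gamma_fs, seed,
            A, B, p, q, eps, sig, rc, gam, lam, c0, mass,
            rlist_skin, rec_stride, log_stride):
    """BAOAB integration; mode 0 = NVE, 1 = NVT, 2 = NPT.

    gamma_fs and piston_gamma_fs are friction rates in 1/fs; Pset_int is the
    external pressure in kcal/mol/Å^3.  Positions evolve unwrapped; a wrapped
    copy is used to (re)build the neighbor list whenever any particle has
    moved more than skin/2.  Returns status, U, K, W, t_fs, volume log and the
    strided records.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    inv_m = 1.0 / (mass * MVSQ_TO_KCAL)
    rlist = rc + rlist_skin

    wrapped = _wrap_nb(pos, box)
    idx, cnt = _build_nlist(wrapped, box, rlist, _MAX_NEIGH)
    ref = pos.copy()
    U, F, W = _mw_forces(wrapped, box, idx, cnt, A, B, p, q, eps, sig, rc,
                         gam, lam, c0)

    c1 = math.exp(-gamma_fs * dt) if mode >= 1 else 1.0
    cnoise = math.sqrt(max(0.0, (1.0 - c1 * c1)) * KB * Tset * inv_m)

    vol = box[0] * box[1] * box[2]
    vdot = 0.0
    pc1 = math.exp(-piston_gamma_fs * dt)
    pnoise = math.sqrt(max(0.0, (1.0 - pc1 * pc1)) * KB * Tset / piston_w) \
        if piston_w > 0 else 0.0

    nrec = 0
    if rec_stride > 0:
        nrec = nsteps // rec_stride + 1
    rec_pos = np.zeros((max(nrec, 1), n, 3))
    rec_box = np.zeros((max(nrec, 1), 3))
    rec_t = np.zeros(max(nrec, 1))
    nlog = 0
    if log_stride > 0:
        nlog = nsteps // log_stride + 1
    logrec = np.zeros((max(nlog, 1), 5))

    irec = 0
    ilog = 0
    status = 0
    t = 0.0
    for step in range(nsteps):
        if rec_stride > 0 and step % rec_stride == 0:
            rec_pos[irec] = pos
            rec_box[irec] = box
            rec_t[irec] = t
            irec += 1
        if log_stride > 0 and step % log_stride == 0:
            K = 0.0
            for i in range(n):
                K += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            K *= 0.5 * mass * MVSQ_TO_KCAL
            Tinst = 2.0 * K / (3.0 * n * KB)
            Pinst = (2.0 * K / 3.0 + W / 3.0) / vol
            logrec[ilog, 0] = t
            logrec[ilog, 1] = Tinst
            logrec[ilog, 2] = Pinst * KCAL_PER_A3_TO_BAR
            logrec[ilog, 3] = U
            logrec[ilog, 4] = vol
            ilog += 1

        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * F[i, d] * inv_m
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        # O: Ornstein-Uhlenbeck (identity in NVE)
        if mode >= 1:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + cnoise * np.random.normal()
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]

        # neighbor-list maintenance (Euclidean displacement vs skin/2)
        maxdisp2 = 0.0
        for i in range(n):
            dd = 0.0
            for d in range(3):
                t1 = pos[i, d] - ref[i, d]
                dd += t1 * t1
            if dd > maxdisp2:
                maxdisp2 = dd
        if maxdisp2 > 0.25 * rlist_skin * rlist_skin:
            wrapped = _wrap_nb(pos, box)
            idx, cnt = _build_nlist(wrapped, box, rlist, _MAX_NEIGH)
            for i in range(n):
                if cnt[i] >= _MAX_NEIGH:
                    return 2, U, 0.0, W, t, pos, vel, box, rec_pos, rec_box, rec_t, logrec, irec, ilog
            ref = pos.copy()
        wrapped = _wrap_nb(pos, box)
        U, F, W = _mw_forces(wrapped, box, idx, cnt, A, B, p, q, eps, sig, rc,
                             gam, lam, c0)
        if not math.isfinite(U):
            return 1, U, 0.0, W, t, pos, vel, box, rec_pos, rec_box, rec_t, logrec, irec, ilog
        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * F[i, d] * inv_m

        # Langevin piston on the volume (isotropic, affine rescale)
        if mode == 2 and piston_w > 0:
            K = 0.0
            for i in range(n):
                K += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            K *= 0.5 * mass * MVSQ_TO_KCAL
            Pinst = (2.0 * K / 3.0 + W / 3.0) / vol
            vdot += dt * (Pinst - Pset_int) / piston_w
            vdot = pc1 * vdot + pnoise * np.random.normal()
            newvol = vol + dt * vdot
            if newvol <= 0.1 * vol:
                # reject pathological contraction, damp the piston
                vdot = 0.0
            else:
                s = (newvol / vol) ** (1.0 / 3.0)
                for i in range(n):
                    for d in range(3):
                        pos[i, d] *= s
                        ref[i, d] *= s
                for d in range(3):
                    box[d] *= s
                vol = newvol
        t += dt
    return status, U, _kinetic_nb(vel, mass), W, t, pos, vel, box, \
        rec_pos, rec_box, rec_t, logrec, irec, ilog


@njit(cache=False)
def _wrap_nb(pos, box):
    n = pos.shape[0]
    out = np.empty_like(pos)
    for i in range(n):
        for d in range(3):
            out[i, d] = pos[i, d] - box[d] * math.floor(pos[i, d] / box[d])
    return out


@njit(cache=False)
def _kinetic_nb(vel, mass):
    K = 0.0
    n = vel.shape[0]
    for i in range(n):
        K += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    return 0.5 * mass * MVSQ_TO_KCAL * K


def _integrate(state: MDState, n_steps: int, dt: float, mode: int,
               T: float, damping: float, P: float,
               piston_period: float, piston_damping: float, seed: int,
               params: MWParams, skin: float, record_stride: int,
               log_stride: int, piston_modulus: float = 20000.0) -> MDState:
    cfg = state.config
    if cfg.velocities is None:
        raise ValueError("velocities required; call draw_velocities first")
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos = cfg.positions.copy()
    vel = cfg.velocities.copy()
    box = cfg.box.copy()
    gamma_fs = 0.0 if (damping is None or damping <= 0 or
                       math.isinf(damping)) else 1.0 / (damping * 1000.0)
    if mode >= 1 and gamma_fs == 0.0:
        mode_eff = 0  # infinite damping time: NVE limit
    else:
        mode_eff = mode
    if mode == 2:
        mode_eff = 2
    piston_w = 0.0
    piston_gamma_fs = 0.0
    Pint = 0.0
    if mode == 2:
        vol = float(np.prod(box))
        omega = 2.0 * math.pi / (piston_period * 1000.0)  # 1/fs
        if math.isfinite(piston_period):
            # piston mass from the oscillation period at an assumed bulk
            # modulus (dP/dV = -K/V): W = K / (V omega^2)
            k_int = piston_modulus / KCAL_PER_A3_TO_BAR
            piston_w = k_int / (vol * omega * omega)
        else:
            piston_w = 0.0
        piston_gamma_fs = 1.0 / (piston_damping * 1000.0)
        Pint = P / KCAL_PER_A3_TO_BAR
        if gamma_fs == 0.0:
            # NPT needs a thermostat; keep the particle Langevin on
            gamma_fs = 1.0 / (1000.0)
    out = _run_md(pos, vel, box, int(n_steps), float(dt), mode_eff,
                  float(T), gamma_fs, Pint, piston_w, piston_gamma_fs,
                  int(seed) & 0x7FFFFFFF,
                  params.A, params.B, params.p, params.q, params.epsilon,
                  params.sigma, params.cutoff, params.gamma, params.lam,
                  params.cos_theta0, params.mass,
                  skin, int(record_stride), int(log_stride))
    (status, U, K, W, t_fs, pos, vel, box,
     rec_pos, rec_box, rec_t, logrec, irec, ilog) = out
    if status == 1:
        raise IntegrationError("non-finite energy during integration "
                               "(overlapping particles?)")
    if status == 2:
        raise IntegrationError("neighbor-list overflow during integration")
    new_cfg = Configuration(pos, box, vel, T if mode >= 1 else cfg.temperature,
                            P if mode == 2 else cfg.pressure)
    traj = None
    if record_stride > 0 and irec > 0:
        traj = Trajectory(rec_t[:irec] / 1000.0, rec_pos[:irec].copy(),
                          rec_box[:irec].copy())
    log = None
    if log_stride > 0 and ilog > 0:
        log = logrec[:ilog].copy()
        log[:, 0] /= 1000.0
    return MDState(new_cfg, U=float(U), K=float(K), W=float(W),
                   t=state.t + t_fs / 1000.0, trajectory=traj, log=log)


def integrate_nve(state: MDState, n_steps: int, dt: float = 4.0, *,
                  params: MWParams = MWParams(), skin: float = 1.0,
                  record_stride: int = 0, log_stride: int = 0) -> MDState:
    """Velocity-Verlet NVE propagation for ``n_steps`` steps of ``dt`` fs."""
    return _integrate(state, n_steps, dt, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0,
                      params, skin, record_stride, log_stride)


def integrate_nvt(state: MDState, n_steps: int, dt: float, T: float,
                  damping: float = 1.0, seed: int = 0, *,
                  params: MWParams = MWParams(), skin: float = 1.0,
                  record_stride: int = 0, log_stride: int = 0) -> MDState:
    """BAOAB Langevin thermostat at temperature ``T``; ``damping`` in ps.

    An infinite (or non-positive) damping time degenerates to NVE.
    """
    return _integrate(state, n_steps, dt, 1, T, damping, 0.0, 0.0, 0.0, seed,
                      params, skin, record_stride, log_stride)


def integrate_npt(state: MDState, n_steps: int, dt: float, T: float, P: float,
                  piston_period: float = 0.5, piston_damping: float = 0.2,
                  damping: float = 1.0, seed: int = 0, *,
                  params: MWParams = MWParams(), skin: float = 1.0,
                  record_stride: int = 0, log_stride: int = 0,
                  piston_modulus: float = 20000.0) -> MDState:
    """Langevin-piston NPT: Langevin particles plus stochastic isotropic
    volume dynamics targeting pressure ``P`` (bar).

    ``piston_period`` and ``piston_damping`` are in ps; an infinite period
    freezes the volume (NVT limit).  ``piston_modulus`` (bar) is the assumed
    isothermal bulk modulus that, together with the period, sets the piston
    mass — ~2e4 bar for a dense molecular liquid, ~the pressure itself for a
    dilute gas."""
    return _integrate(state, n_steps, dt, 2, T, damping, P,
                      piston_period, piston_damping, seed,
                      params, skin, record_stride, log_stride,
                      piston_modulus)


def make_state(config: Configuration, params: MWParams = MWParams()) -> MDState:
    """MDState with energies evaluated for the given configuration."""
    U, _, W = evaluate(config, params)
    K = kinetic_energy(config.velocities, params.mass) \
        if config.velocities is not None else 0.0
    return MDState(config.copy(), U=U, K=K, W=W, t=0.0)


# --------------------------------------------------------------------------
# Generic integrators for arbitrary evaluate() potentials (pure Python;
# used by hybrid Monte Carlo segments and by non-mW potentials such as the
# neural-network model, where the force call dominates anyway)
# --------------------------------------------------------------------------


def integrate_nve_generic(config: Configuration, potential, n_steps: int,
                          dt: float = 4.0):
    """Velocity-Verlet NVE with any ``evaluate(config) -> (U, F, W)``.

    Returns ``(config, U, W)`` with updated positions/velocities.
    """
    if config.velocities is None:
        raise ValueError("velocities required")
    pos = config.positions.copy()
    vel = config.velocities.copy()
    mass = getattr(potential, "mass", MWParams.mass)
    inv_m = 1.0 / (mass * MVSQ_TO_KCAL)
    work = Configuration(pos, config.box.copy(), vel)
    U, F, W = potential.evaluate(work)
    for _ in range(int(n_steps)):
        vel += 0.5 * dt * F * inv_m
        pos += dt * vel
        work = Configuration(pos, config.box.copy(), vel)
        U, F, W = potential.evaluate(work)
        vel += 0.5 * dt * F * inv_m
    return Configuration(pos, config.box.copy(), vel,
                         config.temperature, config.pressure), U, W


def integrate_nvt_generic(config: Configuration, potential, n_steps: int,
                          dt: float, T: float, damping: float = 1.0,
                          seed: int = 0, sample_stride: int = 0):
    """BAOAB Langevin with any ``evaluate()`` potential.

    With ``sample_stride > 0`` also returns per-sample (U, W) rows for
    ensemble averages.  Returns ``(config, U, W, samples)``.
    """
    if config.velocities is None:
        raise ValueError("velocities required")
    rng = np.random.default_rng(seed)
    pos = config.positions.copy()
    vel = config.velocities.copy()
    mass = getattr(potential, "mass", MWParams.mass)
    inv_m = 1.0 / (mass * MVSQ_TO_KCAL)
    gamma_fs = 0.0 if damping <= 0 or math.isinf(damping) \
        else 1.0 / (damping * 1000.0)
    c1 = math.exp(-gamma_fs * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1) * KB * T * inv_m)
    work = Configuration(pos, config.box.copy(), vel)
    U, F, W = potential.evaluate(work)
    samples = []
    for step in range(int(n_steps)):
        vel += 0.5 * dt * F * inv_m
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        pos += 0.5 * dt * vel
        work = Configuration(pos, config.box.copy(), vel)
        U, F, W = potential.evaluate(work)
        vel += 0.5 * dt * F * inv_m
        if sample_stride and (step + 1) % sample_stride == 0:
            samples.append((U, W))
    return (Configuration(pos, config.box.copy(), vel, T, config.pressure),
            U, W, np.asarray(samples))
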