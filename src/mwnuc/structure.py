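"""Structural and dynamical observables, and the crystallinity order parameter.

The nucleation order parameter used throughout the package is ``n``, the size
of the largest crystalline cluster.  A particle is labelled crystalline from
the rank-12 Steinhardt bond-orientational vector q_12: for every bond (i, j)
the coherence d12 = Re <q̂_i, q̂_j> is computed, a particle is crystalline when
it has at least ``xi_c`` coherent bonds (d12 > d_c), and crystalline particles
connected through the neighbor rule are merged into clusters.

Also provided: radial distribution function g(r), time-origin-averaged mean
square displacement with a 6Dt diffusion fit, and a cubic/hexagonal diamond
polymorph discrimination based on staggered vs eclipsed bond dihedrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import sph_harm_y

from .core_md import Configuration, Trajectory, neighbor_list

L_ORDER = 12  # spherical-harmonic rank of the crystallinity detector

#: First-shell cutoff (Å): first minimum of the mW liquid g(r); used for
#: cluster connectivity and polymorph dihedrals.
DEFAULT_NEIGHBOR_CUTOFF = 3.51
#: q12 is averaged over this many nearest neighbors (first + second
#: coordination shells of a tetrahedral network).
DEFAULT_KNN = 16
#: Bond-coherence threshold and coherent-bond count for crystallinity.
DEFAULT_D_C = 0.65
DEFAULT_XI_C = 4


@dataclass(frozen=True)
class OrderParamConfig:
    """Thresholds of the crystallinity classifier, shared by analysis and
    biased sampling so the two can never disagree."""

    knn: int = DEFAULT_KNN
    cluster_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF
    d_c: float = DEFAULT_D_C
    xi_c: int = DEFAULT_XI_C


# --------------------------------------------------------------------------
# Radial distribution function
# --------------------------------------------------------------------------


@dataclass
class RDF:
    r: np.ndarray        # bin centers, Å
    g: np.ndarray        # dimensionless
    density: float       # particles / Å^3
    n: int
    n_frames: int


@njit(cache=False)
def _pair_distance_histogram(pos, box, r_max, n_bins):
    n = pos.shape[0]
    hist = np.zeros(n_bins, dtype=np.int64)
    dr = r_max / n_bins
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * math.floor(dx / box[0] + 0.5)
            dy -= box[1] * math.floor(dy / box[1] + 0.5)
            dz -= box[2] * math.floor(dz / box[2] + 0.5)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_max:
                hist[int(r / dr)] += 1
    return hist


def _as_frames(traj: Union[Trajectory, Configuration, Sequence[Configuration]]
               ) -> List[Configuration]:
    if isinstance(traj, Configuration):
        return [traj]
    if isinstance(traj, Trajectory):
        return [traj.frame(i) for i in range(len(traj))]
    return list(traj)


def compute_rdf(traj, r_max: float, n_bins: int = 150) -> RDF:
    """Pair-correlation function averaged over frames.

    Normalised by the ideal-gas shell count at the frame density, so g -> 1
    at large r for a homogeneous liquid.
    """
    frames = _as_frames(traj)
    if not frames:
        raise ValueError("need at least one frame")
    n = frames[0].n
    dr = r_max / n_bins
    edges = np.arange(n_bins + 1) * dr
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    acc = np.zeros(n_bins)
    rho_acc = 0.0
    for f in frames:
        if r_max > 0.5 * float(np.min(f.box)):
            raise ValueError("r_max exceeds half the smallest box edge")
        hist = _pair_distance_histogram(f.wrapped(), f.box, r_max, n_bins)
        rho = f.n / f.volume
        # 2*hist: ordered pairs; expected ideal count per particle: rho*shell
        acc += 2.0 * hist / (f.n * rho * shell)
        rho_acc += rho
    g = acc / len(frames)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDF(centers, g, rho_acc / len(frames), n, len(frames))


# --------------------------------------------------------------------------
# Mean square displacement and diffusion
# --------------------------------------------------------------------------


@dataclass
class MSDSeries:
    times: np.ndarray   # lag times, ps
    msd: np.ndarray     # Å^2


@dataclass
class DiffusionFit:
    D: float            # Å^2 / ns
    window: tuple       # (t_min, t_max) ps
    slope: float        # Å^2 / ps
    intercept: float


def compute_msd(traj: Trajectory, remove_com: bool = True,
                max_lag_fraction: float = 0.5) -> MSDSeries:
    """Time-origin-averaged mean square displacement of an unwrapped
    trajectory.  Wrapped input (particles jumping by a box length between
    frames) is rejected."""
    pos = traj.positions
    if len(traj) < 2:
        raise ValueError("need at least two frames")
    jumps = np.abs(np.diff(pos, axis=0)).max()
    if jumps > 0.5 * float(np.min(traj.boxes)):
        raise ValueError("trajectory appears wrapped; unwrapped coordinates "
                         "are required for MSD")
    if remove_com:
        pos = pos - pos.mean(axis=1, keepdims=True)
    nf = pos.shape[0]
    max_lag = max(1, int(nf * max_lag_fraction))
    dt = float(traj.times[1] - traj.times[0])
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        d = pos[k:] - pos[:-k]
        msd[k] = np.mean(np.sum(d * d, axis=2))
    return MSDSeries(lags * dt, msd)


def fit_diffusion(msd: MSDSeries, window: tuple) -> DiffusionFit:
    """Least-squares fit <dr^2> = 6 D t over ``window`` (ps); D in Å^2/ns."""
    t0, t1 = window
    m = (msd.times >= t0) & (msd.times <= t1)
    if m.sum() < 2:
        raise ValueError("fit window contains fewer than two points")
    slope, intercept = np.polyfit(msd.times[m], msd.msd[m], 1)
    return DiffusionFit(D=slope / 6.0 * 1000.0, window=(t0, t1),
                        slope=float(slope), intercept=float(intercept))


# --------------------------------------------------------------------------
# Q12 bond-orientational crystallinity
# --------------------------------------------------------------------------


@dataclass
class OrderParamResult:
    qlm: np.ndarray              # N x (2l+1), complex, un-normalised average
    qhat: np.ndarray             # N x (2l+1), complex, unit vectors (0 if no bonds)
    neighbors: np.ndarray        # N x k, indices of the q12 neighbors
    d12: np.ndarray              # N x k, bond coherences to those neighbors
    coherent_counts: np.ndarray  # N, number of coherent bonds per particle
    crystalline: np.ndarray      # N, bool
    config: Configuration
    op_config: OrderParamConfig
    polymorph: Optional[np.ndarray] = None  # 'c', 'h', 'u' or '' per particle

    @property
    def crystalline_fraction(self) -> float:
        return float(np.mean(self.crystalline))


def _bond_vectors(config: Configuration, cutoff: float):
    """Unique neighbor pairs (i<j) within ``cutoff`` and their minimum-image
    bond vectors (used for clustering and polymorph dihedrals)."""
    nl = neighbor_list(config, cutoff, 0.0)
    pairs = nl.pairs()
    if pairs.size == 0:
        return pairs.reshape(0, 2), np.zeros((0, 3))
    pos = config.wrapped()
    d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    d -= config.box[None, :] * np.floor(d / config.box[None, :] + 0.5)
    return pairs, d


def _knn(config: Configuration, k: int):
    """Indices and minimum-image displacement vectors of the k nearest
    neighbors of every particle (O(N^2); fine for N ~ 10^3)."""
    pos = config.wrapped()
    box = config.box
    n = config.n
    k = min(k, n - 1)
    d = pos[None, :, :] - pos[:, None, :]
    d -= box[None, None, :] * np.floor(d / box[None, None, :] + 0.5)
    r = np.sqrt(np.sum(d * d, axis=2))
    np.fill_diagonal(r, np.inf)
    nbr = np.argpartition(r, k - 1, axis=1)[:, :k]
    # sort the k selected by distance for reproducibility
    order = np.argsort(np.take_along_axis(r, nbr, axis=1), axis=1)
    nbr = np.take_along_axis(nbr, order, axis=1)
    vecs = d[np.arange(n)[:, None], nbr]
    return nbr, vecs


def q12_vectors(config: Configuration, k: int = DEFAULT_KNN):
    """Per-particle average of rank-12 spherical harmonics over the bonds to
    the ``k`` nearest neighbors.

    Returns ``(qlm, qhat, neighbors)``.  q_lm(i) = <Y_12,m(r̂_ij)> over the
    neighbor set; qhat rows are normalised to unit length (zero rows for
    particles without neighbors, which are flagged liquid downstream).
    """
    n = config.n
    nbr, vecs = _knn(config, k)
    kk = nbr.shape[1]
    qlm = np.zeros((n, 2 * L_ORDER + 1), dtype=np.complex128)
    if kk > 0:
        flat = vecs.reshape(-1, 3)
        r = np.linalg.norm(flat, axis=1)
        theta = np.arccos(np.clip(flat[:, 2] / r, -1.0, 1.0))
        phi = np.arctan2(flat[:, 1], flat[:, 0])
        for mi, m in enumerate(range(-L_ORDER, L_ORDER + 1)):
            y = sph_harm_y(L_ORDER, m, theta, phi).reshape(n, kk)
            qlm[:, mi] = y.mean(axis=1)
    norms = np.linalg.norm(qlm, axis=1)
    qhat = np.zeros_like(qlm)
    ok = norms > 0
    qhat[ok] = qlm[ok] / norms[ok, None]
    return qlm, qhat, nbr


def bond_coherence(qhat: np.ndarray, i: int, j: int) -> float:
    """d12(i, j) = Re <q̂_i, q̂_j>; symmetric in its arguments."""
    return float(np.real(np.sum(qhat[i] * np.conj(qhat[j]))))


def classify_crystalline(config: Configuration,
                         op: OrderParamConfig = OrderParamConfig()
                         ) -> OrderParamResult:
    """Label particles crystalline when at least ``xi_c`` of their ``k``
    nearest neighbors have bond coherence d12 = Re<q̂_i, q̂_j> above d_c."""
    qlm, qhat, nbr = q12_vectors(config, op.knn)
    d12 = np.real(np.sum(qhat[:, None, :] * np.conj(qhat[nbr]), axis=2))
    counts = np.sum(d12 > op.d_c, axis=1).astype(np.int64)
    crystalline = counts >= op.xi_c
    return OrderParamResult(qlm, qhat, nbr, d12, counts, crystalline,
                            config, op)


@dataclass
class ClusterResult:
    labels: np.ndarray   # component id per particle; -1 for liquid
    n: int               # largest crystalline cluster size
    sizes: np.ndarray    # component sizes, descending

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def largest_cluster(result: OrderParamResult) -> ClusterResult:
    """Connected components of crystalline particles that are first-shell
    neighbors (within ``cluster_cutoff``); ``n`` is the size of the largest
    component, 0 for a fully liquid frame."""
    cr = result.crystalline
    nP = len(cr)
    labels = np.full(nP, -1, dtype=np.int64)
    if not cr.any():
        return ClusterResult(labels, 0, np.zeros(0, dtype=np.int64))
    pairs, _ = _bond_vectors(result.config, result.op_config.cluster_cutoff)
    both = cr[pairs[:, 0]] & cr[pairs[:, 1]] if len(pairs) else \
        np.zeros(0, dtype=bool)
    idx = np.flatnonzero(cr)
    remap = -np.ones(nP, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    rows = remap[pairs[both, 0]] if both.any() else np.zeros(0, dtype=np.int64)
    cols = remap[pairs[both, 1]] if both.any() else np.zeros(0, dtype=np.int64)
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                            shape=(len(idx), len(idx)))
    ncomp, comp = connected_components(adj, directed=False)
    labels[idx] = comp
    sizes = np.sort(np.bincount(comp, minlength=ncomp))[::-1]
    return ClusterResult(labels, int(sizes[0]), sizes)


def largest_cluster_size(config: Configuration,
                         op: OrderParamConfig = OrderParamConfig()) -> int:
    """Convenience: the order parameter n of a single configuration."""
    return largest_cluster(classify_crystalline(config, op)).n


# --------------------------------------------------------------------------
# Cubic vs hexagonal diamond polymorph labelling (diagnostic only)
# --------------------------------------------------------------------------


def _dihedral_score(d: np.ndarray, nbrs_i: np.ndarray, nbrs_j: np.ndarray,
                    vecs_i: np.ndarray, vecs_j: np.ndarray) -> float:
    """Mean cos(3 phi) over dihedrals k-i-j-l of one bond; +1 for an eclipsed
    bond, -1 for a staggered one."""
    scores = []
    b2 = d  # i -> j
    for vk in vecs_i:          # vk points i -> k, so b1 = r_i - r_k = -vk
        b1 = -vk
        n1 = np.cross(b1, b2)
        if np.linalg.norm(n1) < 1e-8:
            continue
        for vl in vecs_j:      # j -> l, b3 = r_l - r_j = vl
            n2 = np.cross(b2, vl)
            if np.linalg.norm(n2) < 1e-8:
                continue
            c = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            c = float(np.clip(c, -1.0, 1.0))
            scores.append(4.0 * c ** 3 - 3.0 * c)  # cos(3 phi)
    return float(np.mean(scores)) if scores else 0.0


def classify_polymorph(result: OrderParamResult) -> np.ndarray:
    """Assign cubic ('c') / hexagonal ('h') character to crystalline particles.

    Each crystalline-crystalline bond is scored by its dihedral pattern:
    staggered bonds (all torsions near ±60°/180°) are diamond-cubic-like,
    eclipsed bonds (torsions near 0°/±120°) occur only along the c axis of
    the hexagonal polymorph.  A particle with at least one eclipsed bond is
    hexagonal, one with only staggered bonds is cubic, and a particle whose
    bonds give no usable dihedral is left unassigned ('u').  Liquid particles
    get an empty label.  The result is diagnostic; it never feeds n.
    """
    cfg = result.config
    cr = result.crystalline
    labels = np.array([''] * cfg.n, dtype=object)
    pairs, d = _bond_vectors(cfg, result.op_config.cluster_cutoff)
    # adjacency of bond vectors per particle
    nbr_vecs: List[List[np.ndarray]] = [[] for _ in range(cfg.n)]
    nbr_ids: List[List[int]] = [[] for _ in range(cfg.n)]
    for (i, j), v in zip(pairs, d):
        nbr_vecs[i].append(v)
        nbr_ids[i].append(j)
        nbr_vecs[j].append(-v)
        nbr_ids[j].append(i)
    eclipsed = np.zeros(cfg.n, dtype=np.int64)
    staggered = np.zeros(cfg.n, dtype=np.int64)
    for (i, j), v in zip(pairs, d):
        if not (cr[i] and cr[j]):
            continue
        vecs_i = [w for jj, w in zip(nbr_ids[i], nbr_vecs[i]) if jj != j]
        vecs_j = [w for ii, w in zip(nbr_ids[j], nbr_vecs[j]) if ii != i]
        if not vecs_i or not vecs_j:
            continue
        s = _dihedral_score(v, np.array(nbr_ids[i]), np.array(nbr_ids[j]),
                            np.array(vecs_i), np.array(vecs_j))
        if s > 0:
            eclipsed[i] += 1
            eclipsed[j] += 1
        else:
            staggered[i] += 1
            staggered[j] += 1
    for i in range(cfg.n):
        if not cr[i]:
            continue
        if eclipsed[i] + staggered[i] == 0:
            labels[i] = 'u'
        elif eclipsed[i] > 0:
            labels[i] = 'h'
        else:
            labels[i] = 'c'
    result.polymorph = labels
    return labels


def frame_summary(config: Configuration,
                  op: OrderParamConfig = OrderParamConfig(),
                  polymorph: bool = False) -> dict:
    """Per-frame analysis record: n, crystalline fraction and, optionally,
    cubic/hexagonal fractions."""
    res = classify_crystalline(config, op)
    cl = largest_cluster(res)
    out = {
        "n": cl.n,
        "crystalline_fraction": res.crystalline_fraction,
    }
    if polymorph:
        lab = classify_polymorph(res)
        ncr = max(1, int(res.crystalline.sum()))
        out["cubic_fraction"] = float(np.sum(lab == 'c')) / ncr
        out["hex_fraction"] = float(np.sum(lab == 'h')) / ncr
    return out


# --------------------------------------------------------------------------
# Self-diffusion pipeline (equilibrate at a state point, then MSD -> D)
# --------------------------------------------------------------------------


def measure_self_diffusion(n: int = 216, T: float = 218.0, P: float = 1.0,
                           seed: int = 0, rho_start: float = 0.99,
                           npt_ps: float = 200.0, aging_ps: float = 400.0,
                           production_ps: float = 400.0, dt: float = 4.0,
                           fit_window: tuple = (30.0, 150.0)) -> dict:
    """Long-time self-diffusion coefficient of the mW liquid at (T, P).

    The full protocol the nucleation analysis rests on: build an equilibrated
    liquid, find the ambient-pressure density with a Langevin-piston NPT
    segment, fix the box at the trailing-mean density, age the liquid in NVT
    (supercooled mW keeps structuring for hundreds of ps), then record an
    unwrapped NVT production trajectory with weak thermostat coupling and
    fit the time-origin-averaged MSD as 6 D t over ``fit_window`` (ps).

    Returns a dict with D (Å^2/ns), the density used, mean production
    temperature, and the MSD series.
    """
    from . import core_md as _cm
    from .synthetic import generate_liquid

    params = _cm.MWParams()
    steps = lambda ps: int(round(ps * 1000.0 / dt))
    liq = generate_liquid(n, rho_start, T, params, seed=seed)
    liq = _cm.draw_velocities(liq, T, seed + 1)
    state = _cm.make_state(liq, params)
    state = _cm.integrate_nvt(state, steps(100.0), dt, T, damping=0.5,
                              seed=seed + 2)
    state = _cm.integrate_npt(state, steps(npt_ps), dt, T, P,
                              seed=seed + 3, log_stride=100)
    vlog = state.log[len(state.log) // 2:, 4]
    rho = _cm.volume_to_density(n, params.mass, float(vlog.mean()))
    # fix the box at the NPT mean density
    target_v = _cm.density_to_volume(n, params.mass, rho)
    s = (target_v / state.config.volume) ** (1.0 / 3.0)
    cfg = Configuration(state.config.positions * s, state.config.box * s,
                        state.config.velocities)
    state = _cm.make_state(cfg, params)
    state = _cm.integrate_nvt(state, steps(aging_ps), dt, T, damping=1.0,
                              seed=seed + 4)
    rec = max(1, steps(production_ps) // 1000)
    state = _cm.integrate_nvt(state, steps(production_ps), dt, T,
                              damping=2.0, seed=seed + 5,
                              record_stride=rec, log_stride=rec)
    msd = compute_msd(state.trajectory)
    hi = min(fit_window[1], msd.times[-1])
    fit = fit_diffusion(msd, (fit_window[0], hi))
    return {
        "D": fit.D,
        "density": rho,
        "T_mean": float(state.log[:, 1].mean()),
        "n": n,
        "production_ps": production_ps,
        "msd": msd,
        "fit": fit,
    }
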