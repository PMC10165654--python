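"""Nucleation kinetics from ensembles of spontaneous trajectories.

The mean first passage time (MFPT) tau(n) — the average time for the largest
crystalline cluster to first reach size n — has, for an activated nucleation
process, the sigmoidal form of Wedekind and Reguera:

    tau(n) = 1 / (2 J V) * [1 + erf(c (n - n_c))]

where J is the nucleation rate per unit volume, V the system volume, n_c the
critical nucleus size (the inflection point) and c is proportional to the
square root of the barrier curvature at the top (the Zeldovich-factor
normalisation is not fixed here; c is reported as a raw fit parameter).
The plateau tau(inf) = 1/(J V) gives the rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .core_md import Configuration, Trajectory
from .structure import OrderParamConfig, largest_cluster_size
from .synthetic import NSeries


# --------------------------------------------------------------------------
# Order-parameter time series from trajectories
# --------------------------------------------------------------------------


def n_series(traj: Trajectory,
             op: OrderParamConfig = OrderParamConfig(),
             stop_fraction: float = 0.5) -> NSeries:
    """Largest-cluster size per frame; evaluation stops once the largest
    cluster comprises ``stop_fraction`` of the system (post-critical growth
    is not of interest and dominates the analysis cost)."""
    times = []
    ns = []
    n_part = traj.positions.shape[1]
    for i in range(len(traj)):
        n = largest_cluster_size(traj.frame(i), op)
        times.append(float(traj.times[i]))
        ns.append(n)
        if n >= stop_fraction * n_part:
            break
    return NSeries(np.asarray(times), np.asarray(ns, dtype=np.int64))


# --------------------------------------------------------------------------
# First passage times
# --------------------------------------------------------------------------


@dataclass
class FPTCurve:
    thresholds: np.ndarray   # n values
    tau: np.ndarray          # mean first passage time per threshold
    counts: np.ndarray       # trajectories that reached each threshold
    censored: np.ndarray     # trajectories that never reached it
    spread: np.ndarray       # across-trajectory standard deviation of the FPT
    volume: float = float("nan")   # Å^3, used by the rate fit

    def usable(self) -> np.ndarray:
        return self.counts > 0


def first_passage(ensemble: Sequence[NSeries],
                  thresholds: Sequence[int],
                  volume: float = float("nan")) -> FPTCurve:
    """Mean first passage time over an ensemble of order-parameter series.

    For each threshold n, tau(n) averages the earliest time each trajectory
    reaches >= n; trajectories that never reach n are excluded from the mean
    and counted as censored.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two trajectories")
    thresholds = np.asarray(thresholds, dtype=np.int64)
    tau = np.full(len(thresholds), np.nan)
    counts = np.zeros(len(thresholds), dtype=np.int64)
    censored = np.zeros(len(thresholds), dtype=np.int64)
    spread = np.full(len(thresholds), np.nan)
    for k, thr in enumerate(thresholds):
        t_hit = np.array([s.first_time_at(int(thr)) for s in ensemble])
        ok = np.isfinite(t_hit)
        counts[k] = int(ok.sum())
        censored[k] = int((~ok).sum())
        if counts[k]:
            tau[k] = float(np.mean(t_hit[ok]))
            spread[k] = float(np.std(t_hit[ok], ddof=1)) if counts[k] > 1 \
                else np.nan
    return FPTCurve(thresholds, tau, counts, censored, spread, volume)


def check_monotone(curve: FPTCurve, noise_sigmas: float = 3.0) -> None:
    """tau(n) must be non-decreasing up to noise; a violation beyond
    ``noise_sigmas`` standard errors aborts with a diagnostic."""
    use = curve.usable()
    tau = curve.tau[use]
    se = curve.spread[use] / np.sqrt(np.maximum(curve.counts[use], 1))
    se = np.where(np.isfinite(se), se, 0.0)
    drop = np.diff(tau)
    tol = noise_sigmas * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
    bad = drop < -np.maximum(tol, 1e-12)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"mean first passage time decreases beyond noise between "
            f"n={curve.thresholds[use][k]} and n={curve.thresholds[use][k+1]}"
        )


# --------------------------------------------------------------------------
# MFPT model and fit
# --------------------------------------------------------------------------


def mfpt_model(n, J, V, n_c, c):
    """Sigmoidal MFPT: tau(n) = (1/(2 J V)) [1 + erf(c (n - n_c))]."""
    n = np.asarray(n, dtype=float)
    return 1.0 / (2.0 * J * V) * (1.0 + erf(c * (n - n_c)))


@dataclass
class MFPTFit:
    J: float          # nucleation rate, (time unit)^-1 Å^-3
    n_c: float        # critical nucleus size
    c: float          # curvature parameter
    V: float          # volume used, Å^3
    covariance: Optional[np.ndarray]   # over (tau_inf, n_c, c)
    fit_max_n: float
    n_points: int
    residual_rms: float


class FitError(RuntimeError):
    def __init__(self, msg, last_params=None, residuals=None):
        super().__init__(msg)
        self.last_params = last_params
        self.residuals = residuals


def fit_mfpt(curve: FPTCurve, fit_max_n: float = 100.0,
             volume: Optional[float] = None) -> MFPTFit:
    """Weighted nonlinear least-squares fit of the sigmoidal MFPT model to
    tau(n) for n < fit_max_n.

    Weights are per-point inverse variances from the across-trajectory
    spread when at least five trajectories contribute, uniform otherwise.
    Initial guesses: n_c at the maximum slope of tau(n), the plateau from the
    top decile of tau, c = 0.05; three perturbed restarts on non-convergence.
    """
    V = volume if volume is not None else curve.volume
    if not np.isfinite(V) or V <= 0:
        raise ValueError("a positive system volume is required for the rate")
    use = curve.usable() & np.isfinite(curve.tau) & \
        (curve.thresholds < fit_max_n)
    n = curve.thresholds[use].astype(float)
    tau = curve.tau[use]
    if len(n) < 4:
        raise ValueError("need at least 4 usable points below fit_max_n")
    check_monotone(curve)
    sig = curve.spread[use] / np.sqrt(np.maximum(curve.counts[use], 1))
    if np.all(np.isfinite(sig)) and np.all(sig > 0) and \
            np.min(curve.counts[use]) >= 5:
        # floored inverse-standard-error weights: without the floor the
        # near-noiseless pre-barrier points (tau ~ 0) dominate the cost and
        # bias the inflection point well below the true critical size
        w = 1.0 / np.maximum(sig, 0.05 * float(np.max(sig)))
    else:
        w = np.ones_like(tau)

    tau_inf0 = 2.0 * float(np.mean(np.sort(tau)[-max(1, len(tau) // 10):]))
    slopes = np.gradient(tau, n)
    n_c0 = float(n[np.argmax(slopes)])
    c0 = 0.05

    def resid(p):
        tau_inf, n_c, c = p
        model = 0.5 * tau_inf * (1.0 + erf(c * (n - n_c)))
        return w * (model - tau)

    best = None
    rng = np.random.default_rng(0)
    for trial in range(4):
        if trial == 0:
            p0 = np.array([tau_inf0, n_c0, c0])
        else:
            p0 = np.array([tau_inf0 * rng.uniform(0.5, 2.0),
                           n_c0 * rng.uniform(0.7, 1.4),
                           c0 * rng.uniform(0.3, 3.0)])
        try:
            sol = least_squares(resid, p0,
                                bounds=([1e-300, 0.0, 1e-12],
                                        [np.inf, np.inf, np.inf]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("MFPT fit did not converge",
                       last_params=None if best is None else best.x,
                       residuals=None if best is None else best.fun)
    tau_inf, n_c, c = best.x
    J = 1.0 / (tau_inf * V)
    # Gauss-Newton covariance over (tau_inf, n_c, c)
    try:
        jac = best.jac
        dof = max(1, len(n) - 3)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = None
    rms = float(np.sqrt(np.mean((best.fun / w) ** 2)))
    return MFPTFit(J=float(J), n_c=float(n_c), c=float(c), V=float(V),
                   covariance=cov, fit_max_n=fit_max_n, n_points=len(n),
                   residual_rms=rms)
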