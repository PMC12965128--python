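"""Protonation statistics: deprotonated fractions and titration-curve fits.

The deprotonated fraction ``S_deprot = N_deprot / (N_prot + N_deprot)``
classifies a frame as protonated when lambda < 0.2 and deprotonated when
lambda > 0.8; intermediate frames are excluded from numerator *and*
denominator.  Titration curves S(pH) are fitted with the
Henderson-Hasselbalch (HH) equation

    S(pH) = 1 / (10^(pKa - pH) + 1)

or its generalized form with a cooperativity exponent n

    S(pH) = 1 / (10^(n (pKa - pH)) + 1),

where n < 1 indicates anti-cooperative protonation.  Fits use iteratively
reweighted least squares (IRLS): starting from inverse-variance weights
1/sigma^2, each iteration re-weights by the model derivative h(1-h)/sigma^2
evaluated at the previous parameters (the constant ln10 / n ln10 prefactors
are omitted), until the parameter step two-norm drops below the tolerance.
Confidence intervals come from a parametric bootstrap that resamples every
point from Normal(mean, sem) -- without clipping -- and refits.

Time-series errors use blocked standard errors extrapolated with single or
double exponentials; equilibration is detected from the drift of segment-wise
linear regressions relative to the segment standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._constants import LN10, rt_ln10

logger = logging.getLogger(__name__)

__all__ = [
    "LambdaTrajectory",
    "TitrationPoint",
    "FitResult",
    "FitError",
    "sdeprot",
    "classify_lambda",
    "hh",
    "ghh",
    "irls_fit",
    "bootstrap_ci",
    "block_sem",
    "detect_equilibration",
    "pka_shift_energy",
]

#: classification thresholds on the titration coordinate
LAMBDA_PROT = 0.2
LAMBDA_DEPROT = 0.8


class FitError(RuntimeError):
    """Raised when a titration-curve fit cannot be computed."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaTrajectory:
    """Time series of the titration coordinate for one site."""

    site_id: int
    times: np.ndarray      # ps, strictly increasing
    lambdas: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lambdas", lam)
        if t.shape != lam.shape:
            raise ValueError("times and lambdas must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TitrationPoint:
    """One (pH, S_deprot, SEM) observation."""

    ph: float
    s_deprot: float
    sem: float

    def __post_init__(self):
        if not 0.0 <= self.s_deprot <= 1.0:
            raise ValueError("s_deprot must lie in [0, 1]")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class FitResult:
    """Fitted (pKa, n) with optional bootstrap confidence intervals."""

    pka: float
    n: float
    ci95_pka: tuple[float, float] | None
    ci95_n: tuple[float, float] | None
    n_iterations: int
    converged: bool
    model: str   # "hh" | "ghh"

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "pka": self.pka,
            "n": self.n,
            "ci95_pka": list(self.ci95_pka) if self.ci95_pka else None,
            "ci95_n": list(self.ci95_n) if self.ci95_n else None,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


# --------------------------------------------------------------------------
# deprotonated fraction
# --------------------------------------------------------------------------

def classify_lambda(lam, lo: float = LAMBDA_PROT, hi: float = LAMBDA_DEPROT):
    """Return (is_protonated, is_deprotonated) boolean arrays for lambda."""
    lam = np.asarray(lam, dtype=float)
    return lam < lo, lam > hi


def sdeprot(trajectories, lo: float = LAMBDA_PROT, hi: float = LAMBDA_DEPROT) -> float:
    """Fraction of deprotonated frames, N_deprot / (N_prot + N_deprot).

    Accepts a single :class:`LambdaTrajectory`, an iterable of them, or raw
    lambda arrays; multi-site snapshots count one entry per site per frame.
    Frames with lo <= lambda <= hi are excluded from both counts.
    """
    if isinstance(trajectories, (LambdaTrajectory, np.ndarray)):
        trajectories = [trajectories]
    n_prot = 0
    n_deprot = 0
    for traj in trajectories:
        lam = traj.lambdas if isinstance(traj, LambdaTrajectory) else np.asarray(traj, float)
        p, d = classify_lambda(lam, lo, hi)
        n_prot += int(p.sum())
        n_deprot += int(d.sum())
    if n_prot + n_deprot == 0:
        raise ValueError(
            "S_deprot undefined: no frame classifiable "
            f"(all lambda within [{lo}, {hi}])"
        )
    return n_deprot / (n_prot + n_deprot)


# --------------------------------------------------------------------------
# titration models
# --------------------------------------------------------------------------

def hh(ph, pka):
    """Henderson-Hasselbalch deprotonated fraction 1/(10^(pKa-pH) + 1)."""
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (np.power(10.0, pka - ph) + 1.0)
    return float(out) if out.ndim == 0 else out


def ghh(ph, pka, n):
    """Generalized HH fraction 1/(10^(n (pKa-pH)) + 1); n=1 recovers hh."""
    if n <= 0:
        raise ValueError("cooperativity n must be positive")
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (np.power(10.0, n * (pka - ph)) + 1.0)
    return float(out) if out.ndim == 0 else out


def _model_and_jacobian(ph: np.ndarray, theta: np.ndarray, model: str):
    if model == "hh":
        (pka,) = theta
        f = 1.0 / (np.power(10.0, pka - ph) + 1.0)
        jac = np.empty((ph.size, 1))
        jac[:, 0] = -LN10 * f * (1.0 - f)
    else:
        pka, n = theta
        f = 1.0 / (np.power(10.0, n * (pka - ph)) + 1.0)
        jac = np.empty((ph.size, 2))
        jac[:, 0] = -LN10 * n * f * (1.0 - f)
        jac[:, 1] = -LN10 * (pka - ph) * f * (1.0 - f)
    return f, jac


def _weighted_nls(ph, y, w, theta0, model, max_steps: int = 200, gtol: float = 1e-12):
    """Damped Gauss-Newton minimizer of sum w (y - f(theta))^2."""
    theta = np.asarray(theta0, dtype=float).copy()
    f, jac = _model_and_jacobian(ph, theta, model)
    sse = float(np.sum(w * (y - f) ** 2))
    mu = 1e-3
    for _ in range(max_steps):
        r = y - f
        g = jac.T @ (w * r)
        h = (jac * w[:, None]).T @ jac
        diag = np.diag(h).copy()
        diag[diag <= 0] = 1.0
        try:
            step = np.linalg.solve(h + mu * np.diag(diag), g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular normal equations in titration fit") from exc
        cand = theta + step
        if model == "ghh":
            cand[1] = max(cand[1], 1e-6)  # keep n positive
        f_cand, jac_cand = _model_and_jacobian(ph, cand, model)
        sse_cand = float(np.sum(w * (y - f_cand) ** 2))
        if sse_cand <= sse:
            theta, f, jac, sse = cand, f_cand, jac_cand, sse_cand
            mu = max(mu * 0.3, 1e-12)
            if np.linalg.norm(step) < gtol:
                break
        else:
            mu *= 10.0
            if mu > 1e12:
                break
    return theta


def _initial_guess(ph: np.ndarray, y: np.ndarray, model: str) -> np.ndarray:
    """Logit-linear regression start values (robust to mild noise)."""
    mask = (y > 0.01) & (y < 0.99)
    if mask.sum() >= 2 and np.ptp(ph[mask]) > 0:
        logit = np.log10(y[mask] / (1.0 - y[mask]))
        slope, intercept = np.polyfit(ph[mask], logit, 1)
        if slope > 1e-6:
            pka0 = -intercept / slope
            n0 = slope
        else:
            pka0, n0 = float(np.median(ph)), 1.0
    else:
        # all points saturated: put pKa between the two regimes
        pka0, n0 = float(np.median(ph)), 1.0
    if model == "hh":
        return np.array([pka0])
    return np.array([pka0, min(max(n0, 0.05), 20.0)])


def _prepare_sigma(sem: np.ndarray) -> np.ndarray:
    sem = np.asarray(sem, dtype=float)
    if np.all(sem == 0):
        warnings.warn("all standard errors are zero; falling back to unit weights")
        return np.ones_like(sem)
    if np.any(sem == 0):
        smallest = sem[sem > 0].min()
        warnings.warn("zero standard errors clamped to smallest positive value")
        sem = np.where(sem == 0, smallest, sem)
    return sem


def _irls_arrays(ph, y, sem, model, tol, max_iter):
    sigma = _prepare_sigma(sem)
    w = 1.0 / sigma**2
    theta = _weighted_nls(ph, y, w, _initial_guess(ph, y, model), model)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f, _ = _model_and_jacobian(ph, theta, model)
        w = f * (1.0 - f) / sigma**2     # ln10 / n ln10 prefactors omitted
        if not np.any(w > 0):
            break                        # fully saturated model: keep theta
        theta_new = _weighted_nls(ph, y, w, theta, model)
        step = float(np.linalg.norm(theta_new - theta))
        theta = theta_new
        if step < tol:
            converged = True
            break
    return theta, iterations, converged


def irls_fit(
    points: Sequence[TitrationPoint],
    model: str = "hh",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Iteratively reweighted least-squares fit of a titration curve.

    Parameters
    ----------
    points
        (pH, S_deprot, sem) observations; at least 2 for ``hh`` and 3 for
        ``ghh``, with non-identical S values.
    model
        ``"hh"`` fits pKa only (n fixed at 1); ``"ghh"`` fits (pKa, n).
    tol
        Convergence threshold on the two-norm of the parameter step.
    """
    if model not in ("hh", "ghh"):
        raise ValueError(f"unknown model {model!r}")
    ph = np.array([p.ph for p in points], dtype=float)
    y = np.array([p.s_deprot for p in points], dtype=float)
    sem = np.array([p.sem for p in points], dtype=float)
    min_pts = 2 if model == "hh" else 3
    if ph.size < min_pts:
        raise ValueError(f"model {model} needs at least {min_pts} points")
    if np.all(y == y[0]):
        raise ValueError("all S_deprot values identical; titration curve is degenerate")
    theta, iterations, converged = _irls_arrays(ph, y, sem, model, tol, max_iter)
    pka = float(theta[0])
    n = float(theta[1]) if model == "ghh" else 1.0
    return FitResult(pka, n, None, None, iterations, converged, model)


def bootstrap_ci(
    points: Sequence[TitrationPoint],
    model: str = "hh",
    n_reps: int = 10_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Parametric bootstrap of the IRLS fit.

    Each replicate resamples every S value from Normal(mean, sem) -- plain
    normal sampling, no clipping to [0, 1] -- and refits; reported pKa and n
    are bootstrap means with central 95% intervals (2.5/97.5 percentiles).
    Deterministic under ``seed``.
    """
    ph = np.array([p.ph for p in points], dtype=float)
    y = np.array([p.s_deprot for p in points], dtype=float)
    sem = np.array([p.sem for p in points], dtype=float)
    if np.any(sem <= 0):
        raise ValueError("bootstrap requires every point to carry sem > 0")
    base = irls_fit(points, model=model, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    pkas, ns = [], []
    failures = 0
    for _ in range(n_reps):
        y_rep = rng.normal(y, sem)
        try:
            theta, _, conv = _irls_arrays(ph, y_rep, sem, model, tol, max_iter)
        except (FitError, np.linalg.LinAlgError):
            failures += 1
            continue
        if not conv:
            failures += 1
            continue
        pkas.append(theta[0])
        ns.append(theta[1] if model == "ghh" else 1.0)
    if failures > 0.01 * n_reps:
        warnings.warn(
            f"bootstrap partial result: {failures}/{n_reps} replicates failed to converge"
        )
    pkas = np.asarray(pkas)
    ns = np.asarray(ns)
    ci_pka = (float(np.percentile(pkas, 2.5)), float(np.percentile(pkas, 97.5)))
    ci_n = (float(np.percentile(ns, 2.5)), float(np.percentile(ns, 97.5)))
    return FitResult(
        pka=float(pkas.mean()),
        n=float(ns.mean()) if model == "ghh" else 1.0,
        ci95_pka=ci_pka,
        ci95_n=ci_n if model == "ghh" else None,
        n_iterations=base.n_iterations,
        converged=base.converged,
        model=model,
    )


# --------------------------------------------------------------------------
# time-series statistics
# --------------------------------------------------------------------------

def _block_sem_curve(series: np.ndarray, n_sizes: int = 24):
    n = series.size
    sizes = np.unique(np.geomspace(1, max(n // 10, 2), n_sizes).astype(int))
    bse = np.empty(sizes.size)
    for i, m in enumerate(sizes):
        nb = n // m
        means = series[: nb * m].reshape(nb, m).mean(axis=1)
        bse[i] = means.std(ddof=1) / np.sqrt(nb)
    return sizes.astype(float), bse


def _single_exp(m, a, tau):
    return a * (1.0 - np.exp(-m / tau))


def _double_exp(m, a, frac, tau1, tau2):
    return a * (frac * (1.0 - np.exp(-m / tau1)) + (1.0 - frac) * (1.0 - np.exp(-m / tau2)))


def block_sem(series) -> float:
    """Standard error of the mean from block averaging.

    Blocked SEM estimates over a geometric ladder of block sizes are
    extrapolated to infinite block length with the better-fitting (by
    residual sum of squares) of a single or double exponential plateau
    model; the plateau value is the returned SEM.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 100:
        raise ValueError(f"block_sem needs >= 100 samples, got {series.size}")
    if series.std() == 0:
        return 0.0
    sizes, bse = _block_sem_curve(series)
    a0 = float(bse[-1])
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            p1, _ = curve_fit(
                _single_exp, sizes, bse, p0=[a0, max(sizes.mean(), 1.0)],
                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10_000,
            )
            rss1 = float(np.sum((bse - _single_exp(sizes, *p1)) ** 2))
            fits.append((rss1, p1[0]))
        except (RuntimeError, ValueError):
            pass
        try:
            p2, _ = curve_fit(
                _double_exp, sizes, bse,
                p0=[a0, 0.5, max(sizes.mean() / 10, 1.0), max(sizes.mean(), 2.0)],
                bounds=([0, 0, 1e-9, 1e-9], [np.inf, 1, np.inf, np.inf]),
                maxfev=10_000,
            )
            rss2 = float(np.sum((bse - _double_exp(sizes, *p2)) ** 2))
            fits.append((rss2, p2[0]))
        except (RuntimeError, ValueError):
            pass
    if not fits:
        return a0  # extrapolation failed; largest-block estimate
    fits.sort(key=lambda t: t[0])
    return float(fits[0][1])


def detect_equilibration(
    series,
    step_frames: int,
    drift_threshold: float = 1.0,
    start_override: int | None = None,
) -> int | None:
    """First start index from which the series shows no significant drift.

    Candidate starts 0, step_frames, 2*step_frames, ... each fit an ordinary
    least-squares line over the remaining segment; the drift
    |yhat(last) - yhat(first)| is compared with the segment's empirical
    standard deviation and the first start with ratio < ``drift_threshold``
    is returned.  ``None`` signals "not equilibrated".  ``start_override``
    bypasses detection (manual adjustment of the equilibrated range) and is
    logged.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n <= step_frames:
        raise ValueError("series must be longer than step_frames")
    if start_override is not None:
        logger.info("equilibration start manually overridden to index %d", start_override)
        return int(start_override)
    for start in range(0, n - step_frames, step_frames):
        seg = series[start:]
        sd = seg.std(ddof=1)
        if sd == 0:
            return start     # zero-variance segment: no drift by definition
        x = np.arange(seg.size, dtype=float)
        slope, _ = np.polyfit(x, seg, 1)
        drift = abs(slope * (seg.size - 1))
        if drift / sd < drift_threshold:
            return start
    return None


def pka_shift_energy(delta_pka: float, temperature: float = 310.0) -> float:
    """Free energy (kJ/mol) equivalent to a protonation-equilibrium shift.

    One pKa unit corresponds to R T ln10, i.e. 5.93 kJ/mol at 310 K.
    """
    return rt_ln10(temperature) * delta_pka
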