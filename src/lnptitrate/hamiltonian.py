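"""The lambda-dependent potentials of the constant-pH Hamiltonian.

Three analytical terms act on each titration coordinate lambda (0 = protonated,
1 = deprotonated):

* ``V_MM`` -- the correction potential, defined as the *negative* of the
  deprotonation free energy of the isolated compound, represented as a
  polynomial whose coefficients are obtained from thermodynamic integration
  (TI) of <dV/dlambda> over a window grid;
* ``V_bias`` -- a symmetric double-well barrier that keeps lambda near the
  physical end states 0 and 1 while still permitting barrier crossings;
* ``V_pH`` -- the linear pH driving force ``R T ln10 (pKa_ref - pH) lambda``,
  the unique (up to a constant) form for which an ideal site titrates along
  the Henderson-Hasselbalch curve.

Site charges interpolate linearly in lambda between the protonated and
deprotonated totals; lambda is deliberately *not* clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "CorrectionPolynomial",
    "BiasPotential",
    "PHPotentialParams",
    "TIDataset",
    "TitratableGroup",
    "default_lambda_grid",
    "eval_vmm",
    "eval_vbias",
    "eval_vph",
    "sample_ti",
    "fit_correction",
    "site_charge",
    "running_mean",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionPolynomial:
    """Polynomial representation of the correction potential V_MM(lambda).

    Coefficients are stored low-to-high order (numpy polynomial convention)
    and give the energy in kJ/mol as a function of the dimensionless lambda.
    The JSON serialization writes them high-to-low order, documented in the
    file header.
    """

    coefficients: tuple[float, ...]
    domain_lo: float = -0.10
    domain_hi: float = 1.10

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if len(self.coefficients) == 0:
            raise ValueError("CorrectionPolynomial needs at least one coefficient")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("CorrectionPolynomial coefficients must be finite")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, lam):
        return eval_vmm(lam, self)

    def dvdl(self, lam):
        """Derivative dV_MM/dlambda (no domain check; used for forces)."""
        return P.polyval(np.asarray(lam, dtype=float), P.polyder(self.coefficients))

    def to_dict(self) -> dict:
        return {
            "_comment": "coefficients are high-to-low order, kJ/mol vs dimensionless lambda",
            "coefficients_high_to_low": list(self.coefficients[::-1]),
            "order": self.order,
            "domain": [self.domain_lo, self.domain_hi],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionPolynomial":
        lo, hi = d["domain"]
        return cls(tuple(d["coefficients_high_to_low"][::-1]), lo, hi)


@dataclass(frozen=True)
class BiasPotential:
    """Symmetric barrier biasing lambda toward its end states.

    The barrier ``h (1 - cos(pi lambda)^(2 m))`` vanishes exactly at
    lambda = 0 and 1, is symmetric about 0.5, and reaches its maximum
    ``barrier_height`` at 0.5.  Its end wells are harmonic and centred
    exactly on the physical states; the sharpness exponent ``m`` stiffens
    them so that, together with the quartic soft walls engaging
    ``wall_onset`` beyond the end states, the equilibrium occupancy ratio
    of the two classified wells tracks the Boltzmann factor of the driving
    free energy to better than 1e-3 in the deprotonated fraction over a
    +-5 pH-unit tilt (verified by direct quadrature of the potential).
    """

    barrier_height: float = 7.5     # kJ/mol
    wall_strength: float = 1.0e4    # kJ/mol per (unit lambda)^4
    wall_onset: float = 0.10
    barrier_sharpness: int = 4      # exponent m of the cos^(2m) barrier

    def __post_init__(self):
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be non-negative")
        if self.wall_strength < 0 or self.wall_onset < 0:
            raise ValueError("wall parameters must be non-negative")


@dataclass(frozen=True)
class PHPotentialParams:
    """Parameters of the pH driving potential V_pH(lambda)."""

    ph: float
    pka_ref: float
    temperature: float = 310.0      # K
    gas_constant: float = 8.314     # J mol^-1 K^-1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class TIDataset:
    """Per-window averages of dV/dlambda from thermodynamic integration."""

    lambda_grid: np.ndarray
    mean_dvdl: np.ndarray
    sem_dvdl: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.lambda_grid, dtype=float)
        object.__setattr__(self, "lambda_grid", grid)
        object.__setattr__(self, "mean_dvdl", np.asarray(self.mean_dvdl, dtype=float))
        object.__setattr__(self, "sem_dvdl", np.asarray(self.sem_dvdl, dtype=float))
        object.__setattr__(self, "n_samples", np.asarray(self.n_samples, dtype=int))
        n = len(grid)
        if n == 0:
            raise ValueError("TIDataset requires a non-empty lambda grid")
        if any(len(a) != n for a in (self.mean_dvdl, self.sem_dvdl, self.n_samples)):
            raise ValueError("TIDataset arrays must share one length")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("lambda_grid must be strictly increasing")

    def to_table(self, path) -> None:
        """Write a whitespace-delimited text table ('#' comment header)."""
        data = np.column_stack(
            [self.lambda_grid, self.mean_dvdl, self.sem_dvdl, self.n_samples]
        )
        np.savetxt(
            path, data,
            header="lambda mean_dvdl_kJ_mol sem_dvdl_kJ_mol n_samples",
            fmt=["%.10g", "%.10g", "%.10g", "%d"],
        )

    @classmethod
    def from_table(cls, path) -> "TIDataset":
        data = np.atleast_2d(np.loadtxt(path, comments="#"))
        if data.shape[1] < 4:
            raise ValueError("TI table needs 4 columns: lambda, mean, sem, n")
        return cls(data[:, 0], data[:, 1], data[:, 2], data[:, 3].astype(int))


@dataclass(frozen=True)
class TitratableGroup:
    """Charge bookkeeping for one titratable amine."""

    q_protonated_total: float = 1.0
    q_deprotonated_total: float = 0.0
    q_proton: float = 0.323          # bookkeeping only
    pka_ref: float = 9.26


def default_lambda_grid() -> np.ndarray:
    """The 25-window TI grid: lambda from -0.10 to 1.10, spacing 0.05."""
    return np.linspace(-0.10, 1.10, 25)


# --------------------------------------------------------------------------
# potential evaluation
# --------------------------------------------------------------------------

def eval_vmm(lam, poly: CorrectionPolynomial):
    """Evaluate the correction potential V_MM(lambda) in kJ/mol.

    Raises a domain error when lambda leaves [domain_lo, domain_hi]; the fit
    is only trusted on the TI window range.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < poly.domain_lo):
        raise ValueError(
            f"lambda below correction-polynomial domain bound domain_lo={poly.domain_lo}"
        )
    if np.any(lam > poly.domain_hi):
        raise ValueError(
            f"lambda above correction-polynomial domain bound domain_hi={poly.domain_hi}"
        )
    out = P.polyval(lam, poly.coefficients)
    return float(out) if out.ndim == 0 else out


def _int_pow(x, n: int):
    # repeated multiplication: numpy's array ** int is far slower
    out = np.ones_like(x)
    base = x
    while n:
        if n & 1:
            out = out * base
        n >>= 1
        if n:
            base = base * base
    return out


def _bias_barrier(lam, bias: BiasPotential):
    c = np.cos(np.pi * lam)
    return bias.barrier_height * (1.0 - _int_pow(c, 2 * bias.barrier_sharpness))


def eval_vbias(lam, bias: BiasPotential):
    """Barrier-plus-walls bias potential in kJ/mol.

    Zero at lambda = 0 and 1, symmetric about 0.5, maximum ``barrier_height``
    at 0.5; quartic repulsive walls outside [-wall_onset, 1 + wall_onset].
    """
    lam = np.asarray(lam, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    v = np.asarray(_bias_barrier(lam, bias), dtype=float)
    lo = -bias.wall_onset
    hi = 1.0 + bias.wall_onset
    below = lam < lo
    if below.any():
        v[below] += bias.wall_strength * _int_pow(lo - lam[below], 4)
    above = lam > hi
    if above.any():
        v[above] += bias.wall_strength * _int_pow(lam[above] - hi, 4)
    return float(v[0]) if scalar else v


def eval_vbias_force(lam, bias: BiasPotential):
    """-dV_bias/dlambda (analytic), used by the stochastic integrator."""
    lam = np.asarray(lam, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    m = bias.barrier_sharpness
    dbump = (
        2.0 * m * np.pi * bias.barrier_height
        * _int_pow(np.cos(np.pi * lam), 2 * m - 1) * np.sin(np.pi * lam)
    )
    lo = -bias.wall_onset
    hi = 1.0 + bias.wall_onset
    below = lam < lo
    if below.any():
        dbump[below] += -4.0 * bias.wall_strength * _int_pow(lo - lam[below], 3)
    above = lam > hi
    if above.any():
        dbump[above] += 4.0 * bias.wall_strength * _int_pow(lam[above] - hi, 3)
    out = -dbump
    return float(out[0]) if scalar else out


def eval_vph(lam, params: PHPotentialParams):
    """pH driving potential V_pH(lambda) = R T ln10 (pKa_ref - pH) lambda, kJ/mol."""
    lam = np.asarray(lam, dtype=float)
    rtln10 = params.gas_constant * 1e-3 * params.temperature * np.log(10.0)
    out = rtln10 * (params.pka_ref - params.ph) * lam
    return float(out) if out.ndim == 0 else out


def site_charge(lam, group: TitratableGroup):
    """Linear charge interpolation (1-lambda) q_prot + lambda q_deprot, in e.

    lambda is intentionally not clamped: transient excursions outside [0, 1]
    carry slightly over/under-compensated charge, exactly as in the linear
    interpolation contract of the constant-pH electrostatics.
    """
    lam = np.asarray(lam, dtype=float)
    out = (1.0 - lam) * group.q_protonated_total + lam * group.q_deprotonated_total
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# thermodynamic integration workflow
# --------------------------------------------------------------------------

def _numeric_derivative(f: Callable[[float], float], x: float, h: float = 1e-6) -> float:
    return (f(x + h) - f(x - h)) / (2.0 * h)


def sample_ti(
    toy_dg: Callable[[float], float],
    grid: Sequence[float] | None = None,
    n_samples: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TIDataset:
    """Emulate TI sampling of <dG_MM/dlambda> on a window grid.

    ``toy_dg`` is a model deprotonation free energy dG_MM(lambda); each window
    draws ``n_samples`` observations of its derivative plus Gaussian noise of
    standard deviation ``noise_sd``, and records their mean and standard error.
    Deterministic for a fixed seed.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("TI window grid must not be empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.empty_like(grid)
    sems = np.empty_like(grid)
    for i, lam in enumerate(grid):
        deriv = _numeric_derivative(toy_dg, float(lam))
        if noise_sd > 0:
            samples = deriv + rng.normal(0.0, noise_sd, size=n_samples)
            means[i] = samples.mean()
            sems[i] = samples.std(ddof=1) / np.sqrt(n_samples) if n_samples > 1 else 0.0
        else:
            means[i] = deriv
            sems[i] = 0.0
    return TIDataset(grid, means, sems, np.full(grid.shape, n_samples, dtype=int))


def running_mean(samples: np.ndarray) -> np.ndarray:
    """Cumulative running mean of a per-window sample stream.

    Convergence of a TI window is monitored by eye on this curve; no
    automatic stopping rule is imposed.
    """
    samples = np.asarray(samples, dtype=float)
    return np.cumsum(samples) / np.arange(1, samples.size + 1)


def fit_correction(ti: TIDataset, order: int = 9) -> CorrectionPolynomial:
    """Least-squares polynomial fit of the correction potential from TI data.

    The polynomial of the given order is fitted to the *negated* window means
    (dV_MM/dlambda = -dG_MM/dlambda) and integrated analytically with
    V_MM(0) = 0; the additive constant is physically irrelevant since only
    forces act on lambda.
    """
    n_windows = ti.lambda_grid.size
    if n_windows < order + 1:
        raise ValueError(
            f"need at least order+1={order + 1} TI windows to fit order {order}; got {n_windows}"
        )
    deriv_coeffs = P.polyfit(ti.lambda_grid, -ti.mean_dvdl, order)
    v_coeffs = P.polyint(deriv_coeffs)  # integration constant 0 => V_MM(0) = 0
    lo = float(ti.lambda_grid[0])
    hi = float(ti.lambda_grid[-1])
    return CorrectionPolynomial(tuple(v_coeffs), domain_lo=lo, domain_hi=hi)
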