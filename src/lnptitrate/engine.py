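"""Desk-scale stochastic lambda-dynamics for titratable membrane lipids.

Each titratable site carries two slow coordinates: the titration coordinate
``lambda`` (0 = protonated amine, 1 = deprotonated) and a signed insertion
depth ``d`` along the membrane normal (d < 0 inside the membrane, d > 0 in
the solvent).  Both evolve by overdamped stochastic dynamics with a
Metropolis acceptance step (MALA), so the stationary distribution of each
conditional move is exactly Boltzmann at the configured temperature:

* the lambda move feels the barrier bias V_bias plus a linear driving term
  ``dG_eff * lambda``, where dG_eff collects the pH driving force at the
  site's local pKa(d), a mean-field anti-cooperative penalty from protonated
  neighbours in the same 0.25 nm depth bin, and (optionally) stabilization of
  the protonated state near static anionic mRNA loci;
* the depth move feels a protonation-state-dependent double well -- a
  protonated well at the membrane surface and a deprotonated well in the
  hydrophobic core -- interpolated linearly in lambda.

The coupling reproduces the phenomenology of ionizable-lipid membranes:
protonation switching on a fast (nanosecond-equivalent) timescale riding on
slow depth migration, bimodal lambda histograms, and monotone depth profiles
of the deprotonated fraction.

Sites whose lambda runs past the re-initialization threshold (1.15, mirrored
at -0.15) are reset to the nearest physical end state, as the bookkeeping of
buffer particles requires in the reference scheme.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from ._constants import rt_kj, rt_ln10
from .hamiltonian import (
    BiasPotential,
    TitratableGroup,
    _int_pow,
    eval_vbias,
    site_charge,
)
from .titration import LambdaTrajectory, LAMBDA_PROT, LAMBDA_DEPROT

logger = logging.getLogger(__name__)

__all__ = [
    "SiteState",
    "DepthPKaProfile",
    "EngineConfig",
    "BufferLedger",
    "ToyEngine",
    "IntegrationError",
    "effective_dg",
    "langevin_step",
    "reinit_check",
    "buffer_ledger",
    "run_titration",
    "validate_bias_distribution",
]


class IntegrationError(RuntimeError):
    """Raised when the stochastic integrator produces non-finite forces."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SiteState:
    """State of one titratable site."""

    site_id: int
    lam: float
    z: float               # nm, signed depth-axis coordinate
    leaflet: str = "upper"  # {"upper", "lower"}

    @property
    def protonation(self) -> str | None:
        """Pure function of lambda: 'protonated' iff lambda < 0.2,
        'deprotonated' iff lambda > 0.8, else None (undefined)."""
        if self.lam < LAMBDA_PROT:
            return "protonated"
        if self.lam > LAMBDA_DEPROT:
            return "deprotonated"
        return None


@dataclass(frozen=True)
class DepthPKaProfile:
    """Sigmoidal local-pKa profile versus insertion depth.

    The apparent pKa interpolates between ``surface_pka`` at the
    solvent-lipid interface (d = 0) and ``core_pka`` deep inside the
    membrane, with a logistic midpoint at ``midpoint_depth`` (nm, negative)
    and slope ``steepness`` (1/nm).  The profile is monotone non-increasing
    from the surface into the membrane.
    """

    surface_pka: float = 7.5
    core_pka: float = 4.0
    midpoint_depth: float = -0.5
    steepness: float = 6.0

    def __post_init__(self):
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.surface_pka < self.core_pka:
            raise ValueError("profile must not increase with depth")

    def local_pka(self, d):
        d = np.asarray(d, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-self.steepness * (d - self.midpoint_depth)))
        out = self.core_pka + (self.surface_pka - self.core_pka) * sig
        return float(out) if out.ndim == 0 else out

    def local_pka_grad(self, d):
        """d pKa_app / d depth (1/nm), used by the depth force."""
        d = np.asarray(d, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-self.steepness * (d - self.midpoint_depth)))
        out = (self.surface_pka - self.core_pka) * self.steepness * sig * (1.0 - sig)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of the toy lambda/depth engine.

    ``lambda_diffusion`` and ``depth_diffusion`` are the mobilities of the
    overdamped integrator (the stated dynamics carries no lambda mass);
    defaults give protonation switching every ~0.1-0.5 ns-equivalent at
    pH = pKa under the 7.5 kJ/mol barrier, much faster than surface/core
    depth relaxation.
    """

    n_sites: int = 1
    temperature: float = 310.0          # K
    timestep: float = 0.1               # ps
    lambda_diffusion: float = 5e-3      # 1/ps
    depth_diffusion: float = 5e-4       # nm^2/ps
    seed: int = 0
    reinit_threshold: float = 1.15
    anticoop_strength: float = 0.0      # kJ/mol per unit local protonated fraction
    depth_profile: DepthPKaProfile | None = None
    depth_well_depths: tuple[float, float] = (0.0, 0.0)  # kJ/mol (surface, core)
    mrna_loci: tuple[tuple[float, float], ...] | None = None  # (depth nm, kJ/mol)
    pka_ref: float = 9.26
    bias: BiasPotential = field(default_factory=BiasPotential)
    bin_width: float = 0.25             # nm, mean-field neighbourhood bin
    well_surface_center: float = 0.0    # nm depth of protonated well
    well_core_center: float = -2.2      # nm depth of deprotonated well
    well_width: float = 0.5             # nm, Gaussian sigma of both wells
    mrna_width: float = 0.4             # nm, Gaussian sigma of mRNA loci
    depth_bounds: tuple[float, float] | None = None  # (d_min, d_max) soft walls
    wall_strength_z: float = 50.0       # kJ/mol/nm^4
    thickness_bilayer: float = 4.0      # nm
    thickness_schedule: bool = False
    init_lambda: float = 0.0
    init_depth: float = 0.0
    init_equilibrium: bool = False  # draw initial lambda from the HH law at pKa_ref

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.mrna_loci is not None:
            object.__setattr__(
                self, "mrna_loci", tuple((float(z), float(s)) for z, s in self.mrna_loci)
            )

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bias"] = asdict(self.bias)
        if self.depth_profile is not None:
            d["depth_profile"] = asdict(self.depth_profile)
        if self.mrna_loci is not None:
            d["mrna_loci"] = [list(pair) for pair in self.mrna_loci]
        d["depth_well_depths"] = list(self.depth_well_depths)
        if self.depth_bounds is not None:
            d["depth_bounds"] = list(self.depth_bounds)
        return d

    def to_yaml(self, path) -> None:
        import yaml
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        import yaml
        from pathlib import Path

        d = yaml.safe_load(Path(path).read_text())
        d["bias"] = BiasPotential(**d["bias"])
        if d.get("depth_profile") is not None:
            d["depth_profile"] = DepthPKaProfile(**d["depth_profile"])
        if d.get("mrna_loci") is not None:
            d["mrna_loci"] = tuple(tuple(pair) for pair in d["mrna_loci"])
        d["depth_well_depths"] = tuple(d["depth_well_depths"])
        if d.get("depth_bounds") is not None:
            d["depth_bounds"] = tuple(d["depth_bounds"])
        return cls(**d)


@dataclass(frozen=True)
class BufferLedger:
    """Collective charge reservoir keeping the system neutral."""

    n_buffer: int
    collective_charge: float

    @staticmethod
    def rule(n_sites: int) -> int:
        """Buffer particle count 2 N + 1 for N titratable sites."""
        return 2 * n_sites + 1


# --------------------------------------------------------------------------
# energetics
# --------------------------------------------------------------------------

def _local_pka_arr(d, config: EngineConfig):
    if config.depth_profile is None:
        return np.full_like(np.asarray(d, dtype=float), config.pka_ref)
    return config.depth_profile.local_pka(d)


def _mrna_gauss(d, h, leaflet_sign, config: EngineConfig):
    """Protonated-state stabilization (kJ/mol, >= 0) at depth d.

    Loci are specified as (insertion depth, strength); anionic nucleotide
    strands buried in the core stabilize nearby protonated amines.  The
    depth convention keeps the loci attached to each leaflet surface as the
    membrane thickens.
    """
    if not config.mrna_loci:
        return np.zeros_like(np.asarray(d, dtype=float))
    d = np.asarray(d, dtype=float)
    total = np.zeros_like(d)
    s2 = 2.0 * config.mrna_width**2
    for d0, strength in config.mrna_loci:
        total = total + strength * np.exp(-((d - d0) ** 2) / s2)
    return total


def effective_dg(
    site: SiteState,
    local_protonated_fraction: float,
    config: EngineConfig,
    ph: float,
) -> float:
    """Free-energy difference (kJ/mol) of the lambda = 0 -> 1 transition.

    ``R T ln10 (pKa_app(d) - pH)`` plus an anti-cooperative term
    ``anticoop_strength * (1 - f_prot_local)`` that destabilizes the
    protonated state when the local neighbourhood is crowded with protonated
    sites, plus the mRNA stabilization of the protonated state.  Reduces to
    the ideal pH driving force when the profile is flat at pKa_ref and the
    couplings vanish.
    """
    h = config.thickness_bilayer / 2.0
    sign = 1.0 if site.leaflet == "upper" else -1.0
    d = site.z - h if site.leaflet == "upper" else -h - site.z
    pka_app = float(_local_pka_arr(np.asarray(d), config))
    dg = rt_ln10(config.temperature) * (pka_app - ph)
    dg += config.anticoop_strength * (1.0 - local_protonated_fraction)
    dg += float(_mrna_gauss(np.asarray(d), h, np.asarray(sign), config))
    return dg


# --------------------------------------------------------------------------
# the engine
# --------------------------------------------------------------------------

class ToyEngine:
    """Vectorized MALA integrator for batches of replica systems.

    Internally the state is shaped (n_replicas, n_sites); every replica row
    is an independent system (its own pH, mean-field neighbourhood, and
    membrane thickness), which lets one engine advance a whole titration
    grid at once.
    """

    def __init__(
        self,
        config: EngineConfig,
        ph: float | Sequence[float],
        n_replicas: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.config = config
        ph = np.atleast_1d(np.asarray(ph, dtype=float))
        if ph.size == 1:
            ph = np.repeat(ph, n_replicas)
        elif ph.size != n_replicas:
            raise ValueError("ph must be scalar or one value per replica")
        self.ph = ph[:, None]                     # (R, 1)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        R, S = n_replicas, config.n_sites
        self.lam = np.full((R, S), float(config.init_lambda))
        self.d = np.full((R, S), float(config.init_depth))
        if config.init_equilibrium:
            # draw the starting state from the model's own equilibrium;
            # removes the protonated-start transient in equilibrium studies
            if config.depth_profile is None:
                p_deprot = 1.0 / (np.power(10.0, config.pka_ref - ph[:, None]) + 1.0)
                self.lam = (self.rng.random((R, S)) < p_deprot).astype(float)
            else:
                self._init_joint_equilibrium()
        # first half upper leaflet, second half lower
        sign = np.ones(S)
        sign[S // 2:] = -1.0 if S > 1 else 1.0
        self.leaflet_sign = np.broadcast_to(sign, (R, S)).copy()
        self.h = np.full((R, 1), config.thickness_bilayer / 2.0)
        self.time = 0.0
        self.n_reinit = 0
        self.reinit_events: list[tuple[float, int, int]] = []  # capped log
        self._reinit_log_cap = 1000
        self._beta = 1.0 / rt_kj(config.temperature)

    def _init_joint_equilibrium(self) -> None:
        """Sample (z, lambda) starts from the joint equilibrium by quadrature.

        The depth marginal is rho0(z) (1 + 10^(pH - pKa_local(z))) with rho0
        the protonated-state density; lambda is then an end-state Bernoulli
        draw from the local titration odds.
        """
        cfg = self.config
        lo, hi = cfg.depth_bounds if cfg.depth_bounds is not None else (-3.5, 1.0)
        z = np.linspace(lo, hi, 1001)
        w2 = 2.0 * cfg.well_width**2
        e_surf, e_core = cfg.depth_well_depths
        gs = e_surf * np.exp(-((z - cfg.well_surface_center) ** 2) / w2)
        gc = e_core * np.exp(-((z - cfg.well_core_center) ** 2) / w2)
        rho0 = np.exp((gs + gc) / rt_kj(cfg.temperature))
        pka_local = cfg.depth_profile.local_pka(z)
        R, S = self.lam.shape
        for r in range(R):
            odds = np.power(10.0, self.ph[r, 0] - pka_local)
            w = rho0 * (1.0 + odds)
            idx = self.rng.choice(z.size, size=S, p=w / w.sum())
            self.d[r] = z[idx]
            p_dep = odds[idx] / (1.0 + odds[idx])
            self.lam[r] = (self.rng.random(S) < p_dep).astype(float)

    # -- energetics on arrays ------------------------------------------------

    def _dg_eff(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear driving of the lambda move, split into (raw, clipped) parts.

        The pH driving force acts on raw lambda (it is defined for the
        whole titration coordinate); the depth-profile, neighbour and mRNA
        couplings act on the clipped charge-interpolation coordinate, the
        same convention the depth potential uses.  The lambda = 0 -> 1
        difference equals effective_dg in both conventions.
        """
        cfg = self.config
        rtl = rt_ln10(cfg.temperature)
        core = cfg.depth_profile.core_pka if cfg.depth_profile is not None else cfg.pka_ref
        dg_raw = np.broadcast_to(rtl * (core - self.ph), self.lam.shape)
        dg_clip = np.zeros_like(self.lam)
        if cfg.depth_profile is not None:
            dg_clip = dg_clip + rtl * (_local_pka_arr(self.d, cfg) - core)
        if cfg.anticoop_strength != 0.0:
            f = self._local_protonated_fraction()
            dg_clip = dg_clip + cfg.anticoop_strength * (1.0 - f)
        if cfg.mrna_loci:
            dg_clip = dg_clip + _mrna_gauss(self.d, self.h, self.leaflet_sign, cfg)
        return dg_raw, dg_clip

    def _local_protonated_fraction(self) -> np.ndarray:
        """Per-site mean-field protonated fraction in its 0.25 nm depth bin."""
        cfg = self.config
        R, S = self.lam.shape
        bins = np.floor(self.d / cfg.bin_width).astype(int)
        bins -= bins.min()
        stride = bins.max() + 1
        flat = (np.arange(R)[:, None] * stride + bins).ravel()
        prot = (self.lam < LAMBDA_PROT).ravel().astype(float)
        clas = ((self.lam < LAMBDA_PROT) | (self.lam > LAMBDA_DEPROT)).ravel().astype(float)
        size = R * stride
        n_prot = np.bincount(flat, weights=prot, minlength=size)
        n_clas = np.bincount(flat, weights=clas, minlength=size)
        with np.errstate(invalid="ignore"):
            frac = np.where(n_clas > 0, n_prot / np.maximum(n_clas, 1), 0.5)
        return frac[flat].reshape(R, S)

    def _uf_lambda(self, lam, dg_raw, dg_clip):
        """Fused (energy, force) of the lambda conditional (shared trig)."""
        bias = self.config.bias
        m = bias.barrier_sharpness
        c = np.cos(np.pi * lam)
        s = np.sin(np.pi * lam)
        c2m1 = _int_pow(c, 2 * m - 1)
        inside = (lam > 0.0) & (lam < 1.0)
        u = (
            bias.barrier_height * (1.0 - c2m1 * c)
            + dg_raw * lam
            + dg_clip * np.clip(lam, 0.0, 1.0)
        )
        dv = 2.0 * m * np.pi * bias.barrier_height * c2m1 * s + dg_raw + dg_clip * inside
        lo = -bias.wall_onset
        hi = 1.0 + bias.wall_onset
        below = lam < lo
        if below.any():
            u[below] += bias.wall_strength * _int_pow(lo - lam[below], 4)
            dv[below] += -4.0 * bias.wall_strength * _int_pow(lo - lam[below], 3)
        above = lam > hi
        if above.any():
            u[above] += bias.wall_strength * _int_pow(lam[above] - hi, 4)
            dv[above] += 4.0 * bias.wall_strength * _int_pow(lam[above] - hi, 3)
        return u, -dv

    def _uf_depth(self, d, lam):
        """Fused (energy, force) of the depth conditional.

        The depth potential is the z-section of the joint (lambda, z)
        measure whose lambda-section is the local titration law:

            U_z(z, lam) = -E_core g_core(z) - E_surf g_surf(z)
                          - (1 - lam) G_mrna(z)
                          + lam R T ln10 (pKa_app(z) - core_pKa)  + walls

        Protonated sites sit in the surface well; deprotonated sites are
        driven down the pKa profile into the core attractor.  The
        lambda-linear profile term is the thermodynamic twin of the
        lambda-move's pH driving force, so local occupancies and depth
        populations derive from one Boltzmann measure.
        """
        cfg = self.config
        lam_c = np.clip(lam, 0.0, 1.0)
        e_surf, e_core = cfg.depth_well_depths
        s2 = 2.0 * cfg.well_width**2
        dxs = d - cfg.well_surface_center
        dxc = d - cfg.well_core_center
        gs = e_surf * np.exp(-(dxs * dxs) / s2)
        gc = e_core * np.exp(-(dxc * dxc) / s2)
        u = -gs - gc
        du = -(gs * (2.0 * dxs / s2) + gc * (2.0 * dxc / s2))  # -dU/dd so far
        if cfg.depth_profile is not None:
            prof = cfg.depth_profile
            rtl = rt_ln10(cfg.temperature)
            u = u + lam_c * rtl * (prof.local_pka(d) - prof.core_pka)
            du = du - lam_c * rtl * prof.local_pka_grad(d)
        if cfg.mrna_loci:
            g = _mrna_gauss(d, self.h, self.leaflet_sign, cfg)
            u = u - (1.0 - lam_c) * g
            eps = 1e-5
            gu = _mrna_gauss(d + eps, self.h, self.leaflet_sign, cfg)
            gl = _mrna_gauss(d - eps, self.h, self.leaflet_sign, cfg)
            du = du + (1.0 - lam_c) * (gu - gl) / (2.0 * eps)
        if cfg.depth_bounds is not None:
            lo, hi = cfg.depth_bounds
            below = d < lo
            if below.any():
                u[below] += cfg.wall_strength_z * _int_pow(lo - d[below], 4)
                du[below] += 4.0 * cfg.wall_strength_z * _int_pow(lo - d[below], 3)
            above = d > hi
            if above.any():
                u[above] += cfg.wall_strength_z * _int_pow(d[above] - hi, 4)
                du[above] -= 4.0 * cfg.wall_strength_z * _int_pow(d[above] - hi, 3)
        return u, du

    def _u_depth(self, d, lam):
        return self._uf_depth(d, lam)[0]

    def _f_depth(self, d, lam):
        return self._uf_depth(d, lam)[1]

    # -- moves ----------------------------------------------------------------

    def _mala_move(self, x, uf_fn, mobility):
        if mobility <= 0.0:
            return x
        dt = self.config.timestep
        c = self._beta * mobility * dt
        ux, fx = uf_fn(x)
        if not np.all(np.isfinite(fx)):
            bad = np.argwhere(~np.isfinite(np.atleast_2d(fx)))
            raise IntegrationError(f"non-finite force at (replica, site) {bad[0].tolist()}")
        drift_x = c * fx
        y = x + drift_x + np.sqrt(2.0 * mobility * dt) * self.rng.standard_normal(x.shape)
        uy, fy = uf_fn(y)
        dxy = y - x
        q = (dxy - drift_x) ** 2 - (dxy + c * fy) ** 2  # -4 m dt (lnq_fwd - lnq_rev)
        log_a = -self._beta * (uy - ux) + q / (4.0 * mobility * dt)
        accept = np.log(self.rng.random(x.shape)) < log_a
        return np.where(accept, y, x)

    def step(self) -> None:
        """Advance every replica by one timestep (lambda sweep + depth sweep)."""
        cfg = self.config
        dg_raw, dg_clip = self._dg_eff()
        self.lam = self._mala_move(
            self.lam, lambda l: self._uf_lambda(l, dg_raw, dg_clip), cfg.lambda_diffusion
        )
        self._apply_reinit()
        if cfg.depth_diffusion > 0 and (
            cfg.depth_well_depths != (0.0, 0.0)
            or cfg.depth_bounds is not None
            or cfg.mrna_loci
            or cfg.depth_profile is not None
        ):
            self.d = self._mala_move(
                self.d, lambda z: self._uf_depth(z, self.lam), cfg.depth_diffusion
            )
        elif cfg.depth_diffusion > 0:
            # free diffusion: plain Brownian update (always accepted)
            sd = np.sqrt(2.0 * cfg.depth_diffusion * cfg.timestep)
            self.d = self.d + sd * self.rng.standard_normal(self.d.shape)
        if cfg.thickness_schedule:
            self._update_thickness()
        self.time += cfg.timestep

    def _apply_reinit(self) -> None:
        thr = self.config.reinit_threshold
        hi = self.lam > thr
        lo = self.lam < -(thr - 1.0)
        n = int(hi.sum()) + int(lo.sum())
        if n:
            self.n_reinit += n
            if len(self.reinit_events) < self._reinit_log_cap:
                for r, s in np.argwhere(hi | lo)[: self._reinit_log_cap]:
                    self.reinit_events.append((self.time, int(r), int(s)))
                    logger.debug(
                        "re-initialized site %d (replica %d) at t=%.1f ps", s, r, self.time
                    )
            self.lam = np.where(hi, 1.0, self.lam)
            self.lam = np.where(lo, 0.0, self.lam)

    def _update_thickness(self) -> None:
        """Logistic thickness schedule between 1x and 5x the bilayer value."""
        prot = (self.lam < LAMBDA_PROT).sum(axis=1)
        clas = ((self.lam < LAMBDA_PROT) | (self.lam > LAMBDA_DEPROT)).sum(axis=1)
        f_prot = np.where(clas > 0, prot / np.maximum(clas, 1), 0.5)
        t = self.config.thickness_bilayer * (1.0 + 4.0 / (1.0 + np.exp((f_prot - 0.5) / 0.1)))
        self.h = (t / 2.0)[:, None]

    @property
    def z(self) -> np.ndarray:
        """Lab-frame z coordinates: sites ride with their leaflet surface."""
        return np.where(self.leaflet_sign > 0, self.h + self.d, -self.h - self.d)

    def run(self, n_steps: int, output_interval: int = 10):
        """Advance and record thinned (time, lambda, z, h) histories."""
        n_out = n_steps // output_interval
        times = np.empty(n_out)
        lam_hist = np.empty((n_out,) + self.lam.shape)
        z_hist = np.empty((n_out,) + self.d.shape)
        h_hist = np.empty((n_out, self.lam.shape[0]))
        k = 0
        for i in range(n_steps):
            self.step()
            if (i + 1) % output_interval == 0:
                times[k] = self.time
                lam_hist[k] = self.lam
                z_hist[k] = self.z
                h_hist[k] = self.h[:, 0]
                k += 1
        return times, lam_hist, z_hist, h_hist


# --------------------------------------------------------------------------
# spec-level operations
# --------------------------------------------------------------------------

def langevin_step(
    sites: list[SiteState],
    config: EngineConfig,
    ph: float,
    rng: np.random.Generator,
) -> list[SiteState]:
    """One stochastic step for a list of sites (functional wrapper).

    For long runs prefer :class:`ToyEngine`, which keeps its state in arrays.
    """
    eng = ToyEngine(config, ph, n_replicas=1, rng=rng)
    eng.lam[0] = [s.lam for s in sites]
    h = float(eng.h[0, 0])
    eng.leaflet_sign[0] = [1.0 if s.leaflet == "upper" else -1.0 for s in sites]
    eng.d[0] = [s.z - h if s.leaflet == "upper" else -h - s.z for s in sites]
    eng.step()
    z = eng.z[0]
    return [
        SiteState(s.site_id, float(eng.lam[0, i]), float(z[i]), s.leaflet)
        for i, s in enumerate(sites)
    ]


def reinit_check(sites: list[SiteState], config: EngineConfig, time: float = 0.0):
    """Reset runaway lambda coordinates to the nearest end state.

    lambda > threshold resets to 1.0 (deprotonated well); the mirror rule
    resets lambda < -(threshold - 1) to 0.0.  Returns (sites, events) with
    events logged as (time, site_id).
    """
    thr = config.reinit_threshold
    events = []
    out = []
    for s in sites:
        lam = s.lam
        if lam > thr:
            lam = 1.0
            events.append((time, s.site_id))
            logger.info("re-initialized site %d at t=%.1f ps (lambda high)", s.site_id, time)
        elif lam < -(thr - 1.0):
            lam = 0.0
            events.append((time, s.site_id))
            logger.info("re-initialized site %d at t=%.1f ps (lambda low)", s.site_id, time)
        out.append(SiteState(s.site_id, lam, s.z, s.leaflet))
    return out, events


def buffer_ledger(sites, group: TitratableGroup | None = None) -> BufferLedger:
    """Buffer bookkeeping: 2 N + 1 particles holding minus the summed site charge."""
    group = group or TitratableGroup()
    if isinstance(sites, int):
        n = sites
        total_charge = float("nan")
    else:
        lams = np.array([s.lam for s in sites], dtype=float)
        n = lams.size
        total_charge = float(np.sum(site_charge(lams, group)))
    return BufferLedger(n_buffer=BufferLedger.rule(n), collective_charge=-total_charge)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Counter-based per-stream seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_titration(
    config: EngineConfig,
    ph_values: Sequence[float],
    duration: float,
    n_replicas: int = 1,
    seed: int = 0,
    output_interval: int = 10,
):
    """Titration grid run: per-pH, per-replica lambda and z trajectories.

    All (pH, replica) systems advance in one vectorized engine; every row is
    statistically independent (the row RNG stream is drawn from a single
    generator seeded by ``seed``), and the run is bit-for-bit reproducible
    for a fixed seed.

    Returns
    -------
    runs : dict
        ``(ph, replica) -> list[LambdaTrajectory]`` (one per site).
    traces : pandas.DataFrame
        Tidy z-coordinate trace of all aminolipid sites with columns
        time_ps, ph, replica, particle_id, species, leaflet, z_nm.
    metadata : dict
        seed, config hash, pH grid, durations.
    """
    ph_values = list(ph_values)
    n_steps = int(round(duration / config.timestep))
    rows = [(ph, rep) for ph in ph_values for rep in range(n_replicas)]
    rng = np.random.default_rng(_spawn_seeds(seed, 1)[0])
    eng = ToyEngine(config, [ph for ph, _ in rows], n_replicas=len(rows), rng=rng)
    times, lam_hist, z_hist, _ = eng.run(n_steps, output_interval)

    runs: dict[tuple[float, int], list[LambdaTrajectory]] = {}
    frames = []
    leaflets = np.where(eng.leaflet_sign[0] > 0, "upper", "lower")
    for r, (ph, rep) in enumerate(rows):
        trajs = [
            LambdaTrajectory(site_id=s, times=times, lambdas=lam_hist[:, r, s])
            for s in range(config.n_sites)
        ]
        runs[(ph, rep)] = trajs
        for s in range(config.n_sites):
            frames.append(
                pd.DataFrame(
                    {
                        "time_ps": times,
                        "ph": ph,
                        "replica": rep,
                        "particle_id": s,
                        "species": "ALC0315",
                        "leaflet": leaflets[s],
                        "z_nm": z_hist[:, r, s],
                    }
                )
            )
    traces = pd.concat(frames, ignore_index=True)
    metadata = {
        "seed": seed,
        "config_hash": config.hash(),
        "ph_values": ph_values,
        "n_replicas": n_replicas,
        "duration_ps": duration,
        "output_interval": output_interval,
        "n_reinit_events": eng.n_reinit,
    }
    return runs, traces, metadata


def validate_bias_distribution(
    trajectory,
    bias: BiasPotential,
    temperature: float = 310.0,
    n_bins: int = 48,
    lo: float = -0.25,
    hi: float = 1.25,
) -> float:
    """Sup-norm discrepancy between the sampled lambda density and exp(-V_bias/RT).

    Valid only for trajectories generated with the pH driving force off and
    the correction potential exactly cancelling the model free energy (the
    validation condition pH = pKa); then p(lambda) should follow the bias
    Boltzmann factor.  Returns max_bins |p_emp - p_ref| / max(p_ref), with
    both histogrammed as probability densities on a common grid.
    """
    lam = trajectory.lambdas if isinstance(trajectory, LambdaTrajectory) else np.asarray(trajectory)
    if lam.size < 10_000:
        raise ValueError(f"insufficient data: need >= 10000 samples, got {lam.size}")
    edges = np.linspace(lo, hi, n_bins + 1)
    emp, _ = np.histogram(lam, bins=edges, density=True)
    # reference density via fine midpoint quadrature per bin
    fine = 16
    xs = np.linspace(lo, hi, n_bins * fine + 1)
    mids = 0.5 * (xs[:-1] + xs[1:])
    w = np.exp(-eval_vbias(mids, bias) / rt_kj(temperature))
    bin_mass = w.reshape(n_bins, fine).mean(axis=1) * (edges[1] - edges[0])
    ref = bin_mass / bin_mass.sum() / (edges[1] - edges[0])
    return float(np.max(np.abs(emp - ref)) / ref.max())
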