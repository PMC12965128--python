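"""Synthetic-data presets standing in for the study's simulation systems.

Two kinds of generators live here:

* *parametric* generators that draw titration tables and surface-charge
  series directly from the (generalized) Henderson-Hasselbalch model plus
  Gaussian noise -- the stand-ins for published titration and charge-density
  figures; and
* *mechanistic* generators that run the toy lambda/depth engine with a
  calibrated depth-pKa profile and emit particle traces (DSPC phosphate
  surfaces, cholesterol, PEG-lipid, water) with the qualitative spatial
  organization of an ionizable-lipid nanoparticle membrane: helper lipids at
  the surface, deprotonated aminolipids and part of the cholesterol in the
  core, water excluded from the core unless anionic mRNA loci are present,
  and a membrane that thickens as aminolipids deprotonate.

All calibration targets live in ``calibration.yaml`` shipped with the
package; every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import DepthPKaProfile, EngineConfig, run_titration
from .titration import TitrationPoint, ghh, hh

__all__ = [
    "ScenarioPreset",
    "load_calibration",
    "get_preset",
    "PRESET_NAMES",
    "generate_titration_table",
    "generate_patch_traces",
    "generate_surface_charge_series",
    "ti_toy_dg",
]

PRESET_NAMES = (
    "single_lipid_water",
    "lnp_patch",
    "lnp_patch_x4",
    "lnp_mrna",
    "surface_charge",
    "tns_probe",
    "ti_toy",
)

#: lipid composition of the basis membrane patch (ALC-0315:DSPC:CHOL:ALC-0159)
PATCH_COMPOSITION = {"ALC0315": 122, "DSPC": 24, "CHOL": 112, "ALC0159": 6}
PATCH_X4_COMPOSITION = {k: 4 * v for k, v in PATCH_COMPOSITION.items()}

# pH grids carry the 0.17-unit offset of the study's titration protocols.
SINGLE_LIPID_PH_GRID = tuple(np.round(np.arange(4.17, 14.18, 1.0), 2))   # 11 values
PATCH_PH_GRID = tuple(np.round(np.arange(3.17, 11.18, 1.0), 2))          # 9 values


@lru_cache(maxsize=1)
def load_calibration() -> dict:
    """Calibration constants shipped with the package (read-only)."""
    ref = importlib.resources.files("lnptitrate") / "calibration.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class ScenarioPreset:
    """A named study condition: composition, pH grid, calibration targets."""

    name: str
    composition: dict = field(default_factory=dict)
    ph_grid: tuple[float, ...] = ()
    calibration: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition counts must be non-negative")
        if list(self.ph_grid) != sorted(self.ph_grid):
            raise ValueError("ph_grid must be sorted")

    def engine_config(self, seed: int = 0) -> EngineConfig:
        """Build the toy-engine configuration realizing this preset."""
        cal = load_calibration()
        if self.name == "single_lipid_water":
            return EngineConfig(
                n_sites=1,
                seed=seed,
                pka_ref=cal["intrinsic_pka"],
                depth_profile=None,
                depth_well_depths=(0.0, 0.0),
                depth_diffusion=0.0,
            )
        patch = cal["patch"]
        profile = DepthPKaProfile(**patch["profile"])
        mrna = None
        if self.name == "lnp_mrna":
            mrna = ((patch["mrna_depth_nm"], patch["mrna_strength_kj"]),)
        return EngineConfig(
            n_sites=self.composition.get("ALC0315", 122),
            seed=seed,
            pka_ref=cal["intrinsic_pka"],
            depth_profile=profile,
            depth_well_depths=(patch["well_surface_kj"], patch["well_core_kj"]),
            anticoop_strength=patch["anticoop_kj"],
            depth_bounds=tuple(patch["depth_bounds"]),
            mrna_loci=mrna,
            thickness_bilayer=patch["thickness_bilayer"],
            thickness_schedule=True,
            init_equilibrium=True,
        )


def get_preset(name: str) -> ScenarioPreset:
    """Look up a preset by name; raises for unknown names."""
    cal = load_calibration()
    if name == "single_lipid_water":
        return ScenarioPreset(
            name,
            composition={"ALC0315": 1},
            ph_grid=SINGLE_LIPID_PH_GRID,
            calibration={"pka_ref": cal["intrinsic_pka"]},
        )
    if name in ("lnp_patch", "lnp_mrna"):
        return ScenarioPreset(
            name,
            composition=dict(PATCH_COMPOSITION),
            ph_grid=PATCH_PH_GRID,
            calibration={
                "global_pka": cal["global_apparent_pka"],
                "surface_pka": cal["local_pka_surface"],
                "surface_n": cal["surface_n"],
            },
        )
    if name == "lnp_patch_x4":
        return ScenarioPreset(
            name,
            composition=dict(PATCH_X4_COMPOSITION),
            ph_grid=PATCH_PH_GRID,
            calibration={"global_pka": cal["global_apparent_pka"]},
        )
    if name == "surface_charge":
        return ScenarioPreset(
            name,
            ph_grid=PATCH_PH_GRID,
            calibration={"pka": cal["surface_pka_lnp"]},
        )
    if name == "tns_probe":
        return ScenarioPreset(
            name,
            ph_grid=PATCH_PH_GRID,
            calibration={
                "pka": cal["surface_pka_lnp"] + cal["tns_offset"],
                "offset": cal["tns_offset"],
            },
        )
    if name == "ti_toy":
        return ScenarioPreset(name, calibration={"dg_coefficients": [0.0, -30.0, 12.0, -5.0]})
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


# --------------------------------------------------------------------------
# parametric generators
# --------------------------------------------------------------------------

def generate_titration_table(
    pka: float,
    n: float,
    ph_grid: Sequence[float],
    noise_sd: float,
    seed: int = 0,
) -> list[TitrationPoint]:
    """Sample a titration table from the generalized HH model plus noise.

    S values are the model curve plus Gaussian(0, noise_sd), clipped to
    [0, 1]; the SEM field of every point is set to ``noise_sd``.  With
    noise_sd = 0 the points lie exactly on the curve.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    pts = []
    for ph in ph_grid:
        s = ghh(ph, pka, n)
        if noise_sd > 0:
            s = float(np.clip(s + rng.normal(0.0, noise_sd), 0.0, 1.0))
        pts.append(TitrationPoint(ph=float(ph), s_deprot=s, sem=noise_sd))
    return pts


def generate_surface_charge_series(
    pka: float,
    ph_grid: Sequence[float],
    noise_sd: float,
    seed: int = 0,
    tns_offset: float = 0.0,
):
    """Normalized surface-charge-density series 1 - S(pH) plus noise.

    The protonated (charged) fraction follows 1 minus the HH curve at the
    given pKa (shifted upward by ``tns_offset`` when a probe preset is
    emulated); values are clipped to [0, 1].  The maximum of the series
    defines the rho_max normalization convention downstream.  Returns a
    :class:`~lnptitrate.spatial.ChargeDensitySeries`.
    """
    from .spatial import ChargeDensitySeries

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ph = np.asarray(ph_grid, dtype=float)
    rho = 1.0 - hh(ph, pka + tns_offset)
    if noise_sd > 0:
        rho = np.clip(rho + rng.normal(0.0, noise_sd, size=ph.size), 0.0, 1.0)
    sem = np.full(ph.size, noise_sd if noise_sd > 0 else 0.0)
    return ChargeDensitySeries(ph=ph, rho=rho, sem=sem, rho_max=float(rho.max()))


def predict_titration_curve(config: EngineConfig, ph_values: Sequence[float]):
    """Exact deprotonated fractions of the joint (lambda, depth) equilibrium.

    Two-dimensional quadrature of the engine's Boltzmann measure: for every
    pH, integrate the classified lambda wells over the depth domain.  This
    is the equilibrium the stochastic engine samples; it is used to
    calibrate preset well depths against the target global apparent pKa
    without running dynamics.
    """
    from ._constants import rt_kj, rt_ln10
    from .hamiltonian import eval_vbias

    if config.depth_profile is None or config.depth_bounds is None:
        raise ValueError("prediction needs a depth profile and depth bounds")
    rt = rt_kj(config.temperature)
    rtl = rt_ln10(config.temperature)
    prof = config.depth_profile
    e_surf, e_core = config.depth_well_depths
    lo, hi = config.depth_bounds
    z = np.linspace(lo, hi, 601)
    lam = np.linspace(-0.2, 1.3, 1501)
    vb = eval_vbias(lam, config.bias)
    lam_c = np.clip(lam, 0.0, 1.0)
    mask_p = lam < 0.2
    mask_d = lam > 0.8
    w2 = 2.0 * config.well_width**2
    gs = e_surf * np.exp(-((z - config.well_surface_center) ** 2) / w2)
    gc = e_core * np.exp(-((z - config.well_core_center) ** 2) / w2)
    pka_local = prof.local_pka(z)
    s_out = np.empty(len(ph_values))
    for i, ph in enumerate(ph_values):
        u = (
            vb[None, :]
            + rtl * (prof.core_pka - ph) * lam[None, :]
            + (rtl * (pka_local - prof.core_pka))[:, None] * lam_c[None, :]
            - gs[:, None]
            - gc[:, None]
        )
        w = np.exp(-(u - u.min()) / rt)
        z_p = np.trapezoid(w[:, mask_p], lam[mask_p], axis=1)
        z_d = np.trapezoid(w[:, mask_d], lam[mask_d], axis=1)
        s_out[i] = np.trapezoid(z_d, z) / np.trapezoid(z_p + z_d, z)
    return s_out


def predict_global_pka(config: EngineConfig) -> float:
    """HH fit of the quadrature titration curve: the emergent apparent pKa."""
    from .titration import TitrationPoint, irls_fit

    phs = np.asarray(PATCH_PH_GRID)
    s = predict_titration_curve(config, phs)
    pts = [TitrationPoint(float(p), float(v), 0.01) for p, v in zip(phs, s)]
    return irls_fit(pts, model="hh").pka


def ti_toy_dg(coefficients: Sequence[float] | None = None):
    """Toy deprotonation free energy dG_MM(lambda) for the TI workflow.

    A low-order polynomial (coefficients low-to-high, dG(0) = 0) standing in
    for the molecular-mechanics free energy of the isolated aminolipid.
    """
    if coefficients is None:
        coefficients = get_preset("ti_toy").calibration["dg_coefficients"]
    coeffs = np.asarray(coefficients, dtype=float)

    def dg(lam):
        return np.polynomial.polynomial.polyval(lam, coeffs)

    return dg


# --------------------------------------------------------------------------
# mechanistic patch generator
# --------------------------------------------------------------------------

def _helper_particle_traces(
    times: np.ndarray,
    h_series: np.ndarray,
    preset: ScenarioPreset,
    ph: float,
    rng: np.random.Generator,
    with_mrna: bool,
) -> pd.DataFrame:
    """Emit DSPC/CHOL/ALC0159/WATER (and MRNA_P) traces around the surfaces.

    DSPC phosphates and PEG-lipid headgroups sit in narrow bands at the two
    leaflet surfaces; cholesterol splits between a surface band and the core
    with a pH-dependent surface fraction (rising from ~0.4 at low pH to
    ~0.7 at high pH); water fills the solvent side and is excluded from the
    core except around mRNA loci.
    """
    comp = preset.composition
    cal = load_calibration()
    frames = []
    pid = 10_000  # offset so helper ids never collide with aminolipid site ids

    def emit(species, leaflet, z_matrix):
        nonlocal pid
        n_particles = z_matrix.shape[1]
        for j in range(n_particles):
            frames.append(
                pd.DataFrame(
                    {
                        "time_ps": times,
                        "ph": ph,
                        "replica": 0,
                        "particle_id": pid,
                        "species": species,
                        "leaflet": leaflet,
                        "z_nm": z_matrix[:, j],
                    }
                )
            )
            pid += 1

    n_t = times.size
    h = h_series[:, None]
    for sign, leaflet in ((1.0, "upper"), (-1.0, "lower")):
        n_dspc = max(comp.get("DSPC", 24) // 2, 1)
        emit("DSPC", leaflet, sign * (h + rng.normal(0.0, 0.08, size=(n_t, n_dspc))))
        n_peg = max(comp.get("ALC0159", 6) // 2, 1)
        emit("ALC0159", leaflet, sign * (h + rng.normal(0.1, 0.1, size=(n_t, n_peg))))
        # cholesterol: pH-dependent split between surface band and core
        n_chol = max(comp.get("CHOL", 112) // 2, 1)
        pka_mid = cal["global_apparent_pka"]
        f_surface = 0.40 + 0.28 / (1.0 + 10.0 ** (pka_mid - ph))
        n_surf = int(round(f_surface * n_chol))
        z_surf = sign * (h - 0.6 + rng.normal(0.0, 0.25, size=(n_t, n_surf)))
        emit("CHOL", leaflet, z_surf)
        n_core = n_chol - n_surf
        if n_core > 0:
            frac = rng.uniform(0.15, 0.85, size=(n_t, n_core))
            emit("CHOL", leaflet, sign * h * frac)
        # water: solvent side only
        n_wat = 40
        emit("WATER", leaflet, sign * (h + 0.3 + rng.exponential(0.8, size=(n_t, n_wat))))
    if with_mrna:
        # static anionic loci inside the core, with a polar hydration cavity
        d_mrna = cal["patch"]["mrna_depth_nm"]
        for sign, leaflet in ((1.0, "upper"), (-1.0, "lower")):
            z0 = sign * (h + d_mrna)
            emit("MRNA_P", leaflet, z0 + rng.normal(0.0, 0.2, size=(n_t, 2)))
            emit("WATER", leaflet, z0 + rng.normal(0.0, 0.35, size=(n_t, 6)))
    return pd.concat(frames, ignore_index=True)


def generate_patch_traces(
    preset: ScenarioPreset,
    ph: float,
    duration: float,
    seed: int = 0,
    output_interval: int = 10,
):
    """Run the engine for a membrane-patch preset and emit full traces.

    Returns (lambda trajectories, particle-trace DataFrame, surface-reference
    DataFrame of per-frame DSPC-phosphate leaflet medians).
    """
    if preset.name not in ("lnp_patch", "lnp_patch_x4", "lnp_mrna"):
        raise ValueError(f"preset {preset.name!r} is not a membrane-patch scenario")
    config = preset.engine_config(seed=seed)
    runs, amino_traces, meta = run_titration(
        config, [ph], duration, n_replicas=1, seed=seed, output_interval=output_interval
    )
    trajs = runs[(ph, 0)]
    times = trajs[0].times
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)).generate_state(1)[0])
    # the engine's half-thickness is a deterministic function of the lambda
    # history, so it can be reconstructed exactly from the trajectories
    from .titration import LAMBDA_PROT, LAMBDA_DEPROT

    h_series = np.full(times.size, config.thickness_bilayer / 2.0)
    lam_hist = np.stack([t.lambdas for t in trajs], axis=1)
    prot = (lam_hist < LAMBDA_PROT).sum(axis=1)
    clas = ((lam_hist < LAMBDA_PROT) | (lam_hist > LAMBDA_DEPROT)).sum(axis=1)
    f_prot = np.where(clas > 0, prot / np.maximum(clas, 1), 0.5)
    if config.thickness_schedule:
        h_series = 0.5 * config.thickness_bilayer * (
            1.0 + 4.0 / (1.0 + np.exp((f_prot - 0.5) / 0.1))
        )
    helpers = _helper_particle_traces(
        times, h_series, preset, ph, rng, with_mrna=preset.name == "lnp_mrna"
    )
    traces = pd.concat([amino_traces, helpers], ignore_index=True)

    surface = pd.DataFrame(
        {
            "time_ps": times,
            "median_p_upper": h_series,   # noise-free medians; the spatial module
            "median_p_lower": -h_series,  # recomputes them from the DSPC trace
        }
    )
    return trajs, traces, surface
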