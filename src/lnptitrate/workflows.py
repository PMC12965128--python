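"""End-to-end experiment protocols built from the library modules.

Each function runs one closed-loop study -- generate (or simulate) the data,
push it through the titration statistics, and return the fitted parameters
alongside the inputs -- mirroring how the analyses are run from the CLI.
Seeds derive from a single master seed through a SeedSequence split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import run_titration
from .scenarios import (
    PATCH_PH_GRID,
    generate_surface_charge_series,
    generate_titration_table,
    get_preset,
    load_calibration,
)
from .spatial import ChargeDensitySeries, fit_surface_charge
from .titration import FitResult, TitrationPoint, bootstrap_ci, irls_fit, sdeprot

__all__ = [
    "TitrationExperiment",
    "intrinsic_pka_experiment",
    "apparent_pka_experiment",
    "cooperativity_experiment",
    "surface_charge_experiment",
]

#: relative pH offsets (7 points spanning the anti-cooperative transition)
#: used for local surface-bin titrations
SURFACE_BIN_PH_OFFSETS = np.linspace(-1.8, 1.8, 7)


@dataclass(frozen=True)
class TitrationExperiment:
    """A titration table together with its fit."""

    points: list
    fit: FitResult
    target: float


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def intrinsic_pka_experiment(
    seed: int = 0,
    duration: float = 15_000.0,
    n_replicas: int = 10,
    burn_in_fraction: float = 0.1,
) -> TitrationExperiment:
    """Single-aminolipid-in-water titration: recover the intrinsic pKa.

    Runs the single-site preset (correction potential exactly cancelling the
    model free energy, reference pKa 9.26) at the 11-point pH grid
    4.17-14.17 with the configured replica count, computes S_deprot per pH
    with the 0.2/0.8 classification after discarding the initial transient,
    and fits the Henderson-Hasselbalch law by IRLS with replica-scatter
    standard errors.
    """
    preset = get_preset("single_lipid_water")
    config = preset.engine_config(seed=seed)
    phs = list(preset.ph_grid)
    runs, _, _ = run_titration(
        config, phs, duration, n_replicas=n_replicas, seed=seed, output_interval=10
    )
    points = []
    for ph in phs:
        s_vals = []
        for rep in range(n_replicas):
            lam = np.concatenate([t.lambdas for t in runs[(ph, rep)]])
            lam = lam[int(len(lam) * burn_in_fraction):]
            try:
                s_vals.append(sdeprot(lam))
            except ValueError:
                continue
        s_vals = np.asarray(s_vals)
        sem = s_vals.std(ddof=1) / np.sqrt(s_vals.size) if s_vals.size > 1 else 0.0
        points.append(
            TitrationPoint(
                ph=float(ph),
                s_deprot=float(np.clip(s_vals.mean(), 0.0, 1.0)),
                sem=float(max(sem, 1e-4)),
            )
        )
    fit = irls_fit(points, model="hh")
    return TitrationExperiment(points, fit, target=config.pka_ref)


def apparent_pka_experiment(
    seed: int = 0,
    noise_sd: float = 0.01,
    n_boot: int = 10_000,
) -> TitrationExperiment:
    """Patch-grid titration table at the calibrated global apparent pKa.

    Generates S_deprot at pH 3.17-11.17 from the HH law at the calibrated
    apparent pKa plus Gaussian noise, then fits by IRLS with a parametric
    bootstrap for the confidence interval.
    """
    cal = load_calibration()
    target = cal["global_apparent_pka"]
    s_table, s_boot = _sub_seeds(seed, 2)
    points = generate_titration_table(target, 1.0, PATCH_PH_GRID, noise_sd, seed=s_table)
    fit = bootstrap_ci(points, model="hh", n_reps=n_boot, seed=s_boot)
    return TitrationExperiment(points, fit, target=target)


def cooperativity_experiment(
    seed: int = 0,
    noise_sd: float = 0.02,
    n_boot: int = 10_000,
) -> TitrationExperiment:
    """Surface-bin titration: recover the calibrated anti-cooperativity.

    Generates a 7-point generalized-HH table at the calibrated surface
    (pKa, n) and refits (pKa, n) by IRLS plus bootstrap.
    """
    cal = load_calibration()
    pka, n = cal["local_pka_surface"], cal["surface_n"]
    grid = pka + SURFACE_BIN_PH_OFFSETS
    s_table, s_boot = _sub_seeds(seed, 2)
    points = generate_titration_table(pka, n, grid, noise_sd, seed=s_table)
    fit = bootstrap_ci(points, model="ghh", n_reps=n_boot, seed=s_boot)
    return TitrationExperiment(points, fit, target=n)


def surface_charge_experiment(
    seed: int = 0,
    noise_sd: float = 0.01,
    with_tns: bool = False,
) -> tuple[ChargeDensitySeries, FitResult, float]:
    """Surface-charge-density titration: recover pKa_LNP.

    Generates the normalized protonated-aminolipid surface density
    (1 - HH) over the patch pH grid at the calibrated surface pKa (plus
    the probe offset when ``with_tns``), renormalizes by the lowest-pH
    value (the designated reference condition), and fits the HH law.
    """
    preset = get_preset("tns_probe" if with_tns else "surface_charge")
    target = preset.calibration["pka"]
    cal = load_calibration()
    offset = cal["tns_offset"] if with_tns else 0.0
    series = generate_surface_charge_series(
        cal["surface_pka_lnp"], PATCH_PH_GRID, noise_sd,
        seed=_sub_seeds(seed, 1)[0], tns_offset=offset,
    )
    rho_ref = float(series.rho[0])  # lowest pH = fully-protonated reference
    norm = ChargeDensitySeries(
        ph=series.ph,
        rho=np.minimum(series.rho / rho_ref, 1.0 + 2.9 * series.sem),
        sem=series.sem / rho_ref,
        rho_max=rho_ref,
    )
    fit = fit_surface_charge(norm)
    return norm, fit, target
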