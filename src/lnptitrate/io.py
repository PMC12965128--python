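"""File formats and run configuration.

lambda time series use the xvg text dialect ('#' and '@' comment lines, two
whitespace-separated numeric columns time_ps / lambda); particle traces and
tabular results are CSV; run configuration round-trips through YAML; fits
and run metadata are JSON with a config hash sufficient to regenerate any
artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .titration import LambdaTrajectory, TitrationPoint

__version__ = "0.1.0"

__all__ = [
    "RunConfig",
    "Thresholds",
    "read_lambda_xvg",
    "write_lambda_xvg",
    "read_titration_csv",
    "write_titration_csv",
    "config_hash",
    "write_metadata",
]


@dataclass(frozen=True)
class Thresholds:
    """Analysis thresholds; defaults are the published protocol values."""

    lambda_prot: float = 0.2
    lambda_deprot: float = 0.8
    reinit: float = 1.15
    bin_width: float = 0.25       # nm
    core_cutoff: float = 1.8      # nm
    local_fit_z_lo: float = -1.2  # nm
    local_fit_z_hi: float = 0.2   # nm
    irls_tol: float = 1e-8
    bootstrap_reps: int = 10_000


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration (YAML round-trip)."""

    preset: str = "single_lipid_water"
    ph_values: tuple[float, ...] = ()
    duration: float = 10_000.0    # ps
    replicas: int = 1
    seed: int = 0
    out_dir: str = "results"
    titrate: bool = True
    localpka: bool = False
    coreshell: bool = False
    surfacecharge: bool = False
    densities: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ph_values"] = list(self.ph_values)
        d["thresholds"] = asdict(self.thresholds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**d.pop("thresholds", {}))
        d["ph_values"] = tuple(d.get("ph_values", ()))
        return cls(**{**d, "thresholds": thr})


def config_hash(obj) -> str:
    """Short sha256 of a canonical YAML rendering of any config mapping."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# lambda trajectories (xvg dialect)
# --------------------------------------------------------------------------

def read_lambda_xvg(path, site_id: int = 0) -> LambdaTrajectory:
    """Parse a two-column xvg-dialect lambda trajectory.

    Skips '#' and '@' lines; requires two numeric columns (time_ps, lambda)
    and strictly increasing times.  Format errors report the line number.
    """
    times, lams = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            try:
                t, lam = float(cols[0]), float(cols[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric data") from exc
            if times and t <= times[-1]:
                raise ValueError(f"{path}:{lineno}: time not strictly increasing")
            times.append(t)
            lams.append(lam)
    if not times:
        raise ValueError(f"{path}: no data rows found")
    return LambdaTrajectory(site_id=site_id, times=np.array(times), lambdas=np.array(lams))


def write_lambda_xvg(path, traj: LambdaTrajectory, comments: dict | None = None) -> None:
    """Write a lambda trajectory in the xvg dialect (full float precision)."""
    with open(path, "w") as fh:
        fh.write(f"# lambda trajectory, site {traj.site_id}\n")
        for k, v in (comments or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("@    xaxis  label \"time (ps)\"\n")
        fh.write("@    yaxis  label \"lambda\"\n")
        for t, lam in zip(traj.times, traj.lambdas):
            fh.write(f"{float(t)!r} {float(lam)!r}\n")


# --------------------------------------------------------------------------
# tables and metadata
# --------------------------------------------------------------------------

def read_titration_csv(path) -> list[TitrationPoint]:
    """Read a (ph, s_deprot, sem) CSV into titration points."""
    df = pd.read_csv(path)
    required = {"ph", "s_deprot", "sem"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration CSV needs columns {sorted(required)}")
    return [
        TitrationPoint(ph=float(r.ph), s_deprot=float(r.s_deprot), sem=float(r.sem))
        for r in df.itertuples()
    ]


def write_titration_csv(path, points) -> None:
    pd.DataFrame(
        {
            "ph": [p.ph for p in points],
            "s_deprot": [p.s_deprot for p in points],
            "sem": [p.sem for p in points],
        }
    ).to_csv(path, index=False)


def write_metadata(path, seed: int, config, extra: dict | None = None) -> None:
    """JSON sidecar with seed, config hash and package version."""
    record = {
        "seed": seed,
        "config_hash": config_hash(config) if not isinstance(config, str) else config,
        "version": __version__,
    }
    record.update(extra or {})
    Path(path).write_text(json.dumps(record, indent=2, default=float))
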