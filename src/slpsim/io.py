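"""Plain-text serialization: ensembles, field states and result tables.

Ensembles round-trip through a CSV of per-particle records plus a JSON
sidecar holding the scalars (box length, volume fraction, seed, ...).
Floats are written with 17 significant digits so the round trip is
lossless to 1e-15 relative.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dipolar import LocalFieldState
from .ensemble import Ensemble
from .params import MaterialParams
from .relaxation import RelaxationSummary

_FLOAT_FMT = "%.17g"


def ensemble_to_csv(ensemble: Ensemble, csv_path, sidecar_path=None) -> None:
    """Write per-particle data as CSV and the scalars as a JSON sidecar
    (default: CSV path with a .json suffix)."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    df = pd.DataFrame(
        {
            "id": np.arange(ensemble.n),
            "x_m": ensemble.positions[:, 0],
            "y_m": ensemble.positions[:, 1],
            "z_m": ensemble.positions[:, 2],
            "d_m": ensemble.core_diameters,
            "dh_m": ensemble.hydro_diameters,
            "ax": ensemble.easy_axes[:, 0],
            "ay": ensemble.easy_axes[:, 1],
            "az": ensemble.easy_axes[:, 2],
            "mx": ensemble.moment_dirs[:, 0],
            "my": ensemble.moment_dirs[:, 1],
            "mz": ensemble.moment_dirs[:, 2],
        }
    )
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "box_length_m": ensemble.box_length,
        "boundary": ensemble.boundary,
        "r_V": ensemble.r_V,
        "r_V_loc": ensemble.r_V_loc,
        "seed": ensemble.seed,
        "site_set": ensemble.site_set,
        "material": asdict(ensemble.material),
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))


def ensemble_from_csv(csv_path, sidecar_path=None) -> Ensemble:
    """Inverse of :func:`ensemble_to_csv`."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    return Ensemble(
        positions=df[["x_m", "y_m", "z_m"]].to_numpy(),
        core_diameters=df["d_m"].to_numpy(),
        hydro_diameters=df["dh_m"].to_numpy(),
        easy_axes=df[["ax", "ay", "az"]].to_numpy(),
        moment_dirs=df[["mx", "my", "mz"]].to_numpy(),
        box_length=meta["box_length_m"],
        boundary=meta["boundary"],
        r_V=meta["r_V"],
        material=MaterialParams(**meta["material"]),
        seed=meta["seed"],
        r_V_loc=meta["r_V_loc"],
        site_set=meta["site_set"],
    )


def fields_to_csv(states: LocalFieldState, path) -> None:
    """Per-particle field diagnostics (id, H components, |H|, psi, h,
    sigma, xi)."""
    pd.DataFrame(
        {
            "id": np.arange(states.H.shape[0]),
            "Hx": states.H_loc[:, 0],
            "Hy": states.H_loc[:, 1],
            "Hz": states.H_loc[:, 2],
            "H_mag": states.H,
            "psi_rad": states.psi,
            "h": states.h,
            "sigma": states.sigma,
            "xi": states.xi,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def relaxation_to_csv(states: LocalFieldState, summary: RelaxationSummary, path) -> None:
    """Per-particle relaxation diagnostics."""
    pd.DataFrame(
        {
            "id": np.arange(states.H.shape[0]),
            "psi_rad": states.psi,
            "h": states.h,
            "sigma": states.sigma,
            "tau_N_s": summary.tau_N,
            "tau_eff_s": summary.tau_eff,
            "model": summary.model,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def summary_to_json(summary: RelaxationSummary, path) -> None:
    """Ensemble-level relaxation summary as JSON."""
    Path(path).write_text(
        json.dumps(
            {
                "model": summary.model,
                "axes_mode": summary.axes_mode,
                "tau_B_s": summary.tau_B,
                "mean_tau_N_s": summary.mean_tau_N,
                "mean_tau_eff_s": summary.mean_tau_eff,
                "n_excluded": summary.n_excluded,
                "average": summary.average,
            },
            indent=1,
        )
    )
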