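"""File formats: parameter JSON, arm CSV, trial CSV, simulation CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_core import DoseInput, PKParameters, SimProfile
from .pk_fit import ObservedArm

__all__ = [
    "save_params",
    "load_params",
    "save_profile",
    "load_arms",
    "save_arms",
    "load_trial",
]

_UNITS = {"CL": "L/min", "C0": "mM", "ka": "1/min", "Km_prime": "mmol",
          "Vd": "L", "Vmax": "mmol/min", "molar_mass": "g/mol"}


def save_params(params: PKParameters, path: str | Path,
                molar_mass: float | None = None) -> None:
    payload: dict = {"units": _UNITS, **params.to_dict()}
    if molar_mass is not None:
        payload["molar_mass"] = molar_mass
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_params(path: str | Path) -> PKParameters:
    payload = json.loads(Path(path).read_text())
    return PKParameters.from_dict(payload)


def save_profile(profile: SimProfile, path: str | Path) -> None:
    pd.DataFrame({"time_min": profile.times, "gut_mmol": profile.gut_amount,
                  "conc_mM": profile.conc}).to_csv(path, index=False)


def save_arms(arms: list[ObservedArm], path: str | Path) -> None:
    rows = []
    for i, arm in enumerate(arms):
        for j, t in enumerate(arm.times):
            rows.append({
                "arm_id": f"arm{i + 1}", "dose_g": arm.dose.dose_grams,
                "time_min": float(t), "conc_mM": float(arm.conc_mean[j]),
                "sd_mM": (float(arm.conc_sd[j]) if arm.conc_sd is not None
                          else np.nan),
                "n": arm.n_subjects if arm.n_subjects is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_arms(path: str | Path) -> list[ObservedArm]:
    """Read dose arms from CSV (arm_id, dose_g, time_min, conc_mM[, sd_mM, n])."""
    df = pd.read_csv(path)
    arms = []
    for _, grp in df.groupby("arm_id", sort=True):
        grp = grp.sort_values("time_min")
        sd = grp["sd_mM"].to_numpy() if "sd_mM" in grp else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        n = int(grp["n"].iloc[0]) if "n" in grp and grp["n"].notna().all() else None
        arms.append(ObservedArm(
            dose=DoseInput(float(grp["dose_g"].iloc[0])),
            times=grp["time_min"].to_numpy(),
            conc_mean=grp["conc_mM"].to_numpy(), conc_sd=sd, n_subjects=n))
    return arms


def load_trial(path: str | Path) -> pd.DataFrame:
    """Read a crossover trial table from CSV."""
    return pd.read_csv(path)
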