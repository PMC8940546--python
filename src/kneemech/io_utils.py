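"""Readers/writers and provenance shared by the CLI and analysis scripts.

Payload files carry a one-line provenance comment (package version, config
hash, seed) instead of timestamps, so identical runs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np
import pandas as pd

import kneemech
from kneemech.errors import ValidationError
from kneemech.knee import results_to_records
from kneemech.ligaments import LigamentBundle

BUNDLE_COLUMNS = ["name", "femur_x", "femur_y", "femur_z",
                  "tibia_x", "tibia_y", "tibia_z", "k_N", "L0_mm", "DL"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_line(config: Optional[dict] = None, seed: Optional[int] = None) -> str:
    parts = [f"kneemech v{kneemech.__version__}"]
    if config is not None:
        parts.append(f"config_sha={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def write_csv(df: pd.DataFrame, path, config: Optional[dict] = None,
              seed: Optional[int] = None, float_format: str = "%.6f") -> None:
    """CSV with a provenance comment line; re-readable via read_csv below."""
    with open(path, "w") as fh:
        fh.write(provenance_line(config, seed) + "\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(payload: dict, path, config: Optional[dict] = None,
               seed: Optional[int] = None) -> None:
    body = {"provenance": provenance_line(config, seed).lstrip("# "), **payload}
    with open(path, "w") as fh:
        json.dump(body, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def kinematics_frame(results) -> pd.DataFrame:
    return pd.DataFrame(results_to_records(results))


def bundles_to_frame(bundles) -> pd.DataFrame:
    rows = []
    for b in bundles:
        rows.append(dict(zip(BUNDLE_COLUMNS, [
            b.name, *np.asarray(b.femur_insertion, dtype=float),
            *np.asarray(b.tibia_insertion, dtype=float),
            b.stiffness_k, b.reference_length_L0, b.transition_strain_DL,
        ])))
    return pd.DataFrame(rows, columns=BUNDLE_COLUMNS)


def bundles_from_frame(df: pd.DataFrame):
    missing = set(BUNDLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"bundle table is missing columns: {sorted(missing)}")
    return [
        LigamentBundle(
            name=row["name"],
            femur_insertion=[row["femur_x"], row["femur_y"], row["femur_z"]],
            tibia_insertion=[row["tibia_x"], row["tibia_y"], row["tibia_z"]],
            stiffness_k=float(row["k_N"]),
            reference_length_L0=float(row["L0_mm"]),
            transition_strain_DL=float(row["DL"]),
        )
        for _, row in df.iterrows()
    ]


# Landmark measurement tables -------------------------------------------------

LANDMARK_COLUMNS = (["patient_id", "bone"]
                    + [f"{end}_{ax}" for end in ("entry", "exit") for ax in "xyz"]
                    + [f"d{s}_{r}" for s in (1, 2, 3) for r in (1, 2, 3)]
                    + ["intraop_mm"])


def measure_landmark_table(df: pd.DataFrame) -> pd.DataFrame:
    """Morphometry for each row of a landmark CSV (see LANDMARK_COLUMNS)."""
    from kneemech.tunnels import enlargement_rate, plane_angle, triplicate_mean, tunnel_axis

    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"landmark table is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        entry = row[["entry_x", "entry_y", "entry_z"]].to_numpy(dtype=float)
        exit_ = row[["exit_x", "exit_y", "exit_z"]].to_numpy(dtype=float)
        axis = tunnel_axis(entry, exit_)
        stations = [triplicate_mean([row[f"d{s}_{r}"] for r in (1, 2, 3)]) for s in (1, 2, 3)]
        mean_d = float(np.mean(stations))
        out.append({
            "patient_id": row["patient_id"],
            "bone": row["bone"],
            "coronal_angle_deg": plane_angle(axis, "coronal"),
            "sagittal_angle_deg": plane_angle(axis, "sagittal"),
            "distal_mm": stations[0], "mid_mm": stations[1], "proximal_mm": stations[2],
            "mean_diameter_mm": mean_d,
            "enlargement_percent": enlargement_rate(mean_d, float(row["intraop_mm"])),
        })
    return pd.DataFrame(out)
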