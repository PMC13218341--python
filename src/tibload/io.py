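"""Readers and writers for the package's plain-text exchange formats.

Meshes go out as STL or PLY (via trimesh); landmark sets, gait trials and
muscle sets as CSV with fixed column schemas; load cases and dataset
manifests as JSON. The ankle-contact-force table writer mirrors the
supplementary-data layout used in the running-study literature: one row
per participant x condition with axial/AP/ML components at the peak
instant, raw newtons and body-weight normalized.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gaitgen import GaitTrial, Muscle, MuscleSet
from .geometry import SurfaceMesh
from .musculo import LoadCase

GAIT_COLUMNS = ("time_s", "grf_z_N", "rf_ax_N", "rf_ap_N", "rf_ml_N",
                "ankle_moment_Nm", "knee_moment_Nm", "foot_angle_deg")


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """STL or PLY chosen by extension."""
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise ValueError("mesh format must be .stl or .ply")
    mesh.to_trimesh().export(path)


def read_mesh(path: str | Path) -> SurfaceMesh:
    import trimesh
    tm = trimesh.load_mesh(path, process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [{"name": k, "x_mm": v[0], "y_mm": v[1], "z_mm": v[2]}
            for k, v in landmarks.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {str(r.name): np.array([r.x_mm, r.y_mm, r.z_mm])
            for r in df.itertuples(index=False)}


def write_gait_trial(trial: GaitTrial, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": trial.time_s, "grf_z_N": trial.grf_z_n,
        "rf_ax_N": trial.rf_axial_n, "rf_ap_N": trial.rf_ap_n,
        "rf_ml_N": trial.rf_ml_n, "ankle_moment_Nm": trial.ankle_moment_nm,
        "knee_moment_Nm": trial.knee_moment_nm,
        "foot_angle_deg": trial.foot_angle_deg})
    df.to_csv(path, index=False)


def read_gait_trial(path: str | Path, rate_hz: float | None = None,
                    condition: str = "", participant: str = "") -> GaitTrial:
    df = pd.read_csv(path)
    missing = [c for c in GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gait CSV missing columns {missing}")
    t = df["time_s"].to_numpy()
    if rate_hz is None and len(t) > 1:
        dt = np.diff(t)
        rate_hz = float(1.0 / dt.mean()) if np.allclose(dt, dt[0]) else None
    return GaitTrial(
        time_s=t, grf_z_n=df["grf_z_N"].to_numpy(),
        rf_axial_n=df["rf_ax_N"].to_numpy(), rf_ap_n=df["rf_ap_N"].to_numpy(),
        rf_ml_n=df["rf_ml_N"].to_numpy(),
        ankle_moment_nm=df["ankle_moment_Nm"].to_numpy(),
        knee_moment_nm=df["knee_moment_Nm"].to_numpy(),
        foot_angle_deg=float(df["foot_angle_deg"].iloc[0]),
        rate_hz=rate_hz, condition=condition, participant=participant)


def write_muscle_set(muscles: MuscleSet, path: str | Path) -> None:
    rows = [{"name": m.name, "pcsa_mm2": m.pcsa_mm2,
             "arm_ankle_m": m.arm_ankle_m, "arm_knee_m": m.arm_knee_m,
             "dir_x": m.direction[0], "dir_y": m.direction[1],
             "dir_z": m.direction[2]} for m in muscles.muscles]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_muscle_set(path: str | Path) -> MuscleSet:
    df = pd.read_csv(path)
    return MuscleSet([Muscle(name=r.name, pcsa_mm2=r.pcsa_mm2,
                             arm_ankle_m=r.arm_ankle_m,
                             arm_knee_m=r.arm_knee_m,
                             direction=(r.dir_x, r.dir_y, r.dir_z))
                      for r in df.itertuples(index=False)])


def write_load_case(load: LoadCase, path: str | Path,
                    body_weight_n: float | None = None) -> None:
    doc = {
        "axial_N": load.f_axial_n, "ap_N": load.f_ap_n, "ml_N": load.f_ml_n,
        "fibula_share": load.fibula_share,
        "application_point_mm": list(map(float, load.application_point_mm)),
        "peak_index": load.peak_index,
        "muscle_forces_N": list(map(float, load.muscle_forces_n)),
    }
    if body_weight_n:
        doc.update({"axial_BW": load.f_axial_n / body_weight_n,
                    "ap_BW": load.f_ap_n / body_weight_n,
                    "ml_BW": load.f_ml_n / body_weight_n})
    Path(path).write_text(json.dumps(doc, indent=2))


def write_ajcf_table(records: list[dict], path: str | Path) -> None:
    """Supplementary-style peak contact-force table.

    Each record: participant, condition, axial_N, ap_N, ml_N,
    body_weight_N; normalized columns are derived.
    """
    df = pd.DataFrame(records)
    for c in ("axial", "ap", "ml"):
        df[f"{c}_BW"] = df[f"{c}_N"] / df["body_weight_N"]
    df.to_csv(path, index=False)


def read_ajcf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"participant", "condition", "axial_N", "ap_N", "ml_N"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"contact-force table missing columns {missing}")
    return df


def write_manifest(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2))
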