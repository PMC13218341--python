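"""End-to-end experiment drivers.

Two studies are orchestrated here:

* the reconstruction-accuracy experiment: fit every validation phantom
  under the four marker configurations (9-marker +/-3 SD reference;
  4-marker +/-3, +/-2, +/-1 SD), score Jaccard overlap and surface errors
  against the ground-truth geometry, and compare configurations with
  Friedman + Wilcoxon/Bonferroni statistics;

* the foot-strike loading experiment: reconstruct each runner's tibia
  from the 4-marker set at +/-2 SD, derive the distal-third section and a
  participant-specific tetrahedral mesh, estimate muscle forces and the
  ankle joint contact force per condition, and compute internal loading
  with both the 2D beam model and the 3D finite element model from
  identical load cases, ending in condition statistics and the 2D-vs-3D
  agreement analysis.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import refdata
from .beam import peak_stresses, stress_series
from .dataset import (StudyDataset, generate_study_dataset,
                      training_population_spec)
from .fem import (DEFAULT_MATERIALS, FEConfig, build_fe_model, field_metrics,
                  solve_linear_elasticity, summarize_results)
from .gaitgen import CONDITIONS, EffectSpec, generate_muscle_set
from .metrics import (align_to_reference, fit_distal_section, jaccard_index,
                      surface_error, tibial_length)
from .musculo import (assemble_ajcf, preprocess_gait,
                      solve_static_optimization_series)
from .phantom import (extract_landmarks, generate_population,
                      landmark_weights, noisy_landmarks, perturb_phantom)
from .ssm import (MARKERS_4, MARKERS_9, MarkerConfig, ShapeModel,
                  TrabecularModel, fit_landmarks, reconstruct)
from .stats import (condition_report, group_descriptives, length_agreement,
                    method_agreement, percent_change)

MARKER_CONFIGS = (
    ("9m_3sd", MARKERS_9, 3.0),
    ("4m_3sd", MARKERS_4, 3.0),
    ("4m_2sd", MARKERS_4, 2.0),
    ("4m_1sd", MARKERS_4, 1.0),
)


@dataclass
class RunConfig:
    """Everything a run needs; a run is reproducible from this object."""

    seed: int = 1
    n_training: int = 30          # shape-model training phantoms
    n_validation: int = 20        # reconstruction-accuracy phantoms
    n_participants: int = refdata.N_RUNNERS
    include_short_outlier: bool = True
    chosen_marker_ksd: float = 2.0          # study configuration: 4m +/-2 SD
    voxel_mm: float = 1.0
    mesh_edge_mm: float = 3.6               # study FE mesh (coarse, linear)
    fibula_share: float = 0.1
    kappa: float = 1.0
    landmark_noise_validation_mm: float = 0.5   # digitization-level noise
    landmark_noise_study_mm: float = 3.0        # skin-marker soft tissue
    out_of_span_mm: float = 1.2   # anatomical detail beyond the model span
    grid_rings: int = 40
    grid_circ: int = 24
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def screen_participants(heights_cm, training_mean_cm: float | None = None,
                        training_sd_cm: float | None = None,
                        ) -> tuple[list[int], list[int]]:
    """Indices (included, excluded) by the +/-2 SD height window.

    Bounds are inclusive: a participant exactly at a bound is included.
    Defaults reproduce the shape-model training cohort window
    (152.8-199.3 cm).
    """
    heights = np.asarray(heights_cm, dtype=float)
    if np.any(heights <= 0):
        raise ValueError("heights must be positive")
    if training_mean_cm is None:
        lo, hi = refdata.HEIGHT_SCREEN_CM
    else:
        if training_sd_cm is None or training_mean_cm <= 0 or training_sd_cm <= 0:
            raise ValueError("training mean and SD must be positive")
        lo = training_mean_cm - 2 * training_sd_cm
        hi = training_mean_cm + 2 * training_sd_cm
    inc = [i for i, h in enumerate(heights) if lo <= h <= hi]
    exc = [i for i, h in enumerate(heights) if not lo <= h <= hi]
    return inc, exc


def train_shape_models(config: RunConfig, seed: int,
                       ) -> tuple[ShapeModel, ShapeModel, TrabecularModel]:
    """Cortical + endosteal shape models and the trabecular regression."""
    pop = generate_population(
        config.n_training,
        training_population_spec(config.grid_rings, config.grid_circ),
        seed=seed)
    lm_defs = landmark_weights(config.grid_rings, config.grid_circ)
    # default variance cutoff: high-variance modes carry the anatomy, the
    # sampling-noise tail would only let sparse-landmark fits chase noise
    cort = build_ssm_from([p.cortical for p in pop], lm_defs, None)
    endo = build_ssm_from([p.endosteal for p in pop], lm_defs, None)
    trab = TrabecularModel(cort, endo).fit([p.cortical for p in pop],
                                           [p.endosteal for p in pop])
    return cort, endo, trab


def build_ssm_from(meshes, lm_defs, n_modes) -> ShapeModel:
    from .ssm import build_ssm
    return build_ssm(meshes, lm_defs, n_modes=n_modes)


def load_case_hash(load) -> str:
    """Stable digest of a load case — the 'identical inputs' contract."""
    payload = np.round(np.concatenate([
        load.force_vector(), load.application_point_mm,
        [load.fibula_share]]), 6).tobytes()
    return hashlib.sha1(payload).hexdigest()[:12]


# --------------------------------------------------------------------------
# experiment 1: reconstruction accuracy
# --------------------------------------------------------------------------

def run_reconstruction_experiment(config: RunConfig) -> dict:
    """Marker-configuration accuracy study on synthetic phantoms."""
    root = np.random.SeedSequence(config.seed)
    s_train, s_valid, s_noise = root.spawn(3)
    cort, _, _ = train_shape_models(config, seed=np.random.default_rng(s_train))
    rng_valid = np.random.default_rng(s_valid)
    validation = generate_population(
        config.n_validation,
        training_population_spec(config.grid_rings, config.grid_circ),
        seed=rng_valid)
    validation = [perturb_phantom(ph, config.out_of_span_mm, rng_valid)
                  for ph in validation]
    rng_noise = np.random.default_rng(s_noise)

    rows = []
    for i, ph in enumerate(validation):
        observed = noisy_landmarks(ph.landmarks,
                                   config.landmark_noise_validation_mm,
                                   rng_noise)
        for label, markers, ksd in MARKER_CONFIGS:
            fit = fit_landmarks(cort, observed, markers, k_sd=ksd)
            recon_lms = extract_landmarks(fit.mesh, config.grid_rings,
                                          config.grid_circ)
            aligned = align_to_reference(fit.mesh, recon_lms, ph.landmarks)
            jac = jaccard_index(aligned, ph.cortical, config.voxel_mm)
            mean_e, max_e = surface_error(aligned, ph.cortical,
                                          mode="correspondence")
            rows.append({"participant": f"V{i + 1:02d}", "config": label,
                         "k_sd": ksd, "jaccard": jac,
                         "mean_err_mm": mean_e, "max_err_mm": max_e})
    table = pd.DataFrame(rows)

    stats_reports = {}
    for metric in ("jaccard", "mean_err_mm", "max_err_mm"):
        wide = table.pivot(index="participant", columns="config",
                           values=metric)[list(refdata.RECON_CONFIGS)]
        stats_reports[metric] = condition_report(
            wide.to_numpy(), tuple(wide.columns), variable=metric)

    summary = table.groupby("config", sort=False).agg(
        jaccard_mean=("jaccard", "mean"), jaccard_sd=("jaccard", "std"),
        mean_err_mean=("mean_err_mm", "mean"),
        mean_err_sd=("mean_err_mm", "std"),
        max_err_mean=("max_err_mm", "mean"),
        max_err_sd=("max_err_mm", "std")).reset_index()

    report = {"table": table, "summary": summary, "stats": stats_reports,
              "config": config}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "reconstruction_accuracy.csv", index=False)
        summary.to_csv(out / "reconstruction_summary.csv", index=False)
    return report


# --------------------------------------------------------------------------
# experiment 2: foot-strike loading
# --------------------------------------------------------------------------

def run_loading_experiment(config: RunConfig,
                           effect: EffectSpec | None = None) -> dict:
    """Per-participant 2D + 3D internal loading across conditions."""
    from .tetmesh import tet_mesh_from_reconstruction

    root = np.random.SeedSequence(config.seed + 1)
    s_train, s_data = root.spawn(2)
    cort, endo, trab = train_shape_models(
        config, seed=np.random.default_rng(s_train))
    dataset = generate_study_dataset(
        n_participants=config.n_participants,
        seed=int(s_data.generate_state(1)[0] % (2 ** 31)),
        effect=effect,
        landmark_noise_sd_mm=config.landmark_noise_study_mm,
        include_short_outlier=config.include_short_outlier,
        n_rings=config.grid_rings, n_circ=config.grid_circ)
    muscles = generate_muscle_set()
    fe_config = FEConfig(kappa=config.kappa)

    heights = [p.height_cm for p in dataset.participants]
    included, excluded = screen_participants(heights)
    analyzed = [dataset.participants[i] for i in included]

    rows_2d, rows_3d, geo_rows = [], [], []
    failures = []
    for p in analyzed:
        observed = dataset.landmarks_observed[p.pid]
        fit = fit_landmarks(cort, observed, MARKERS_4,
                            k_sd=config.chosen_marker_ksd)
        recon = reconstruct(cort, fit.scores)            # canonical frame
        endo_mesh = trab.predict_surface(fit.scores)
        section = fit_distal_section(recon, endo_mesh)
        geo_rows.append({
            "participant": p.pid, "sex": p.sex, "height_cm": p.height_cm,
            "length_marker_mm": tibial_length(observed),
            "length_ssm_mm": tibial_length(recon),
            "a_o": section.a_o, "b_o": section.b_o,
            "a_i": section.a_i, "b_i": section.b_i,
            "csa_mm2": section.csa_mm2, "i_ml_mm4": section.i_ml_mm4,
            "i_ap_mm4": section.i_ap_mm4,
            "bound_active": int(fit.bound_active.sum())})

        mesh = tet_mesh_from_reconstruction(
            recon.vertices, endo_mesh.vertices,
            config.grid_rings, config.grid_circ, config.mesh_edge_mm)
        model = None
        for cond in CONDITIONS:
            trial = preprocess_gait(dataset.trial(p.pid, cond))
            forces = solve_static_optimization_series(trial, muscles)
            load = assemble_ajcf(trial, forces, muscles,
                                 fibula_share=config.fibula_share)
            lhash = load_case_hash(load)

            series = stress_series(load, section)
            pk_ant, pk_post, i_ant, i_post = peak_stresses(series)
            rows_2d.append({"participant": p.pid, "condition": cond,
                            "peak_ant_mpa": pk_ant, "peak_post_mpa": pk_post,
                            "peak_index": i_ant, "load_hash": lhash})
            try:
                if model is None:
                    model = build_fe_model(mesh, DEFAULT_MATERIALS,
                                           load.external_force())
                else:
                    model = model.with_load(load.external_force())
                u = solve_linear_elasticity(model)
                result = field_metrics(u, mesh, DEFAULT_MATERIALS, fe_config)
                summ = summarize_results(result, mesh, fe_config)
                rows_3d.append({
                    "participant": p.pid, "condition": cond,
                    "pct95_pmvm_ue": summ.pct95_pmvm_ue,
                    "strained_vol_mm3": summ.strained_volume_mm3,
                    "peak_tens_mpa": summ.peak_tensile_mpa,
                    "peak_comp_mpa": summ.peak_compressive_mpa,
                    "load_hash": lhash})
            except Exception as err:  # keep the study running
                failures.append({"participant": p.pid, "condition": cond,
                                 "stage": "fe3d", "error": str(err)})

    table_2d = pd.DataFrame(rows_2d)
    table_3d = pd.DataFrame(rows_3d)
    geometry = pd.DataFrame(geo_rows)

    def _wide(tbl, value):
        return tbl.pivot(index="participant", columns="condition",
                         values=value)[list(CONDITIONS)]

    stats_reports = {"beam_peak_anterior": condition_report(
        _wide(table_2d, "peak_ant_mpa").to_numpy(), CONDITIONS,
        "peak anterior tensile stress (MPa)")}
    for metric, label in (("pct95_pmvm_ue", "95th percentile PMvM strain"),
                          ("strained_vol_mm3", "strained volume (mm^3)"),
                          ("peak_tens_mpa", "peak principal tensile stress"),
                          ("peak_comp_mpa", "peak principal compressive stress")):
        if not table_3d.empty:
            stats_reports[metric] = condition_report(
                _wide(table_3d, metric).to_numpy(), CONDITIONS, label)

    # 2D-vs-3D agreement on hRFS -> iFFS percentage change
    ant = _wide(table_2d, "peak_ant_mpa")
    pc2 = percent_change(ant["hRFS"].to_numpy(), ant["iFFS"].to_numpy())
    agreement = None
    if not table_3d.empty:
        ten = _wide(table_3d, "peak_tens_mpa")
        pc3 = percent_change(ten["hRFS"].to_numpy(), ten["iFFS"].to_numpy())
        agreement = method_agreement(pc2, pc3)

    lengths = length_agreement(geometry["length_marker_mm"].to_numpy(),
                               geometry["length_ssm_mm"].to_numpy())
    sex_tables = {
        "csa": group_descriptives(geometry["csa_mm2"].to_numpy(),
                                  geometry["sex"].to_numpy())}
    for cond in CONDITIONS:
        sub = table_2d[table_2d.condition == cond].merge(
            geometry[["participant", "sex"]], on="participant")
        sex_tables[f"anterior_stress_{cond}"] = group_descriptives(
            sub["peak_ant_mpa"].to_numpy(), sub["sex"].to_numpy())

    report = {
        "table_2d": table_2d, "table_3d": table_3d, "geometry": geometry,
        "stats": stats_reports, "agreement": agreement,
        "length_agreement": lengths, "sex_descriptives": sex_tables,
        "excluded_participants": [dataset.participants[i].pid
                                  for i in excluded],
        "fe_failures": failures, "config": config, "dataset": dataset,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_2d.to_csv(out / "beam_outcomes.csv", index=False)
        table_3d.to_csv(out / "fe_outcomes.csv", index=False)
        geometry.to_csv(out / "geometry.csv", index=False)
        with open(out / "run_config.json", "w") as fh:
            fh.write(config.to_json())
    return report
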