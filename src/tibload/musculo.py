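"""Gait preprocessing, static optimization and ankle joint contact force.

The processing chain mirrors standard running-biomechanics practice:
zero-lag Butterworth filtering, stance detection on the filtered vertical
GRF (> 10 N), time-normalization to 101 samples (0-100 % stance), muscle
force estimation by minimizing the sum of cubed muscle stresses subject
to sagittal ankle and knee moment constraints, and assembly of the ankle
joint contact force

    F_AJCF = (1 - fibula_share) * (RF + sum_i f_i)

component-wise in the shank frame, taken at the instant of peak resultant.
The default fibula share is 0.1 (the classic ~10 % fibular load path),
giving the 0.9 scaling of the tibial contact force.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import butter, filtfilt

from .gaitgen import GaitTrial, MuscleSet

N_STANCE_SAMPLES = 101
STANCE_THRESHOLD_N = 10.0
# channels low-passed at the kinematic cutoff (joint moments derive from
# marker trajectories); force channels use the kinetic cutoff
_KINEMATIC_CHANNELS = ("ankle_moment_nm", "knee_moment_nm")


class NoStanceError(RuntimeError):
    pass


class InfeasibleError(RuntimeError):
    pass


def _zero_lag_lowpass(x: np.ndarray, cutoff_hz: float, rate_hz: float,
                      ) -> np.ndarray:
    """Fourth-order zero-lag Butterworth: 2nd-order design, two passes."""
    nyq = rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie between 0 and the Nyquist rate")
    b, a = butter(2, cutoff_hz / nyq)
    return filtfilt(b, a, x)


def preprocess_gait(trial: GaitTrial, kinematic_cutoff_hz: float = 10.0,
                    kinetic_cutoff_hz: float = 20.0) -> GaitTrial:
    """Filter, crop to stance and resample to 101 points.

    Stance is the longest contiguous run with filtered vertical GRF above
    10 N; all channels are linearly resampled onto 101 equally spaced
    time points across it.
    """
    if trial.normalized or trial.rate_hz is None:
        raise ValueError("trial is already normalized")
    filt = {}
    for name, x in trial.channels().items():
        cutoff = (kinematic_cutoff_hz if name in _KINEMATIC_CHANNELS
                  else kinetic_cutoff_hz)
        filt[name] = _zero_lag_lowpass(x, cutoff, trial.rate_hz)

    above = filt["grf_z_n"] > STANCE_THRESHOLD_N
    if not above.any():
        raise NoStanceError("vertical GRF never exceeds 10 N")
    # longest contiguous True run
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    run = np.argmax(stops - starts)
    i0, i1 = starts[run], stops[run]  # [i0, i1)

    t = trial.time_s
    t_new = np.linspace(t[i0], t[i1 - 1], N_STANCE_SAMPLES)
    out = {name: np.interp(t_new, t[i0:i1], x[i0:i1])
           for name, x in filt.items()}
    return trial.copy_with(time_s=t_new, rate_hz=None, normalized=True,
                           grf_z_n=out["grf_z_n"],
                           rf_axial_n=out["rf_axial_n"],
                           rf_ap_n=out["rf_ap_n"], rf_ml_n=out["rf_ml_n"],
                           ankle_moment_nm=out["ankle_moment_nm"],
                           knee_moment_nm=out["knee_moment_nm"])


def classify_foot_strike(angle_deg: float) -> str:
    """'rearfoot' iff the contact angle exceeds 8 degrees (strict)."""
    if not np.isfinite(angle_deg):
        raise ValueError("foot strike angle must be finite")
    return "rearfoot" if angle_deg > 8.0 else "non-rearfoot"


# --------------------------------------------------------------------------
# static optimization
# --------------------------------------------------------------------------

@dataclass
class MuscleForceSolution:
    forces_n: np.ndarray          # (11,) all >= 0
    objective: float              # sum of cubed stresses, (N/mm^2)^3
    residuals_nm: np.ndarray      # per-DOF equality residuals


def solve_static_optimization(targets_nm: dict[str, float],
                              muscles: MuscleSet,
                              max_stress_mpa: float | None = None,
                              x0: np.ndarray | None = None,
                              ) -> MuscleForceSolution:
    """Muscle forces minimizing sum_i (f_i / PCSA_i)^3, f_i >= 0.

    Equality constraints enforce the target net moment for each
    constrained degree of freedom (sagittal ankle and knee by default —
    whichever keys ``targets_nm`` carries). The cubic stress objective is
    smooth and strictly convex on the nonnegative orthant, so the SLSQP
    solution from a deterministic start is the global optimum.
    """
    if not targets_nm:
        raise ValueError("need at least one constrained DOF")
    dofs = sorted(targets_nm)
    R = np.stack([muscles.arms(d) for d in dofs])     # (ndof, 11)
    if not np.all(np.isfinite(R)):
        raise ValueError("moment-arm matrix must be finite")
    m_target = np.array([targets_nm[d] for d in dofs])
    for row, d, m in zip(R, dofs, m_target):
        if m != 0 and not ((row * np.sign(m)) > 0).any():
            raise InfeasibleError(
                f"no muscle can produce a moment of the required sign "
                f"at DOF '{d}'")

    area = muscles.pcsa()
    # scale forces to O(1) for the optimizer
    scale = max(1.0, np.abs(m_target).max() / max(np.abs(R).max(), 1e-9))

    def fun(x):
        f = x * scale
        s = f / area
        return float((s ** 3).sum())

    def jac(x):
        f = x * scale
        return 3.0 * (f / area) ** 2 / area * scale

    cons = [{"type": "eq",
             "fun": lambda x, row=row, m=m: float(row @ (x * scale) - m),
             "jac": lambda x, row=row: row * scale}
            for row, m in zip(R, m_target)]
    ub = None if max_stress_mpa is None else max_stress_mpa * area / scale
    bounds = [(0.0, None if ub is None else ub[i]) for i in range(len(area))]
    start = (np.full(len(area), 1.0 / scale) if x0 is None
             else np.maximum(x0, 1.0) / scale)
    res = minimize(fun, start, jac=jac, bounds=bounds, constraints=cons,
                   method="SLSQP",
                   options={"maxiter": 400, "ftol": 1e-14})
    f = np.maximum(res.x * scale, 0.0)
    resid = R @ f - m_target
    tol = 1e-6 * np.maximum(1.0, np.abs(m_target))
    if np.any(np.abs(resid) > tol):
        raise InfeasibleError(
            f"static optimization failed to satisfy moment constraints "
            f"(residuals {resid})")
    return MuscleForceSolution(forces_n=f, objective=float(((f / area) ** 3).sum()),
                               residuals_nm=resid)


def solve_static_optimization_series(trial: GaitTrial, muscles: MuscleSet,
                                     dofs: tuple[str, ...] = ("ankle", "knee"),
                                     ) -> np.ndarray:
    """Per-sample muscle forces (n_samples, 11) over a normalized trial.

    Warm-starts each sample from the previous solution for speed and
    continuity; the convex objective makes the result start-independent.
    """
    channels = {"ankle": trial.ankle_moment_nm, "knee": trial.knee_moment_nm}
    n = len(trial.ankle_moment_nm)
    forces = np.zeros((n, len(muscles.muscles)))
    prev = None
    for i in range(n):
        targets = {d: float(channels[d][i]) for d in dofs}
        sol = solve_static_optimization(targets, muscles, x0=prev)
        forces[i] = sol.forces_n
        prev = sol.forces_n
    return forces


# --------------------------------------------------------------------------
# ankle joint contact force
# --------------------------------------------------------------------------

@dataclass
class LoadCase:
    """Scaled ankle joint contact force at the instant of peak resultant.

    Components follow the package's shank-frame conventions (axial
    tension-positive, so stance compression is negative). The application
    point is the distal reference location in the bone's canonical frame;
    its default posterior offset represents the eccentric load path
    through the distal articular surface.
    """

    f_axial_n: float
    f_ap_n: float
    f_ml_n: float
    fibula_share: float
    application_point_mm: np.ndarray     # offset from the distal end centre
    muscle_forces_n: np.ndarray          # (11,) at the peak instant
    peak_index: int
    series_n: np.ndarray                 # (n_samples, 3) [ap, ml, axial]

    def force_vector(self) -> np.ndarray:
        """(AP, ML, axial) in the internal sign convention."""
        return np.array([self.f_ap_n, self.f_ml_n, self.f_axial_n])

    def external_force(self) -> np.ndarray:
        """External force on the distal surface for the FE model, (x, y, z).

        The axial component flips sign: an internal compressive (negative)
        axial force is a proximally-directed push on the distal surface.
        """
        return np.array([self.f_ap_n, self.f_ml_n, -self.f_axial_n])


DEFAULT_APPLICATION_POINT_MM = np.array([-8.0, 0.0, 0.0])


def assemble_ajcf(trial: GaitTrial, muscle_forces: np.ndarray,
                  muscles: MuscleSet, fibula_share: float = 0.1,
                  application_point_mm: np.ndarray | None = None,
                  ) -> LoadCase:
    """Per-sample F = (1 - share) * (RF + sum f_i), peak-resultant pick.

    ``muscle_forces`` is (n_samples, 11); each muscle's force vector is
    its magnitude times its unit line of action, whose components are
    summed with the reaction force per axis. Ties in the peak resultant
    resolve to the earliest sample.
    """
    if not 0.0 <= fibula_share < 1.0:
        raise ValueError("fibula share must lie in [0, 1)")
    if muscle_forces.shape[0] != len(trial.rf_axial_n):
        raise ValueError("muscle forces and trial must share the time base")
    dirs = muscles.directions()                       # (11, 3) x,y,z
    m_xyz = muscle_forces @ dirs                      # (n, 3)
    rf = np.column_stack([trial.rf_ap_n, trial.rf_ml_n, trial.rf_axial_n])
    m_apmlax = np.column_stack([m_xyz[:, 0], m_xyz[:, 1], m_xyz[:, 2]])
    F = (1.0 - fibula_share) * (rf + m_apmlax)        # (n, 3) ap, ml, axial
    peak = int(np.argmax(np.linalg.norm(F, axis=1)))
    ap = (DEFAULT_APPLICATION_POINT_MM if application_point_mm is None
          else np.asarray(application_point_mm, dtype=float))
    return LoadCase(f_axial_n=float(F[peak, 2]), f_ap_n=float(F[peak, 0]),
                    f_ml_n=float(F[peak, 1]), fibula_share=fibula_share,
                    application_point_mm=ap,
                    muscle_forces_n=muscle_forces[peak].copy(),
                    peak_index=peak, series_n=F)


def bending_moment_at_section(f_ap_n: np.ndarray | float,
                              f_axial_n: np.ndarray | float,
                              section_z_mm: float,
                              section_centroid_x_mm: float = 0.0,
                              application_point_mm: np.ndarray = DEFAULT_APPLICATION_POINT_MM,
                              ) -> np.ndarray | float:
    """Sagittal free-body bending moment about the ML axis, N*m.

    Quasi-static free body of the bone distal to the section: the AP
    shear acts over the axial lever arm and the axial force over its AP
    eccentricity relative to the section centroid. Positive moment puts
    the anterior cortex in tension:

        M_ML = (x_A - x_c) * F_axial - (z_s - z_A) * F_AP

    with lengths in mm converted to metres. The sign follows the
    eccentric-column convention: a compressive (negative) axial force
    applied posterior to the centroid produces anterior tension, and an
    anteriorly-directed shear at the ankle produces anterior compression
    at the section (cantilever sense).
    """
    if section_z_mm <= application_point_mm[2]:
        raise ValueError("section must lie proximal to the load application")
    ecc_m = (application_point_mm[0] - section_centroid_x_mm) / 1000.0
    lever_m = (section_z_mm - application_point_mm[2]) / 1000.0
    return ecc_m * np.asarray(f_axial_n) - lever_m * np.asarray(f_ap_n)
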