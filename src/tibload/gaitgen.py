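"""Synthetic stance-phase gait signals and the tibia-spanning muscle set.

The generator emits raw-rate time series (vertical GRF, three ankle
joint reaction force components in the shank frame, sagittal ankle and
knee moments, and the foot angle at contact) for each of the three foot
strike conditions: habitual rearfoot (hRFS), imposed rearfoot (iRFS) and
imposed forefoot (iFFS).

Sign conventions (shank frame, +X anterior, +Y lateral, +Z proximal):

* axial force components use the internal-force convention, tension
  positive, so stance-phase joint compression is negative;
* AP / ML components are the external force on the distal tibia along
  +X / +Y;
* ankle dorsiflexion is the positive sagittal moment, so the stance
  plantarflexion moment is negative.

Condition effects are multiplicative on the participant's base ankle
moment and reaction force: the imposed forefoot strike raises the
plantar-flexor demand and the imposed rearfoot strike lowers it, so peak
plantarflexion moments are ordered iFFS > hRFS > iRFS by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import refdata

CONDITIONS = ("hRFS", "iRFS", "iFFS")


@dataclass
class GaitTrial:
    """One running trial's stance-relevant signals at a common time base."""

    time_s: np.ndarray
    grf_z_n: np.ndarray           # vertical ground reaction force, N (>= 0)
    rf_axial_n: np.ndarray        # ankle reaction force, axial (tension +)
    rf_ap_n: np.ndarray           # anterior-posterior component (+X)
    rf_ml_n: np.ndarray           # medial-lateral component (+Y)
    ankle_moment_nm: np.ndarray   # sagittal, dorsiflexion positive
    knee_moment_nm: np.ndarray    # sagittal, extension positive
    foot_angle_deg: float
    rate_hz: float | None
    condition: str = ""
    participant: str = ""
    normalized: bool = False      # True after stance-cropping to 101 points

    def channels(self) -> dict[str, np.ndarray]:
        return {"grf_z_n": self.grf_z_n, "rf_axial_n": self.rf_axial_n,
                "rf_ap_n": self.rf_ap_n, "rf_ml_n": self.rf_ml_n,
                "ankle_moment_nm": self.ankle_moment_nm,
                "knee_moment_nm": self.knee_moment_nm}

    def copy_with(self, **kw) -> "GaitTrial":
        return replace(self, **kw)


@dataclass(frozen=True)
class EffectSpec:
    """Per-condition magnitudes of the synthetic loading model.

    ``moment_scale`` multiplies the participant's base peak plantarflexion
    moment; ``force_scale`` multiplies the ankle reaction force. The
    default scales encode the imposed-forefoot increase in plantar-flexor
    demand and are the synthetic study's fixed experimental conditions.
    """

    foot_angle_deg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(refdata.FOOT_STRIKE_ANGLE_DEG))
    moment_scale: dict[str, float] = field(
        default_factory=lambda: {"hRFS": 1.0, "iRFS": 0.82, "iFFS": 1.18})
    force_scale: dict[str, float] = field(
        default_factory=lambda: {"hRFS": 1.0, "iRFS": 0.93, "iFFS": 1.06})
    # participant-level biological variability (SD as fraction of mean)
    between_participant_cv: float = 0.08
    # trial-level repeatability noise (SD as fraction of mean)
    within_participant_cv: float = 0.02
    # base magnitudes for a participant of unit body weight
    peak_grf_bw: float = 2.4
    peak_rf_axial_bw: float = -2.4
    peak_rf_ap_bw: float = -0.45          # posteriorly directed shear
    peak_rf_ml_bw: float = 0.12
    peak_ankle_moment_nm_per_kg: float = -2.0   # plantarflexion
    # knee demand assigned to the tibia-spanning set (gastrocnemii are its
    # only knee-crossing members, so the sagittal knee target is flexion)
    peak_knee_moment_nm_per_kg: float = -0.5
    stance_duration_s: float = 0.24
    rate_hz: float = 1000.0

    def validate_conditions(self, conditions) -> None:
        for c in conditions:
            if c not in self.moment_scale or c not in self.foot_angle_deg:
                raise KeyError(f"unknown condition label '{c}'")


@dataclass(frozen=True)
class Participant:
    pid: str
    height_cm: float
    mass_kg: float
    sex: str                      # "M" | "F"

    @property
    def weight_n(self) -> float:
        return self.mass_kg * 9.81


def _stance_shape(t_norm: np.ndarray, sharpness: float = 1.0) -> np.ndarray:
    """Smooth half-sine-like stance waveform, zero outside [0, 1]."""
    w = np.zeros_like(t_norm)
    inside = (t_norm >= 0) & (t_norm <= 1)
    w[inside] = np.sin(np.pi * t_norm[inside]) ** sharpness
    return w


def generate_gait_trials(participants: list[Participant],
                         conditions: tuple[str, ...] = CONDITIONS,
                         effect: EffectSpec | None = None,
                         seed: int | np.random.Generator = 0,
                         ) -> list[GaitTrial]:
    """Raw-rate trials for every participant x condition.

    Each record spans 0.5 s with stance centred in it; signals are smooth,
    so the Butterworth preprocessing stage mainly exercises its stance
    detection and time-normalization contract.
    """
    effect = effect if effect is not None else EffectSpec()
    effect.validate_conditions(conditions)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = np.arange(0.0, 0.5, 1.0 / effect.rate_hz)
    t0 = (0.5 - effect.stance_duration_s) / 2.0
    tn = (t - t0) / effect.stance_duration_s
    base = _stance_shape(tn)
    late = _stance_shape(tn, sharpness=2.0)  # moment peaks more mid-stance

    trials = []
    for p in participants:
        # participant-level scale factors, shared across conditions so the
        # within-participant condition contrast is clean
        g = 1.0 + effect.between_participant_cv * rng.standard_normal(4)
        for cond in conditions:
            ms = effect.moment_scale[cond]
            fs = effect.force_scale[cond]
            noise = 1.0 + effect.within_participant_cv \
                * rng.standard_normal(4)
            bw = p.weight_n
            grf = effect.peak_grf_bw * bw * g[0] * fs * noise[0] * base
            rf_ax = effect.peak_rf_axial_bw * bw * g[1] * fs * noise[1] * base
            rf_ap = effect.peak_rf_ap_bw * bw * g[1] * fs * noise[1] * late
            rf_ml = effect.peak_rf_ml_bw * bw * g[2] * fs * noise[2] * base
            ank = (effect.peak_ankle_moment_nm_per_kg * p.mass_kg
                   * g[3] * ms * noise[3] * late)
            kne = (effect.peak_knee_moment_nm_per_kg * p.mass_kg
                   * g[3] * noise[3] * base)
            mu, sd = effect.foot_angle_deg[cond]
            angle = float(rng.normal(mu, sd))
            trials.append(GaitTrial(
                time_s=t.copy(), grf_z_n=grf, rf_axial_n=rf_ax,
                rf_ap_n=rf_ap, rf_ml_n=rf_ml, ankle_moment_nm=ank,
                knee_moment_nm=kne, foot_angle_deg=angle,
                rate_hz=effect.rate_hz, condition=cond, participant=p.pid))
    return trials


# --------------------------------------------------------------------------
# muscle set
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Muscle:
    name: str
    pcsa_mm2: float
    arm_ankle_m: float      # sagittal ankle moment arm (dorsiflexion +)
    arm_knee_m: float       # sagittal knee moment arm (extension +)
    direction: tuple[float, float, float]  # unit line of action, shank frame

    def __post_init__(self) -> None:
        if self.pcsa_mm2 <= 0:
            raise ValueError("PCSA must be positive")


@dataclass
class MuscleSet:
    muscles: list[Muscle]

    def __post_init__(self) -> None:
        if len(self.muscles) != 11:
            raise ValueError("the tibia-spanning set has 11 muscles")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def pcsa(self) -> np.ndarray:
        return np.array([m.pcsa_mm2 for m in self.muscles])

    def arms(self, dof: str) -> np.ndarray:
        attr = {"ankle": "arm_ankle_m", "knee": "arm_knee_m"}[dof]
        return np.array([getattr(m, attr) for m in self.muscles])

    def directions(self) -> np.ndarray:
        return np.array([m.direction for m in self.muscles])

    def plantar_flexors(self) -> np.ndarray:
        return self.arms("ankle") < 0


# PCSA from maximal isometric forces of a widely used full-body running
# model divided by 60 N/cm^2 specific tension; moment arms and lines of
# action are plausible shank-frame magnitudes. Plantar flexors pull the
# distal tibia posteriorly/distally (negative x and z components).
_MUSCLE_TABLE = (
    # name, pcsa mm^2, ankle arm m, knee arm m, direction (x, y, z)
    ("soleus",             5900.0, -0.048,  0.000, (-0.20,  0.02, -0.9798)),
    ("gastrocnemius_med",  2600.0, -0.050, -0.030, (-0.20,  0.05, -0.9785)),
    ("gastrocnemius_lat",  1140.0, -0.049, -0.030, (-0.20, -0.05, -0.9785)),
    ("tibialis_posterior", 2650.0, -0.014,  0.000, (-0.12,  0.06, -0.9910)),
    ("flexor_hal_longus",  1510.0, -0.022,  0.000, (-0.12,  0.03, -0.9923)),
    ("flexor_dig_longus",   630.0, -0.018,  0.000, (-0.12,  0.04, -0.9920)),
    ("peroneus_longus",    1930.0, -0.010,  0.000, (-0.05, -0.08, -0.9955)),
    ("peroneus_brevis",    1500.0, -0.008,  0.000, (-0.05, -0.08, -0.9955)),
    ("tibialis_anterior",  1780.0,  0.040,  0.000, ( 0.20,  0.03, -0.9793)),
    ("extensor_dig_long",  1000.0,  0.030,  0.000, ( 0.18, -0.02, -0.9835)),
    ("extensor_hal_long",   270.0,  0.035,  0.000, ( 0.18,  0.02, -0.9835)),
)


def generate_muscle_set(seed: int | np.random.Generator = 0,
                        jitter_cv: float = 0.0) -> MuscleSet:
    """The 11-muscle tibia-spanning set.

    Deterministic by default; ``jitter_cv`` adds seeded multiplicative
    noise to PCSA and moment arms for sensitivity studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    muscles = []
    for name, pcsa, arm_a, arm_k, d in _MUSCLE_TABLE:
        if jitter_cv > 0:
            pcsa *= 1.0 + jitter_cv * rng.standard_normal()
            arm_a *= 1.0 + jitter_cv * rng.standard_normal()
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        muscles.append(Muscle(name=name, pcsa_mm2=float(pcsa),
                              arm_ankle_m=float(arm_a),
                              arm_knee_m=float(arm_k),
                              direction=tuple(d)))
    return MuscleSet(muscles)
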