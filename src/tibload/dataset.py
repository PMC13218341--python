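"""Synthetic study cohorts: anthropometrics, bone geometry and gait.

Two cohorts are emulated. The *training* cohort stands in for the
cadaveric CT population behind the statistical shape model (taller, more
variable). The *runner* cohort matches the motion-capture study's
anthropometrics (see ``tibload.refdata``); each runner gets a
ground-truth tibia phantom whose size tracks height, skin-landmark
observations with optional soft-tissue noise, and per-condition stance
trials. Everything is reproducible from (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import refdata
from .gaitgen import (CONDITIONS, EffectSpec, GaitTrial, Participant,
                      generate_gait_trials)
from .phantom import (PhantomSpec, PopulationSpec, TibiaPhantom,
                      make_phantom, noisy_landmarks, perturb_phantom)

# tibial length as a fraction of stature (mm per cm of height), from the
# reference cohort's 398.2 mm mean length at 166.4 cm mean height
LENGTH_PER_HEIGHT = 398.2 / 166.4


def training_population_spec(n_rings: int = 40, n_circ: int = 24,
                             ) -> PopulationSpec:
    """Parameter distribution emulating the CT training cohort."""
    h_mean, h_sd = refdata.TRAINING_HEIGHT_CM
    scale = h_mean * LENGTH_PER_HEIGHT / 398.2
    return PopulationSpec(
        length=(h_mean * LENGTH_PER_HEIGHT, h_sd * LENGTH_PER_HEIGHT),
        ap_semi_axis=(13.8 * scale, 1.5),
        ml_semi_axis=(12.3 * scale, 1.05),
        n_rings=n_rings, n_circ=n_circ)


@dataclass
class StudyDataset:
    participants: list[Participant]
    phantoms: dict[str, TibiaPhantom]
    landmarks_observed: dict[str, dict[str, np.ndarray]]
    trials: dict[tuple[str, str], GaitTrial]     # (pid, condition) -> trial
    effect: EffectSpec
    seed: int

    def trial(self, pid: str, condition: str) -> GaitTrial:
        return self.trials[(pid, condition)]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_participants": len(self.participants),
            "conditions": list(CONDITIONS),
            "participants": [
                {"id": p.pid, "height_cm": p.height_cm,
                 "mass_kg": p.mass_kg, "sex": p.sex,
                 "length_mm": self.phantoms[p.pid].spec.length}
                for p in self.participants],
        }


def _draw_participant(pid: str, sex: str, rng: np.random.Generator,
                      ) -> Participant:
    lo, hi = refdata.HEIGHT_SCREEN_CM
    mu_h = 171.0 if sex == "M" else 161.8   # pools to the cohort 166.4 +/- 6.3
    mu_m = 66.0 if sex == "M" else 57.0
    while True:
        h = rng.normal(mu_h, 4.5)
        if lo <= h <= hi:
            break
    return Participant(pid=pid, height_cm=float(h),
                       mass_kg=float(np.clip(rng.normal(mu_m, 4.5), 40, 110)),
                       sex=sex)


def _participant_phantom_spec(p: Participant, rng: np.random.Generator,
                              n_rings: int, n_circ: int) -> PhantomSpec:
    length = p.height_cm * LENGTH_PER_HEIGHT + rng.normal(0.0, 6.0)
    size = length / 398.2
    sex_f = 1.01 if p.sex == "M" else 0.99
    return PhantomSpec(
        length=float(length),
        ap_semi_axis=float(13.8 * size * sex_f * (1 + rng.normal(0, 0.05))),
        ml_semi_axis=float(12.3 * size * sex_f * (1 + rng.normal(0, 0.05))),
        endosteal_fraction=float(np.clip(rng.normal(0.51, 0.03), 0.3, 0.75)),
        proximal_flare=float(np.clip(rng.normal(2.2, 0.15), 1.3, 3.0)),
        distal_flare=float(np.clip(rng.normal(1.45, 0.10), 1.1, 2.0)),
        bow_mm=float(np.clip(rng.normal(5.0, 2.0), 0.5, 10.0)),
        bow2_mm=float(np.clip(rng.normal(0.0, 1.2), -3.0, 3.0)),
        ap_taper=float(np.clip(rng.normal(0.0, 0.06), -0.2, 0.2)),
        n_rings=n_rings, n_circ=n_circ)


def generate_study_dataset(n_participants: int = refdata.N_RUNNERS,
                           seed: int = 0,
                           effect: EffectSpec | None = None,
                           landmark_noise_sd_mm: float = 3.0,
                           out_of_span_mm: float = 1.2,
                           include_short_outlier: bool = True,
                           n_rings: int = 40, n_circ: int = 24,
                           ) -> StudyDataset:
    """The full synthetic running study.

    Balanced sexes; heights drawn inside the shape-model screening window
    so the analyzed sample keeps its nominal size. When
    ``include_short_outlier`` is set, one extra participant falls below
    the screening window (as happens in practice) and is expected to be
    removed by the screening stage.
    """
    effect = effect if effect is not None else EffectSpec()
    rng = np.random.default_rng(seed)
    participants = []
    for i in range(n_participants):
        sex = "M" if i % 2 == 0 else "F"
        participants.append(_draw_participant(f"P{i + 1:02d}", sex, rng))
    if include_short_outlier:
        lo, _ = refdata.HEIGHT_SCREEN_CM
        participants.append(Participant(
            pid=f"P{n_participants + 1:02d}", height_cm=float(lo - 1.0),
            mass_kg=float(np.clip(rng.normal(48.0, 3.0), 40, 110)), sex="F"))

    phantoms = {}
    observed = {}
    for p in participants:
        spec = _participant_phantom_spec(p, rng, n_rings, n_circ)
        ph = make_phantom(spec)
        if out_of_span_mm > 0:
            ph = perturb_phantom(ph, out_of_span_mm, rng)
        phantoms[p.pid] = ph
        observed[p.pid] = noisy_landmarks(ph.landmarks,
                                          landmark_noise_sd_mm, rng)

    trials = {(t.participant, t.condition): t
              for t in generate_gait_trials(participants, CONDITIONS,
                                            effect, rng)}
    return StudyDataset(participants=participants, phantoms=phantoms,
                        landmarks_observed=observed, trials=trials,
                        effect=effect, seed=seed)
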