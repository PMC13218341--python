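"""Published reference summaries used to calibrate the synthetic cohort.

Group-level values reported by a motion-capture running study (18 habitual
rearfoot strikers, overground running at 4.0 m/s under habitual rearfoot
(hRFS), imposed rearfoot (iRFS) and imposed forefoot (iFFS) conditions)
and by its companion shape-model validation analysis (35 adults, MRI
reference geometries). The synthetic-data generator draws its default
magnitudes from these tables; they also serve as printed-table inputs for
worked percentage-change arithmetic. They are data, not computed output.
"""
from __future__ import annotations

# --- shape-model validation: reconstruction accuracy, mean (SD), n = 35 ---
# marker configurations: 9-marker +/-3 SD (reference), 4-marker +/-3/2/1 SD
RECON_CONFIGS = ("9m_3sd", "4m_3sd", "4m_2sd", "4m_1sd")
JACCARD_MEAN = {"9m_3sd": 0.64, "4m_3sd": 0.49, "4m_2sd": 0.53,
                "4m_1sd": 0.55}
JACCARD_SD = {"9m_3sd": 0.05, "4m_3sd": 0.10, "4m_2sd": 0.09,
              "4m_1sd": 0.10}
MEAN_SURF_ERR_MM = {"9m_3sd": 6.49, "4m_3sd": 10.05, "4m_2sd": 8.79,
                    "4m_1sd": 8.70}
MAX_SURF_ERR_MM = {"9m_3sd": 13.11, "4m_3sd": 19.43, "4m_2sd": 16.68,
                   "4m_1sd": 16.38}

# --- cohort anthropometrics (running study), mean (SD) ---
HEIGHT_CM = (166.4, 6.3)
BODY_MASS_KG = (61.6, 6.6)
# shape-model training population (cadaveric CT cohort)
TRAINING_HEIGHT_CM = (176.1, 11.6)
# height screening window: training mean +/- 2 SD
HEIGHT_SCREEN_CM = (152.8, 199.3)

# --- tibial length and distal-third section, mean (SD), n = 18 ---
LENGTH_MARKER_MM = (398.2, 14.0)
LENGTH_SSM_MM = (403.6, 24.7)
DISTAL_CSA_MM2 = (393.1, 65.4)
DISTAL_I_ML_MM4 = (23607.5, 8368.2)
DISTAL_I_AP_MM4 = (18894.2, 6251.5)

# --- foot strike angle at contact (deg), mean (SD) per condition ---
FOOT_STRIKE_ANGLE_DEG = {"hRFS": (14.3, 4.3), "iRFS": (29.0, 5.7),
                         "iFFS": (-4.4, 4.7)}
REARFOOT_ANGLE_THRESHOLD_DEG = 8.0

# --- stress/strain outcomes across conditions, mean (SD), n = 18 ---
CONDITIONS = ("hRFS", "iRFS", "iFFS")
BEAM_PEAK_ANTERIOR_MPA = {"hRFS": (76.8, 26.2), "iRFS": (64.2, 20.0),
                          "iFFS": (89.8, 31.2)}
FE_PCT95_PMVM_UE = {"hRFS": (3625.9, 955.7), "iRFS": (3067.4, 709.4),
                    "iFFS": (4260.0, 1222.3)}
FE_STRAINED_VOL_MM3 = {"hRFS": (5916.0, 4333.0), "iRFS": (3071.3, 2723.6),
                       "iFFS": (8716.5, 4397.6)}
FE_PEAK_TENSILE_MPA = {"hRFS": (82.9, 21.9), "iRFS": (69.1, 15.4),
                       "iFFS": (98.4, 27.4)}
FE_PEAK_COMPRESSIVE_MPA = {"hRFS": (-98.4, 26.5), "iRFS": (-81.4, 20.5),
                           "iFFS": (-114.3, 32.4)}

# --- method agreement (hRFS -> iFFS percentage change per participant) ---
AGREEMENT_MEAN_PCT_2D = 18.7
AGREEMENT_MEAN_PCT_3D = 21.2
AGREEMENT_MEAN_ABS_DIFF_PCT = (5.3, 5.1)

N_VALIDATION = 35
N_RUNNERS = 18


def percent_change(baseline: float, changed: float) -> float:
    """100 * (changed - baseline) / baseline."""
    if baseline == 0:
        raise ZeroDivisionError("undefined percentage change: zero baseline")
    return 100.0 * (changed - baseline) / baseline
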