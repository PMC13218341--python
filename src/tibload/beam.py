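"""2D beam-theory normal stress at the distal-third tibial section.

Anterior and posterior normal stresses superpose the axial stress
(N / CSA) and the bending stress (M * c / I_ML) on the hollow-ellipse
section, with the periosteal AP semi-axis as the fiber distance c and
tension positive. Statistical comparisons downstream use anterior stress;
posterior stress is reported descriptively.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import HollowEllipseSection
from .musculo import LoadCase, bending_moment_at_section


class DegenerateSectionError(ValueError):
    pass


def normal_stress(axial_force_n: float | np.ndarray,
                  bending_moment_nm: float | np.ndarray,
                  section: HollowEllipseSection,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(anterior, posterior) normal stress in MPa; tension positive.

    sigma_ant = N/A + M*c/I, sigma_post = N/A - M*c/I with c = a_o.
    Units: N, N*m and mm-based section properties -> MPa.
    """
    csa = section.csa_mm2
    i_ml = section.i_ml_mm4
    if csa <= 0 or i_ml <= 0:
        raise DegenerateSectionError("section has zero area or inertia")
    axial = np.asarray(axial_force_n, dtype=float) / csa
    bend = (np.asarray(bending_moment_nm, dtype=float) * 1e3
            * section.a_o / i_ml)
    return axial + bend, axial - bend


@dataclass
class BeamStressSeries:
    """Anterior/posterior normal stress over the 101 stance samples."""

    sigma_ant_mpa: np.ndarray
    sigma_post_mpa: np.ndarray

    @property
    def peak_anterior_mpa(self) -> float:
        """Most tensile anterior value (maximum; may be negative)."""
        return float(self.sigma_ant_mpa.max())

    @property
    def peak_posterior_mpa(self) -> float:
        """Most compressive posterior value (minimum)."""
        return float(self.sigma_post_mpa.min())


def stress_series(load: LoadCase, section: HollowEllipseSection,
                  ) -> BeamStressSeries:
    """Beam stress over stance from the per-sample contact force series."""
    f_ap = load.series_n[:, 0]
    f_ax = load.series_n[:, 2]
    # application point is specified relative to the distal end centre
    offset = load.application_point_mm
    app = np.array([section.distal_centre_x_mm + offset[0], offset[1],
                    section.distal_z_mm + offset[2]])
    m_ml = bending_moment_at_section(
        f_ap, f_ax, section_z_mm=section.z_mm,
        section_centroid_x_mm=section.centroid_x,
        application_point_mm=app)
    ant, post = normal_stress(f_ax, m_ml, section)
    return BeamStressSeries(sigma_ant_mpa=ant, sigma_post_mpa=post)


def peak_stresses(series: BeamStressSeries) -> tuple[float, float, int, int]:
    """(peak anterior tensile, peak posterior compressive, their indices)."""
    if len(series.sigma_ant_mpa) == 0:
        raise ValueError("empty stress series")
    i_ant = int(np.argmax(series.sigma_ant_mpa))
    i_post = int(np.argmin(series.sigma_post_mpa))
    return (float(series.sigma_ant_mpa[i_ant]),
            float(series.sigma_post_mpa[i_post]), i_ant, i_post)
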