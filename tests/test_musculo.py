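"""Gait preprocessing, static optimization and contact-force assembly."""
import numpy as np
import pytest

from tibload.gaitgen import GaitTrial, generate_muscle_set
from tibload.musculo import (DEFAULT_APPLICATION_POINT_MM, InfeasibleError,
                             NoStanceError, assemble_ajcf,
                             bending_moment_at_section, classify_foot_strike,
                             preprocess_gait, solve_static_optimization)


def _trial(grf, rate=1000.0, **channels):
    n = len(grf)
    zeros = np.zeros(n)
    return GaitTrial(
        time_s=np.arange(n) / rate, grf_z_n=np.asarray(grf, float),
        rf_axial_n=channels.get("rf_axial", zeros.copy()),
        rf_ap_n=channels.get("rf_ap", zeros.copy()),
        rf_ml_n=channels.get("rf_ml", zeros.copy()),
        ankle_moment_nm=channels.get("ankle", zeros.copy()),
        knee_moment_nm=channels.get("knee", zeros.copy()),
        foot_angle_deg=channels.get("angle", 10.0), rate_hz=rate)


class TestPreprocess:
    def test_constant_grf_full_stance(self):
        out = preprocess_gait(_trial(np.full(500, 800.0)))
        assert len(out.grf_z_n) == 101
        assert out.normalized

    def test_no_stance_error(self):
        with pytest.raises(NoStanceError):
            preprocess_gait(_trial(np.full(500, 5.0)))

    def test_half_sine_crossings_within_one_sample(self):
        rate = 1000.0
        t = np.arange(0, 0.5, 1 / rate)
        peak, dur, t0 = 1000.0, 0.3, 0.1
        grf = np.where((t >= t0) & (t <= t0 + dur),
                       peak * np.sin(np.pi * (t - t0) / dur), 0.0)
        # near-transparent filter isolates the detection contract from
        # filter onset smearing
        out = preprocess_gait(_trial(grf), kinetic_cutoff_hz=450.0,
                              kinematic_cutoff_hz=450.0)
        # analytic 10 N crossings of the raw half-sine
        dt_cross = dur / np.pi * np.arcsin(10.0 / peak)
        assert out.time_s[0] == pytest.approx(t0 + dt_cross, abs=2 / rate)
        assert out.time_s[-1] == pytest.approx(t0 + dur - dt_cross,
                                               abs=2 / rate)

    def test_dc_signals_pass_unchanged(self):
        out = preprocess_gait(_trial(np.full(400, 700.0),
                                     ankle=np.full(400, -100.0)))
        np.testing.assert_allclose(out.ankle_moment_nm, -100.0, rtol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            preprocess_gait(_trial(np.full(400, 700.0)),
                            kinetic_cutoff_hz=600.0)


class TestFootStrike:
    @pytest.mark.parametrize("angle,label", [
        (14.3, "rearfoot"),        # habitual rearfoot group mean
        (-4.4, "non-rearfoot"),    # imposed forefoot group mean
        (8.0, "non-rearfoot"),     # boundary is strict
        (8.0001, "rearfoot"),
    ])
    def test_classification(self, angle, label):
        assert classify_foot_strike(angle) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_foot_strike(float("nan"))


class TestStaticOptimization:
    def test_single_muscle_equality(self, muscle_set):
        sol = solve_static_optimization({"ankle": -15.0}, muscle_set)
        np.testing.assert_allclose(
            muscle_set.arms("ankle") @ sol.forces_n, -15.0, atol=1e-6)
        assert np.all(sol.forces_n >= 0)

    def test_two_equal_muscles_split_evenly(self):
        from tibload.gaitgen import Muscle, MuscleSet
        muscles = [Muscle(f"m{i}", 1000.0, -0.05 if i < 2 else 0.04, 0.0,
                          (0.0, 0.0, -1.0)) for i in range(11)]
        ms = MuscleSet(muscles)
        sol = solve_static_optimization({"ankle": -20.0}, ms)
        active = sol.forces_n[:2]
        assert active[0] == pytest.approx(active[1], rel=1e-4)
        assert active.sum() == pytest.approx(20.0 / 0.05, rel=1e-6)

    def test_kkt_force_ratio_for_pcsa_ratio(self):
        """Equal arms, PCSA 2:1 -> force ratio 2^{3/2} (KKT stationarity)."""
        from tibload.gaitgen import Muscle, MuscleSet
        muscles = [Muscle("a", 2000.0, -0.05, 0.0, (0, 0, -1.0)),
                   Muscle("b", 1000.0, -0.05, 0.0, (0, 0, -1.0))]
        muscles += [Muscle(f"d{i}", 500.0, 0.03, 0.0, (0, 0, -1.0))
                    for i in range(9)]
        ms = MuscleSet(muscles)
        sol = solve_static_optimization({"ankle": -30.0}, ms)
        ratio = sol.forces_n[0] / sol.forces_n[1]
        assert ratio == pytest.approx(2 ** 1.5, rel=1e-4)

    def test_infeasible_sign_detected(self):
        from tibload.gaitgen import Muscle, MuscleSet
        muscles = [Muscle(f"m{i}", 1000.0, -0.05, 0.0, (0, 0, -1.0))
                   for i in range(11)]
        with pytest.raises(InfeasibleError):
            solve_static_optimization({"ankle": 10.0}, MuscleSet(muscles))

    def test_positive_homogeneity(self, muscle_set):
        s1 = solve_static_optimization({"ankle": -20.0, "knee": -8.0},
                                       muscle_set)
        s3 = solve_static_optimization({"ankle": -60.0, "knee": -24.0},
                                       muscle_set)
        np.testing.assert_allclose(s3.forces_n, 3 * s1.forces_n, rtol=1e-4,
                                   atol=1e-4)


class TestAssembleAJCF:
    def test_component_arithmetic(self, muscle_set):
        n = 3
        trial = _trial(np.full(n, 800.0),
                       rf_axial=np.full(n, -1000.0)).copy_with(
            normalized=True, rate_hz=None)
        # craft muscle forces summing to -2000 N axial with no shear
        from tibload.gaitgen import Muscle, MuscleSet
        ms = MuscleSet([Muscle(f"m{i}", 1000.0, -0.05, 0.0, (0.0, 0.0, -1.0))
                        for i in range(11)])
        forces = np.zeros((n, 11))
        forces[:, 0] = 2000.0
        lc = assemble_ajcf(trial, forces, ms, fibula_share=0.1)
        assert lc.f_axial_n == pytest.approx(-2700.0)
        assert lc.f_ap_n == pytest.approx(0.0)

    def test_zero_muscle_forces(self, muscle_set):
        n = 5
        trial = _trial(np.full(n, 800.0),
                       rf_axial=np.full(n, -1500.0),
                       rf_ap=np.full(n, 100.0)).copy_with(normalized=True)
        lc = assemble_ajcf(trial, np.zeros((n, 11)), muscle_set)
        assert lc.f_axial_n == pytest.approx(0.9 * -1500.0)
        assert lc.f_ap_n == pytest.approx(0.9 * 100.0)

    def test_linearity_in_inputs(self, muscle_set):
        n = 7
        rng = np.random.default_rng(0)
        trial = _trial(np.full(n, 800.0),
                       rf_axial=-rng.uniform(500, 1500, n),
                       rf_ap=rng.normal(0, 100, n)).copy_with(normalized=True)
        f = rng.uniform(0, 500, (n, 11))
        lc1 = assemble_ajcf(trial, f, muscle_set)
        trial2 = trial.copy_with(rf_axial_n=2 * trial.rf_axial_n,
                                 rf_ap_n=2 * trial.rf_ap_n,
                                 rf_ml_n=2 * trial.rf_ml_n)
        lc2 = assemble_ajcf(trial2, 2 * f, muscle_set)
        np.testing.assert_allclose(lc2.series_n, 2 * lc1.series_n, rtol=1e-12)

    def test_invalid_share(self, muscle_set):
        trial = _trial(np.full(3, 800.0)).copy_with(normalized=True)
        with pytest.raises(ValueError):
            assemble_ajcf(trial, np.zeros((3, 11)), muscle_set,
                          fibula_share=1.0)


class TestBendingMoment:
    def test_axial_through_centroid_is_zero(self):
        m = bending_moment_at_section(
            0.0, -4000.0, section_z_mm=130.0, section_centroid_x_mm=0.0,
            application_point_mm=np.array([0.0, 0.0, 0.0]))
        assert m == pytest.approx(0.0)

    def test_shear_lever_arm(self):
        m = bending_moment_at_section(
            -500.0, 0.0, section_z_mm=250.0,
            application_point_mm=np.array([0.0, 0.0, 0.0]))
        assert m == pytest.approx(0.25 * 500.0)  # posterior shear: ant tension

    def test_axial_offset_matches_cross_product(self):
        """Moment of an offset axial force equals the r x F oracle."""
        f = np.array([0.0, 0.0, -3000.0])
        r = np.array([10.0, 0.0, 0.0]) / 1000.0  # anterior offset, m
        oracle = np.cross(r, f)  # torque about the section centroid
        m = bending_moment_at_section(
            0.0, -3000.0, section_z_mm=100.0, section_centroid_x_mm=0.0,
            application_point_mm=np.array([10.0, 0.0, 0.0]))
        # anterior-tension-positive convention equals -tau_y of the oracle
        assert m == pytest.approx(-oracle[1])
        assert m == pytest.approx(-30.0)

    def test_section_below_application_rejected(self):
        with pytest.raises(ValueError):
            bending_moment_at_section(
                0.0, -1000.0, section_z_mm=-5.0,
                application_point_mm=np.array([0.0, 0.0, 0.0]))
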