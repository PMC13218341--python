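"""Shape model construction and bounded landmark fitting."""
import numpy as np
import pytest

from tibload.geometry import Pose, procrustes_pose
from tibload.phantom import (PhantomSpec, extract_landmarks,
                             generate_population, landmark_weights,
                             make_phantom)
from tibload.ssm import (MARKERS_4, MARKERS_9, PCScores, TrabecularModel,
                         build_ssm, fit_landmarks, model_landmarks,
                         project_to_scores, reconstruct)


def _lm_defs():
    return landmark_weights(40, 24)


def test_identical_training_meshes_give_zero_variance(default_phantom):
    meshes = [default_phantom.cortical.copy() for _ in range(5)]
    model = build_ssm(meshes, _lm_defs())
    assert np.all(model.variances < 1e-16)
    centred = default_phantom.cortical.vertices \
        - default_phantom.cortical.vertices.mean(axis=0)
    np.testing.assert_allclose(model.mean.reshape(-1, 3), centred, atol=1e-9)


def test_rank_one_population_recovers_displacement_field(default_phantom):
    """A population varying along one field yields that field as mode 1."""
    rng = np.random.default_rng(2)
    base = default_phantom.cortical
    field = rng.standard_normal(base.vertices.shape)
    field /= np.linalg.norm(field)
    field -= field.mean(axis=0)  # keep it centred: GPA removes translation
    field /= np.linalg.norm(field)
    coeffs = rng.normal(0.0, 0.5, 30)
    meshes = []
    for c in coeffs:
        m = base.copy()
        m.vertices = m.vertices + c * field
        meshes.append(m)
    model = build_ssm(meshes, _lm_defs(), n_modes=5)
    cos = abs(model.modes[:, 0] @ field.reshape(-1))
    assert cos > 0.99
    assert model.variances[0] == pytest.approx(np.var(coeffs, ddof=1),
                                               rel=0.10)


def test_variance_partition_and_mode_count(small_population):
    n = len(small_population)
    model = build_ssm([m.cortical for m in small_population], _lm_defs(),
                      n_modes=n - 1)
    assert model.n_modes <= n - 1
    ortho = model.modes.T @ model.modes
    np.testing.assert_allclose(ortho, np.eye(model.n_modes), atol=1e-8)
    assert np.all(np.diff(model.variances) <= 1e-9)
    # with all n-1 modes kept, variances account for the total variance
    shapes = np.stack([m.cortical.vertices for m in small_population])
    from tibload.ssm import generalized_procrustes
    X = generalized_procrustes(shapes).reshape(n, -1)
    total = ((X - X.mean(0)) ** 2).sum() / (n - 1)
    assert model.variances.sum() == pytest.approx(total, rel=1e-6)


def test_reconstruct_linearity(trained_model):
    b = 0.5 * trained_model.sd()[:3]
    m1 = reconstruct(trained_model, b)
    m2 = reconstruct(trained_model, 2 * b)
    mean = reconstruct(trained_model, np.zeros(0))
    np.testing.assert_allclose(m2.vertices - mean.vertices,
                               2 * (m1.vertices - mean.vertices), atol=1e-9)


def test_reconstruct_single_mode_matches_matrix_arithmetic(trained_model):
    lam1 = trained_model.variances[0]
    b = np.zeros(trained_model.n_modes)
    b[0] = np.sqrt(lam1)
    mesh = reconstruct(trained_model, b)
    direct = (trained_model.mean
              + trained_model.modes @ b).reshape(-1, 3)
    np.testing.assert_allclose(mesh.vertices, direct, atol=1e-12)


def test_score_vector_too_long_rejected(trained_model):
    with pytest.raises(ValueError):
        reconstruct(trained_model, np.zeros(trained_model.n_modes + 1))


def test_fit_mean_landmarks_returns_mean(trained_model):
    mean_mesh = reconstruct(trained_model, np.zeros(0))
    lms = extract_landmarks(mean_mesh, 40, 24)
    fit = fit_landmarks(trained_model, lms, MARKERS_9, k_sd=3.0)
    assert np.all(np.abs(fit.scores.b)
                  <= 1e-3 * np.maximum(trained_model.sd(), 1e-6))


def test_k_zero_forces_zero_scores(trained_model, rng):
    truth = reconstruct(trained_model, 0.5 * trained_model.sd())
    lms = extract_landmarks(truth, 40, 24)
    fit = fit_landmarks(trained_model, lms, MARKERS_4, k_sd=0.0)
    assert np.all(fit.scores.b == 0.0)


def test_missing_landmark_and_negative_k(trained_model):
    with pytest.raises(KeyError):
        fit_landmarks(trained_model, {"medial_condyle": np.zeros(3)},
                      MARKERS_4, k_sd=2.0)
    with pytest.raises(ValueError):
        fit_landmarks(trained_model, {}, MARKERS_4, k_sd=-1.0)


def test_recovery_matches_grid_search_oracle(trained_model):
    """9-marker fit of a two-mode shape agrees with brute-force search."""
    model = trained_model
    sd = model.sd()
    b_true = np.zeros(model.n_modes)
    b_true[0] = 0.6 * sd[0]
    b_true[1] = -0.4 * sd[1]
    truth = reconstruct(model, b_true)
    lms = extract_landmarks(truth, 40, 24)
    fit = fit_landmarks(model, lms, MARKERS_9, k_sd=3.0)

    y = np.stack([lms[n] for n in MARKERS_9.landmarks])
    step = 0.05
    grid = np.arange(-1.0, 1.0 + 1e-9, step)
    best = (np.inf, None)
    for g1 in grid:
        for g2 in grid:
            b = np.zeros(model.n_modes)
            b[0] = g1 * sd[0]
            b[1] = g2 * sd[1]
            pred = model_landmarks(model, b, MARKERS_9.landmarks)
            pose = procrustes_pose(pred, y)
            obj = ((pose.apply(pred) - y) ** 2).sum()
            if obj < best[0]:
                best = (obj, (g1, g2))
    assert abs(fit.scores.b[0] / sd[0] - best[1][0]) <= step
    assert abs(fit.scores.b[1] / sd[1] - best[1][1]) <= step
    assert fit.objective <= best[0] + 1e-9
    # generating scores recovered
    assert fit.scores.b[0] == pytest.approx(b_true[0], abs=0.02 * sd[0])
    assert fit.scores.b[1] == pytest.approx(b_true[1], abs=0.02 * sd[1])


def test_objective_nondecreasing_as_bounds_tighten(trained_model, rng):
    truth = reconstruct(trained_model, 1.5 * trained_model.sd())
    lms = extract_landmarks(truth, 40, 24)
    lms = {k: v + rng.normal(0, 1.0, 3) for k, v in lms.items()}
    objs = [fit_landmarks(trained_model, lms, MARKERS_4, k_sd=k).objective
            for k in (3.0, 2.0, 1.0, 0.0)]
    for a, b in zip(objs, objs[1:]):
        assert b >= a - 1e-9


def test_pose_invariance_of_scores(trained_model, rng):
    truth = reconstruct(trained_model, 0.7 * trained_model.sd())
    lms = extract_landmarks(truth, 40, 24)
    fit0 = fit_landmarks(trained_model, lms, MARKERS_9, k_sd=3.0)
    theta = 0.4
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = {k: R @ v + np.array([10.0, -5.0, 3.0]) for k, v in lms.items()}
    fit1 = fit_landmarks(trained_model, moved, MARKERS_9, k_sd=3.0)
    np.testing.assert_allclose(fit1.scores.b, fit0.scores.b, atol=1e-6)


def test_nine_marker_self_consistency(trained_model, rng):
    """On model-span shapes the 9-marker fit is near-exact; 4-marker not."""
    errs9, errs4 = [], []
    for _ in range(20):
        b = rng.uniform(-1.0, 1.0, trained_model.n_modes) * trained_model.sd()
        truth = reconstruct(trained_model, b)
        lms = extract_landmarks(truth, 40, 24)
        for markers, out in ((MARKERS_9, errs9), (MARKERS_4, errs4)):
            fit = fit_landmarks(trained_model, lms, markers, k_sd=3.0)
            pose = procrustes_pose(fit.mesh.vertices, truth.vertices)
            aligned = pose.apply(fit.mesh.vertices)
            out.append(np.linalg.norm(aligned - truth.vertices,
                                      axis=1).mean())
    assert np.mean(errs9) < 0.05 * np.mean(errs4)


def test_trabecular_regression_fixed_fraction():
    """Training at a fixed endosteal fraction is recovered within 2%."""
    rng = np.random.default_rng(5)
    specs = [PhantomSpec(length=float(rng.normal(400, 20)),
                         ap_semi_axis=float(rng.normal(13.8, 1.0)),
                         ml_semi_axis=float(rng.normal(12.3, 0.9)),
                         bow_mm=float(rng.normal(5, 1.5)),
                         endosteal_fraction=0.6) for _ in range(12)]
    pop = [make_phantom(s) for s in specs]
    lm = _lm_defs()
    cort = build_ssm([p.cortical for p in pop], lm, n_modes=11)
    endo = build_ssm([p.endosteal for p in pop], lm, n_modes=11)
    trab = TrabecularModel(cort, endo).fit([p.cortical for p in pop],
                                           [p.endosteal for p in pop])
    # in-sample: prediction matches the true endosteal surface closely
    scores = project_to_scores(cort, pop[0].cortical)
    pred = trab.predict_surface(scores)
    pose = procrustes_pose(pred.vertices, pop[0].endosteal.vertices)
    err = np.linalg.norm(pose.apply(pred.vertices)
                         - pop[0].endosteal.vertices, axis=1).mean()
    assert err < 0.25
    # mid-shaft width ratio close to the training fraction
    mid = slice(19 * 24, 20 * 24)
    width_e = pred.vertices[mid, 1].max() - pred.vertices[mid, 1].min()
    scores_posed = reconstruct(cort, scores)
    width_c = scores_posed.vertices[mid, 1].max() \
        - scores_posed.vertices[mid, 1].min()
    assert width_e / width_c == pytest.approx(0.6, rel=0.02)


def test_trabecular_requires_training(trained_model):
    from tibload.ssm import UntrainedModelError
    t = TrabecularModel(trained_model, trained_model)
    with pytest.raises(UntrainedModelError):
        t.predict_scores(PCScores(np.zeros(3), 3.0))


def test_zero_variance_training_predicts_constant(default_phantom):
    meshes_c = [default_phantom.cortical.copy() for _ in range(5)]
    meshes_e = [default_phantom.endosteal.copy() for _ in range(5)]
    lm = _lm_defs()
    cort = build_ssm(meshes_c, lm)
    endo = build_ssm(meshes_e, lm)
    trab = TrabecularModel(cort, endo).fit(meshes_c, meshes_e)
    p1 = trab.predict_surface(np.zeros(cort.n_modes))
    p2 = trab.predict_surface(0.5 * np.ones(cort.n_modes))
    np.testing.assert_allclose(p1.vertices, p2.vertices, atol=1e-6)


def test_mismatched_vertex_counts_rejected(default_phantom):
    from tibload.ssm import CorrespondenceError
    small = make_phantom(PhantomSpec(n_rings=20, n_circ=16))
    with pytest.raises(CorrespondenceError):
        build_ssm([default_phantom.cortical, small.cortical,
                   default_phantom.cortical], _lm_defs())
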