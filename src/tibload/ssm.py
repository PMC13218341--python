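"""Statistical shape modelling and sparse-landmark reconstruction.

A point-distribution model is built from a population of surface meshes in
point correspondence: after generalized Procrustes alignment
(rotation + translation; isotropic scale optional and off by default so
that overall bone size is captured by the shape modes, where it dominates
the first mode), the mean shape and orthonormal variation modes come from
a PCA of the stacked vertex coordinates.

Reconstruction from sparse anatomical landmarks fits principal-component
scores under hard per-mode box bounds |b_j| <= k * sqrt(lambda_j) (the
"+/- k SD" constraint), alternating a closed-form similarity pose step
with a bound-constrained linear least-squares score step. The optimization
is deterministic: it starts at b = 0 with the identity pose.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .geometry import Pose, SurfaceMesh, procrustes_pose

# tiny Tikhonov weight: among equal-objective score vectors prefer small |b|
_RIDGE = 1e-12


class CorrespondenceError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerConfig:
    """Named, ordered landmark subset used for a fit."""

    name: str
    landmarks: tuple[str, ...]


MARKERS_4 = MarkerConfig("4-marker", (
    "medial_condyle", "lateral_condyle",
    "medial_malleolus", "lateral_malleolus"))
MARKERS_9 = MarkerConfig("9-marker", (
    "medial_condyle", "lateral_condyle",
    "medial_malleolus", "lateral_malleolus",
    "tibial_tuberosity", "fibular_head",
    "ant_border_25", "ant_border_50", "ant_border_75"))


@dataclass
class PCScores:
    """Principal-component scores (mm per mode) with their bound."""

    b: np.ndarray
    k_sd: float

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.k_sd < 0:
            raise ValueError("bound multiplier k must be non-negative")


@dataclass
class ShapeModel:
    """Mean shape, orthonormal modes and per-mode variances.

    ``mean`` is the 3N vector of the Procrustes-mean vertex coordinates;
    ``modes`` has orthonormal columns; ``variances`` (mm^2) are
    non-increasing. ``landmark_defs`` maps landmark names to affine vertex
    weights, letting landmarks be evaluated on any shape in the model
    span.
    """

    mean: np.ndarray                   # (3N,)
    modes: np.ndarray                  # (3N, K)
    variances: np.ndarray              # (K,)
    faces: np.ndarray
    landmark_defs: dict[str, list[tuple[int, float]]]
    allow_scale: bool = False

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.mean) // 3

    def sd(self) -> np.ndarray:
        return np.sqrt(self.variances)

    def landmark_matrix(self, names: tuple[str, ...]) -> np.ndarray:
        """Sparse-in-spirit (L, N) weight matrix for the named landmarks."""
        W = np.zeros((len(names), self.n_vertices))
        for r, name in enumerate(names):
            if name not in self.landmark_defs:
                raise KeyError(f"model has no landmark '{name}'")
            for idx, w in self.landmark_defs[name]:
                W[r, idx] = w
        return W

    def save(self, path) -> None:
        names = sorted(self.landmark_defs)
        np.savez_compressed(
            path, mean=self.mean, modes=self.modes, variances=self.variances,
            faces=self.faces, allow_scale=self.allow_scale,
            lm_names=np.array(names),
            lm_tables=np.array(
                [np.array(self.landmark_defs[n], dtype=float)
                 for n in names], dtype=object),
            allow_pickle=True)

    @staticmethod
    def load(path) -> "ShapeModel":
        z = np.load(path, allow_pickle=True)
        defs = {str(n): [(int(i), float(w)) for i, w in tab]
                for n, tab in zip(z["lm_names"], z["lm_tables"])}
        return ShapeModel(mean=z["mean"], modes=z["modes"],
                          variances=z["variances"], faces=z["faces"],
                          landmark_defs=defs,
                          allow_scale=bool(z["allow_scale"]))


# --------------------------------------------------------------------------
# model building
# --------------------------------------------------------------------------

def generalized_procrustes(shapes: np.ndarray, allow_scale: bool = False,
                           iterations: int = 10) -> np.ndarray:
    """Align (n, N, 3) shapes to their evolving mean; returns aligned copy."""
    aligned = shapes - shapes.mean(axis=1, keepdims=True)
    ref = aligned[0]
    for _ in range(iterations):
        new = np.empty_like(aligned)
        for i, s in enumerate(aligned):
            new[i] = procrustes_pose(s, ref, allow_scale=allow_scale).apply(s)
        mean = new.mean(axis=0)
        if np.allclose(mean, ref, atol=1e-12):
            aligned = new
            break
        ref = mean
        aligned = new
    return aligned


def build_ssm(meshes: list[SurfaceMesh],
              landmark_defs: dict[str, list[tuple[int, float]]],
              variance_kept: float = 0.99,
              n_modes: int | None = None,
              allow_scale: bool = False) -> ShapeModel:
    """PCA point-distribution model from corresponding training meshes."""
    if len(meshes) < 3:
        raise CorrespondenceError("need at least 3 training meshes")
    counts = {m.n_vertices for m in meshes}
    if len(counts) != 1:
        raise CorrespondenceError(f"mismatched vertex counts: {counts}")
    shapes = np.stack([m.vertices for m in meshes])
    aligned = generalized_procrustes(shapes, allow_scale=allow_scale)
    n = len(meshes)
    X = aligned.reshape(n, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD: modes are right singular vectors, variances s^2/(n-1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s ** 2 / (n - 1)
    k_max = min(n - 1, len(lam))
    if n_modes is None:
        total = lam[:k_max].sum()
        if total <= 0:
            k = 1  # degenerate population: keep one null mode
        else:
            cum = np.cumsum(lam[:k_max]) / total
            k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    else:
        k = min(n_modes, k_max)
    return ShapeModel(mean=mean, modes=Vt[:k].T, variances=lam[:k],
                      faces=meshes[0].faces.copy(),
                      landmark_defs=dict(landmark_defs),
                      allow_scale=allow_scale)


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------

def reconstruct(model: ShapeModel, scores: PCScores | np.ndarray,
                pose: Pose | None = None) -> SurfaceMesh:
    """Surface for given scores: pose o (mean + modes @ b). Linear in b."""
    b = scores.b if isinstance(scores, PCScores) else np.asarray(scores, float)
    if len(b) > model.n_modes:
        raise ValueError(f"{len(b)} scores but model has {model.n_modes} modes")
    x = model.mean + model.modes[:, :len(b)] @ b
    verts = x.reshape(-1, 3)
    if pose is not None:
        verts = pose.apply(verts)
    return SurfaceMesh(verts, model.faces.copy())


def model_landmarks(model: ShapeModel, b: np.ndarray,
                    names: tuple[str, ...]) -> np.ndarray:
    W = model.landmark_matrix(names)
    verts = (model.mean + model.modes[:, :len(b)] @ b).reshape(-1, 3)
    return W @ verts


@dataclass
class FitResult:
    scores: PCScores
    mesh: SurfaceMesh          # reconstruction posed into the landmark frame
    pose: Pose
    objective: float           # sum of squared landmark distances (mm^2)
    n_iterations: int
    bound_active: np.ndarray   # per-mode flag: |b_j| at its bound


def fit_landmarks(model: ShapeModel, observed: dict[str, np.ndarray],
                  config: MarkerConfig, k_sd: float = 2.0,
                  allow_scale: bool | None = None,
                  tol: float = 1e-9, max_iter: int = 200) -> FitResult:
    """Bounded PC-score fit of the model to observed landmarks.

    Minimizes the sum of squared distances between the posed model
    landmarks and the observations over (pose, b), subject to
    |b_j| <= k_sd * sqrt(lambda_j), by alternating a closed-form
    Kabsch/Umeyama pose step with a box-constrained least-squares score
    step. Scale in the pose follows the model's training setting unless
    overridden.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be non-negative")
    missing = [n for n in config.landmarks if n not in observed]
    if missing:
        raise KeyError(f"observed landmarks missing {missing}")
    if allow_scale is None:
        allow_scale = model.allow_scale

    names = config.landmarks
    y = np.stack([np.asarray(observed[n], dtype=float) for n in names])
    if not np.all(np.isfinite(y)):
        raise ValueError("landmark coordinates must be finite")
    W = model.landmark_matrix(names)
    K = model.n_modes
    bound = k_sd * model.sd()
    # A_full maps scores to stacked landmark coordinates in the model frame
    A_model = np.stack([W @ model.modes[:, j].reshape(-1, 3)
                        for j in range(K)], axis=2)   # (L, 3, K)
    l0 = W @ model.mean.reshape(-1, 3)                # (L, 3)

    from scipy.spatial.transform import Rotation

    b = np.zeros(K)
    pose = Pose.identity()
    prev_obj = np.inf
    it = 0
    n_pose = 7 if allow_scale else 6
    eff = np.maximum(bound, 1e-15)  # zero-variance modes: pin b ~ 0
    for it in range(1, max_iter + 1):
        lm = l0 + np.einsum("lck,k->lc", A_model, b)
        if it == 1:
            pose = procrustes_pose(lm, y, allow_scale=allow_scale)
        posed = pose.apply(lm)
        resid = y - posed
        obj = float((resid ** 2).sum())
        if prev_obj - obj < tol * max(1.0, abs(prev_obj)) and it > 2:
            prev_obj = min(obj, prev_obj)
            break
        prev_obj = min(obj, prev_obj)
        if k_sd == 0.0 or K == 0:
            pose = procrustes_pose(lm, y, allow_scale=allow_scale)
            prev_obj = float(((pose.apply(lm) - y) ** 2).sum())
            continue
        # joint Gauss-Newton step: scores (box-bounded) + pose increment
        L = len(lm)
        J_b = (pose.scale
               * np.einsum("ci,lik->lck", pose.rotation, A_model)
               ).reshape(-1, K)
        J_pose = np.zeros((L, 3, n_pose))
        rel = posed - pose.translation      # s R m
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = 1.0
            J_pose[:, :, axis] = np.cross(e, rel)   # rotation increment
            J_pose[:, axis, 3 + axis] = 1.0         # translation
        if allow_scale:
            J_pose[:, :, 6] = rel                   # d/d(log s)
        J = np.hstack([J_b, J_pose.reshape(-1, n_pose)])
        # tiny ridge on the total scores: smallest-norm b among ties
        A_aug = np.vstack([J, np.sqrt(_RIDGE)
                           * np.hstack([np.eye(K), np.zeros((K, n_pose))])])
        r_aug = np.concatenate([resid.reshape(-1), -np.sqrt(_RIDGE) * b])
        lb = np.concatenate([-eff - b, np.full(n_pose, -np.inf)])
        ub = np.concatenate([eff - b, np.full(n_pose, np.inf)])
        sol = lsq_linear(A_aug, r_aug, bounds=(lb, ub), tol=1e-12,
                         method="bvls")
        db = sol.x[:K]
        dw = sol.x[K:K + 3]
        dt = sol.x[K + 3:K + 6]
        b = np.clip(b + db, -eff, eff)
        R_new = Rotation.from_rotvec(dw).as_matrix() @ pose.rotation
        s_new = pose.scale * float(np.exp(sol.x[K + 6])) if allow_scale \
            else pose.scale
        pose = Pose(scale=s_new, rotation=R_new,
                    translation=pose.translation + dt)
    # final objective at the returned iterate
    lm = l0 + np.einsum("lck,k->lc", A_model, b)
    prev_obj = float(((pose.apply(lm) - y) ** 2).sum())

    scores = PCScores(b=b, k_sd=k_sd)
    mesh = reconstruct(model, scores, pose)
    active = np.isclose(np.abs(b), bound, rtol=1e-6, atol=1e-12) & (bound > 0)
    return FitResult(scores=scores, mesh=mesh, pose=pose, objective=prev_obj,
                     n_iterations=it, bound_active=active)


def project_to_scores(model: ShapeModel, mesh: SurfaceMesh) -> np.ndarray:
    """Least-squares scores of a corresponding mesh (aligned, unbounded)."""
    if mesh.n_vertices != model.n_vertices:
        raise CorrespondenceError("vertex count differs from model")
    pose = procrustes_pose(mesh.vertices,
                           model.mean.reshape(-1, 3),
                           allow_scale=model.allow_scale)
    x = pose.apply(mesh.vertices).reshape(-1)
    return model.modes.T @ (x - model.mean)


# --------------------------------------------------------------------------
# trabecular (endosteal) prediction
# --------------------------------------------------------------------------

class UntrainedModelError(RuntimeError):
    pass


@dataclass
class TrabecularModel:
    """Linear regression from cortical PC scores to endosteal PC scores.

    Emulates a regression-based internal-geometry predictor: the endosteal
    surface of a new bone is not observable from skin landmarks, so it is
    predicted from the fitted cortical shape coefficients.
    """

    cortical_model: ShapeModel
    endosteal_model: ShapeModel
    coef: np.ndarray | None = None        # (Kc + 1, Ke) with intercept row
    residual_sd: np.ndarray | None = None

    def fit(self, cortical_meshes: list[SurfaceMesh],
            endosteal_meshes: list[SurfaceMesh]) -> "TrabecularModel":
        if len(cortical_meshes) != len(endosteal_meshes):
            raise ValueError("paired training lists required")
        Xc = np.stack([project_to_scores(self.cortical_model, m)
                       for m in cortical_meshes])
        Ye = np.stack([project_to_scores(self.endosteal_model, m)
                       for m in endosteal_meshes])
        X1 = np.column_stack([np.ones(len(Xc)), Xc])
        self.coef, *_ = np.linalg.lstsq(X1, Ye, rcond=None)
        resid = Ye - X1 @ self.coef
        dof = max(1, len(Xc) - X1.shape[1])
        self.residual_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
        return self

    def predict_scores(self, cortical_scores: PCScores | np.ndarray,
                       ) -> np.ndarray:
        if self.coef is None:
            raise UntrainedModelError("trabecular regression not fitted")
        b = (cortical_scores.b if isinstance(cortical_scores, PCScores)
             else np.asarray(cortical_scores, float))
        bc = np.zeros(self.cortical_model.n_modes)
        bc[:len(b)] = b
        return np.concatenate([[1.0], bc]) @ self.coef

    def predict_surface(self, cortical_scores: PCScores | np.ndarray,
                        pose: Pose | None = None) -> SurfaceMesh:
        be = self.predict_scores(cortical_scores)
        return reconstruct(self.endosteal_model, be, pose)


def predict_trabecular(trained: TrabecularModel,
                       cortical_scores: PCScores,
                       pose: Pose | None = None) -> SurfaceMesh:
    """Endosteal surface predicted from fitted cortical scores."""
    return trained.predict_surface(cortical_scores, pose)
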