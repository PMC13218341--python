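"""Linear-elastic tetrahedral finite elements for whole-bone loading.

Four-node (constant-strain) tetrahedra, assembled into a sparse global
stiffness matrix. Boundary conditions follow the whole-bone convention
used throughout the package: every degree of freedom of the proximal
plateau node set is fixed, and the ankle joint contact force is distributed
uniformly (equal nodal forces) over the distal articular surface node set.

Internal unit system is mm-N-MPa, so Young's moduli are stored in MPa and
strains are dimensionless (reported as microstrain where stated).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .tetmesh import TetMesh

MICRO = 1e6  # strain -> microstrain


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic linear elasticity, E in GPa."""

    youngs_gpa: float
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if self.youngs_gpa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")

    @property
    def youngs_mpa(self) -> float:
        return self.youngs_gpa * 1e3

    def lame(self) -> tuple[float, float]:
        E, nu = self.youngs_mpa, self.poisson
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


DEFAULT_MATERIALS = {0: MaterialProperties(17.0, 0.3),   # cortical
                     1: MaterialProperties(1.0, 0.3)}    # trabecular


@dataclass(frozen=True)
class FEConfig:
    """Field-summary and convergence-study settings."""

    strain_threshold_ue: float = 3000.0     # strained-volume threshold
    percentile: float = 95.0                # volume-weighted percentile
    kappa: float = 1.0                      # tension/compression asymmetry
    mesh_ladder_mm: tuple[float, ...] = (5.5, 3.6, 2.7, 2.0)
    convergence_tol_pct: float = 5.0
    exclude_bc_adjacent: bool = True

    def __post_init__(self) -> None:
        if self.strain_threshold_ue <= 0:
            raise ValueError("strain threshold must be positive")
        if self.kappa < 1.0:
            raise ValueError("kappa must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if any(a <= b for a, b in zip(self.mesh_ladder_mm,
                                      self.mesh_ladder_mm[1:])):
            raise ValueError("mesh ladder must be strictly decreasing")


class ModelError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# element kinematics
# --------------------------------------------------------------------------

def _element_gradients(nodes: np.ndarray, tets: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric gradients (M, 4, 3) and volumes (M,) from corner nodes.

    For linear tets these are the shape-function gradients; for
    straight-sided quadratic tets they are the (constant) gradients of the
    barycentric coordinates from which the 10-node gradients follow.
    """
    v = nodes[tets[:, :4]]
    J = v[:, 1:] - v[:, :1]                       # (M, 3, 3) edge matrix
    vol = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)                       # rows: d(local)/d(x)
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:] = np.transpose(Jinv, (0, 2, 1))  # dN_i/dx for i = 1..3
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    return grads, vol


# 4-point Gauss rule on the tetrahedron (exact for quadratic integrands)
_QP_A, _QP_B = 0.5854101966249685, 0.13819660112501052
_QUAD_POINTS = np.array([
    [_QP_A, _QP_B, _QP_B, _QP_B],
    [_QP_B, _QP_A, _QP_B, _QP_B],
    [_QP_B, _QP_B, _QP_A, _QP_B],
    [_QP_B, _QP_B, _QP_B, _QP_A],
])
_TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


def _tet10_gradients(bary_grads: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """10-node shape gradients (M, 10, 3) at barycentric point ``lam``."""
    M = len(bary_grads)
    g = np.empty((M, 10, 3))
    for i in range(4):
        g[:, i] = (4.0 * lam[i] - 1.0) * bary_grads[:, i]
    for e, (a, b) in enumerate(_TET10_EDGES):
        g[:, 4 + e] = 4.0 * (lam[a] * bary_grads[:, b]
                             + lam[b] * bary_grads[:, a])
    return g


def _elastic_d(material: MaterialProperties) -> np.ndarray:
    lam, mu = material.lame()
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.diag([mu, mu, mu])
    return D


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (M, 6, 3*nn), engineering shear."""
    M, nn = grads.shape[:2]
    B = np.zeros((M, 6, 3 * nn))
    for a in range(nn):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


_FACE_LOCAL = (  # (corner triple, matching midside locals in 10-node layout)
    ((0, 1, 2), (4, 5, 6)),
    ((0, 1, 3), (4, 8, 7)),
    ((0, 2, 3), (6, 9, 7)),
    ((1, 2, 3), (5, 9, 8)),
)


def _surface_load_weights(mesh: TetMesh, node_set: np.ndarray) -> np.ndarray:
    """Per-node weights of a consistent uniform traction on a boundary set.

    Boundary triangles are tet faces whose corner nodes all belong to the
    set. Linear elements: each corner carries a third of the face area.
    Quadratic elements: each midside carries a third, corners none (the
    consistent load vector of a uniform traction on a 6-node triangle).
    """
    member = np.zeros(len(mesh.nodes), dtype=bool)
    member[node_set] = True
    order2 = mesh.tets.shape[1] == 10
    w = np.zeros(len(mesh.nodes))
    seen = set()
    for corners, mids in _FACE_LOCAL:
        tri = mesh.tets[:, corners]
        on = member[tri].all(axis=1)
        if not on.any():
            continue
        idx = np.flatnonzero(on)
        pts = mesh.nodes[tri[idx]]
        area = 0.5 * np.linalg.norm(
            np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0]), axis=1)
        targets = mesh.tets[idx][:, mids] if order2 else tri[idx]
        for row, a, t in zip(tri[idx], area, targets):
            key = tuple(sorted(row))
            if key in seen:  # each boundary face borders exactly one tet,
                continue     # but guard against duplicates anyway
            seen.add(key)
            w[t] += a / 3.0
    total = w.sum()
    if total <= 0:
        raise ModelError("load node set has no boundary faces")
    return w / total


# --------------------------------------------------------------------------
# model assembly and solution
# --------------------------------------------------------------------------

@dataclass
class FEModel:
    """Assembled, constrained linear system for one mesh."""

    mesh: TetMesh
    materials: dict[int, MaterialProperties]
    stiffness: sp.csr_matrix                    # full symmetric K
    fixed_dofs: np.ndarray
    free_dofs: np.ndarray
    rhs: np.ndarray                             # full-length load vector
    load: np.ndarray                            # net applied force (3,)
    load_weights: np.ndarray | None = None      # per-node traction weights
    _lu: spla.SuperLU | None = field(default=None, repr=False)

    @property
    def n_dofs(self) -> int:
        return 3 * len(self.mesh.nodes)

    def with_load(self, force: np.ndarray) -> "FEModel":
        """Same stiffness (and factorization), new distal load."""
        force = np.asarray(force, dtype=float)
        rhs = _weighted_rhs(self.load_weights, force)
        return replace(self, rhs=rhs, load=force)


def _weighted_rhs(weights: np.ndarray, force: np.ndarray) -> np.ndarray:
    rhs = np.zeros(3 * len(weights))
    for c in range(3):
        rhs[c::3] = weights * force[c]
    return rhs


def build_fe_model(mesh: TetMesh,
                   materials: dict[int, MaterialProperties] | None = None,
                   load: np.ndarray | tuple = (0.0, 0.0, 0.0),
                   fix_components: tuple[int, ...] = (0, 1, 2),
                   extra_fixed_dofs: np.ndarray | None = None) -> FEModel:
    """Assemble stiffness, fix the proximal plateau, distribute the load.

    The load is the net external force vector (N) acting on the distal
    surface in the shank frame; it is split equally over the distal-surface
    nodes (uniform distributing coupling). ``fix_components`` selects which
    displacement components of the plateau nodes are constrained (all three
    by default -- the fully fixed plateau); ``extra_fixed_dofs`` adds global
    DOF indices, e.g. pins that remove rigid-body modes in analytic
    benchmark states.
    """
    materials = dict(DEFAULT_MATERIALS if materials is None else materials)
    for name in ("proximal_plateau", "distal_surface"):
        if name not in mesh.node_sets or len(mesh.node_sets[name]) == 0:
            raise ModelError(f"mesh lacks required node set '{name}'")
    load = np.asarray(load, dtype=float)
    if not np.all(np.isfinite(load)):
        raise ModelError("load must be finite")

    grads, vol = _element_gradients(mesh.nodes, mesh.tets)
    if np.any(vol <= 0):
        raise ModelError("mesh contains non-positive element volumes")
    D = np.empty((len(mesh.tets), 6, 6))
    for mid, props in materials.items():
        D[mesh.material == mid] = _elastic_d(props)

    order2 = mesh.tets.shape[1] == 10
    nn = 10 if order2 else 4
    n = 3 * len(mesh.nodes)
    blocks = []
    chunk = 20000
    for s in range(0, len(mesh.tets), chunk):
        sl = slice(s, min(s + chunk, len(mesh.tets)))
        if order2:
            ke = 0.0
            for lam in _QUAD_POINTS:
                B = _b_matrices(_tet10_gradients(grads[sl], lam))
                ke = ke + 0.25 * np.einsum("mji,mjk,mkl,m->mil",
                                           B, D[sl], B, vol[sl],
                                           optimize=True)
        else:
            B = _b_matrices(grads[sl])
            ke = np.einsum("mji,mjk,mkl,m->mil", B, D[sl], B, vol[sl],
                           optimize=True)
        dof = (3 * mesh.tets[sl, :, None] + np.arange(3)).reshape(-1, 3 * nn)
        rows = np.repeat(dof, 3 * nn, axis=1).ravel()
        cols = np.tile(dof, (1, 3 * nn)).ravel()
        blocks.append(sp.coo_matrix((ke.ravel(), (rows, cols)),
                                    shape=(n, n)).tocsr())
    K = blocks[0]
    for b in blocks[1:]:
        K = K + b

    fixed = (3 * mesh.node_sets["proximal_plateau"][:, None]
             + np.asarray(fix_components, dtype=np.int64)).ravel()
    if extra_fixed_dofs is not None:
        fixed = np.concatenate([fixed, np.asarray(extra_fixed_dofs,
                                                  dtype=np.int64)])
    fixed = np.unique(fixed)
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    weights = _surface_load_weights(mesh, mesh.node_sets["distal_surface"])
    return FEModel(mesh=mesh, materials=materials, stiffness=K,
                   fixed_dofs=fixed, free_dofs=free,
                   rhs=_weighted_rhs(weights, load), load=load,
                   load_weights=weights)


def solve_linear_elasticity(model: FEModel) -> np.ndarray:
    """Nodal displacements (N, 3); fixed DOFs exactly zero."""
    Kff = model.stiffness[model.free_dofs][:, model.free_dofs].tocsc()
    if model._lu is None:
        # minimum-degree on K + K^T exploits the symmetric FEM structure
        model._lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
    f = model.rhs[model.free_dofs]
    u_free = model._lu.solve(f)
    resid = np.linalg.norm(Kff @ u_free - f)
    denom = np.linalg.norm(f)
    if denom > 0 and resid / denom > 1e-8:
        raise ModelError(f"solver residual too large: {resid / denom:.2e}")
    u = np.zeros(model.n_dofs)
    u[model.free_dofs] = u_free
    return u.reshape(-1, 3)


def reaction_forces(model: FEModel, displacements: np.ndarray) -> np.ndarray:
    """Net reaction at the fixed node set (equals -applied load)."""
    r = model.stiffness @ displacements.ravel() - model.rhs
    return np.array([r[model.fixed_dofs[model.fixed_dofs % 3 == c]].sum()
                     for c in range(3)])


# --------------------------------------------------------------------------
# field quantities
# --------------------------------------------------------------------------

@dataclass
class FEResult:
    strain: np.ndarray             # (M, 6) engineering [xx yy zz xy yz zx]
    stress: np.ndarray             # (M, 6) MPa
    principal_stress: np.ndarray   # (M, 3) sorted descending, MPa
    pmvm_strain: np.ndarray        # (M,) dimensionless equivalent strain
    element_volume: np.ndarray     # (M,) mm^3


@dataclass
class FieldSummary:
    pct95_pmvm_ue: float
    strained_volume_mm3: float
    peak_tensile_mpa: float
    peak_compressive_mpa: float


def equivalent_strain_pmvm(strain: np.ndarray, poisson: float,
                           kappa: float = 1.0) -> np.ndarray:
    """Pressure-modified von Mises equivalent strain.

    A pressure-sensitive equivalent strain for materials with asymmetric
    tensile/compressive strength (bone, concrete). ``kappa`` is the
    compressive-to-tensile strength ratio; at ``kappa = 1`` the measure
    reduces exactly to the von Mises equivalent strain, normalized so a
    uniaxial stress state returns |eps_axial|.

    ``strain`` is (M, 6) engineering notation [xx yy zz xy yz zx].
    """
    e = np.asarray(strain, dtype=float)
    i1 = e[:, :3].sum(axis=1)
    # tensor shears = engineering/2; J2 of the deviatoric strain tensor
    dev = e[:, :3] - i1[:, None] / 3.0
    j2 = 0.5 * (dev ** 2).sum(axis=1) + 0.25 * (e[:, 3:] ** 2).sum(axis=1)
    nu = poisson
    k = kappa
    a = (k - 1.0) / (2.0 * k * (1.0 - 2.0 * nu)) if k != 1.0 else 0.0
    inner = ((k - 1.0) / (1.0 - 2.0 * nu)) ** 2 * i1 ** 2 if k != 1.0 else 0.0
    root = np.sqrt(inner + 12.0 * k / (1.0 + nu) ** 2 * j2)
    return a * i1 + root / (2.0 * k)


def field_metrics(displacements: np.ndarray, mesh: TetMesh,
                  materials: dict[int, MaterialProperties] | None = None,
                  config: FEConfig = FEConfig()) -> FEResult:
    """Per-element (centroid) strain, stress and derived measures."""
    materials = dict(DEFAULT_MATERIALS if materials is None else materials)
    grads, vol = _element_gradients(mesh.nodes, mesh.tets)
    if mesh.tets.shape[1] == 10:  # evaluate at the element centroid
        grads = _tet10_gradients(grads, np.full(4, 0.25))
    u = displacements[mesh.tets]                     # (M, nn, 3)
    H = np.einsum("maj,mai->mij", grads, u)          # displacement gradient
    eps = 0.5 * (H + np.transpose(H, (0, 2, 1)))
    strain = np.column_stack([
        eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
        2 * eps[:, 0, 1], 2 * eps[:, 1, 2], 2 * eps[:, 2, 0]])

    stress_t = np.empty_like(eps)
    pois = np.empty(len(mesh.tets))
    tr = np.trace(eps, axis1=1, axis2=2)
    eye = np.eye(3)
    for mid, props in materials.items():
        mask = mesh.material == mid
        lam, mu = props.lame()
        stress_t[mask] = lam * tr[mask, None, None] * eye + 2 * mu * eps[mask]
        pois[mask] = props.poisson
    stress = np.column_stack([
        stress_t[:, 0, 0], stress_t[:, 1, 1], stress_t[:, 2, 2],
        stress_t[:, 0, 1], stress_t[:, 1, 2], stress_t[:, 2, 0]])
    princ = np.linalg.eigvalsh(stress_t)[:, ::-1]    # sorted descending

    if len(set(np.round(pois, 12))) == 1:
        pmvm = equivalent_strain_pmvm(strain, float(pois[0]), config.kappa)
    else:  # per-material Poisson ratios
        pmvm = np.empty(len(strain))
        for mid, props in materials.items():
            mask = mesh.material == mid
            pmvm[mask] = equivalent_strain_pmvm(strain[mask], props.poisson,
                                                config.kappa)
    return FEResult(strain=strain, stress=stress, principal_stress=princ,
                    pmvm_strain=pmvm, element_volume=vol)


def volume_weighted_percentile(values: np.ndarray, volumes: np.ndarray,
                               pct: float) -> float:
    """Value at which the sorted cumulative volume first reaches pct%."""
    order = np.argsort(values)
    cum = np.cumsum(volumes[order])
    target = pct / 100.0 * cum[-1]
    return float(values[order][np.searchsorted(cum, target)])


def _bc_adjacent_elements(mesh: TetMesh) -> np.ndarray:
    fixed_nodes = mesh.node_sets["proximal_plateau"]
    mask = np.zeros(len(mesh.nodes), dtype=bool)
    mask[fixed_nodes] = True
    return mask[mesh.tets].any(axis=1)


def summarize_results(result: FEResult, mesh: TetMesh,
                      config: FEConfig = FEConfig()) -> FieldSummary:
    """Strained volume, volume-weighted strain percentile and stress peaks.

    Peak principal stresses optionally exclude elements touching the fixed
    plateau nodes (the constrained face carries a stress singularity in the
    displacement formulation).
    """
    thresh = config.strain_threshold_ue / MICRO
    strained = float(result.element_volume[result.pmvm_strain > thresh].sum())
    pct = volume_weighted_percentile(result.pmvm_strain,
                                     result.element_volume,
                                     config.percentile) * MICRO
    include = np.ones(len(result.pmvm_strain), dtype=bool)
    if config.exclude_bc_adjacent:
        include &= ~_bc_adjacent_elements(mesh)
        if not include.any():
            include[:] = True
    peak_t = float(result.principal_stress[include, 0].max())
    peak_c = float(result.principal_stress[include, 2].min())
    return FieldSummary(pct95_pmvm_ue=pct, strained_volume_mm3=strained,
                        peak_tensile_mpa=peak_t, peak_compressive_mpa=peak_c)


# --------------------------------------------------------------------------
# convenience driver and mesh convergence
# --------------------------------------------------------------------------

def run_fe_case(mesh: TetMesh, load: np.ndarray,
                materials: dict[int, MaterialProperties] | None = None,
                config: FEConfig = FEConfig()) -> FieldSummary:
    model = build_fe_model(mesh, materials, load)
    u = solve_linear_elasticity(model)
    res = field_metrics(u, mesh, materials, config)
    return summarize_results(res, mesh, config)


def apply_convergence_rule(sizes, metric_rows, tol_pct: float):
    """First ladder size whose metrics all change < tol% vs the previous.

    ``metric_rows`` is (n_sizes, n_metrics), coarse to fine. Returns the
    converged size or ``None`` when the ladder never settles.
    """
    rows = np.asarray(metric_rows, dtype=float)
    for i in range(1, len(rows)):
        change = 100.0 * np.abs(rows[i] - rows[i - 1]) / np.maximum(
            np.abs(rows[i - 1]), 1e-300)
        if np.all(change < tol_pct):
            return sizes[i]
    return None


def run_mesh_convergence(mesh_factory, load: np.ndarray,
                         materials: dict[int, MaterialProperties] | None = None,
                         config: FEConfig = FEConfig()):
    """Run the mesh-size ladder coarse-to-fine and apply the <tol% rule.

    ``mesh_factory(edge_mm)`` must return a :class:`TetMesh`. Returns
    ``(converged_size_mm or None, table)`` where the table rows carry the
    three key metrics (strain percentile, peak tensile, peak compressive)
    and their percentage change from the previous ladder entry. The first
    ladder size whose three changes are all below tolerance is reported;
    a ladder that never converges yields ``None`` rather than an error.
    """
    import pandas as pd

    if len(config.mesh_ladder_mm) < 2:
        raise ValueError("convergence ladder needs at least two sizes")
    rows = []
    prev = None
    metric_rows = []
    for size in config.mesh_ladder_mm:
        mesh = mesh_factory(size)
        summ = run_fe_case(mesh, load, materials, config)
        metrics = np.array([summ.pct95_pmvm_ue, summ.peak_tensile_mpa,
                            summ.peak_compressive_mpa])
        metric_rows.append(metrics)
        if prev is None:
            changes = np.full(3, np.nan)
        else:
            changes = 100.0 * np.abs(metrics - prev) / np.maximum(
                np.abs(prev), 1e-300)
        rows.append({"mesh_size_mm": size, "n_elements": mesh.n_elements,
                     "pct95_pmvm_ue": metrics[0],
                     "peak_tensile_mpa": metrics[1],
                     "peak_compressive_mpa": metrics[2],
                     "change_strain_pct": changes[0],
                     "change_tensile_pct": changes[1],
                     "change_compressive_pct": changes[2]})
        prev = metrics
    converged = apply_convergence_rule(config.mesh_ladder_mm, metric_rows,
                                       config.convergence_tol_pct)
    return converged, pd.DataFrame(rows)
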