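"""Structured tetrahedral meshing of tibia phantoms and boxes.

The mesher splits a structured cylindrical (or cartesian) hexahedral grid
into tetrahedra with a fixed main-diagonal pattern that is conforming
across cell faces, avoiding a general-purpose mesher dependency. Elements
are labelled cortical or trabecular by whether their centroid falls inside
the endosteal boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, pi, sqrt

import numpy as np

from .phantom import PhantomSpec, _ENDO_AXIAL_INSET

CORTICAL = 0
TRABECULAR = 1


class MeshingError(RuntimeError):
    pass


@dataclass
class TetMesh:
    nodes: np.ndarray                     # (N, 3) mm
    tets: np.ndarray                      # (M, 4) int, positive orientation
    material: np.ndarray                  # (M,) int in {CORTICAL, TRABECULAR}
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def element_volumes(self) -> np.ndarray:
        # corner nodes define the (straight-sided) geometry for any order
        v = self.nodes[self.tets[:, :4]]
        d = v[:, 1:] - v[:, :1]
        return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    @property
    def n_elements(self) -> int:
        return len(self.tets)


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    v = nodes[tets]
    d = v[:, 1:] - v[:, :1]
    vol = np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0
    neg = vol < 0
    tets = tets.copy()
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    vol = np.abs(vol)
    if np.any(vol <= 1e-12):
        raise MeshingError("degenerate (zero-volume) elements produced")
    return tets


# six-tet main-diagonal split of a hex (conforming on structured grids)
_HEX_TETS = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
             (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))
# three-tet split of a wedge (centre prism), diagonal matched to _HEX_TETS
_WEDGE_TETS = ((0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3))


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan approximation
    return pi * (3 * (a + b) - sqrt((3 * a + b) * (a + 3 * b)))


def tet_mesh_from_profiles(
    z_planes: np.ndarray,
    centre_x: np.ndarray,
    a_peri: np.ndarray,
    b_peri: np.ndarray,
    n_theta: int,
    n_radial: int,
    endo_z: np.ndarray | None = None,
    endo_a: np.ndarray | None = None,
    endo_b: np.ndarray | None = None,
    endo_cx: np.ndarray | None = None,
) -> TetMesh:
    """Build the structured solid mesh from per-plane elliptical profiles.

    ``endo_*`` arrays (sampled on their own axial stations) define the
    endosteal boundary used only for material labelling; outside their
    axial range the bone is labelled cortical (solid ends).
    """
    z_planes = np.asarray(z_planes, dtype=float)
    nz = len(z_planes) - 1
    nper = 1 + n_radial * n_theta
    theta = 2 * pi * np.arange(n_theta) / n_theta
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rho = np.arange(1, n_radial + 1) / n_radial

    nodes = np.empty(((nz + 1) * nper, 3))
    for p, z in enumerate(z_planes):
        off = p * nper
        nodes[off] = (centre_x[p], 0.0, z)
        ring = off + 1 + np.arange(n_radial * n_theta)
        rr = np.repeat(rho, n_theta)
        nodes[ring, 0] = centre_x[p] + rr * a_peri[p] * np.tile(cos_t, n_radial)
        nodes[ring, 1] = rr * b_peri[p] * np.tile(sin_t, n_radial)
        nodes[ring, 2] = z

    def nid(p: int, k: int, i: int) -> int:
        # k = 0 is the centre node, k >= 1 are rings
        if k == 0:
            return p * nper
        return p * nper + 1 + (k - 1) * n_theta + (i % n_theta)

    tets = []
    for p in range(nz):
        for i in range(n_theta):
            w = (nid(p, 0, 0), nid(p, 1, i), nid(p, 1, i + 1),
                 nid(p + 1, 0, 0), nid(p + 1, 1, i), nid(p + 1, 1, i + 1))
            tets.extend(tuple(w[a] for a in t) for t in _WEDGE_TETS)
        for k in range(1, n_radial):
            for i in range(n_theta):
                h = (nid(p, k, i), nid(p, k + 1, i), nid(p, k + 1, i + 1),
                     nid(p, k, i + 1), nid(p + 1, k, i), nid(p + 1, k + 1, i),
                     nid(p + 1, k + 1, i + 1), nid(p + 1, k, i + 1))
                tets.extend(tuple(h[a] for a in t) for t in _HEX_TETS)
    tets = _orient_positive(nodes, np.asarray(tets, dtype=np.int64))

    centroids = nodes[tets].mean(axis=1)
    material = np.full(len(tets), CORTICAL, dtype=np.int64)
    if endo_a is not None:
        ez = np.asarray(endo_z, dtype=float)
        zc = centroids[:, 2]
        in_range = (zc >= ez[0]) & (zc <= ez[-1])
        ai = np.interp(zc, ez, endo_a)
        bi = np.interp(zc, ez, endo_b)
        cxi = np.interp(zc, ez, endo_cx if endo_cx is not None else
                        np.interp(ez, z_planes, centre_x))
        r2 = ((centroids[:, 0] - cxi) / np.maximum(ai, 1e-12)) ** 2 + \
             (centroids[:, 1] / np.maximum(bi, 1e-12)) ** 2
        material[in_range & (r2 < 1.0)] = TRABECULAR

    node_sets = {
        "distal_surface": np.arange(nper, dtype=np.int64),
        "proximal_plateau": np.arange(nz * nper, (nz + 1) * nper, dtype=np.int64),
    }
    return TetMesh(nodes=nodes, tets=tets, material=material, node_sets=node_sets)


def make_tet_mesh(spec: PhantomSpec, target_edge_mm: float) -> TetMesh:
    """Tetrahedral mesh of a phantom at roughly the requested edge length."""
    if target_edge_mm <= 0:
        raise ValueError("target edge length must be positive")
    L = spec.length
    nz = max(4, ceil(L / target_edge_mm))
    per = _ellipse_perimeter(spec.ap_semi_axis, spec.ml_semi_axis)
    n_theta = max(12, ceil(per / target_edge_mm))
    n_radial = max(2, ceil(spec.ap_semi_axis / target_edge_mm))

    zhat = np.linspace(0.0, 1.0, nz + 1)
    a, b = spec.semi_axes(zhat)
    cx = spec.bow_offset(zhat)
    z = zhat * L

    f = spec.endosteal_fraction
    ez = (_ENDO_AXIAL_INSET + zhat * (1 - 2 * _ENDO_AXIAL_INSET)) * L
    ezhat = ez / L
    ea, eb = spec.semi_axes(ezhat)
    ecx = spec.bow_offset(ezhat)
    return tet_mesh_from_profiles(z, cx, a, b, n_theta, n_radial,
                                  endo_z=ez, endo_a=f * ea, endo_b=f * eb,
                                  endo_cx=ecx)


def rings_from_structured_mesh(vertices: np.ndarray, n_rings: int, n_circ: int,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-ring (z, centre_x, a, b) from a structured tube mesh.

    Exact for any shape in the span of the parametric grid: a linear
    combination of elliptical rings sampled at common angles is itself an
    elliptical ring.
    """
    rings = vertices[: n_rings * n_circ].reshape(n_rings, n_circ, 3)
    z = rings[:, :, 2].mean(axis=1)
    cx = rings[:, :, 0].mean(axis=1)
    a = (rings[:, :, 0].max(axis=1) - rings[:, :, 0].min(axis=1)) / 2.0
    b = (rings[:, :, 1].max(axis=1) - rings[:, :, 1].min(axis=1)) / 2.0
    return z, cx, a, b


def tet_mesh_from_reconstruction(cortical_vertices: np.ndarray,
                                 endosteal_vertices: np.ndarray | None,
                                 n_rings: int, n_circ: int,
                                 target_edge_mm: float) -> TetMesh:
    """Solid mesh of an SSM-reconstructed tibia (structured-grid shapes)."""
    if target_edge_mm <= 0:
        raise ValueError("target edge length must be positive")
    z, cx, a, b = rings_from_structured_mesh(cortical_vertices, n_rings, n_circ)
    order = np.argsort(z)
    z, cx, a, b = z[order], cx[order], a[order], b[order]
    L = z[-1] - z[0]
    nz = max(4, ceil(L / target_edge_mm))
    n_theta = max(12, ceil(_ellipse_perimeter(np.median(a), np.median(b))
                           / target_edge_mm))
    n_radial = max(2, ceil(np.median(a) / target_edge_mm))
    zp = np.linspace(z[0], z[-1], nz + 1)
    kwargs: dict = {}
    if endosteal_vertices is not None:
        ezr, ecx, ea, eb = rings_from_structured_mesh(
            endosteal_vertices, n_rings, n_circ)
        eo = np.argsort(ezr)
        kwargs = dict(endo_z=ezr[eo], endo_a=ea[eo], endo_b=eb[eo],
                      endo_cx=ecx[eo])
    return tet_mesh_from_profiles(zp, np.interp(zp, z, cx), np.interp(zp, z, a),
                                  np.interp(zp, z, b), n_theta, n_radial,
                                  **kwargs)


_TET_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


def promote_to_quadratic(mesh: TetMesh) -> TetMesh:
    """Insert midside nodes, turning 4-node tets into 10-node tets.

    Edges stay straight, so the geometric map remains affine; only the
    displacement interpolation becomes quadratic. Boundary node sets are
    extended with midside nodes whose both endpoints belong to the set.
    """
    if mesh.tets.shape[1] != 4:
        raise MeshingError("mesh is already quadratic")
    edges = {}
    extra_nodes = []
    mid = np.empty((len(mesh.tets), 6), dtype=np.int64)
    base = len(mesh.nodes)
    for e, (a, b) in enumerate(_TET_EDGES):
        na, nb = mesh.tets[:, a], mesh.tets[:, b]
        for m in range(len(mesh.tets)):
            key = (na[m], nb[m]) if na[m] < nb[m] else (nb[m], na[m])
            nid = edges.get(key)
            if nid is None:
                nid = base + len(extra_nodes)
                edges[key] = nid
                extra_nodes.append(0.5 * (mesh.nodes[key[0]]
                                          + mesh.nodes[key[1]]))
            mid[m, e] = nid
    nodes = np.vstack([mesh.nodes, np.asarray(extra_nodes)])
    tets = np.hstack([mesh.tets, mid])
    node_sets = {}
    for name, ns in mesh.node_sets.items():
        member = np.zeros(base, dtype=bool)
        member[ns] = True
        extra = [nid for (a, b), nid in edges.items() if member[a] and member[b]]
        node_sets[name] = np.concatenate([ns, np.asarray(extra, dtype=np.int64)])
    return TetMesh(nodes=nodes, tets=tets, material=mesh.material.copy(),
                   node_sets=node_sets)


def box_tet_mesh(lx: float, ly: float, lz: float, target_edge_mm: float,
                 ) -> TetMesh:
    """Structured tet mesh of a solid box (analytic-oracle workhorse)."""
    if target_edge_mm <= 0:
        raise ValueError("target edge length must be positive")
    nx = max(1, ceil(lx / target_edge_mm))
    ny = max(1, ceil(ly / target_edge_mm))
    nz = max(1, ceil(lz / target_edge_mm))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i: int, j: int, k: int) -> int:
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                h = (nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                     nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                     nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1))
                tets.extend(tuple(h[a] for a in t) for t in _HEX_TETS)
    tets = _orient_positive(nodes, np.asarray(tets, dtype=np.int64))
    bottom = np.flatnonzero(np.isclose(nodes[:, 2], 0.0))
    top = np.flatnonzero(np.isclose(nodes[:, 2], lz))
    return TetMesh(nodes=nodes, tets=tets,
                   material=np.zeros(len(tets), dtype=np.int64),
                   node_sets={"distal_surface": bottom,
                              "proximal_plateau": top})
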