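"""Synthetic tibia phantom geometry.

The phantom is a tapered hollow elliptical shaft with cosine-blended
proximal/distal flares and a sagittal (anterior) bow. It is deliberately
simple — analytic cross-sections make volume and section-property oracles
exact — yet rich enough that a 4-landmark reconstruction is genuinely
underdetermined (width, bow and flare are not pinned down by two condyle
and two malleolus points).

Every phantom in a population is built on the same parametric grid
(``n_rings`` axial rings x ``n_circ`` circumferential points plus two cap
centres), so populations are in point correspondence by construction and a
named landmark always maps to the same vertex weights.

Default population magnitudes are calibrated to published adult distal-third
tibial section properties (CSA ~ 393 mm^2, I_ML ~ 23.6e3 mm^4,
I_AP ~ 18.9e3 mm^4) and a ~400 mm tibial length; see ``tibload.refdata``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import SurfaceMesh

# Flare blend widths as fractions of bone length (fixed model constants).
_PROX_FLARE_FRAC = 0.45
_DIST_FLARE_FRAC = 0.20
# Endosteal surface is inset axially by this fraction of length at each end
# so it lies strictly inside the periosteal surface.
_ENDO_AXIAL_INSET = 0.01

LANDMARK_NAMES_9 = (
    "medial_condyle",
    "lateral_condyle",
    "medial_malleolus",
    "lateral_malleolus",
    "tibial_tuberosity",
    "fibular_head",
    "ant_border_25",
    "ant_border_50",
    "ant_border_75",
)
LANDMARK_NAMES_4 = (
    "medial_condyle",
    "lateral_condyle",
    "medial_malleolus",
    "lateral_malleolus",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one tibia phantom (mm and dimensionless)."""

    length: float = 400.0
    ap_semi_axis: float = 13.8     # periosteal AP semi-axis at mid-shaft
    ml_semi_axis: float = 12.3     # periosteal ML semi-axis at mid-shaft
    endosteal_fraction: float = 0.51
    proximal_flare: float = 2.2
    distal_flare: float = 1.45
    bow_mm: float = 4.0            # anterior bow amplitude of the shaft axis
    bow2_mm: float = 0.0           # asymmetric (second-harmonic) bow term
    ap_taper: float = 0.0          # linear AP-width trend along the shaft
    n_rings: int = 40
    n_circ: int = 24

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 < self.endosteal_fraction < 1.0:
            raise ValueError("endosteal_fraction must lie in (0, 1)")
        for name in ("ap_semi_axis", "ml_semi_axis", "proximal_flare",
                     "distal_flare"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.ap_taper) >= 0.5:
            raise ValueError("ap_taper must stay in (-0.5, 0.5)")
        if self.n_rings < 4 or self.n_circ < 8:
            raise ValueError("grid resolution too coarse")

    # ---- analytic profile functions (zhat = normalized axial position) ----

    def flare(self, zhat: np.ndarray) -> np.ndarray:
        """Multiplier on the mid-shaft semi-axes at normalized height zhat."""
        zhat = np.asarray(zhat, dtype=float)

        def smooth(t: np.ndarray) -> np.ndarray:
            t = np.clip(t, 0.0, 1.0)
            return 0.5 * (1.0 - np.cos(np.pi * t))

        prox = (self.proximal_flare - 1.0) * smooth(
            (zhat - (1.0 - _PROX_FLARE_FRAC)) / _PROX_FLARE_FRAC)
        dist = (self.distal_flare - 1.0) * smooth(
            (_DIST_FLARE_FRAC - zhat) / _DIST_FLARE_FRAC)
        return 1.0 + prox + dist

    def semi_axes(self, zhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zhat = np.asarray(zhat, dtype=float)
        f = self.flare(zhat)
        taper = 1.0 + self.ap_taper * (zhat - 0.5)
        return self.ap_semi_axis * f * taper, self.ml_semi_axis * f

    def bow_offset(self, zhat: np.ndarray) -> np.ndarray:
        """Anterior (+X) offset of the ring centre at normalized height."""
        zhat = np.asarray(zhat, dtype=float)
        return (self.bow_mm * np.sin(np.pi * zhat)
                + self.bow2_mm * np.sin(2.0 * np.pi * zhat))


@dataclass(frozen=True)
class PopulationSpec:
    """Normal parameter distributions for a phantom population.

    Draws are clipped at 2.5 SD to keep geometry valid; a mean within
    2.5 SD of zero for a radius-like parameter is rejected as an invalid
    range.
    """

    length: tuple[float, float] = (400.0, 25.0)
    ap_semi_axis: tuple[float, float] = (13.8, 1.5)
    ml_semi_axis: tuple[float, float] = (12.3, 1.0)
    endosteal_fraction: tuple[float, float] = (0.51, 0.04)
    proximal_flare: tuple[float, float] = (2.2, 0.05)
    distal_flare: tuple[float, float] = (1.45, 0.04)
    bow_mm: tuple[float, float] = (5.0, 2.5)
    bow2_mm: tuple[float, float] = (0.0, 2.0)
    ap_taper: tuple[float, float] = (0.0, 0.10)
    n_rings: int = 40
    n_circ: int = 24

    def __post_init__(self) -> None:
        for name in ("length", "ap_semi_axis", "ml_semi_axis",
                     "proximal_flare", "distal_flare"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: negative SD")
            if mean - 2.5 * sd <= 0:
                raise ValueError(f"{name}: range admits non-positive values")
        mean, sd = self.endosteal_fraction
        if sd < 0:
            raise ValueError("endosteal_fraction: negative SD")
        if mean - 2.5 * sd <= 0 or mean + 2.5 * sd >= 1:
            raise ValueError("endosteal_fraction: range leaves (0, 1)")

    def draw(self, rng: np.random.Generator) -> PhantomSpec:
        def d(name: str) -> float:
            mean, sd = getattr(self, name)
            return float(np.clip(rng.normal(mean, sd),
                                 mean - 2.5 * sd, mean + 2.5 * sd))

        return PhantomSpec(
            length=d("length"),
            ap_semi_axis=d("ap_semi_axis"),
            ml_semi_axis=d("ml_semi_axis"),
            endosteal_fraction=d("endosteal_fraction"),
            proximal_flare=d("proximal_flare"),
            distal_flare=d("distal_flare"),
            bow_mm=d("bow_mm"),
            bow2_mm=d("bow2_mm"),
            ap_taper=d("ap_taper"),
            n_rings=self.n_rings,
            n_circ=self.n_circ,
        )


# --------------------------------------------------------------------------
# surface construction
# --------------------------------------------------------------------------

def _ring_grid(spec: PhantomSpec, endosteal: bool) -> np.ndarray:
    """Vertex array of the structured tube surface (rings then two caps)."""
    nr, nc = spec.n_rings, spec.n_circ
    zhat = np.linspace(0.0, 1.0, nr)
    a, b = spec.semi_axes(zhat)
    cx = spec.bow_offset(zhat)
    if endosteal:
        a = a * spec.endosteal_fraction
        b = b * spec.endosteal_fraction
        z = (_ENDO_AXIAL_INSET + zhat * (1.0 - 2 * _ENDO_AXIAL_INSET)) * spec.length
    else:
        z = zhat * spec.length
    theta = 2.0 * np.pi * np.arange(nc) / nc
    verts = np.empty((nr * nc + 2, 3))
    verts[: nr * nc, 0] = (cx[:, None] + a[:, None] * np.cos(theta)).ravel()
    verts[: nr * nc, 1] = (b[:, None] * np.sin(theta)).ravel()
    verts[: nr * nc, 2] = np.repeat(z, nc)
    verts[nr * nc] = (cx[0], 0.0, z[0])        # distal cap centre
    verts[nr * nc + 1] = (cx[-1], 0.0, z[-1])  # proximal cap centre
    return verts


def _tube_faces(nr: int, nc: int) -> np.ndarray:
    """Triangle faces for the structured tube, outward-oriented."""
    faces = []
    for j in range(nr - 1):
        for i in range(nc):
            i1 = (i + 1) % nc
            v00 = j * nc + i
            v10 = j * nc + i1
            v01 = (j + 1) * nc + i
            v11 = (j + 1) * nc + i1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    dc = nr * nc
    pc = nr * nc + 1
    for i in range(nc):
        i1 = (i + 1) % nc
        faces.append((dc, (0) * nc + i1, (0) * nc + i))          # distal, -Z out
        faces.append((pc, (nr - 1) * nc + i, (nr - 1) * nc + i1))  # proximal
    return np.asarray(faces, dtype=np.int64)


def build_surface(spec: PhantomSpec, endosteal: bool = False) -> SurfaceMesh:
    """Watertight surface mesh of the periosteal or endosteal boundary."""
    mesh = SurfaceMesh(_ring_grid(spec, endosteal),
                       _tube_faces(spec.n_rings, spec.n_circ))
    if mesh.enclosed_volume() < 0:  # defensive; construction should be outward
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, [0, 2, 1]])
    return mesh


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

def landmark_weights(n_rings: int, n_circ: int) -> dict[str, list[tuple[int, float]]]:
    """Affine vertex-weight definition of every named landmark.

    Each landmark is a weight-1 affine combination of grid vertices, so it
    transforms consistently with the mesh under any similarity pose. The
    fibular-head surrogate is extrapolated laterally from the proximal
    shaft (the phantom models the tibia only).
    """
    def idx(i: int, j: int) -> int:
        return j * n_circ + i

    i_ant = 0
    i_lat = n_circ // 4
    i_med = (3 * n_circ) // 4
    j_top = n_rings - 1
    j_tub = round(0.88 * (n_rings - 1))
    j_fib = round(0.93 * (n_rings - 1))

    def ring_at(frac_from_prox: float) -> int:
        return round((1.0 - frac_from_prox) * (n_rings - 1))

    return {
        "medial_condyle": [(idx(i_med, j_top), 1.0)],
        "lateral_condyle": [(idx(i_lat, j_top), 1.0)],
        "medial_malleolus": [(idx(i_med, 1), 1.0)],
        "lateral_malleolus": [(idx(i_lat, 1), 1.0)],
        "tibial_tuberosity": [(idx(i_ant, j_tub), 1.0)],
        "fibular_head": [(idx(i_lat, j_fib), 1.25), (idx(i_med, j_fib), -0.25)],
        "ant_border_25": [(idx(i_ant, ring_at(0.25)), 1.0)],
        "ant_border_50": [(idx(i_ant, ring_at(0.50)), 1.0)],
        "ant_border_75": [(idx(i_ant, ring_at(0.75)), 1.0)],
    }


def extract_landmarks(mesh: SurfaceMesh, n_rings: int, n_circ: int,
                      names: tuple[str, ...] = LANDMARK_NAMES_9,
                      ) -> dict[str, np.ndarray]:
    weights = landmark_weights(n_rings, n_circ)
    out = {}
    for name in names:
        pts = sum(w * mesh.vertices[i] for i, w in weights[name])
        out[name] = np.asarray(pts, dtype=float)
    return out


# --------------------------------------------------------------------------
# population generation
# --------------------------------------------------------------------------

@dataclass
class TibiaPhantom:
    """One synthetic tibia: geometry, spec and ground-truth landmarks."""

    spec: PhantomSpec
    cortical: SurfaceMesh          # periosteal surface
    endosteal: SurfaceMesh
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)


def make_phantom(spec: PhantomSpec) -> TibiaPhantom:
    cort = build_surface(spec, endosteal=False)
    endo = build_surface(spec, endosteal=True)
    lms = extract_landmarks(cort, spec.n_rings, spec.n_circ)
    return TibiaPhantom(spec=spec, cortical=cort, endosteal=endo, landmarks=lms)


def generate_population(n: int, dist: PopulationSpec | None = None,
                        seed: int | np.random.Generator = 0,
                        ) -> list[TibiaPhantom]:
    """Draw ``n`` corresponding phantoms from a parameter distribution."""
    if n < 3:
        raise ValueError("population needs at least 3 phantoms")
    dist = dist if dist is not None else PopulationSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [make_phantom(dist.draw(rng)) for _ in range(n)]


def noisy_landmarks(landmarks: dict[str, np.ndarray], sd_mm: float,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Isotropic Gaussian offsets emulating soft-tissue artifact."""
    if sd_mm < 0:
        raise ValueError("noise SD must be non-negative")
    return {k: v + rng.normal(0.0, sd_mm, 3) for k, v in landmarks.items()}


def spec_with_grid(spec: PhantomSpec, n_rings: int, n_circ: int) -> PhantomSpec:
    return replace(spec, n_rings=n_rings, n_circ=n_circ)


def perturb_phantom(phantom: TibiaPhantom, amplitude_mm: float,
                    rng: np.random.Generator,
                    endosteal_factor: float = 0.5) -> TibiaPhantom:
    """Add smooth anatomical detail beyond the parametric family.

    A low-order harmonic radial field (circumferential orders 0-3, two
    axial half-waves, zero at the ends) displaces the periosteal surface
    with the requested RMS amplitude; the endosteal surface follows at a
    reduced factor. Landmarks are re-extracted from the perturbed
    surface. This emulates real-bone features a statistical shape model
    trained on the parametric family cannot represent, which is what
    makes sparse-landmark reconstructions genuinely imperfect.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be non-negative")
    spec = phantom.spec
    nr, nc = spec.n_rings, spec.n_circ
    theta = 2.0 * np.pi * np.arange(nc) / nc
    coeffs = rng.standard_normal((2, 4, 2))  # (cos/sin, order m, axial l)

    def field(zhat: np.ndarray) -> np.ndarray:
        f = np.zeros((len(zhat), nc))
        for m in range(4):
            for l in range(1, 3):
                ax = np.sin(np.pi * l * zhat)[:, None]
                f += coeffs[0, m, l - 1] * np.cos(m * theta) * ax
                f += coeffs[1, m, l - 1] * np.sin(m * theta) * ax
        rms = np.sqrt((f ** 2).mean())
        return f * (amplitude_mm / rms) if rms > 0 else f

    def displaced(mesh: SurfaceMesh, amp_field: np.ndarray) -> SurfaceMesh:
        verts = mesh.vertices.copy()
        rings = verts[: nr * nc].reshape(nr, nc, 3)
        centre = rings.mean(axis=1, keepdims=True)
        radial = rings - centre
        radial[:, :, 2] = 0.0
        norm = np.linalg.norm(radial, axis=2, keepdims=True)
        unit = radial / np.maximum(norm, 1e-12)
        rings = rings + amp_field[:, :, None] * unit
        verts[: nr * nc] = rings.reshape(-1, 3)
        return SurfaceMesh(verts, mesh.faces.copy())

    zhat = np.linspace(0.0, 1.0, nr)
    f = field(zhat)
    cort = displaced(phantom.cortical, f)
    endo = displaced(phantom.endosteal, endosteal_factor * f)
    lms = extract_landmarks(cort, nr, nc)
    return TibiaPhantom(spec=spec, cortical=cort, endosteal=endo,
                       landmarks=lms)
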