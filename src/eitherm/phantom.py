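"""Synthetic layered torso phantom, electrodes and heating scenarios.

The phantom is an elliptic cylinder (default half-axes 15 cm x 10 cm,
height 20 cm) with concentric skin and fat shells around a muscle bulk and
parametric inclusions (spine-like bone, liver-like organ, urine-filled
bladder, tumor).  It stands in for a licensed anatomical torso section while
reproducing its salient property for impedance imaging: a heterogeneous
conductivity spanning ~0 S/m (internal air) to 3 S/m (urine).

Coordinates are metres internally, millimetres at the configuration surface;
z runs along the torso axis with the origin at the section centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay

from .mesh import ConductivityField, TetMesh, split_hexes, split_prisms
from .tissues import TissueTable, default_tissue_table

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "HeatingScenario",
    "build_phantom",
    "place_electrodes",
    "apply_gaussian_heating",
    "insert_spherical_anomaly",
    "scenario_fixture",
    "ball_mesh",
    "SCENARIO_IDS",
]


@dataclass(frozen=True)
class Inclusion:
    """Embedded tissue structure; later entries override earlier ones.

    ``shape`` is ``'sphere'`` (radii: scalar), ``'ellipsoid'`` (radii: 3) or
    ``'cylinder'`` (axis along z; radii: (rx, ry), full phantom height).
    Positions/sizes in metres.
    """

    tissue: str
    shape: str
    center: tuple
    radii: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - np.asarray(self.center)
        if self.shape == "sphere":
            return (p ** 2).sum(axis=1) <= self.radii[0] ** 2
        if self.shape == "ellipsoid":
            r = np.asarray(self.radii)
            return ((p / r) ** 2).sum(axis=1) <= 1.0
        if self.shape == "cylinder":
            rx, ry = self.radii[0], self.radii[1]
            return (p[:, 0] / rx) ** 2 + (p[:, 1] / ry) ** 2 <= 1.0
        raise ValueError(f"unknown inclusion shape {self.shape!r}")


def _default_inclusions() -> tuple:
    return (
        Inclusion("bone", "cylinder", (0.0, -0.065, 0.0), (0.018, 0.018)),
        Inclusion("organ", "ellipsoid", (-0.065, 0.02, 0.04), (0.05, 0.045, 0.06)),
        Inclusion("urine", "sphere", (0.0, 0.01, -0.05), (0.035,)),
        Inclusion("tumor", "sphere", (0.028, 0.01, -0.05), (0.018,)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry parameters of the synthetic torso phantom.

    ``a``/``b`` are the outer half-axes of the elliptic cross-section (m),
    ``height`` the axial extent (m).  ``skin_frac``/``fat_frac`` are shell
    thicknesses as fractions of the normalized elliptic radius.
    """

    a: float = 0.15
    b: float = 0.10
    height: float = 0.20
    target_elements: int = 30000
    skin_frac: float = 0.06
    fat_frac: float = 0.12
    inclusions: tuple = field(default_factory=_default_inclusions)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.height <= 0:
            raise ValueError("phantom axes and height must be positive")
        for inc in self.inclusions:
            c = np.asarray(inc.center)
            if (c[0] / self.a) ** 2 + (c[1] / self.b) ** 2 >= 1.0 or abs(c[2]) > self.height / 2:
                raise ValueError(f"inclusion {inc.tissue!r} lies outside the outer boundary")

    # -- analytic geometry ----------------------------------------------------
    def normalized_radius(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.sqrt((p[:, 0] / self.a) ** 2 + (p[:, 1] / self.b) ** 2)

    def inside(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (self.normalized_radius(p) <= 1.0) & (np.abs(p[:, 2]) <= self.height / 2)

    def label_at(self, points: np.ndarray, table: TissueTable) -> np.ndarray:
        """Tissue id at arbitrary points (shells then inclusions; last wins)."""
        p = np.atleast_2d(points)
        s = self.normalized_radius(p)
        labels = np.full(len(p), table.id_of("muscle"), dtype=np.int64)
        labels[s > 1.0 - self.skin_frac - self.fat_frac] = table.id_of("fat")
        labels[s > 1.0 - self.skin_frac] = table.id_of("skin")
        for inc in self.inclusions:
            labels[inc.contains(p)] = table.id_of(inc.tissue)
        return labels

    def analytic_volume(self) -> float:
        return float(np.pi * self.a * self.b * self.height)


# ---------------------------------------------------------------------------
# Mesh generation: structured concentric-ring cross-section, 2D Delaunay on
# the (convex) unit disk, affine map to the ellipse, extrusion to prisms and
# min-index prism splitting.  Fully deterministic.
# ---------------------------------------------------------------------------

def _disk_points(n_rings: int) -> np.ndarray:
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        m = 8 * k
        ang = 2 * np.pi * np.arange(m) / m
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.asarray(pts)


def _resolution_for_target(spec: PhantomSpec) -> tuple[int, int]:
    # tets = 3 * n_tri * nz with n_tri ~ 8 K^2 and nz ~ height*K/b,
    # i.e. 24 * (height/b) * K^3 ~ target
    k = (spec.target_elements / (24.0 * spec.height / spec.b)) ** (1.0 / 3.0)
    n_rings = max(6, int(2 * round(k / 2)))
    nz = max(8, int(4 * round(spec.height * n_rings / spec.b / 4)))
    return n_rings, nz


def build_phantom(
    spec: Optional[PhantomSpec] = None,
    table: Optional[TissueTable] = None,
    frequency_tag: str = "lf",
) -> tuple[TetMesh, ConductivityField]:
    """Generate the phantom mesh and its reference conductivity field.

    Returns a :class:`TetMesh` with tissue labels assigned by element
    centroid and a :class:`ConductivityField` populated from the tissue
    table at the requested frequency.  The element count lands within ~30 %
    of ``spec.target_elements``.
    """
    spec = spec or PhantomSpec()
    table = table or default_tissue_table()
    n_rings, nz = _resolution_for_target(spec)

    disk = _disk_points(n_rings)
    tri = Delaunay(disk)
    triangles = tri.simplices
    n2d = len(disk)

    xy = np.column_stack([disk[:, 0] * spec.a, disk[:, 1] * spec.b])
    zs = np.linspace(-spec.height / 2, spec.height / 2, nz + 1)
    nodes = np.concatenate(
        [np.column_stack([xy, np.full(n2d, z)]) for z in zs], axis=0
    )

    layer = np.arange(nz)[:, None, None]
    bottom = triangles[None, :, :] + layer * n2d
    top = bottom + n2d
    prisms = np.concatenate([bottom, top], axis=2).reshape(-1, 6)
    tets = split_prisms(prisms)

    labels = np.zeros(len(tets), dtype=np.int64)
    mesh = TetMesh(nodes, tets, labels)
    mesh.labels[:] = spec.label_at(mesh.centroids, table)
    sigma = ConductivityField(table.sigma_array(mesh.labels, frequency_tag), frequency_tag)
    return mesh, sigma


def place_electrodes(
    mesh: TetMesh,
    n_electrodes: int = 16,
    rings: int = 2,
    ring_heights: Optional[Sequence[float]] = None,
    max_snap_edge_lengths: float = 2.0,
) -> np.ndarray:
    """Place point electrodes on the lateral boundary, interleaved by ring.

    Electrodes are arranged in ``rings`` rows with equal angular spacing per
    ring and a half-spacing azimuthal offset between rings; consecutive
    electrode indices alternate between rings.  Each ideal position is
    snapped to the nearest boundary node; snapping farther than
    ``max_snap_edge_lengths`` median edge lengths raises.

    Ring heights default to symmetric quarter-height positions (two rings:
    +-height/4 of the mesh z-extent).
    """
    if n_electrodes % rings != 0:
        raise ValueError("n_electrodes must be divisible by rings")
    bnodes = mesh.boundary_nodes()
    if len(bnodes) == 0:
        raise ValueError("mesh has no boundary nodes")
    coords = mesh.node_coords
    zmin, zmax = coords[:, 2].min(), coords[:, 2].max()
    if ring_heights is None:
        # symmetric rows: two rings sit at the quarter heights (+- h/4)
        fracs = (2.0 * np.arange(rings) + 1.0) / (2.0 * rings)
        ring_heights = zmin + (zmax - zmin) * fracs
    ring_heights = np.asarray(ring_heights, dtype=float)

    # lateral extent for building ideal target points
    bc = coords[bnodes]
    a = bc[:, 0].max()
    b = bc[:, 1].max()

    per_ring = n_electrodes // rings
    step = 2 * np.pi / per_ring
    targets = np.empty((n_electrodes, 3))
    for j in range(n_electrodes):
        ring = j % rings
        ang = (j // rings) * step + ring * step / rings
        targets[j] = (a * np.cos(ang), b * np.sin(ang), ring_heights[ring])

    from scipy.spatial import cKDTree

    tree = cKDTree(bc)
    dist, idx = tree.query(targets)
    edge = mesh.edge_length_scale()
    if np.max(dist) > max_snap_edge_lengths * edge:
        raise ValueError(
            f"electrode snap distance {np.max(dist):.4g} m exceeds "
            f"{max_snap_edge_lengths} edge lengths ({edge:.4g} m)"
        )
    chosen = bnodes[idx]
    if len(np.unique(chosen)) != n_electrodes:
        raise ValueError("electrode positions collide on the same boundary node")
    mesh.electrode_nodes = list(chosen)
    return chosen


# ---------------------------------------------------------------------------
# Heating and anomaly scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeatingScenario:
    """Spherical Gaussian heating region (and optional anomaly).

    The conductivity multiplier is ``1 + peak * exp(-r^2 / (2 R^2))`` with
    ``r`` the distance from ``center_mm``; when ``cutoff_mm`` is given the
    multiplier is applied only inside that radius (the heated sphere),
    leaving the outside untouched.  Positions in millimetres at this surface.
    """

    center_mm: tuple
    radius_mm: float  # Gaussian width R
    peak: float = 0.4
    cutoff_mm: Optional[float] = None
    anomaly: Optional[dict] = None  # {'center_mm', 'diameter_mm', 'sigma_value'}

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("Gaussian radius must be positive")
        if self.peak < 0:
            raise ValueError("peak increase must be >= 0")
        if self.anomaly is not None and self.anomaly["diameter_mm"] <= 0:
            raise ValueError("anomaly diameter must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float) / 1e3

    @property
    def radius(self) -> float:
        return self.radius_mm / 1e3


def gaussian_multiplier(r: np.ndarray, radius: float, peak: float) -> np.ndarray:
    """The heated-region conductivity multiplier ``1 + peak exp(-r^2/2R^2)``."""
    return 1.0 + peak * np.exp(-np.asarray(r, dtype=float) ** 2 / (2.0 * radius ** 2))


def apply_gaussian_heating(
    sigma: ConductivityField, scenario: HeatingScenario, mesh: TetMesh
) -> ConductivityField:
    """Apply the Gaussian heating multiplier to a conductivity field.

    ``r`` is measured from element centroids to the scenario centre.  With a
    cutoff radius the change is confined to the heated sphere; otherwise the
    Gaussian itself localizes the change.
    """
    r = np.linalg.norm(mesh.centroids - scenario.center, axis=1)
    mult = gaussian_multiplier(r, scenario.radius, scenario.peak)
    if scenario.cutoff_mm is not None:
        mult = np.where(r <= scenario.cutoff_mm / 1e3, mult, 1.0)
    return ConductivityField(sigma.values * mult, sigma.frequency_tag)


def insert_spherical_anomaly(
    sigma: ConductivityField,
    mesh: TetMesh,
    center_mm: Sequence[float],
    diameter_mm: float,
    sigma_value: float,
) -> ConductivityField:
    """Overwrite conductivity inside a sphere (centroid membership test)."""
    if diameter_mm <= 0:
        return sigma.copy()
    if sigma_value < 0:
        raise ValueError("sigma_value must be >= 0")
    center = np.asarray(center_mm, dtype=float) / 1e3
    r = np.linalg.norm(mesh.centroids - center, axis=1)
    inside = r <= diameter_mm / 2e3
    if not np.any(inside):
        warnings.warn("anomaly sphere contains no element centroids; field unchanged")
    out = sigma.values.copy()
    out[inside] = sigma_value
    return ConductivityField(out, sigma.frequency_tag)


# Heated-region fixtures: positions are stated in a reference torso frame
# (mm) and mapped into the phantom by linear per-axis scaling of the frame's
# half-extents onto the phantom's, preserving relative geometry.
_SOURCE_FRAME_HALF_EXTENTS = np.array([170.0, 110.0, 100.0])  # mm
_SCENARIOS = {
    "P1": {"center": (-90.0, 20.0, 15.0), "diameter": 60.0},
    "P2": {"center": (-90.0, 20.0, 15.0), "diameter": 40.0},
    "P3": {"center": (-90.0, 20.0, 15.0), "diameter": 80.0},
    "P4": {"center": (-40.0, 50.0, 15.0), "diameter": 60.0},
    "P5": {"center": (30.0, 50.0, 15.0), "diameter": 60.0},
    "air": {"center": (50.0, 30.0, 15.0), "diameter": 50.0},
}
SCENARIO_IDS = tuple(_SCENARIOS)


def scenario_fixture(
    scenario_id: str, spec: Optional[PhantomSpec] = None, peak: float = 0.4
) -> HeatingScenario:
    """Heated-region fixture P1..P5 (or the 50 mm air object) for a phantom.

    The Gaussian width R equals the region radius (diameter/2) and the
    multiplier is truncated at the sphere boundary.  For ``'air'`` the
    returned scenario carries a zero-conductivity spherical anomaly instead
    of heating (peak 0).
    """
    if scenario_id not in _SCENARIOS:
        raise KeyError(f"unknown scenario id {scenario_id!r}; valid: {SCENARIO_IDS}")
    spec = spec or PhantomSpec()
    entry = _SCENARIOS[scenario_id]
    half = np.array([spec.a, spec.b, spec.height / 2]) * 1e3
    center = tuple(np.asarray(entry["center"]) * half / _SOURCE_FRAME_HALF_EXTENTS)
    d = entry["diameter"]
    if scenario_id == "air":
        return HeatingScenario(
            center_mm=center,
            radius_mm=d / 2,
            peak=0.0,
            cutoff_mm=d / 2,
            anomaly={"center_mm": center, "diameter_mm": d, "sigma_value": 0.0},
        )
    return HeatingScenario(center_mm=center, radius_mm=d / 2, peak=peak, cutoff_mm=d / 2)


# ---------------------------------------------------------------------------
# Validation geometry: homogeneous ball (analytic transfer impedances exist)
# ---------------------------------------------------------------------------

def ball_mesh(radius: float = 0.1, n: int = 8) -> TetMesh:
    """Structured tetrahedral mesh of a ball, for solver validation.

    A (2n)^3 hexahedral grid on the cube [-1, 1]^3 is split into tets and
    radially mapped onto the ball (p -> p * ||p||_inf / ||p||_2), which keeps
    boundary nodes exactly on the sphere.  All elements have positive volume
    (asserted).  Single label 0.
    """
    m = 2 * n + 1
    axis = np.linspace(-1.0, 1.0, m)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * m + j) * m + k

    I, J, K = np.meshgrid(np.arange(m - 1), np.arange(m - 1), np.arange(m - 1), indexing="ij")
    i, j, k = I.ravel(), J.ravel(), K.ravel()
    hexes = np.column_stack([
        vid(i, j, k), vid(i + 1, j, k), vid(i + 1, j + 1, k), vid(i, j + 1, k),
        vid(i, j, k + 1), vid(i + 1, j, k + 1), vid(i + 1, j + 1, k + 1), vid(i, j + 1, k + 1),
    ])
    tets = split_hexes(hexes)

    norm2 = np.linalg.norm(pts, axis=1)
    norminf = np.max(np.abs(pts), axis=1)
    scale = np.ones(len(pts))
    nz = norm2 > 0
    scale[nz] = norminf[nz] / norm2[nz]
    ball_pts = pts * scale[:, None] * radius
    mesh = TetMesh(ball_pts, tets, np.zeros(len(tets), dtype=np.int64))
    assert np.all(mesh.volumes > 0)
    return mesh
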