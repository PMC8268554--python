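"""Labeled tetrahedral meshes and per-element conductivity fields.

The mesh container is deliberately small: node coordinates (m), 4-node
tetrahedra, an integer tissue label per element and an ordered list of
electrode nodes.  Helper routines provide signed volumes, centroids,
P1 shape-function gradients and boundary-node extraction; these are the
substrate of the quasi-static forward solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["TetMesh", "ConductivityField", "split_prisms", "split_hexes"]


@dataclass
class TetMesh:
    """Labeled tetrahedral mesh.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array
        Node positions in metres.
    tets : (n_elems, 4) int array
        Node indices per tetrahedron, oriented to positive signed volume.
    labels : (n_elems,) int array
        Tissue id per element (index into a :class:`~eitherm.tissues.TissueTable`).
    electrode_nodes : list of int
        Ordered electrode node indices (empty until electrodes are placed).
    """

    node_coords: np.ndarray
    tets: np.ndarray
    labels: np.ndarray
    electrode_nodes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.tets.shape[1] != 4:
            raise ValueError("tets must be (n, 4)")
        if len(self.labels) != len(self.tets):
            raise ValueError("labels must have one entry per element")
        self._fix_orientation()
        self._cache: dict = {}

    # -- geometry ------------------------------------------------------------
    def _fix_orientation(self) -> None:
        vol = _signed_volumes(self.node_coords, self.tets)
        neg = vol < 0
        if np.any(neg):
            self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]
        vol = np.abs(vol)
        if np.any(vol <= 0):
            raise ValueError("mesh contains degenerate (zero-volume) tetrahedra")

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def volumes(self) -> np.ndarray:
        """Element volumes (m^3), strictly positive."""
        if "volumes" not in self._cache:
            self._cache["volumes"] = np.abs(_signed_volumes(self.node_coords, self.tets))
        return self._cache["volumes"]

    @property
    def centroids(self) -> np.ndarray:
        """Element centroids, shape (n_elements, 3)."""
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.node_coords[self.tets].mean(axis=1)
        return self._cache["centroids"]

    def shape_gradients(self) -> np.ndarray:
        """Gradients of the four P1 shape functions, shape (n_elems, 4, 3).

        For element ``e`` and field values ``u`` the element-wise gradient is
        ``einsum('i,ik->k', u[tets[e]], G[e])``.
        """
        if "grads" not in self._cache:
            p = self.node_coords[self.tets]  # (n, 4, 3)
            M = p[:, 1:, :] - p[:, :1, :]  # rows are edge vectors
            invM = np.linalg.inv(M)
            g = np.empty((len(self.tets), 4, 3))
            # grad(lambda_i) = i-th column of M^-1 (lambda = M^-T (x - p0))
            g[:, 1:, :] = np.transpose(invM, (0, 2, 1))
            g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
            self._cache["grads"] = g
        return self._cache["grads"]

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces belonging to exactly one tetrahedron."""
        if "bfaces" not in self._cache:
            faces = self.tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
            key = np.sort(faces, axis=1)
            _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
            self._cache["bfaces"] = faces[idx[counts == 1]]
        return self._cache["bfaces"]

    def boundary_nodes(self) -> np.ndarray:
        """Sorted indices of nodes lying on the mesh boundary surface."""
        return np.unique(self.boundary_faces())

    def edge_length_scale(self) -> float:
        """Median edge length of the mesh (m)."""
        e = self.node_coords[self.tets[:, [0, 0, 0, 1, 1, 2]]] - \
            self.node_coords[self.tets[:, [1, 2, 3, 2, 3, 3]]]
        return float(np.median(np.linalg.norm(e, axis=2)))

    def validate_labels(self, table) -> None:
        if self.labels.min() < 0 or self.labels.max() >= len(table):
            raise ValueError("element label outside the tissue table")


def _signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return np.linalg.det(p[:, 1:, :] - p[:, :1, :]) / 6.0


@dataclass
class ConductivityField:
    """Per-element electrical conductivity (S/m) with a frequency tag."""

    values: np.ndarray
    frequency_tag: str = "lf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("conductivity must be non-negative")
        if self.frequency_tag not in ("lf", "hf"):
            raise ValueError("frequency_tag must be 'lf' or 'hf'")

    def copy(self) -> "ConductivityField":
        return ConductivityField(self.values.copy(), self.frequency_tag)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Prism / hexahedron subdivision (min-index diagonal rule).  Choosing every
# quad-face diagonal through the face's smallest global node index yields
# conforming, valid tetrahedralizations (no Schoenhardt prisms).
# ---------------------------------------------------------------------------

def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each.

    ``prisms`` is (n, 6): bottom triangle (v0, v1, v2), top (v3, v4, v5) with
    vi+3 above vi.  Returns (3 n, 4) tetrahedra (orientation not normalized).
    """
    prisms = np.asarray(prisms, dtype=np.int64)
    out = np.empty((len(prisms), 3, 4), dtype=np.int64)
    for n, p in enumerate(prisms):
        # rotate so the globally smallest vertex of the bottom triangle is first
        rots = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
        r = min(rots, key=lambda t: p[t[0]])
        v = [p[r[0]], p[r[1]], p[r[2]], p[r[0] + 3], p[r[1] + 3], p[r[2] + 3]]
        if min(v[1], v[5]) < min(v[2], v[4]):
            tets = [(v[0], v[1], v[2], v[5]),
                    (v[0], v[1], v[5], v[4]),
                    (v[0], v[4], v[5], v[3])]
        else:
            tets = [(v[0], v[1], v[2], v[4]),
                    (v[0], v[4], v[2], v[5]),
                    (v[0], v[4], v[5], v[3])]
        out[n] = tets
    return out.reshape(-1, 4)


def split_hexes(hexes: np.ndarray) -> np.ndarray:
    """Split hexahedra into tets by cutting each into two prisms.

    ``hexes`` is (n, 8) in VTK ordering: bottom (v0..v3) counter-clockwise,
    top (v4..v7) above them.  The cut plane through (v0, v2, v6, v4) is used,
    and each prism is subdivided with the min-index rule, so meshes from the
    same structured grid are conforming.
    """
    hexes = np.asarray(hexes, dtype=np.int64)
    prisms = np.concatenate(
        [hexes[:, [0, 1, 2, 4, 5, 6]], hexes[:, [0, 2, 3, 4, 6, 7]]], axis=0
    )
    return split_prisms(prisms)
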