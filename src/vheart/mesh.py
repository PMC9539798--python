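"""Volumetric tetrahedral meshes on regular voxel lattices.

The simulator builds all geometry deterministically by labelling voxel
centers of a regular grid with tissue labels and subdividing every labelled
voxel into six tetrahedra (Kuhn/Freudenthal subdivision, conformal across
voxel faces by construction).  Node coordinates are stored in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    """Tissue / region labels used across the heart and torso meshes."""

    LV = 1
    RV = 2
    LA = 3
    RA = 4
    BB = 5          # Bachmann's bundle inter-atrial bridge
    FO_RIM = 6      # fossa-ovalis rim septal pathway
    SAN_REGION = 7  # sino-atrial node region (atrial EP)
    AVN = 8         # reserved; the AV node is modelled as a 1-D cable
    BLOOD_LV = 10
    BLOOD_RV = 11
    BLOOD_LA = 12
    BLOOD_RA = 13
    LUNG_L = 20
    LUNG_R = 21
    TORSO = 30


#: labels that conduct (participate in the Eikonal solve)
CONDUCTING = frozenset(
    {Tissue.LV, Tissue.RV, Tissue.LA, Tissue.RA, Tissue.BB, Tissue.FO_RIM,
     Tissue.SAN_REGION}
)
#: myocardial labels of the ventricles / atria
VENTRICULAR = frozenset({Tissue.LV, Tissue.RV})
ATRIAL = frozenset({Tissue.LA, Tissue.RA, Tissue.BB, Tissue.FO_RIM,
                    Tissue.SAN_REGION})

# Kuhn subdivision of the unit cube: six tetrahedra sharing the main
# diagonal (0,0,0)-(1,1,1).  Corner ids are bit-coded ix + 2*iy + 4*iz.
_KUHN_PATHS = (
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
)
_CORNER_OFFSETS = np.array(
    [[i & 1, (i >> 1) & 1, (i >> 2) & 1] for i in range(8)], dtype=np.int64
)


@dataclass
class VolumetricMesh:
    """Tetrahedral mesh with per-element labels and fiber frames.

    Attributes
    ----------
    nodes : (n, 3) float array, node positions in mm.
    elements : (m, 4) int array, positively oriented tetrahedra.
    element_labels : (m,) int array of :class:`Tissue` values.
    element_fibers : (m, 3, 3) array; rows are the orthonormal fiber
        frame f (fiber), s (sheet), n (sheet normal) per element, or
        ``None`` before fibers are assigned.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_labels: np.ndarray
    element_fibers: np.ndarray | None = None
    #: voxel-lattice metadata (origin, spacing, shape) when applicable
    grid: dict | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        p = self.nodes[self.elements]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        return v / 6.0

    def label_mask(self, labels) -> np.ndarray:
        """Boolean element mask for a label or iterable of labels."""
        labels = {int(labels)} if np.isscalar(labels) else {int(l) for l in labels}
        return np.isin(self.element_labels, sorted(labels))

    def nodes_of(self, labels) -> np.ndarray:
        """Sorted unique node indices touched by elements of given labels."""
        return np.unique(self.elements[self.label_mask(labels)])

    def validate(self, tol: float = 1e-6) -> None:
        """Check orientation, label values and fiber orthonormality."""
        vol = self.element_volumes()
        if not np.all(vol > 0):
            raise ValueError(f"{np.sum(vol <= 0)} non-positively oriented tets")
        valid = {int(t) for t in Tissue}
        if not set(np.unique(self.element_labels)).issubset(valid):
            raise ValueError("unknown element label present")
        if self.element_fibers is not None:
            f = self.element_fibers
            gram = np.einsum("eij,ekj->eik", f, f)
            err = np.abs(gram - np.eye(3)).max()
            if err > tol:
                raise ValueError(f"fiber frames not orthonormal (err={err:.2e})")


def mesh_from_voxels(origin, spacing: float, labels3d: np.ndarray) -> VolumetricMesh:
    """Tetrahedralize the labelled voxels of a regular grid.

    ``labels3d[i, j, k]`` is the tissue label of the voxel spanning
    ``origin + spacing*(i, j, k)`` to ``origin + spacing*(i+1, j+1, k+1)``;
    zero marks empty space.  Deterministic: no RNG involved.
    """
    origin = np.asarray(origin, dtype=float)
    filled = np.argwhere(labels3d > 0)
    if len(filled) == 0:
        raise ValueError("no labelled voxels")
    vox_labels = labels3d[filled[:, 0], filled[:, 1], filled[:, 2]]

    # lattice corner ids on the (nx+1, ny+1, nz+1) node grid
    nshape = np.asarray(labels3d.shape) + 1
    corners = filled[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (v, 8, 3)
    corner_flat = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), nshape
    )

    tets = np.concatenate(
        [corner_flat[:, list(path)] for path in _KUHN_PATHS], axis=0
    )
    labels = np.tile(vox_labels, 6)

    used, inv = np.unique(tets, return_inverse=True)
    elements = inv.reshape(tets.shape).astype(np.int64)
    ijk = np.stack(np.unravel_index(used, nshape), axis=1)
    nodes = origin + spacing * ijk.astype(float)

    mesh = VolumetricMesh(
        nodes=nodes,
        elements=elements,
        element_labels=labels.astype(np.int16),
        grid={"origin": origin, "spacing": float(spacing),
              "shape": tuple(int(s) for s in labels3d.shape)},
    )
    # fix orientation element-wise (Kuhn paths alternate in parity)
    vol = mesh.element_volumes()
    flip = vol < 0
    mesh.elements[flip, 2], mesh.elements[flip, 3] = (
        mesh.elements[flip, 3].copy(),
        mesh.elements[flip, 2].copy(),
    )
    return mesh


def _face_view(elements: np.ndarray) -> np.ndarray:
    """All four faces of every tet, nodes sorted, shape (4m, 3)."""
    f = np.concatenate(
        [elements[:, idx] for idx in ((1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2))],
        axis=0,
    )
    return np.sort(f, axis=1)


def boundary_faces(mesh: VolumetricMesh, element_mask=None) -> np.ndarray:
    """Faces belonging to exactly one element of the (sub)mesh."""
    elems = mesh.elements if element_mask is None else mesh.elements[element_mask]
    faces = _face_view(elems)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return uniq[counts == 1]


def interface_faces(mesh: VolumetricMesh, labels_a, labels_b) -> np.ndarray:
    """Faces shared between an element of ``labels_a`` and one of ``labels_b``."""
    ba = boundary_faces(mesh, mesh.label_mask(labels_a))
    bb = boundary_faces(mesh, mesh.label_mask(labels_b))
    # rows present in both boundary sets
    dt = np.dtype((np.void, ba.dtype.itemsize * 3))
    a = np.ascontiguousarray(ba).view(dt).ravel()
    b = np.ascontiguousarray(bb).view(dt).ravel()
    common = np.intersect1d(a, b)
    return common.view(ba.dtype).reshape(-1, 3)


def extract_surface_nodes(faces: np.ndarray) -> np.ndarray:
    return np.unique(faces)
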