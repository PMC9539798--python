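"""Synthetic four-chamber heart and torso volume-conductor anatomy.

The subject-specific imaging pipeline is replaced by an idealized,
fully deterministic parametric anatomy:

* LV: truncated thick-walled ellipsoid (cavity ~25 x 25 x 60 mm, wall 10 mm)
* RV: crescent formed by an offset ellipsoidal shell (wall 4 mm) wrapped
  around the LV epicardium
* LA / RA: spherical shells (wall 2.5 mm) above an electrically open AV
  plane, connected only by a Bachmann's-bundle bridge and a fossa-ovalis
  rim pathway
* torso: elliptic cylinder with two lung ellipsoids, the heart embedded
  with a physiological long-axis tilt, and the ten standard 12-lead
  electrodes snapped to the torso surface

Atria and ventricles share no mesh nodes (the AV base is electrically
isolated); the only atrio-ventricular link is the 1-D AV-node cable added
by :mod:`vheart.conduction`.  Apicobasal / transmural / rotational frame
coordinates are computed from the parameterization itself (transmural via
distances to the discrete endo/epi surfaces, so surface nodes sit exactly
at t=0 / t=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (ATRIAL, VENTRICULAR, Tissue, VolumetricMesh,
                   boundary_faces, interface_faces, mesh_from_voxels)

DEG = np.pi / 180.0


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartConfig:
    """Geometry of the synthetic four-chamber heart (mm, heart frame).

    The heart frame has the long axis along z with the base plane at z=0
    and the apex pointing to -z; the RV crescent lies on the -x side.
    Defaults are calibrated so that the default conduction system yields a
    sinus QRS near 85 ms and a tunable PR of 200 ms.
    """

    lv_endo: tuple = (25.0, 25.0, 60.0)
    lv_wall: float = 10.0
    rv_center: tuple = (-18.0, 0.0, -5.0)
    rv_endo: tuple = (40.0, 30.0, 50.0)
    rv_wall: float = 4.0
    ra_center: tuple = (-25.0, -2.0, 32.0)
    ra_outer: float = 22.0
    la_center: tuple = (20.0, -2.0, 32.0)
    la_outer: float = 19.0
    atrial_wall: float = 2.5
    av_gap: float = 2.5
    bb_radius: float = 4.0
    fo_radius: float = 3.0
    san_radius: float = 5.0
    edge_length: float = 2.5
    #: heart placement in the torso: intrinsic rotations about y then x,
    #: then translation (tilts the apex left-anterior-inferior)
    tilt_y_deg: float = -40.0
    tilt_x_deg: float = 20.0
    position: tuple = (25.0, 15.0, 60.0)

    def validate(self) -> None:
        if self.lv_wall >= min(self.lv_endo):
            raise ValueError("degenerate config: LV wall >= cavity semi-axis")
        if self.rv_wall >= min(self.rv_endo):
            raise ValueError("degenerate config: RV wall >= cavity semi-axis")
        if self.atrial_wall >= min(self.ra_outer, self.la_outer):
            raise ValueError("degenerate config: atrial wall >= outer radius")
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")
        gap = (np.linalg.norm(np.subtract(self.la_center, self.ra_center))
               - self.la_outer - self.ra_outer)
        if gap <= 0:
            raise ValueError("degenerate config: atrial shells intersect")

    @property
    def lv_epi(self) -> tuple:
        return tuple(a + self.lv_wall for a in self.lv_endo)

    @property
    def rv_epi(self) -> tuple:
        return tuple(a + self.rv_wall for a in self.rv_endo)

    def rotation(self) -> np.ndarray:
        """Heart-frame -> torso-frame rotation matrix."""
        ay, ax = self.tilt_y_deg * DEG, self.tilt_x_deg * DEG
        cy, sy, cx, sx = np.cos(ay), np.sin(ay), np.cos(ax), np.sin(ax)
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        return rx @ ry

    def to_torso(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation().T + np.asarray(self.position)

    def to_heart(self, pts: np.ndarray) -> np.ndarray:
        return (pts - np.asarray(self.position)) @ self.rotation()


@dataclass(frozen=True)
class TorsoConfig:
    """Elliptic-cylinder torso with two lung ellipsoids (mm, torso frame)."""

    semi_x: float = 140.0
    semi_y: float = 100.0
    half_height: float = 250.0
    edge_length: float = 8.0
    lung_l_center: tuple = (85.0, -10.0, 60.0)
    lung_l_axes: tuple = (40.0, 70.0, 140.0)
    lung_r_center: tuple = (-75.0, -10.0, 60.0)
    lung_r_axes: tuple = (50.0, 75.0, 140.0)

    def inside(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        r2 = (pts[:, 0] / (self.semi_x - margin)) ** 2 + (
            pts[:, 1] / (self.semi_y - margin)) ** 2
        return (r2 <= 1.0) & (np.abs(pts[:, 2]) <= self.half_height - margin)


#: conductivities of the passive volume conductor, S/m
CONDUCTIVITY_S_PER_M = {
    Tissue.LUNG_L: 0.0389,
    Tissue.LUNG_R: 0.0389,
    Tissue.BLOOD_LV: 0.7,
    Tissue.BLOOD_RV: 0.7,
    Tissue.BLOOD_LA: 0.7,
    Tissue.BLOOD_RA: 0.7,
    Tissue.TORSO: 0.22,
}


# --------------------------------------------------------------------------
# implicit geometry helpers (heart frame)
# --------------------------------------------------------------------------

def _ellipsoid_f(pts, center, axes):
    """sqrt of the ellipsoid level function; ==1 on the surface."""
    d = (pts - np.asarray(center)) / np.asarray(axes)
    return np.sqrt(np.einsum("...i,...i->...", d, d))


def _capsule_dist(pts, p0, p1):
    """Distance from points to the segment p0-p1."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    return np.linalg.norm(pts - p0 - t[:, None] * d, axis=1)


class HeartGeometry:
    """Implicit-geometry oracle for the synthetic heart.

    Provides point labelling (used by both the fine heart mesher and the
    coarse torso mesher), surface projections for the Purkinje growth, and
    anatomical anchor points.
    """

    def __init__(self, config: HeartConfig):
        config.validate()
        self.config = config
        c = config
        # Bachmann's bundle: bridge between the atrial roofs
        d_ra = np.array([0.74, 0.0, 0.67])
        d_la = np.array([-0.74, 0.0, 0.67])
        self.bb_p0 = np.asarray(c.ra_center) + c.ra_outer * d_ra
        self.bb_p1 = np.asarray(c.la_center) + c.la_outer * d_la
        # FO rim pathway: straight septal bridge between the shell equators
        axis = np.asarray(c.la_center, float) - np.asarray(c.ra_center, float)
        axis /= np.linalg.norm(axis)
        self.fo_p0 = np.asarray(c.ra_center) + (c.ra_outer - 2 * c.fo_radius) * axis
        self.fo_p1 = np.asarray(c.la_center) - (c.la_outer - 2 * c.fo_radius) * axis
        # SAN: high posterior RA roof
        d_san = np.array([0.0, -0.45, 0.89])
        d_san /= np.linalg.norm(d_san)
        self.san_point = np.asarray(c.ra_center) + c.ra_outer * d_san
        # AV-node atrial anchor: basal RA wall near the septum
        d_avn = np.array([0.5, 0.0, -0.866])
        self.avn_anchor = np.asarray(c.ra_center) + (c.ra_outer - c.atrial_wall / 2) * d_avn
        # His bundle: top of the ventricular septum, LV subendocardium
        self.his_point = self.project_lv_endo(np.array([[-24.0, 0.0, -5.0]]))[0]

    # -- labelling ---------------------------------------------------------

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        """Tissue label for each heart-frame point (0 = empty)."""
        c = self.config
        out = np.zeros(len(pts), dtype=np.int16)
        z = pts[:, 2]
        f_lv_en = _ellipsoid_f(pts, (0, 0, 0), c.lv_endo)
        f_lv_ep = _ellipsoid_f(pts, (0, 0, 0), c.lv_epi)
        f_rv_en = _ellipsoid_f(pts, c.rv_center, c.rv_endo)
        f_rv_ep = _ellipsoid_f(pts, c.rv_center, c.rv_epi)
        below = z <= 0.0
        above = z >= c.av_gap
        r_ra = np.linalg.norm(pts - np.asarray(c.ra_center), axis=1)
        r_la = np.linalg.norm(pts - np.asarray(c.la_center), axis=1)

        lv = below & (f_lv_ep <= 1.0) & (f_lv_en >= 1.0)
        rv = below & (f_rv_ep <= 1.0) & (f_rv_en >= 1.0) & (f_lv_ep > 1.0)
        ra = above & (r_ra <= c.ra_outer) & (r_ra >= c.ra_outer - c.atrial_wall)
        la = above & (r_la <= c.la_outer) & (r_la >= c.la_outer - c.atrial_wall)
        san = ra & (np.linalg.norm(pts - self.san_point, axis=1) <= c.san_radius)
        bb = above & (_capsule_dist(pts, self.bb_p0, self.bb_p1) <= c.bb_radius)
        fo = above & (_capsule_dist(pts, self.fo_p0, self.fo_p1) <= c.fo_radius)

        out[lv] = Tissue.LV
        out[rv & (out == 0)] = Tissue.RV
        out[ra & (out == 0)] = Tissue.RA
        out[la & (out == 0)] = Tissue.LA
        out[san] = Tissue.SAN_REGION
        out[bb & (out == 0)] = Tissue.BB
        out[fo & (out == 0)] = Tissue.FO_RIM
        out[(out == 0) & below & (f_lv_en < 1.0)] = Tissue.BLOOD_LV
        out[(out == 0) & below & (f_rv_en < 1.0) & (f_lv_ep > 1.0)] = Tissue.BLOOD_RV
        out[(out == 0) & above & (r_ra < c.ra_outer - c.atrial_wall)] = Tissue.BLOOD_RA
        out[(out == 0) & above & (r_la < c.la_outer - c.atrial_wall)] = Tissue.BLOOD_LA
        return out

    def bounding_box(self):
        c = self.config
        lo = np.array([c.rv_center[0] - c.rv_epi[0], -max(c.lv_epi[1], c.rv_epi[1]),
                       -c.lv_epi[2]])
        hi = np.array([c.la_center[0] + c.la_outer,
                       max(c.lv_epi[1], c.rv_epi[1]),
                       max(c.ra_center[2] + c.ra_outer, c.la_center[2] + c.la_outer)])
        return lo - 2.0, hi + 2.0

    # -- surfaces for the conduction system --------------------------------

    def project_lv_endo(self, pts):
        return self._project_ellipsoid(pts, (0, 0, 0), self.config.lv_endo)

    def project_rv_septal(self, pts):
        """RV septal endocardium = LV epicardial surface facing the RV cavity."""
        return self._project_ellipsoid(pts, (0, 0, 0), self.config.lv_epi)

    def project_rv_freewall(self, pts):
        return self._project_ellipsoid(pts, self.config.rv_center,
                                       self.config.rv_endo)

    @staticmethod
    def _project_ellipsoid(pts, center, axes, iters: int = 12):
        """Radial projection onto an ellipsoid (from its center)."""
        pts = np.atleast_2d(np.asarray(pts, float))
        f = _ellipsoid_f(pts, center, axes)
        f = np.where(f < 1e-9, 1.0, f)
        return np.asarray(center) + (pts - np.asarray(center)) / f[:, None]

    def on_lv_endo(self, pts) -> np.ndarray:
        return np.atleast_2d(pts)[:, 2] <= -3.0

    def on_rv_septal(self, pts) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (pts[:, 2] <= -3.0) & (
            _ellipsoid_f(pts, self.config.rv_center, self.config.rv_endo) < 1.0)

    def on_rv_freewall(self, pts) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (pts[:, 2] <= -3.0) & (
            _ellipsoid_f(pts, (0, 0, 0), self.config.lv_epi) > 1.0)


# --------------------------------------------------------------------------
# frame coordinates
# --------------------------------------------------------------------------

@dataclass
class FrameCoordinates:
    """Per-heart-node anatomical coordinates.

    apicobasal ``a`` in [0, 1] (0 apex, 1 base for ventricles; 0 AV side,
    1 roof for atria); transmural ``t`` in [0, 1] (0 endo, 1 epi);
    rotational ``r`` in [-pi, pi); ``chamber`` is the host tissue label
    (0 for torso-only / blood-only nodes).
    """

    a: np.ndarray
    t: np.ndarray
    r: np.ndarray
    chamber: np.ndarray


def _surface_distance_t(nodes, node_idx, endo_nodes, outer_nodes):
    """Transmural coordinate from distances to discrete endo/outer surfaces."""
    t = np.zeros(len(node_idx))
    if len(endo_nodes) == 0 or len(outer_nodes) == 0:
        return t
    d0 = cKDTree(nodes[endo_nodes]).query(nodes[node_idx])[0]
    d1 = cKDTree(nodes[outer_nodes]).query(nodes[node_idx])[0]
    denom = d0 + d1
    denom[denom == 0] = 1.0
    return d0 / denom


def compute_frame_coordinates(mesh: VolumetricMesh,
                              geom: HeartGeometry) -> FrameCoordinates:
    """Analytic-parameterization frame coordinates on the heart mesh.

    Transmural t is distance-based (0 exactly on the endocardial surface
    nodes, 1 on the epicardial / outer nodes); apicobasal and rotational
    follow the ellipsoid parameterization.  Operates in the heart frame.
    """
    c = geom.config
    hpts = c.to_heart(mesh.nodes)
    n = mesh.n_nodes
    a = np.zeros(n)
    t = np.zeros(n)
    r = np.zeros(n)
    chamber = np.zeros(n, dtype=np.int16)

    # host chamber per node: ventricles take precedence at junctions
    for lab in (Tissue.BB, Tissue.FO_RIM, Tissue.SAN_REGION, Tissue.LA,
                Tissue.RA, Tissue.RV, Tissue.LV):
        chamber[mesh.nodes_of(lab)] = lab

    # discrete surfaces (exclude the basal truncation rims via a z filter)
    h = c.edge_length

    def _nodes_of_faces(faces, zmax=None):
        idx = np.unique(faces)
        if zmax is not None and len(idx):
            idx = idx[hpts[idx, 2] <= zmax]
        return idx

    lv_endo = _nodes_of_faces(interface_faces(mesh, Tissue.LV, Tissue.BLOOD_LV))
    rv_endo = _nodes_of_faces(np.concatenate([
        interface_faces(mesh, Tissue.RV, Tissue.BLOOD_RV).reshape(-1, 3),
        interface_faces(mesh, Tissue.LV, Tissue.BLOOD_RV).reshape(-1, 3)]))
    heart_boundary = boundary_faces(
        mesh, mesh.label_mask({Tissue.LV, Tissue.RV, Tissue.BLOOD_LV,
                               Tissue.BLOOD_RV}))
    vent_epi = _nodes_of_faces(heart_boundary, zmax=-0.6 * h)

    lv_nodes = np.where(chamber == Tissue.LV)[0]
    rv_nodes = np.where(chamber == Tissue.RV)[0]
    # septal LV tissue is bounded by LV endo on one side, RV endo or epi on
    # the other; pool the outer surfaces accordingly
    lv_outer = np.union1d(vent_epi, rv_endo)
    t[lv_nodes] = _surface_distance_t(mesh.nodes, lv_nodes, lv_endo, lv_outer)
    rv_outer = np.setdiff1d(vent_epi, rv_endo)
    t[rv_nodes] = _surface_distance_t(mesh.nodes, rv_nodes, rv_endo, rv_outer)

    for nodes_i in (lv_nodes, rv_nodes):
        p = hpts[nodes_i]
        z_apex = -geom.config.lv_epi[2]
        a[nodes_i] = np.clip((p[:, 2] - z_apex) / (0.0 - z_apex), 0.0, 1.0)
        r[nodes_i] = np.arctan2(p[:, 1], p[:, 0])

    # atria: shells around their centers
    for lab, center, outer in ((Tissue.RA, c.ra_center, c.ra_outer),
                               (Tissue.LA, c.la_center, c.la_outer)):
        idx = np.where((chamber == lab) |
                       ((chamber == Tissue.SAN_REGION) & (lab == Tissue.RA)))[0]
        if len(idx) == 0:
            continue
        d = hpts[idx] - np.asarray(center)
        rho = np.linalg.norm(d, axis=1)
        rho[rho == 0] = 1.0
        t[idx] = np.clip((rho - (outer - c.atrial_wall)) / c.atrial_wall, 0, 1)
        a[idx] = np.clip(0.5 * (1.0 + d[:, 2] / rho), 0, 1)
        r[idx] = np.arctan2(d[:, 1], d[:, 0])

    # bridges inherit from the nearer atrium
    for lab in (Tissue.BB, Tissue.FO_RIM):
        idx = np.where(chamber == lab)[0]
        if len(idx) == 0:
            continue
        d_ra = np.linalg.norm(hpts[idx] - np.asarray(c.ra_center), axis=1)
        d_la = np.linalg.norm(hpts[idx] - np.asarray(c.la_center), axis=1)
        a[idx] = 0.5
        t[idx] = 0.5
        r[idx] = np.where(d_ra < d_la, 0.0, np.pi / 2)

    return FrameCoordinates(a=a, t=t, r=r, chamber=chamber)


# --------------------------------------------------------------------------
# fibers
# --------------------------------------------------------------------------

def _orthonormalize(f, n):
    """Build right-handed orthonormal frames from fiber f and normal n."""
    f = f / np.linalg.norm(f, axis=1, keepdims=True)
    n = n - np.einsum("ij,ij->i", n, f)[:, None] * f
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    s = np.cross(n, f)
    return np.stack([f, s, n], axis=1)


def _local_ventricular_basis(cent_h, center, axes):
    """Circumferential / apicobasal / transmural basis at element centroids."""
    d = (cent_h - np.asarray(center)) / np.square(np.asarray(axes))
    nrm = np.linalg.norm(d, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    n = d / nrm
    zhat = np.array([0.0, 0.0, 1.0])
    ec = np.cross(np.broadcast_to(zhat, n.shape), n)
    bad = np.linalg.norm(ec, axis=1) < 1e-6
    if bad.any():  # apex: pick any tangent
        ec[bad] = np.cross(n[bad], np.array([1.0, 0.0, 0.0]))
    ec /= np.linalg.norm(ec, axis=1, keepdims=True)
    el = np.cross(n, ec)
    return ec, el, n


def assign_ventricular_fibers(mesh: VolumetricMesh, coords: FrameCoordinates,
                              geom: HeartGeometry,
                              endo_angle_deg: float = 60.0,
                              epi_angle_deg: float = -60.0) -> None:
    """Rule-based transmurally rotating ventricular fibers.

    The helix angle interpolates linearly in the transmural coordinate,
    ``alpha(t) = endo + t*(epi - endo)`` (defaults +60 deg endo to -60 deg
    epi), applied in the circumferential-apicobasal tangent plane.
    Modifies ``mesh.element_fibers`` in place (ventricular elements).
    """
    if coords is None:
        raise ValueError("frame coordinates required for fiber assignment")
    if mesh.element_fibers is None:
        mesh.element_fibers = np.tile(np.eye(3), (mesh.n_elements, 1, 1))
    R = geom.config.rotation()
    cent_h = geom.config.to_heart(mesh.element_centroids())
    t_elem = coords.t[mesh.elements].mean(axis=1)

    for lab, center, axes in (
            (Tissue.LV, (0, 0, 0), np.add(geom.config.lv_endo,
                                          geom.config.lv_wall / 2)),
            (Tissue.RV, geom.config.rv_center, np.add(geom.config.rv_endo,
                                                      geom.config.rv_wall / 2))):
        m = mesh.element_labels == lab
        if not m.any():
            continue
        ec, el, n = _local_ventricular_basis(cent_h[m], center, axes)
        alpha = (endo_angle_deg + t_elem[m] * (epi_angle_deg - endo_angle_deg)) * DEG
        f = np.cos(alpha)[:, None] * ec + np.sin(alpha)[:, None] * el
        frames = _orthonormalize(f, n)
        mesh.element_fibers[m] = frames @ R.T  # rotate rows into torso frame


def assign_atrial_fibers(mesh: VolumetricMesh, coords: FrameCoordinates,
                         geom: HeartGeometry) -> None:
    """Parametric atrial fibers: circumferential per chamber, axial on BB/FO.

    A surrogate for atlas-mapped atrial architecture: fibers run
    circumferentially around each atrial shell; bundle elements (BB, FO
    rim) are fibered along their bridge axis.
    """
    if coords is None:
        raise ValueError("frame coordinates required for fiber assignment")
    if mesh.element_fibers is None:
        mesh.element_fibers = np.tile(np.eye(3), (mesh.n_elements, 1, 1))
    c = geom.config
    R = c.rotation()
    cent_h = c.to_heart(mesh.element_centroids())
    zhat = np.array([0.0, 0.0, 1.0])

    for lab, center in ((Tissue.RA, c.ra_center), (Tissue.LA, c.la_center),
                        (Tissue.SAN_REGION, c.ra_center)):
        m = mesh.element_labels == lab
        if not m.any():
            continue
        d = cent_h[m] - np.asarray(center)
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        n = d / nrm
        f = np.cross(np.broadcast_to(zhat, n.shape), n)
        bad = np.linalg.norm(f, axis=1) < 1e-6
        if bad.any():
            f[bad] = np.cross(n[bad], np.array([1.0, 0.0, 0.0]))
        mesh.element_fibers[m] = _orthonormalize(f, n) @ R.T

    for lab, p0, p1 in ((Tissue.BB, geom.bb_p0, geom.bb_p1),
                        (Tissue.FO_RIM, geom.fo_p0, geom.fo_p1)):
        m = mesh.element_labels == lab
        if not m.any():
            continue
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        f = np.broadcast_to(axis, (int(m.sum()), 3)).copy()
        radial = cent_h[m] - p0 - ((cent_h[m] - p0) @ axis)[:, None] * axis
        nrm = np.linalg.norm(radial, axis=1, keepdims=True)
        nrm[nrm < 1e-6] = 1.0
        n = radial / nrm
        small = (nrm < 1e-6).ravel()
        if small.any():
            n[small] = np.cross(axis, np.array([0.0, 0.0, 1.0]))[None, :]
        mesh.element_fibers[m] = _orthonormalize(f, n) @ R.T


# --------------------------------------------------------------------------
# heart / torso builders
# --------------------------------------------------------------------------

@dataclass
class HeartModel:
    """Bundle of the heart mesh, geometry oracle and frame coordinates."""

    mesh: VolumetricMesh
    geom: HeartGeometry
    coords: FrameCoordinates
    #: anatomical anchor node indices on the mesh
    san_node: int = -1
    avn_attach_node: int = -1


def build_heart(config: HeartConfig | None = None) -> HeartModel:
    """Build the labelled four-chamber heart mesh with fibers and coordinates.

    Deterministic (no RNG): the same config always yields byte-identical
    meshes.  Node coordinates are returned in the torso frame.
    """
    config = config or HeartConfig()
    geom = HeartGeometry(config)
    h = config.edge_length
    lo, hi = geom.bounding_box()
    origin = np.floor(lo / h) * h
    shape = np.ceil((hi - origin) / h).astype(int)
    ii = np.arange(shape[0])
    jj = np.arange(shape[1])
    kk = np.arange(shape[2])
    centers = np.stack(np.meshgrid(ii, jj, kk, indexing="ij"), axis=-1)
    pts = origin + h * (centers + 0.5)
    labels = geom.label_points(pts.reshape(-1, 3)).reshape(shape)
    mesh = mesh_from_voxels(origin, h, labels)
    mesh.nodes = config.to_torso(mesh.nodes)
    mesh.metadata["kind"] = "heart"

    coords = compute_frame_coordinates(mesh, geom)
    mesh.element_fibers = np.tile(np.eye(3), (mesh.n_elements, 1, 1))
    assign_ventricular_fibers(mesh, coords, geom)
    assign_atrial_fibers(mesh, coords, geom)

    tissue_nodes = mesh.nodes_of(ATRIAL | VENTRICULAR)
    hpts = config.to_heart(mesh.nodes)
    san_local = tissue_nodes[coords.chamber[tissue_nodes] == Tissue.SAN_REGION]
    if len(san_local) == 0:
        san_local = tissue_nodes
    san_node = int(san_local[np.argmin(
        np.linalg.norm(hpts[san_local] - geom.san_point, axis=1))])
    ra_nodes = tissue_nodes[np.isin(coords.chamber[tissue_nodes],
                                    [Tissue.RA, Tissue.SAN_REGION])]
    avn_node = int(ra_nodes[np.argmin(
        np.linalg.norm(hpts[ra_nodes] - geom.avn_anchor, axis=1))])
    return HeartModel(mesh=mesh, geom=geom, coords=coords,
                      san_node=san_node, avn_attach_node=avn_node)


@dataclass
class ElectrodeSet:
    """Named electrodes mapped to torso-surface node indices."""

    positions: dict  # name -> requested xyz (mm)
    nodes: dict      # name -> torso node index

    def __getitem__(self, name: str) -> int:
        return self.nodes[name]

    @property
    def names(self):
        return list(self.nodes)


def standard_electrode_positions(torso: TorsoConfig) -> dict:
    """Approximate standard 12-lead electrode sites on the torso surface."""
    def ys(x, frac=1.0):
        return frac * torso.semi_y * np.sqrt(max(1 - (x / torso.semi_x) ** 2, 0.0))

    return {
        "RA": (-125.0, 20.0, 220.0),
        "LA": (125.0, 20.0, 220.0),
        "RL": (-80.0, ys(-80.0, 0.6), -230.0),
        "LL": (80.0, ys(80.0, 0.6), -230.0),
        "V1": (-20.0, ys(-20.0), 60.0),
        "V2": (15.0, ys(15.0), 60.0),
        "V3": (40.0, ys(40.0), 45.0),
        "V4": (62.0, ys(62.0), 30.0),
        "V5": (85.0, ys(85.0), 30.0),
        "V6": (105.0, ys(105.0), 30.0),
    }


@dataclass
class TorsoModel:
    mesh: VolumetricMesh
    electrodes: ElectrodeSet
    config: TorsoConfig


def build_torso(heart: HeartModel,
                config: TorsoConfig | None = None) -> TorsoModel:
    """Coarse torso volume-conductor mesh embedding the heart and lungs.

    The torso lattice (default 8 mm) is labelled with TORSO / lungs and a
    coarse re-labelling of the heart tissues and blood pools (used for the
    FEM conductivity field of the lead-field and pseudo-bidomain solves).
    Standard 12-lead electrodes are snapped to torso-surface nodes; RL is
    the electrical ground.
    """
    config = config or TorsoConfig()
    # the heart must fit inside the torso
    extent = np.abs(heart.mesh.nodes)
    if (np.any(extent[:, 0] > config.semi_x) or
            np.any(extent[:, 1] > config.semi_y) or
            np.any(extent[:, 2] > config.half_height)):
        raise ValueError("heart mesh does not fit inside the torso")

    h = config.edge_length
    lo = np.array([-config.semi_x, -config.semi_y, -config.half_height])
    hi = -lo
    origin = np.floor(lo / h) * h
    shape = np.ceil((hi - origin) / h).astype(int)
    grid = np.stack(np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                                np.arange(shape[2]), indexing="ij"), axis=-1)
    pts = (origin + h * (grid + 0.5)).reshape(-1, 3)

    labels = np.zeros(len(pts), dtype=np.int16)
    inside = config.inside(pts)
    labels[inside] = Tissue.TORSO
    for lab, cen, ax in ((Tissue.LUNG_L, config.lung_l_center, config.lung_l_axes),
                         (Tissue.LUNG_R, config.lung_r_center, config.lung_r_axes)):
        m = inside & (_ellipsoid_f(pts, cen, ax) <= 1.0)
        labels[m] = lab
    heart_labels = heart.geom.label_points(heart.geom.config.to_heart(pts))
    m = inside & (heart_labels > 0)
    labels[m] = heart_labels[m]

    mesh = mesh_from_voxels(origin, h, labels.reshape(shape))
    mesh.metadata["kind"] = "torso"

    # coarse fibers on heart-labelled elements (needed for sigma_i in FEM)
    coarse_coords = _coarse_heart_coords(mesh, heart.geom)
    mesh.element_fibers = np.tile(np.eye(3), (mesh.n_elements, 1, 1))
    assign_ventricular_fibers(mesh, coarse_coords, heart.geom)
    assign_atrial_fibers(mesh, coarse_coords, heart.geom)

    electrodes = _snap_electrodes(mesh, standard_electrode_positions(config))
    return TorsoModel(mesh=mesh, electrodes=electrodes, config=config)


def _coarse_heart_coords(mesh: VolumetricMesh,
                         geom: HeartGeometry) -> FrameCoordinates:
    """Cheap transmural estimate for coarse torso-mesh heart elements."""
    n = mesh.n_nodes
    c = geom.config
    hpts = c.to_heart(mesh.nodes)
    t = np.zeros(n)
    chamber = np.zeros(n, dtype=np.int16)
    for lab in (Tissue.BB, Tissue.FO_RIM, Tissue.SAN_REGION, Tissue.LA,
                Tissue.RA, Tissue.RV, Tissue.LV):
        chamber[mesh.nodes_of(lab)] = lab
    lv = np.isin(chamber, [Tissue.LV])
    f_en = _ellipsoid_f(hpts[lv], (0, 0, 0), c.lv_endo)
    f_ep = _ellipsoid_f(hpts[lv], (0, 0, 0), c.lv_epi)
    t[lv] = np.clip((f_en - 1.0) / np.maximum(f_en - f_ep + 1e-9, 1e-9) /
                    (1 + 1e-12), 0, 1)
    rv = np.isin(chamber, [Tissue.RV])
    f_en = _ellipsoid_f(hpts[rv], c.rv_center, c.rv_endo)
    f_ep = _ellipsoid_f(hpts[rv], c.rv_center, c.rv_epi)
    t[rv] = np.clip((f_en - 1.0) / np.maximum(f_en - f_ep + 1e-9, 1e-9), 0, 1)
    a = np.zeros(n)
    r = np.zeros(n)
    return FrameCoordinates(a=a, t=t, r=r, chamber=chamber)


def _snap_electrodes(mesh: VolumetricMesh, positions: dict) -> ElectrodeSet:
    surf = boundary_faces(mesh)
    surf_nodes = np.unique(surf)
    tree = cKDTree(mesh.nodes[surf_nodes])
    nodes = {}
    for name, pos in positions.items():
        _, i = tree.query(np.asarray(pos, float))
        nodes[name] = int(surf_nodes[i])
    if "RL" not in nodes:
        raise ValueError("electrode set must include the RL ground")
    return ElectrodeSet(positions=dict(positions), nodes=nodes)


# --------------------------------------------------------------------------
# calibration slab (validation probe geometry)
# --------------------------------------------------------------------------

def build_slab(size=(40.0, 12.0, 12.0), edge_length: float = 2.5,
               fiber_dir=(1.0, 0.0, 0.0), sheet_dir=(0.0, 1.0, 0.0),
               label: Tissue = Tissue.LV) -> VolumetricMesh:
    """Rectangular slab with uniform fibers, for planar-wave CV probes."""
    size = np.asarray(size, float)
    shape = np.maximum(np.round(size / edge_length).astype(int), 1)
    labels = np.full(shape, int(label), dtype=np.int16)
    mesh = mesh_from_voxels(np.zeros(3), edge_length, labels)
    f = np.asarray(fiber_dir, float)
    f = f / np.linalg.norm(f)
    s = np.asarray(sheet_dir, float)
    s = s - (s @ f) * f
    s /= np.linalg.norm(s)
    n = np.cross(f, s)
    frame = np.stack([f, s, n])
    mesh.element_fibers = np.tile(frame, (mesh.n_elements, 1, 1))
    mesh.metadata["kind"] = "slab"
    return mesh
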