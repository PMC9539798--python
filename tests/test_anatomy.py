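"""Synthetic anatomy: determinism, coordinates, fibers, electrodes."""

import numpy as np
import pytest

from vheart.anatomy import (CONDUCTIVITY_S_PER_M, HeartConfig, TorsoConfig,
                            build_heart, build_torso)
from vheart.mesh import ATRIAL, VENTRICULAR, Tissue, boundary_faces


@pytest.fixture(scope="module")
def coarse_heart():
    # coarser than default to keep unit tests quick
    return build_heart(HeartConfig(edge_length=3.5))


def test_same_config_builds_identical_meshes(coarse_heart):
    again = build_heart(HeartConfig(edge_length=3.5))
    assert np.array_equal(coarse_heart.mesh.nodes, again.mesh.nodes)
    assert np.array_equal(coarse_heart.mesh.elements, again.mesh.elements)
    assert np.array_equal(coarse_heart.mesh.element_fibers,
                          again.mesh.element_fibers)


def test_degenerate_configs_rejected():
    with pytest.raises(ValueError, match="wall"):
        HeartConfig(lv_wall=30.0).validate()
    with pytest.raises(ValueError, match="atrial shells"):
        HeartConfig(ra_outer=40.0, la_outer=40.0).validate()


def test_ventricular_endocardial_nodes_have_zero_transmural(coarse_heart):
    hm = coarse_heart
    from vheart.mesh import interface_faces

    endo = np.unique(interface_faces(hm.mesh, Tissue.LV, Tissue.BLOOD_LV))
    assert len(endo) > 50
    assert np.all(hm.coords.t[endo] == 0.0)
    # and the transmural coordinate spans the wall
    lv = np.where(hm.coords.chamber == Tissue.LV)[0]
    assert hm.coords.t[lv].max() == pytest.approx(1.0)


def test_atria_and_ventricles_share_no_nodes(coarse_heart):
    atrial = coarse_heart.mesh.nodes_of(ATRIAL)
    vent = coarse_heart.mesh.nodes_of(VENTRICULAR)
    assert len(np.intersect1d(atrial, vent)) == 0


def test_av_isolation_before_avn_attachment(coarse_heart):
    """Tissue connectivity has atria and ventricles in separate components."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from vheart.mesh import CONDUCTING

    mesh = coarse_heart.mesh
    el = mesh.elements[mesh.label_mask(CONDUCTING)]
    edges = np.concatenate([el[:, [i, j]] for i in range(4)
                            for j in range(i + 1, 4)])
    n = mesh.n_nodes
    adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                     shape=(n, n))
    _, lab = connected_components(adj + adj.T, directed=False)
    assert len(np.unique(lab[mesh.nodes_of(ATRIAL)])) == 1
    assert len(np.unique(lab[mesh.nodes_of(VENTRICULAR)])) == 1
    assert (set(lab[mesh.nodes_of(ATRIAL)])
            != set(lab[mesh.nodes_of(VENTRICULAR)]))


def test_fiber_rule_endpoints_and_midpoint(coarse_heart):
    """Helix angle runs +60 deg (endo) to -60 deg (epi), linear in t."""
    from vheart.anatomy import (_local_ventricular_basis,
                                assign_ventricular_fibers)

    hm = coarse_heart
    mesh = hm.mesh
    geom = hm.geom
    t_elem = hm.coords.t[mesh.elements].mean(axis=1)
    R = geom.config.rotation()
    lv = mesh.element_labels == Tissue.LV
    cent_h = geom.config.to_heart(mesh.element_centroids())[lv]
    ec, el, _ = _local_ventricular_basis(
        cent_h, (0, 0, 0), np.add(geom.config.lv_endo, 5.0))
    fib_local = mesh.element_fibers[lv][:, 0, :] @ R  # un-rotate
    cosang = np.einsum("ei,ei->e", fib_local, ec)
    sinang = np.einsum("ei,ei->e", fib_local, el)
    angle = np.degrees(np.arctan2(sinang, cosang))
    expected = 60.0 - 120.0 * t_elem[lv]
    assert np.allclose(angle, expected, atol=1.0)
    for t_val, a_exp in ((0.0, 60.0), (1.0, -60.0), (0.5, 0.0)):
        sel = np.abs(t_elem[lv] - t_val) < 0.05
        if sel.any():
            assert abs(np.median(angle[sel]) - a_exp) < 8.0


def test_fiber_frames_orthonormal(coarse_heart):
    f = coarse_heart.mesh.element_fibers
    gram = np.einsum("eij,ekj->eik", f, f)
    assert np.abs(gram - np.eye(3)).max() < 1e-6


def test_bb_fibers_follow_bridge_axis(coarse_heart):
    hm = coarse_heart
    bb = hm.mesh.element_labels == Tissue.BB
    assert bb.any()
    axis = hm.geom.bb_p1 - hm.geom.bb_p0
    axis = hm.geom.config.rotation() @ (axis / np.linalg.norm(axis))
    fib = hm.mesh.element_fibers[bb][:, 0, :]
    ang = np.degrees(np.arccos(np.clip(np.abs(fib @ axis), 0, 1)))
    assert ang.max() < 5.0


def test_torso_electrodes_and_conductivities(coarse_heart):
    torso = build_torso(coarse_heart)
    surf = np.unique(boundary_faces(torso.mesh))
    for name in ("RA", "LA", "RL", "LL", "V1", "V6"):
        assert torso.electrodes[name] in surf
    assert CONDUCTIVITY_S_PER_M[Tissue.LUNG_L] == 0.0389
    assert CONDUCTIVITY_S_PER_M[Tissue.BLOOD_LV] == 0.7
    assert CONDUCTIVITY_S_PER_M[Tissue.TORSO] == 0.22


def test_heart_outside_torso_rejected(coarse_heart):
    with pytest.raises(ValueError, match="fit"):
        build_torso(coarse_heart, TorsoConfig(semi_x=40.0, semi_y=40.0))
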