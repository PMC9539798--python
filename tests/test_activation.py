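"""Anisotropic Eikonal solver: planar-wave accuracy and invariants."""

import numpy as np
import pytest

from conftest import slab_activation
from vheart import TissueEP, build_slab, measure_effective_cv
from vheart.activation import EikonalSolver, dijkstra_oracle
from vheart.mesh import Tissue


def test_planar_wave_matches_closed_form():
    slab, amap = slab_activation((40, 12, 12), 0, Tissue.LV)
    expected = slab.nodes[:, 0] / 0.6
    err = np.abs(amap.at - expected)
    mask = slab.nodes[:, 0] > 5
    assert (err[mask] / expected[mask]).max() < 0.03


@pytest.mark.parametrize("label,axis,fiber,size,cv_expected", [
    (Tissue.LV, 0, (1, 0, 0), (40, 12, 12), 0.6),    # fiber axis
    (Tissue.LV, 1, (1, 0, 0), (12, 40, 12), 0.3),    # sheet axis (4:2:1)
    (Tissue.LA, 0, (1, 0, 0), (40, 12, 12), 1.2),    # atrial fiber axis
])
def test_effective_cv_on_slab(label, axis, fiber, size, cv_expected):
    slab, amap = slab_activation(size, axis, label, fiber_dir=fiber)
    direction = np.zeros(3)
    direction[axis] = 1.0
    cv = measure_effective_cv(slab, amap, direction)
    assert cv == pytest.approx(cv_expected, rel=0.03)


def test_chain_matches_dijkstra_oracle():
    """On a quasi-1D chain the FIM equals the edge-graph shortest path."""
    slab = build_slab(size=(40, 2.5, 2.5), edge_length=2.5)
    ep = TissueEP()
    src = [(int(i), 0.0) for i in np.where(slab.nodes[:, 0] == 0)[0]]
    at = EikonalSolver(slab, ep).solve(src).at
    oracle = dijkstra_oracle(slab, ep, src)
    # along the chain axis the oracle is exact
    axis_nodes = np.where((slab.nodes[:, 1] == 0) & (slab.nodes[:, 2] == 0))[0]
    assert np.allclose(at[axis_nodes], oracle[axis_nodes], atol=1e-6)


def test_two_sources_equal_min_superposition():
    """Multi-source map equals the node-wise min of single-source maps.

    Exact for the continuous Eikonal; on the discrete mesh the meeting
    ridge of two fronts is concave and linear face interpolation
    undershoots there, so agreement is to discretization tolerance.
    """
    slab = build_slab(size=(40, 12, 12), edge_length=2.5)
    solver = EikonalSolver(slab, TissueEP())
    n = slab.n_nodes
    s1, s2 = 0, n - 1
    a1 = solver.solve([(s1, 0.0)]).at
    a2 = solver.solve([(s2, 5.0)]).at
    both = solver.solve([(s1, 0.0), (s2, 5.0)]).at
    ref = np.minimum(a1, a2)
    assert np.all(both <= ref + 1e-2)           # extra sources never slow
    assert np.all(np.abs(both - ref) <= 0.05 * ref + 0.01)


def test_tilted_fiber_error_shrinks_under_refinement():
    """First-order convergence: refining 2x at least halves the error.

    Fibers are tilted 15 degrees off-lattice so the discrete solution is
    not exact; the error is evaluated only where the optimal ray lands
    inside the stimulated face (no finite-slab clipping).
    """
    c, s = np.cos(np.deg2rad(15)), np.sin(np.deg2rad(15))
    fiber = (c, s, 0.0)
    M = np.diag([0.6, 0.3, 0.15]) ** 2
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    mw = rot @ M @ rot.T
    cx = np.sqrt(mw[0, 0])
    ray = mw[0, 1] / mw[0, 0]
    errs = []
    for h in (3.0, 1.5):
        slab = build_slab(size=(30, 30, 6), edge_length=h, fiber_dir=fiber,
                          sheet_dir=(-s, c, 0.0))
        solver = EikonalSolver(slab, TissueEP())
        src = [(int(i), 0.0) for i in np.where(slab.nodes[:, 0] == 0)[0]]
        at = solver.solve(src).at
        x, y = slab.nodes[:, 0], slab.nodes[:, 1]
        sel = (x > 6) & (y - ray * x > 3) & (y - ray * x < 27)
        errs.append(np.abs(at - x / cx)[sel].max())
    assert errs[0] > 0  # genuinely inexact at the coarse level
    assert errs[1] <= 0.55 * errs[0] + 1e-6


def test_causality_no_negative_travel_times():
    slab, amap = slab_activation((30, 12, 12), 0, Tissue.LV)
    solver = EikonalSolver(slab, TissueEP())
    # AT of any node >= 0 and within physical bounds of the slowest speed
    assert np.all(amap.at >= 0)
    dmax = np.linalg.norm(slab.nodes.max(axis=0) - slab.nodes.min(axis=0))
    assert np.all(amap.at[np.isfinite(amap.at)] <= dmax / 0.15 + 1e-6)


def test_unreachable_nodes_reported_infinite():
    slab = build_slab(size=(20, 5, 5), edge_length=2.5)
    # only conduct LV; relabel half the slab as blood (non-conducting)
    cut = slab.element_centroids()[:, 0] > 10
    slab.element_labels[cut] = Tissue.BLOOD_LV
    solver = EikonalSolver(slab, TissueEP())
    at = solver.solve([(0, 0.0)]).at
    blood_only = np.setdiff1d(np.unique(slab.elements[cut]),
                              np.unique(slab.elements[~cut]))
    assert np.all(np.isinf(at[blood_only]))


def test_missing_fibers_rejected():
    slab = build_slab(size=(10, 5, 5), edge_length=2.5)
    slab.element_fibers = None
    with pytest.raises(ValueError, match="fiber"):
        EikonalSolver(slab, TissueEP())
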