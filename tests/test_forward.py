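"""FEM lead fields, ECG assembly, pseudo-ECG and filtering."""

import numpy as np
import pytest
from scipy.sparse.linalg import splu

from vheart import build_slab
from vheart.anatomy import _snap_electrodes
from vheart.forward import (ConductivityConfig, ECGForwardOperator,
                            ECGRecording, LeadFieldSet, PseudoECGOperator,
                            assemble_stiffness, element_conductivities,
                            filter_ecg, infinite_medium_leadfields,
                            twelve_lead_from_potentials)
from vheart.membrane import reaction_eikonal_vm
from vheart.mesh import Tissue


def _solve_pinned(K, rhs, ground):
    K = K.tolil()
    K[ground, :] = 0.0
    K[:, ground] = 0.0
    K[ground, ground] = 1.0
    rhs = rhs.copy()
    rhs[ground] = 0.0
    return splu(K.tocsc()).solve(rhs)


@pytest.fixture(scope="module")
def bar():
    """Homogeneous conducting bar, 40 x 8 x 8 mm, sigma = 0.22 S/m."""
    mesh = build_slab(size=(40, 8, 8), edge_length=2.0, label=Tissue.LV)
    mesh.element_labels[:] = Tissue.TORSO
    return mesh


def test_bar_resistance_matches_closed_form(bar):
    """Linear potential along a bar; R = L / (sigma A) exactly in 1-D."""
    sigma = element_conductivities(bar, ConductivityConfig())
    K = assemble_stiffness(bar, sigma)
    left = np.where(bar.nodes[:, 0] == 0.0)[0]
    right = np.where(bar.nodes[:, 0] == 40.0)[0]
    rhs = np.zeros(bar.n_nodes)
    rhs[right] = 1.0 / len(right)      # 1 A total, uniformly over the face
    rhs[left] -= 1.0 / len(left)
    z = _solve_pinned(K, rhs, int(left[0]))
    # mean face-to-face drop equals I * L / (sigma A)
    drop = z[right].mean() - z[left].mean()
    expected = 1.0 * (40e-3) / (0.22 * (8e-3) ** 2)
    assert drop == pytest.approx(expected, rel=0.02)
    # interior potential is linear in x
    mid = (bar.nodes[:, 1] == 4.0) & (bar.nodes[:, 2] == 4.0)
    coeffs = np.polyfit(bar.nodes[mid, 0], z[mid], 1)
    assert np.abs(np.polyval(coeffs, bar.nodes[mid, 0]) - z[mid]).max() \
        < 0.02 * abs(drop)


def test_reciprocity_swapping_electrode_and_ground_negates_field(bar):
    sigma = element_conductivities(bar, ConductivityConfig())
    K = assemble_stiffness(bar, sigma)
    a, b = 0, bar.n_nodes - 1
    rhs = np.zeros(bar.n_nodes)
    rhs[a], rhs[b] = 1.0, -1.0
    z_ab = _solve_pinned(K, rhs, b)
    z_ba = _solve_pinned(K, -rhs, a)
    # up to the additive gauge both solves are negatives of each other
    d = z_ab + z_ba
    assert np.ptp(d) < 1e-8 * np.ptp(z_ab)


def test_lead_field_maximal_at_injection_node(bar):
    sigma = element_conductivities(bar, ConductivityConfig())
    K = assemble_stiffness(bar, sigma)
    a, b = 0, bar.n_nodes - 1
    rhs = np.zeros(bar.n_nodes)
    rhs[a], rhs[b] = 1.0, -1.0
    z = _solve_pinned(K, rhs, b)
    assert np.argmax(z) == a


def test_electrode_set_requires_ground(bar):
    with pytest.raises(ValueError, match="RL"):
        _snap_electrodes(bar, {"V1": (0.0, 0.0, 0.0)})


def _slab_vm(reversed_direction=False):
    """Planar depolarization crossing a slab, as a VmTraceSet."""
    slab = build_slab(size=(30, 10, 10), edge_length=2.5, label=Tissue.LV)
    x = slab.nodes[:, 0]
    at = (30.0 - x if reversed_direction else x) / 0.6 + 5.0
    tc = np.full(slab.n_nodes, 140.0)
    return slab, reaction_eikonal_vm(at, tc, duration_ms=250)


def test_einthoven_and_goldberger_identities_exact():
    rng = np.random.default_rng(1)
    t = np.arange(200.0)
    phi = {n: rng.normal(size=200) for n in
           ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")}
    rec = twelve_lead_from_potentials(phi, t)
    d = rec.leads["I"] + rec.leads["III"] - rec.leads["II"]
    assert np.abs(d).max() < 1e-12      # machine precision
    s = rec.leads["aVR"] + rec.leads["aVL"] + rec.leads["aVF"]
    assert np.abs(s).max() < 1e-12


def test_uniform_vm_produces_null_ecg():
    slab, _ = _slab_vm()
    lf = infinite_medium_leadfields(slab, [[60, 5, 5], [0, 50, 5]])
    op = ECGForwardOperator(lf, slab)
    vm = np.full((slab.n_nodes, 50), -20.0, dtype=np.float32)
    assert np.abs(op.potentials(vm)).max() < 1e-9


def test_ecg_operator_linear_in_vm():
    slab, vmset = _slab_vm()
    lf = infinite_medium_leadfields(slab, [[60, 5, 5]])
    op = ECGForwardOperator(lf, slab)
    a = op.potentials(vmset.vm)
    b = op.potentials(2.5 * vmset.vm - 7.0)
    assert np.allclose(b, 2.5 * a, atol=1e-9 + 1e-9 * np.abs(a).max())


def test_wavefront_reversal_flips_deflection_polarity():
    slab, fwd = _slab_vm(False)
    _, bwd = _slab_vm(True)
    op = PseudoECGOperator(slab, [[45.0, 5.0, 5.0]])   # facing the +x end
    a = op(fwd.vm)[0]
    b = op(bwd.vm)[0]
    # approaching wave: dominant positive deflection; receding: negative
    assert a[np.abs(a).argmax()] > 0
    assert b[np.abs(b).argmax()] < 0


def test_pseudo_ecg_scales_inversely_with_bulk_conductivity():
    slab, vmset = _slab_vm()
    a = PseudoECGOperator(slab, [[60, 5, 5]], sigma_bulk=0.22)(vmset.vm)
    b = PseudoECGOperator(slab, [[60, 5, 5]], sigma_bulk=0.44)(vmset.vm)
    assert np.allclose(b, 0.5 * a)


def test_pseudo_ecg_agrees_with_leadfield_machinery():
    """Direct integral vs bilinear form with analytic unbounded Z."""
    slab, vmset = _slab_vm()
    ex = [[60.0, 5.0, 5.0], [15.0, 40.0, 5.0]]
    pe = PseudoECGOperator(slab, ex)(vmset.vm)
    lf = infinite_medium_leadfields(slab, ex)
    unit = ConductivityConfig(sigma_i_longitudinal=1.0,
                              sigma_i_transverse=1.0)
    pb = ECGForwardOperator(lf, slab, unit).potentials(vmset.vm)
    pb *= 1.0 / 0.22   # pseudo integral carries the 1/sigma_bulk factor
    for k in range(len(ex)):
        cc = np.corrcoef(pe[k], pb[k])[0, 1]
        assert cc > 0.99


class TestFilter:
    def _rec(self, x, fs=1000.0):
        t = np.arange(len(x)) / fs * 1000.0
        return ECGRecording(leads={"I": x}, times=t)

    def test_highpass_removes_dc_offset(self):
        rec = self._rec(np.full(2000, 3.0))
        out = filter_ecg(rec)
        assert abs(out.leads["I"].mean()) < 1e-6

    def test_notch_attenuates_mains_by_20db(self):
        # long tone: the narrow notch has a long impulse response, so the
        # steady-state attenuation is read in the middle of a 10 s signal
        t = np.arange(10000) / 1000.0
        rec = self._rec(np.sin(2 * np.pi * 50.0 * t))
        out = filter_ecg(rec, notch_hz=50.0)
        mid = slice(4000, 6000)
        atten = (np.abs(out.leads["I"][mid]).max()
                 / np.abs(rec.leads["I"][mid]).max())
        assert atten < 0.1   # > 20 dB

    def test_passband_tone_preserved(self):
        t = np.arange(10000) / 1000.0
        rec = self._rec(np.sin(2 * np.pi * 10.0 * t))
        out = filter_ecg(rec)
        mid = slice(4000, 6000)
        ratio = (np.abs(out.leads["I"][mid]).max()
                 / np.abs(rec.leads["I"][mid]).max())
        assert ratio == pytest.approx(1.0, abs=0.05)
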