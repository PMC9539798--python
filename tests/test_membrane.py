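"""Mitchell-Schaeffer dynamics, ARI mapping and Vm reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vheart.membrane import (MSParams, RepolConfig, ari_map,
                             calibrate_tau_close, integrate_ms, measure_apd,
                             measure_plateau_duration, reaction_eikonal_vm,
                             tau_close_from_ari)


def test_unstimulated_cell_stays_at_rest():
    p = MSParams()
    t, v, h = integrate_ms(p, stimulus_times=(), duration_ms=500)
    assert p.to_mv(v[-1]) == pytest.approx(-86.2, abs=0.1)


def test_stimulated_peak_reaches_prescribed_potential():
    p = MSParams()
    t, v, h = integrate_ms(p, stimulus_times=(10.0,), duration_ms=650)
    assert p.to_mv(v).max() == pytest.approx(40.0, abs=2.0)


@pytest.mark.parametrize("tau_close", [100.0, 175.0, 300.0])
def test_plateau_duration_matches_analytic_apd(tau_close):
    """The plateau duration tracks tau_close * ln(tau_out/(4 tau_in))."""
    p = MSParams(tau_close=tau_close)
    t, v, h = integrate_ms(p, stimulus_times=(10.0,), duration_ms=900)
    apd = measure_plateau_duration(t, p.to_mv(v), p.v_rest_mv)
    assert apd == pytest.approx(p.apd_max_ms, rel=0.05)


def test_apd90_exceeds_plateau_duration():
    p = MSParams()
    t, v, h = integrate_ms(p, stimulus_times=(10.0,), duration_ms=900)
    apd90 = measure_apd(t, p.to_mv(v), p.v_rest_mv)
    assert apd90 > measure_plateau_duration(t, p.to_mv(v), p.v_rest_mv)


def test_overlarge_dt_rejected():
    with pytest.raises(ValueError, match="dt"):
        integrate_ms(MSParams(), stimulus_times=(10.0,), dt_ms=0.5)


@given(tau_close=st.floats(60.0, 400.0), tau_open=st.floats(50.0, 300.0))
@settings(max_examples=10, deadline=None)
def test_gate_and_potential_stay_bounded(tau_close, tau_open):
    """One suprathreshold beat from rest keeps h in [0,1], v in [-.05,1.05]."""
    p = MSParams(tau_close=tau_close, tau_open=tau_open)
    t, v, h = integrate_ms(p, stimulus_times=(5.0,), duration_ms=900)
    assert np.all((h >= 0.0) & (h <= 1.0))
    assert np.all((v >= -0.05) & (v <= 1.05))


def test_ari_map_linear_rule():
    at = np.array([0.0, 100.0, 50.0])
    ari = ari_map(at, RepolConfig())
    assert ari[0] == pytest.approx(215.0)
    assert ari[1] == pytest.approx(-0.66 * 100 + 215)  # 149 ms
    flat = ari_map(at, RepolConfig(slope=0.0, intercept_ms=180.0))
    assert np.all(flat == 180.0)
    with pytest.raises(ValueError, match="non-positive"):
        ari_map(np.array([400.0]), RepolConfig())


def test_non_ventricular_nodes_get_maximal_ari():
    at = np.array([0.0, 60.0, np.inf])
    mask = np.array([True, True, False])
    ari = ari_map(at, RepolConfig(), ventricular_mask=mask)
    assert ari[2] == ari[:2].max() == pytest.approx(215.0)


def test_tau_close_inversion_examples():
    assert tau_close_from_ari(215.0) == pytest.approx(215 / np.log(4.5),
                                                      abs=0.01)
    assert tau_close_from_ari(175.0 * np.log(4.5)) == pytest.approx(175.0)
    assert tau_close_from_ari(0.0) == 0.0
    with pytest.raises(ValueError, match="plateau"):
        tau_close_from_ari(200.0, tau_in=2.0, tau_out=5.0)


def test_calibrated_inversion_reproduces_ari_as_apd90():
    p = MSParams()
    ari = np.array([160.0, 215.0])
    tc = calibrate_tau_close(ari, p)
    for a, c in zip(ari, tc):
        t, v, h = integrate_ms(MSParams(tau_close=c), stimulus_times=(10.0,),
                               duration_ms=900)
        assert measure_apd(t, p.to_mv(v), p.v_rest_mv) == pytest.approx(
            a, abs=2.0)


class TestReactionEikonal:
    def test_uniform_at_gives_identical_traces(self):
        at = np.full(5, 40.0)
        tc = np.full(5, 140.0)
        vmset = reaction_eikonal_vm(at, tc, duration_ms=600)
        assert np.allclose(vmset.vm, vmset.vm[0][None, :])

    def test_upstroke_within_3ms_of_activation(self):
        at = np.array([30.0, 120.5, 333.25])
        tc = np.full(3, 140.0)
        vmset = reaction_eikonal_vm(at, tc, duration_ms=700)
        for k, t0 in enumerate(at):
            cross = vmset.times[np.argmax(vmset.vm[k] > -40.0)]
            assert t0 <= cross <= t0 + 3.0

    def test_inactive_nodes_stay_at_rest(self):
        at = np.array([np.inf, 50.0])
        tc = np.array([np.nan, 140.0])
        vmset = reaction_eikonal_vm(at, tc)
        assert np.allclose(vmset.vm[0], MSParams().v_rest_mv)

    def test_missing_tau_close_rejected(self):
        with pytest.raises(ValueError, match="tau_close"):
            reaction_eikonal_vm(np.array([10.0]), np.array([np.nan]))

    def test_vm_bounded_by_rest_and_peak(self):
        at = np.linspace(20, 300, 40)
        tc = np.linspace(100, 200, 40)
        vmset = reaction_eikonal_vm(at, tc)
        p = vmset.params
        assert vmset.vm.min() >= p.v_rest_mv - 2.0
        assert vmset.vm.max() <= p.v_peak_mv + 2.0

    def test_rt_minus_at_reproduces_ari(self):
        """RT at 90% repolarization minus AT regresses on ARI with slope 1."""
        rng = np.random.default_rng(0)
        at = rng.uniform(10, 90, size=60)
        ari = ari_map(at, RepolConfig())
        tc = calibrate_tau_close(ari)
        vmset = reaction_eikonal_vm(at, tc, duration_ms=700)
        rt = vmset.repolarization_times()
        slope = np.polyfit(ari, rt - at, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)
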