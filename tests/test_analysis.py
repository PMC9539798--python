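"""Beat splitting/averaging, similarity metrics, interval detection."""

import numpy as np
import pytest

from vheart.analysis import (check_lbbb, check_rbbb, compare,
                             measure_intervals, split_and_average)
from vheart.forward import ECGRecording, STANDARD_LEADS


def _gauss(t, mu, sd, amp):
    return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)


def synthetic_beat(t, qrs_at=300.0):
    """P-QRS-T template on a ms grid."""
    p = _gauss(t, qrs_at - 160, 18, 0.15)
    q = -_gauss(t, qrs_at - 18, 5, 0.2)
    r = _gauss(t, qrs_at, 8, 1.2)
    s = -_gauss(t, qrs_at + 18, 6, 0.3)
    tw = _gauss(t, qrs_at + 250, 40, 0.35)
    return p + q + r + s + tw


def synthetic_recording(n_beats=1, rr_ms=800.0, fs=1000.0):
    n = int((n_beats * rr_ms + 200) * fs / 1000.0)
    t = np.arange(n) / fs * 1000.0
    x = np.zeros(n)
    for k in range(n_beats):
        x += synthetic_beat(t, qrs_at=300.0 + k * rr_ms)
    leads = {name: x * (1.0 if name != "aVR" else -1.0)
             for name in STANDARD_LEADS}
    return ECGRecording(leads=leads, times=t)


class TestSplitAndAverage:
    def test_train_of_identical_beats_recovered(self):
        rec = synthetic_recording(n_beats=12)
        ens = split_and_average(rec, threshold_mv=0.2)
        assert ens.n_beats == 12
        one = ens.beats[3].leads["I"]
        assert np.allclose(ens.mean.leads["I"], one, atol=1e-9)
        assert max(s.max() for s in ens.std.values()) < 1e-9

    def test_single_beat_mean_is_itself(self):
        rec = synthetic_recording(n_beats=1)
        ens = split_and_average(rec)
        assert ens.n_beats == 1
        assert np.allclose(ens.mean.leads["II"], ens.beats[0].leads["II"])

    def test_flat_recording_rejected(self):
        t = np.arange(2000.0)
        rec = ECGRecording(leads={"I": np.zeros(2000)}, times=t)
        with pytest.raises(ValueError):
            split_and_average(rec)


class TestCompare:
    def test_identity_comparison(self):
        rec = synthetic_recording()
        out = compare(rec, rec, scale=1.0)
        assert out["avg_L2"] == pytest.approx(0.0, abs=1e-12)
        assert out["avg_CC"] == pytest.approx(1.0)

    def test_anticorrelated(self):
        rec = synthetic_recording()
        neg = ECGRecording(leads={k: -v for k, v in rec.leads.items()},
                           times=rec.times)
        assert compare(rec, neg, scale=1.0)["avg_CC"] == pytest.approx(-1.0)

    def test_amplitude_scaling_cancels(self):
        rec = synthetic_recording()
        double = ECGRecording(leads={k: 2 * v for k, v in rec.leads.items()},
                              times=rec.times)
        out = compare(double, rec, scale=0.5)
        assert out["avg_L2"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_of_cc_and_l2(self):
        a = synthetic_recording()
        b = ECGRecording(leads={k: v + 0.05 * np.sin(a.times / 50)
                                for k, v in a.leads.items()}, times=a.times)
        ab = compare(a, b, scale=1.0)
        ba = compare(b, a, scale=1.0)
        assert ab["avg_CC"] == pytest.approx(ba["avg_CC"], abs=1e-12)
        assert ab["avg_L2"] == pytest.approx(ba["avg_L2"], abs=1e-12)


class TestIntervals:
    def test_boxcar_qrs_width_recovered(self):
        t = np.arange(1000.0)
        x = np.zeros(1000)
        x[300:380] = 1.0   # 80 ms boxcar
        leads = {n: x for n in STANDARD_LEADS}
        rep = measure_intervals(ECGRecording(leads=leads, times=t))
        assert rep.qrs_ms == pytest.approx(80.0, abs=2.0)

    def test_pr_and_qt_on_synthetic_beat(self):
        rec = synthetic_recording()
        rep = measure_intervals(rec)
        # P starts ~3 sd before its center; PR measured onset-to-onset
        assert 100.0 <= rep.pr_ms <= 180.0
        assert rep.qt_ms is not None and 250.0 <= rep.qt_ms <= 400.0

    def test_flatline_rejected(self):
        t = np.arange(500.0)
        rec = ECGRecording(leads={n: np.zeros(500) for n in STANDARD_LEADS},
                           times=t)
        with pytest.raises(ValueError, match="flat"):
            measure_intervals(rec)

    def test_sampling_rate_invariance(self):
        rec1 = synthetic_recording(fs=1000.0)
        rec2 = synthetic_recording(fs=500.0)
        q1 = measure_intervals(rec1).qrs_ms
        q2 = measure_intervals(rec2).qrs_ms
        assert abs(q1 - q2) <= 2.0 + 1e-9   # one sample at the coarser rate


def test_criteria_checkers_are_pure():
    rec = synthetic_recording()
    a = check_lbbb(rec).to_dict()
    b = check_lbbb(rec).to_dict()
    assert a == b
    c = check_rbbb(rec).to_dict()
    d = check_rbbb(rec).to_dict()
    assert c == d


def test_narrow_qrs_fails_both_block_criteria():
    rec = synthetic_recording()
    assert not check_lbbb(rec).verdict
    assert not check_rbbb(rec).verdict
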