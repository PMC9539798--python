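"""ECG comparison, interval measurement and clinical criteria checking.

Beat handling follows the clinical processing chain: a long recording is
split on QRS peaks of lead I (0.2 mV threshold), aligned and averaged;
simulated and reference signals are compared per lead by L2 norm and
Pearson correlation after amplitude scaling (default 0.32).  Interval
onsets/offsets are read from the RMS signal across leads with an
adaptive threshold (5% of the RMS peak, 10 ms debounce).  Complete
left/right bundle-branch-block reports operationalize the standard
clinical recommendations (QRS > 120 ms plus lead-group morphology).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .forward import ECGRecording, STANDARD_LEADS


# --------------------------------------------------------------------------
# beat splitting and averaging
# --------------------------------------------------------------------------

@dataclass
class BeatEnsemble:
    beats: list                      # list of ECGRecording, aligned
    mean: ECGRecording
    std: dict                        # lead -> per-sample std

    @property
    def n_beats(self) -> int:
        return len(self.beats)


def split_and_average(rec: ECGRecording, threshold_mv: float = 0.2,
                      refractory_ms: float = 300.0,
                      window_ms=(250.0, 450.0)) -> BeatEnsemble:
    """Split a multi-beat recording into aligned beats and average them.

    QRS peaks are detected on lead I where |signal| exceeds the threshold
    (default 0.2 mV) with a refractory spacing; beats are windowed around
    each peak and truncated to the common length.
    """
    if "I" not in rec.leads:
        raise ValueError("recording has no lead I")
    lead1 = rec.leads["I"]
    if np.allclose(lead1, lead1[0]):
        raise ValueError("flat lead I; cannot split beats")
    dt = float(rec.times[1] - rec.times[0])
    dist = max(int(refractory_ms / dt), 1)
    peaks, _ = sp_signal.find_peaks(np.abs(lead1), height=threshold_mv,
                                    distance=dist)
    if len(peaks) < 1:
        raise ValueError("no QRS peaks above threshold detected on lead I")

    pre = int(window_ms[0] / dt)
    post = int(window_ms[1] / dt)
    pre = min(pre, peaks.min())
    post = min(post, len(lead1) - peaks.max())
    beats = []
    for p in peaks:
        t = np.arange(-pre, post) * dt
        leads = {k: v[p - pre:p + post].copy() for k, v in rec.leads.items()}
        beats.append(ECGRecording(leads=leads, times=t))
    names = beats[0].lead_names
    stacks = {k: np.stack([b.leads[k] for b in beats]) for k in names}
    mean = ECGRecording(leads={k: s.mean(axis=0) for k, s in stacks.items()},
                        times=beats[0].times)
    std = {k: s.std(axis=0) for k, s in stacks.items()}
    return BeatEnsemble(beats=beats, mean=mean, std=std)


def compare(sim: ECGRecording, ref: ECGRecording, scale: float = 0.32,
            leads=None) -> dict:
    """Average L2 difference and Pearson CC across leads.

    The simulated signal is scaled (default 0.32) and linearly resampled
    onto the shorter common time grid.  L2 is the per-lead RMS of the
    sample differences (root-sum-square normalized by sample count).
    """
    leads = leads or [l for l in STANDARD_LEADS
                      if l in sim.leads and l in ref.leads]
    if not leads:
        raise ValueError("no common leads to compare")
    t0 = max(sim.times[0], ref.times[0])
    t1 = min(sim.times[-1], ref.times[-1])
    n = min(len(sim.times), len(ref.times))
    grid = np.linspace(t0, t1, n)
    l2s, ccs = [], []
    for name in leads:
        a = np.interp(grid, sim.times, sim.leads[name]) * scale
        b = np.interp(grid, ref.times, ref.leads[name])
        l2s.append(np.sqrt(np.mean((a - b) ** 2)))
        sa, sb = a.std(), b.std()
        ccs.append(0.0 if sa == 0 or sb == 0 else
                   float(np.corrcoef(a, b)[0, 1]))
    return {"avg_L2": float(np.mean(l2s)), "avg_CC": float(np.mean(ccs)),
            "leads": list(leads)}


# --------------------------------------------------------------------------
# interval measurement
# --------------------------------------------------------------------------

def _rms_signal(rec: ECGRecording, leads=None) -> np.ndarray:
    leads = leads or [l for l in STANDARD_LEADS if l in rec.leads]
    x = rec.stack(leads)
    x = x - np.median(x, axis=1, keepdims=True)
    return np.sqrt(np.mean(x ** 2, axis=0))


def _active_runs(mask: np.ndarray, min_len: int, max_gap: int):
    """Contiguous True runs, closing gaps < max_gap, dropping short runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > max_gap:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return [(a, b) for a, b in runs if b - a + 1 >= min_len]


@dataclass
class IntervalReport:
    qrs_ms: float
    pr_ms: float | None
    qt_ms: float | None
    qrs_onset_ms: float
    qrs_offset_ms: float
    p_onset_ms: float | None
    t_end_ms: float | None
    details: dict = field(default_factory=dict)


def measure_intervals(rec: ECGRecording, threshold_frac: float = 0.05,
                      debounce_ms: float = 10.0,
                      max_qrs_ms: float = 250.0) -> IntervalReport:
    """QRS duration, PR and QT from the multi-lead RMS envelope.

    The RMS across leads is thresholded at ``threshold_frac`` of its peak
    with a debounce; the run containing the global maximum is the QRS,
    the preceding run the P wave, the following one the T wave.  When a
    broad QRS merges with a discordant T (the run exceeds ``max_qrs_ms``),
    the complex is split at the deepest RMS valley after the QRS peak.
    T end is found by the tangent method on the descending T limb.
    """
    rms = _rms_signal(rec)
    if rms.max() <= 0 or np.ptp(rms) < 1e-9:
        raise ValueError("flatline recording")
    dt = float(rec.times[1] - rec.times[0])
    nd = max(int(debounce_ms / dt), 1)
    thr = threshold_frac * rms.max()
    runs = _active_runs(rms > thr, min_len=nd, max_gap=nd)
    if not runs:
        raise ValueError("no activity above threshold")
    imax = int(np.argmax(rms))
    qrs_run = next(((a, b) for a, b in runs if a <= imax <= b), None)
    if qrs_run is None:
        raise ValueError("QRS peak not inside any suprathreshold run")
    k = runs.index(qrs_run)
    a, b = qrs_run
    if (b - a) * dt > max_qrs_ms:
        # merged QRS+T: split at the deepest valley after the QRS peak,
        # provided a later hump (the T wave) follows
        margin = max(int(40.0 / dt), 1)
        lo, hi = imax + margin, b - margin
        if hi > lo:
            valley = lo + int(np.argmin(rms[lo:hi]))
            if rms[valley:hi].max() > 1.5 * rms[valley]:
                runs[k] = (a, valley)
                runs.insert(k + 1, (valley, b))
                qrs_run = runs[k]
    qrs_on, qrs_off = rec.times[qrs_run[0]], rec.times[qrs_run[1]]

    p_on = None
    if k > 0:
        p_on = float(rec.times[runs[k - 1][0]])

    t_end = None
    if k + 1 < len(runs):
        ta, tb = runs[k + 1]
        # tangent method: steepest descent after the T peak, extrapolated
        # to the baseline
        tpk = ta + int(np.argmax(rms[ta:tb + 1]))
        seg = rms[tpk:min(tb + nd, len(rms) - 1) + 1]
        if len(seg) > 2:
            d = np.diff(seg) / dt
            j = int(np.argmin(d))
            slope = d[j]
            if slope < 0:
                t_cross = rec.times[tpk + j] + (0.0 - seg[j]) / slope
                t_end = float(min(t_cross, rec.times[-1]))
        if t_end is None:
            t_end = float(rec.times[tb])

    return IntervalReport(
        qrs_ms=float(qrs_off - qrs_on),
        pr_ms=None if p_on is None else float(qrs_on - p_on),
        qt_ms=None if t_end is None else float(t_end - qrs_on),
        qrs_onset_ms=float(qrs_on),
        qrs_offset_ms=float(qrs_off),
        p_onset_ms=p_on,
        t_end_ms=t_end,
        details={"threshold_mv": float(thr), "n_runs": len(runs)},
    )


# --------------------------------------------------------------------------
# bundle-branch-block criteria
# --------------------------------------------------------------------------

@dataclass
class CriteriaReport:
    """Per-criterion verdicts with the supporting measurements."""

    name: str
    verdict: bool
    checks: dict                     # criterion name -> bool
    measurements: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "verdict": bool(self.verdict),
                "checks": {k: bool(v) for k, v in self.checks.items()},
                "measurements": self.measurements}


def _qrs_window(rec: ECGRecording, report: IntervalReport | None):
    report = report or measure_intervals(rec)
    i0 = int(np.searchsorted(rec.times, report.qrs_onset_ms))
    i1 = int(np.searchsorted(rec.times, report.qrs_offset_ms))
    return report, i0, i1


def _lead_morphology(tr: np.ndarray, dt: float, level_frac: float = 0.05,
                     ripple_frac: float = 0.01,
                     monophasic_frac: float = 0.10,
                     minor_frac: float = 0.25) -> dict:
    """Deflection morphology of one lead inside the QRS window.

    A notch is >= 2 local extrema of matching sign whose amplitude
    exceeds ``level_frac`` of the peak (a small ``ripple_frac``
    prominence floor suppresses numerical ripple).  Monophasic R allows
    no opposite excursion beyond ``monophasic_frac`` of R; the looser
    ``minor_frac`` tolerates small initial/terminal deflections in the
    "essentially positive" checks.
    """
    tr = tr - tr[0]
    peak = np.abs(tr).max()
    if peak == 0:
        return {"n_pos_peaks": 0, "n_neg_peaks": 0, "dominant_sign": 0,
                "monophasic_r": False, "notched_positive": False,
                "w_shaped_negative": False, "positive_major": False,
                "r_mv": 0.0, "s_mv": 0.0}
    prom = ripple_frac * peak
    level = level_frac * peak
    pos, _ = sp_signal.find_peaks(tr, prominence=prom)
    neg, _ = sp_signal.find_peaks(-tr, prominence=prom)
    pos = pos[tr[pos] > level]
    neg = neg[tr[neg] < -level]
    area = float(np.trapezoid(tr) * dt)
    r_mv = float(tr.max())
    s_mv = float(tr.min())
    dominant = 1 if area >= 0 else -1
    monophasic = bool(len(pos) >= 1 and -s_mv <= monophasic_frac * r_mv)
    m_pattern = bool(len(pos) >= 2 and dominant > 0)
    return {
        "n_pos_peaks": int(len(pos)),
        "n_neg_peaks": int(len(neg)),
        "dominant_sign": dominant,
        # single positive deflection, no negative excursion > 10% of R
        "monophasic_r": monophasic,
        # essentially positive R with a notch (small deflections tolerated)
        "notched_positive": bool(len(pos) >= 2 and dominant > 0
                                 and -s_mv <= minor_frac * r_mv),
        # deep/broad S with >= 2 negative troughs ("W" shape)
        "w_shaped_negative": bool(len(neg) >= 2 and dominant < 0),
        # dominant positive complex: monophasic R or rsR'/M pattern
        "positive_major": bool(monophasic or m_pattern),
        "r_mv": r_mv,
        "s_mv": s_mv,
    }


def _st_discordance(rec: ECGRecording, lead: str, i0: int, i1: int) -> bool:
    """Sign of the ST/T area opposite the dominant QRS area."""
    tr = rec.leads[lead]
    qrs_area = float(np.trapezoid(tr[i0:i1] - tr[i0]))
    st = tr[i1:]
    if len(st) < 3:
        return False
    st_area = float(np.trapezoid(st - tr[i0]))
    return bool(np.sign(st_area) == -np.sign(qrs_area) and qrs_area != 0)


def check_lbbb(rec: ECGRecording,
               report: IntervalReport | None = None) -> CriteriaReport:
    """Complete-LBBB criteria: broad QRS, W-shaped S in V1/V2, notched
    all-positive R in V5/V6, ST/T discordance."""
    report, i0, i1 = _qrs_window(rec, report)
    dt = float(rec.times[1] - rec.times[0])
    morph = {l: _lead_morphology(rec.leads[l][i0:i1], dt)
             for l in ("V1", "V2", "V5", "V6")}
    checks = {
        "qrs_gt_120": report.qrs_ms > 120.0,
        "v1_v2_w_shape": any(morph[l]["w_shaped_negative"] and
                             morph[l]["dominant_sign"] < 0
                             for l in ("V1", "V2")),
        "v5_v6_notched_positive": any(morph[l]["notched_positive"]
                                      for l in ("V5", "V6")),
        # ST elevation over the negative V1/V2 complexes, depression /
        # T inversion over the positive lateral leads
        "st_discordance": (any(_st_discordance(rec, l, i0, i1)
                               for l in ("V1", "V2"))
                           and any(_st_discordance(rec, l, i0, i1)
                                   for l in ("V5", "V6"))),
    }
    return CriteriaReport(
        name="complete_lbbb", verdict=all(checks.values()), checks=checks,
        measurements={"qrs_ms": report.qrs_ms,
                      "morphology": morph})


def check_rbbb(rec: ECGRecording,
               report: IntervalReport | None = None) -> CriteriaReport:
    """Complete-RBBB criteria: broad QRS, dominant positive R complex in
    V1/V2 (monophasic R or the classic rsR'/M pattern), slurred (broad)
    S in I/aVL."""
    report, i0, i1 = _qrs_window(rec, report)
    dt = float(rec.times[1] - rec.times[0])
    morph = {l: _lead_morphology(rec.leads[l][i0:i1], dt)
             for l in ("V1", "V2", "I", "aVL")}
    checks = {
        "qrs_gt_120": report.qrs_ms > 120.0,
        "v1_v2_positive_r": all(morph[l]["positive_major"]
                                for l in ("V1", "V2")),
        "v1_v2_monophasic_r": all(morph[l]["monophasic_r"] and
                                  morph[l]["dominant_sign"] > 0
                                  for l in ("V1", "V2")),
        "i_avl_s_wave": any(morph[l]["s_mv"] < -0.025 for l in ("I", "aVL")),
    }
    verdict = (checks["qrs_gt_120"] and checks["v1_v2_positive_r"]
               and checks["i_avl_s_wave"])
    return CriteriaReport(
        name="complete_rbbb", verdict=verdict, checks=checks,
        measurements={"qrs_ms": report.qrs_ms, "morphology": morph})
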