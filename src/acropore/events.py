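"""Event detection and kinetic quantification from two-channel traces.

Detects, per cell: the acrosomal Ca2+ rise (ACR) in the green channel, any
prespike-foot (PSF)-like transient preceding it, and membrane fusion (MF)
as sustained loss of the red channel; and measures the kinetic parameters
reported for each (onset, peak time, rise duration, amplitude, slope; foot
duration/amplitude; red-loss onset, duration, fractional loss, decay
slope, and the ACR-to-MF delay).

Traces are first normalized to dF = F - F0 with F0 the mean over a
pre-stimulus baseline window; onsets use a sustained-threshold rule (at
least ``m_frames`` consecutive frames beyond ``k_sigma`` baseline SDs).
All event times are reported in seconds after stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import DetectionParams
from .simulate import CellTrace

__all__ = [
    "NormalizedTrace",
    "ACREvent",
    "PSFEvent",
    "MFEvent",
    "EventSet",
    "CellOutcome",
    "normalize",
    "detect_acr",
    "classify_speed",
    "detect_psf",
    "detect_mf",
    "classify_cell",
    "analyze_trace",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class NormalizedTrace:
    t_s: np.ndarray
    dF_green: np.ndarray
    dF_red: np.ndarray
    F0_green: float
    F0_red: float
    baseline_sd_green: float
    baseline_sd_red: float
    stim_time_s: float
    frame_rate_hz: float

    @property
    def stim_idx(self) -> int:
        return int(np.searchsorted(self.t_s, self.stim_time_s))


@dataclass
class ACREvent:
    onset_s: float            # after stimulus
    peak_s: float
    rise_duration_s: float
    amplitude_dF: float
    slope_dF_per_s: float
    speed_class: Optional[str] = None     # fast | slow
    peak_truncated: bool = False          # peak not reached within recording
    onset_idx: int = 0
    peak_idx: int = 0


@dataclass
class PSFEvent:
    psf_onset_s: float
    duration_s: float         # initial rise -> start of the main Ca2+ rise
    amplitude_dF: float       # baseline -> level where the foot ends
    slope_dF_per_s: float
    main_onset_idx: int = 0   # frame where the main rise begins


@dataclass
class MFEvent:
    mf_onset_s: float
    duration_s: float         # onset -> minimum intensity
    dF_over_F0: float
    decay_slope_dF_per_s: float
    acr_mf_delay_s: Optional[float] = None
    onset_idx: int = 0
    min_idx: int = 0


@dataclass
class EventSet:
    acr: Optional[ACREvent] = None
    psf: list[PSFEvent] = field(default_factory=list)
    mf: Optional[MFEvent] = None


@dataclass
class CellOutcome:
    cell_id: str
    condition: str
    acr_positive: bool
    mf_positive: bool
    psf_count: int
    ca_independent_mf: bool
    events: EventSet


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def normalize(trace: CellTrace,
              baseline_window_s: float | None = None) -> NormalizedTrace:
    """dF = F - F0, with F0 the mean over the pre-stimulus baseline window.

    The window runs from t = 0 to ``baseline_window_s`` (default: the
    stimulus time) and must lie entirely before the stimulus and inside the
    recording.
    """
    t = np.asarray(trace.t_s, dtype=float)
    window = trace.stim_time_s if baseline_window_s is None else baseline_window_s
    if window <= 0 or window > trace.stim_time_s + 1e-9:
        raise ValueError(
            f"baseline window ({window} s) must lie within (0, stimulus "
            f"time = {trace.stim_time_s} s]")
    if window > t[-1]:
        raise ValueError("baseline window extends beyond the recording")
    sel = t < window
    if sel.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 frames")
    g = np.asarray(trace.f_green_au, dtype=float)
    r = np.asarray(trace.f_red_au, dtype=float)
    F0_g, F0_r = float(g[sel].mean()), float(r[sel].mean())
    if F0_g <= 0 or F0_r <= 0:
        raise ValueError("non-positive baseline fluorescence (F0 <= 0)")
    return NormalizedTrace(
        t_s=t, dF_green=g - F0_g, dF_red=r - F0_r, F0_green=F0_g,
        F0_red=F0_r,
        baseline_sd_green=float(g[sel].std(ddof=1)),
        baseline_sd_red=float(r[sel].std(ddof=1)),
        stim_time_s=trace.stim_time_s, frame_rate_hz=trace.frame_rate_hz)


# --------------------------------------------------------------------------
# Onset rule
# --------------------------------------------------------------------------

def first_sustained_crossing(above: np.ndarray, m_frames: int,
                             start: int = 0) -> Optional[int]:
    """First index >= start beginning a run of >= m_frames True values."""
    a = np.asarray(above[start:], dtype=bool)
    if len(a) < m_frames:
        return None
    if m_frames == 1:
        hits = np.flatnonzero(a)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(a, m_frames)
        hits = np.flatnonzero(windows.all(axis=1))
    if len(hits) == 0:
        return None
    return start + int(hits[0])


def _lsq_slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2:
        return 0.0
    tc = t - t.mean()
    denom = float(tc @ tc)
    return float(tc @ (y - y.mean()) / denom) if denom else 0.0


def _smooth(y: np.ndarray, w: int = 5) -> np.ndarray:
    if w <= 1 or len(y) < w:
        return y
    kernel = np.ones(w) / w
    pad = np.concatenate([np.full(w // 2, y[0]), y, np.full(w // 2, y[-1])])
    return np.convolve(pad, kernel, mode="valid")[: len(y)]


# --------------------------------------------------------------------------
# ACR detection
# --------------------------------------------------------------------------

def _red_loss_complete_idx(norm: NormalizedTrace, det: DetectionParams) -> int:
    """Frame by which red loss (if any) is complete; end of trace otherwise.

    Used to stop the green-peak search before the sensor has left the
    compartment.
    """
    n = len(norm.t_s)
    thr = -det.k_sigma * max(norm.baseline_sd_red, 1e-12)
    red_sm = _smooth(norm.dF_red)
    onset = first_sustained_crossing(red_sm < thr, det.m_frames,
                                     start=norm.stim_idx)
    if onset is None:
        return n - 1
    min_val = red_sm[onset:].min()
    loss = -min_val
    if loss < 0.5 * norm.F0_red:
        return n - 1
    done = np.flatnonzero(red_sm[onset:] <= -det.mf_complete_frac * loss)
    return onset + int(done[0]) if len(done) else n - 1


def detect_acr(norm: NormalizedTrace, k_sigma: float = 3.0,
               m_frames: int = 3,
               det: DetectionParams | None = None) -> Optional[ACREvent]:
    """Detect the major green-channel rise.

    Onset: first post-stimulus frame opening a run of >= ``m_frames``
    frames with dF_green > ``k_sigma`` x baseline SD. Peak: argmax of
    dF_green up to red-loss completion. Slope: least-squares fit from onset
    to the frame first reaching ``slope_upper_frac`` of the amplitude.
    Returns None when no sustained crossing exists.
    """
    det = det or DetectionParams(k_sigma=k_sigma, m_frames=m_frames)
    thr = det.k_sigma * max(norm.baseline_sd_green, 1e-12)
    onset_idx = first_sustained_crossing(norm.dF_green > thr, det.m_frames,
                                         start=norm.stim_idx)
    if onset_idx is None:
        return None
    end = max(_red_loss_complete_idx(norm, det), onset_idx + 1)
    return _measure_acr(norm, onset_idx, end, det)


def _measure_acr(norm: NormalizedTrace, onset_idx: int, end: int,
                 det: DetectionParams) -> ACREvent:
    t = norm.t_s
    dF = norm.dF_green
    # peak and amplitude from a lightly smoothed copy: the raw argmax of a
    # noisy plateau systematically overstates the amplitude, which would
    # also stretch the slope window past the rise
    dF_sm = _smooth(dF, 3)
    peak_idx = onset_idx + int(np.argmax(dF_sm[onset_idx:end + 1]))
    amp = float(dF_sm[peak_idx])
    lvl = det.slope_upper_frac * amp
    # crossing on the raw trace: smoothing delays a short rise by a frame,
    # which would fold plateau frames into the slope window
    rel = np.flatnonzero(dF[onset_idx:peak_idx + 1] >= lvl)
    i80 = onset_idx + (int(rel[0]) if len(rel) else 1)
    i80 = max(i80, onset_idx + 1)
    slope = _lsq_slope(t[onset_idx:i80 + 1], dF[onset_idx:i80 + 1])
    truncated = peak_idx >= len(t) - 2
    return ACREvent(
        onset_s=float(t[onset_idx] - norm.stim_time_s),
        peak_s=float(t[peak_idx] - norm.stim_time_s),
        rise_duration_s=float(t[peak_idx] - t[onset_idx]),
        amplitude_dF=amp, slope_dF_per_s=slope,
        peak_truncated=truncated, onset_idx=onset_idx, peak_idx=peak_idx)


def classify_speed(event: ACREvent,
                   slow_min_rise_s: float = 120.0) -> str:
    """Fast vs slow responder: slow iff the rise lasts at least
    ``slow_min_rise_s`` or never peaks within the recording."""
    if event.peak_truncated or event.rise_duration_s >= slow_min_rise_s:
        return "slow"
    return "fast"


# --------------------------------------------------------------------------
# PSF detection
# --------------------------------------------------------------------------

class _SegmentCost:
    """O(1) least-squares line SSE/slope on [i, j) via prefix sums."""

    def __init__(self, t: np.ndarray, y: np.ndarray) -> None:
        z = np.zeros(1)
        self.n = np.concatenate([z, np.cumsum(np.ones_like(t))])
        self.st = np.concatenate([z, np.cumsum(t)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.stt = np.concatenate([z, np.cumsum(t * t)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])
        self.sty = np.concatenate([z, np.cumsum(t * y)])

    def sse_slope(self, i: int, j: int) -> tuple[float, float]:
        n = self.n[j] - self.n[i]
        if n < 2:
            return 0.0, 0.0
        st = self.st[j] - self.st[i]
        sy = self.sy[j] - self.sy[i]
        ctt = (self.stt[j] - self.stt[i]) - st * st / n
        cyy = (self.syy[j] - self.syy[i]) - sy * sy / n
        cty = (self.sty[j] - self.sty[i]) - st * sy / n
        if ctt <= 0:
            return max(float(cyy), 0.0), 0.0
        return max(float(cyy - cty * cty / ctt), 0.0), float(cty / ctt)

    def sse(self, i: int, j: int) -> float:
        return self.sse_slope(i, j)[0]


def detect_psf(norm: NormalizedTrace, acr: ACREvent,
               max_amp_ratio: float = 0.25, max_slope_ratio: float = 0.5,
               det: DetectionParams | None = None) -> list[PSFEvent]:
    """Detect a prespike-foot-like transient preceding the major rise.

    A pre-ACR segment qualifies when (i) its shelf amplitude is at most
    ``max_amp_ratio`` of the ACR amplitude, (ii) its overall slope is at
    most ``max_slope_ratio`` of the main-rise slope, and (iii) the rise
    profile is biphasic: a two-changepoint piecewise-linear fit (foot rise
    / shelf / main rise) must reduce the residual of the best
    single-changepoint fit by at least ``biphasic_factor``.
    """
    det = det or DetectionParams(max_amp_ratio=max_amp_ratio,
                                 max_slope_ratio=max_slope_ratio)
    t, dF = norm.t_s, norm.dF_green
    lvl = det.slope_upper_frac * acr.amplitude_dF
    rel = np.flatnonzero(dF[acr.onset_idx:acr.peak_idx + 1] >= lvl)
    i80 = acr.onset_idx + (int(rel[0]) if len(rel) else 1)
    # the changepoint window ends halfway up the main rise: enough to pin
    # the hand-over slope without letting main-rise curvature dominate
    rel50 = np.flatnonzero(
        dF[acr.onset_idx:acr.peak_idx + 1] >= 0.5 * acr.amplitude_dF)
    i50 = acr.onset_idx + (int(rel50[0]) if len(rel50) else 1)
    i50 = min(max(i50, acr.onset_idx + 2), i80)
    # the sustained k-sigma crossing lands partway up a slow foot; walk back
    # to the departure from baseline (three consecutive sub-sigma frames) so
    # the foot's own rise phase is inside the changepoint window
    sd = max(norm.baseline_sd_green, 1e-12)
    lo = acr.onset_idx
    while lo > norm.stim_idx:
        back = dF[max(lo - 3, 0):lo]
        if len(back) and (back < sd).all():
            break
        lo -= 1
    n_full = i50 - lo + 1
    min_len = 3
    if n_full < 3 * min_len + 2:
        return []
    # changepoint search on at most ~120 support points (coarsened for very
    # long windows), on a lightly smoothed copy so the test reflects the
    # shelf structure rather than frame noise
    step = max(1, n_full // 120)
    idx = np.arange(lo, i50 + 1, step)
    if idx[-1] != i50:
        idx = np.append(idx, i50)
    dF_sm = _smooth(dF[lo:i50 + 1], 3)
    ts, ys = t[idx], dF_sm[idx - lo]
    n = len(ts)
    if n < 3 * min_len + 2:
        return []
    cost = _SegmentCost(ts, ys)

    best1 = min(cost.sse(0, c) + cost.sse(c, n)
                for c in range(min_len, n - min_len + 1))
    # best admissible biphasic partition: foot rise / flat shelf / main rise
    best2, best_c = np.inf, None
    for c1 in range(min_len, n - 2 * min_len + 1):
        sse_a, s1 = cost.sse_slope(0, c1)
        if s1 <= 0 or sse_a >= best2:
            continue
        for c2 in range(c1 + min_len, n - min_len + 1):
            sse_m, s2 = cost.sse_slope(c1, c2)
            sse_b, s3 = cost.sse_slope(c2, n)
            if s3 <= 0 or abs(s2) > 0.25 * s3:
                continue
            sse = sse_a + sse_m + sse_b
            if sse < best2:
                best2, best_c = sse, (c1, c2)
    if best_c is None:
        return []
    if best1 / max(best2, 1e-12) < det.biphasic_factor:
        return []

    c1, c2 = best_c
    shelf_level = float(np.median(ys[max(c2 - min_len, c1):c2]))
    if shelf_level <= 0:
        return []
    if float(ts[c2] - ts[c1]) < 1.0:           # a real shelf has extent
        return []
    if shelf_level > det.max_amp_ratio * acr.amplitude_dF:
        return []
    foot_duration = float(ts[c2] - ts[0])
    if foot_duration <= 0:
        return []
    foot_slope = shelf_level / foot_duration
    main_idx = int(idx[c2])
    main_slope = _main_rise_slope(norm, main_idx, i80, det)
    if main_slope > 0 and foot_slope > det.max_slope_ratio * main_slope:
        return []
    return [PSFEvent(
        psf_onset_s=float(ts[0] - norm.stim_time_s),
        duration_s=foot_duration, amplitude_dF=shelf_level,
        slope_dF_per_s=foot_slope, main_onset_idx=main_idx)]


def _main_rise_slope(norm: NormalizedTrace, start: int, i80: int,
                     det: DetectionParams) -> float:
    i80 = max(i80, start + 1)
    return _lsq_slope(norm.t_s[start:i80 + 1], norm.dF_green[start:i80 + 1])


# --------------------------------------------------------------------------
# MF detection
# --------------------------------------------------------------------------

def detect_mf(norm: NormalizedTrace, loss_fraction_min: float = 0.8,
              det: DetectionParams | None = None) -> Optional[MFEvent]:
    """Detect membrane fusion as sustained loss of the red channel.

    MF-positive iff the red channel loses at least ``loss_fraction_min`` of
    its baseline F0. Onset: first frame of a sustained decrease below
    -k_sigma x baseline SD. Duration: onset to the frame where the (lightly
    smoothed) loss first reaches ``mf_complete_frac`` of its final extent —
    the operational reading of "until minimum intensity" under noise.
    """
    det = det or DetectionParams(loss_fraction_min=loss_fraction_min)
    t = norm.t_s
    thr = -det.k_sigma * max(norm.baseline_sd_red, 1e-12)
    onset_idx = first_sustained_crossing(norm.dF_red < thr, det.m_frames,
                                         start=norm.stim_idx)
    if onset_idx is None:
        return None
    red_sm = _smooth(norm.dF_red)
    min_rel = int(np.argmin(red_sm[onset_idx:]))
    raw_min = float(red_sm[onset_idx + min_rel])
    # robust floor: median of all frames near the minimum, so the loss
    # estimate is not inflated by the deepest noise dip on the floor
    near = red_sm[onset_idx:][
        red_sm[onset_idx:] <= raw_min + 2.0 * norm.baseline_sd_red]
    loss = -float(np.median(near))
    if loss < det.loss_fraction_min * norm.F0_red:
        return None
    done = np.flatnonzero(
        red_sm[onset_idx:] <= -det.mf_complete_frac * loss)
    min_idx = onset_idx + (int(done[0]) if len(done) else min_rel)
    min_idx = max(min_idx, onset_idx + 1)
    slope = _lsq_slope(t[onset_idx:min_idx + 1],
                       norm.dF_red[onset_idx:min_idx + 1])
    return MFEvent(
        mf_onset_s=float(t[onset_idx] - norm.stim_time_s),
        duration_s=float(t[min_idx] - t[onset_idx]),
        dF_over_F0=min(loss / norm.F0_red, 1.0),
        decay_slope_dF_per_s=slope,
        onset_idx=onset_idx, min_idx=min_idx)


# --------------------------------------------------------------------------
# Per-cell pipeline
# --------------------------------------------------------------------------

def classify_cell(cell_id: str, condition: str, acr: Optional[ACREvent],
                  psf: list[PSFEvent], mf: Optional[MFEvent]) -> CellOutcome:
    """Combine per-channel detections into the cell's outcome flags.

    MF without ACR is permitted but flagged as Ca2+-independent (the
    chelated-Ca2+ phenotype).
    """
    return CellOutcome(
        cell_id=cell_id, condition=condition,
        acr_positive=acr is not None, mf_positive=mf is not None,
        psf_count=len(psf),
        ca_independent_mf=(mf is not None and acr is None),
        events=EventSet(acr=acr, psf=psf, mf=mf))


def analyze_trace(trace: CellTrace,
                  det: DetectionParams | None = None) -> CellOutcome:
    """Full single-cell analysis: normalize, detect ACR / PSF / MF, refine
    the ACR onset past any foot, truncate the rise at red-loss onset, and
    classify responder speed."""
    det = det or DetectionParams()
    norm = normalize(trace, det.baseline_window_s)
    acr = detect_acr(norm, det=det)
    mf = detect_mf(norm, det=det)
    psf: list[PSFEvent] = []
    if acr is not None:
        psf = detect_psf(norm, acr, det=det)
        if psf:
            # the first sustained crossing was the foot; the ACR proper
            # starts where the foot hands over to the main rise
            end = max(_red_loss_complete_idx(norm, det),
                      psf[0].main_onset_idx + 1)
            acr = _measure_acr(norm, psf[0].main_onset_idx, end, det)
        if mf is not None:
            mf.acr_mf_delay_s = mf.mf_onset_s - acr.onset_s
            if mf.mf_onset_s < acr.peak_s:
                # rise cut short by the onset of exocytosis
                acr.rise_duration_s = max(mf.mf_onset_s - acr.onset_s,
                                          1.0 / norm.frame_rate_hz)
        acr.speed_class = classify_speed(acr, det.slow_min_rise_s)
    return classify_cell(trace.cell_id, trace.condition, acr, psf, mf)
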