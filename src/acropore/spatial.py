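"""Spatial initiation sites and propagation patterns from head movies.

The apical acrosome is parameterized by a rostro-caudal axis coordinate
s in [0, 1]: s = 0 at the subacrosomal ring ("bottom"), s = 1 at the
perforatorium tip ("top"). Pixel traces are pooled into axis bins, each
bin's onset is found with the same sustained-threshold rule used for
whole-cell traces (sign-flipped for red loss), and the resulting onset
profile is classified into the propagation taxonomy:

* green / ACR: diffuse (D), top-to-bottom (T>B), center-outward (C>TB),
  bottom-to-top (B>T);
* red / MF: diffuse (D), top-to-bottom (T>B), both-ends-to-center (TB>C),
  bottom-to-top (B>T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .config import DetectionParams
from .events import first_sustained_crossing, _lsq_slope
from .simulate import HeadMovie

__all__ = [
    "OnsetProfile",
    "PatternCall",
    "segment_head",
    "compute_onset_profile",
    "classify_pattern",
    "same_initiation",
    "analyze_movie",
]


@dataclass
class OnsetProfile:
    bin_centers_s01: np.ndarray
    onset_s: np.ndarray            # absolute seconds; NaN = never crossed
    initial_slope: np.ndarray      # |dF| rate just after onset, for ties
    stim_time_s: float
    frame_period_s: float

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.onset_s).sum())


@dataclass
class PatternCall:
    channel: str                   # "ACR" | "MF"
    label: Optional[str]           # None = unclassifiable (abstained)
    init_site_s01: float           # NaN for diffuse / abstained
    init_region: Optional[str]     # bottom | center | top | diffuse

    @property
    def unclassifiable(self) -> bool:
        return self.label is None


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def segment_head(movie: HeadMovie) -> tuple[np.ndarray, np.ndarray]:
    """Head mask and axis coordinate from the baseline red channel.

    The acrosome is intact (red bright) before the stimulus, so the mask is
    the largest connected component above an Otsu threshold of the mean
    baseline red image. The axis is the principal axis of the mask,
    oriented so the sharper (narrower) end — the perforatorium tip — maps
    to s = 1.
    """
    base_sel = movie.frame_times_s < movie.stim_time_s
    if not base_sel.any():
        raise ValueError("no pre-stimulus frames to segment on")
    img = movie.red_stack[base_sel].mean(axis=0)
    if float(img.std()) < 1e-6:
        raise ValueError("blank baseline image; cannot segment head")
    thr = filters.threshold_otsu(img)
    binary = img > thr
    if not binary.any() or binary.all():
        raise ValueError("segmentation produced an empty or full mask")
    labels = measure.label(binary)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if mask.sum() < 30:
        raise ValueError("head mask too small; segmentation failed")

    yx = np.argwhere(mask).astype(float)
    centered = yx - yx.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    proj = centered @ major
    s = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
    # orient: the perforatorium end is the locally thinner arm; local
    # thickness = distance to the mask edge, robust to how an arc-shaped
    # head projects onto its principal axis
    edt = ndimage.distance_transform_edt(mask)[mask]
    thick_low = edt[s < 0.25].max() if (s < 0.25).any() else 0.0
    thick_high = edt[s > 0.75].max() if (s > 0.75).any() else 0.0
    if thick_high > thick_low:
        s = 1.0 - s
    axis_s = np.full(mask.shape, np.nan)
    axis_s[mask] = s
    return mask, axis_s


# --------------------------------------------------------------------------
# Onset profiles
# --------------------------------------------------------------------------

def compute_onset_profile(stack: np.ndarray, mask: np.ndarray,
                          axis_s: np.ndarray, frame_times_s: np.ndarray,
                          stim_time_s: float, direction: str = "rise",
                          det: DetectionParams | None = None) -> OnsetProfile:
    """Per-axis-bin onset times for a signal rise or loss.

    Pixels are grouped into ``det.n_axis_bins`` bins along s; each bin's
    mean trace is normalized against the pre-stimulus baseline and its
    onset found by the k_sigma / m_frames sustained rule (negated for
    ``direction='loss'``).
    """
    if direction not in ("rise", "loss"):
        raise ValueError("direction must be 'rise' or 'loss'")
    det = det or DetectionParams()
    nb = det.n_axis_bins
    s_pix = axis_s[mask]
    traces = stack[:, mask].astype(float)          # (T, P)
    bin_idx = np.clip((s_pix * nb).astype(int), 0, nb - 1)
    t = np.asarray(frame_times_s, dtype=float)
    base_sel = t < stim_time_s
    stim_idx = int(np.searchsorted(t, stim_time_s))
    frame_period = float(np.median(np.diff(t)))

    centers = (np.arange(nb) + 0.5) / nb
    onset = np.full(nb, np.nan)
    slope0 = np.zeros(nb)
    bin_dF: list[np.ndarray | None] = [None] * nb
    bin_sd = np.full(nb, np.nan)
    for b in range(nb):
        sel = bin_idx == b
        if sel.sum() == 0:
            continue
        y = traces[:, sel].mean(axis=1)
        f0 = float(y[base_sel].mean())
        bin_sd[b] = float(y[base_sel].std(ddof=1))
        dF = y - f0
        bin_dF[b] = -dF if direction == "loss" else dF
    # bins share the same per-pixel noise statistics; a pooled SD keeps the
    # threshold stable where a short baseline under-estimates one bin's SD
    pooled_sd = max(float(np.nanmedian(bin_sd)), 1e-12)
    for b in range(nb):
        dF = bin_dF[b]
        if dF is None:
            continue
        i = first_sustained_crossing(dF > det.k_sigma * pooled_sd,
                                     det.m_frames, start=stim_idx)
        if i is None:
            continue
        onset[b] = t[i]
        j = min(i + 4, len(t) - 1)
        slope0[b] = _lsq_slope(t[i:j + 1], dF[i:j + 1])
    return OnsetProfile(bin_centers_s01=centers, onset_s=onset,
                        initial_slope=slope0, stim_time_s=stim_time_s,
                        frame_period_s=frame_period)


# --------------------------------------------------------------------------
# Pattern classification
# --------------------------------------------------------------------------

def _region_of(s: float) -> str:
    if s < 1.0 / 3.0:
        return "bottom"
    if s <= 2.0 / 3.0:
        return "center"
    return "top"


def classify_pattern(profile: OnsetProfile, channel: str,
                     spread_max_s: float | None = None,
                     det: DetectionParams | None = None) -> PatternCall:
    """Classify a bin-onset profile into the channel's pattern taxonomy.

    Diffuse iff the onset spread is at most ``spread_max_s`` (default 1.5
    frame periods). Otherwise the initiation bin is the earliest-onset bin
    (ties broken toward the steepest initial slope) and the label follows
    the profile shape: center-initiated green events propagating both ways
    are C>TB; red loss starting early at both ends with the latest onsets
    centrally is TB>C; otherwise the label is directional from the
    initiation region. Fewer than 3 measurable bins -> abstain.
    """
    if channel not in ("ACR", "MF"):
        raise ValueError("channel must be 'ACR' or 'MF'")
    det = det or DetectionParams()
    if spread_max_s is None:
        spread_max_s = det.spread_max_frames * profile.frame_period_s
    onset = profile.onset_s
    valid = np.isfinite(onset)
    if valid.sum() < 3:
        return PatternCall(channel=channel, label=None,
                           init_site_s01=float("nan"), init_region=None)
    ov = onset[valid]
    centers = profile.bin_centers_s01[valid]
    spread = float(ov.max() - ov.min())
    if spread <= spread_max_s:
        return PatternCall(channel=channel, label="D",
                           init_site_s01=float("nan"), init_region="diffuse")

    tol = profile.frame_period_s * 0.75
    is_min = ov <= ov.min() + tol
    cand = np.flatnonzero(is_min)
    init_i = cand[int(np.argmax(profile.initial_slope[valid][cand]))]
    init_site = float(centers[init_i])
    region = _region_of(init_site)

    ends_early = (ov[0] <= ov.min() + max(tol, 0.35 * spread)
                  and ov[-1] <= ov.min() + max(tol, 0.35 * spread))
    latest_center = 1.0 / 3.0 < centers[int(np.argmax(ov))] <= 2.0 / 3.0
    if channel == "MF" and ends_early and latest_center:
        return PatternCall(channel=channel, label="TB>C",
                           init_site_s01=init_site, init_region=region)
    if channel == "ACR" and region == "center":
        return PatternCall(channel=channel, label="C>TB",
                           init_site_s01=init_site, init_region=region)
    if region == "center":
        # MF taxonomy has no center-initiated label; fall back to the
        # direction the front predominantly travels
        trend = _lsq_slope(centers, ov)
        label = "B>T" if trend > 0 else "T>B"
        return PatternCall(channel=channel, label=label,
                           init_site_s01=init_site, init_region=region)
    label = "B>T" if region == "bottom" else "T>B"
    return PatternCall(channel=channel, label=label,
                       init_site_s01=init_site, init_region=region)


def same_initiation(acr_call: PatternCall,
                    mf_call: PatternCall) -> Optional[bool]:
    """Do ACR and MF initiate at the same location? Diffuse matches
    diffuse; abstained calls yield None (excluded from denominators)."""
    if acr_call.unclassifiable or mf_call.unclassifiable:
        return None
    return acr_call.init_region == mf_call.init_region


def analyze_movie(movie: HeadMovie, det: DetectionParams | None = None,
                  ) -> tuple[PatternCall, PatternCall]:
    """Segment the head, build both channels' onset profiles and classify
    their propagation patterns."""
    det = det or DetectionParams()
    mask, axis_s = segment_head(movie)
    prof_g = compute_onset_profile(movie.green_stack, mask, axis_s,
                                   movie.frame_times_s, movie.stim_time_s,
                                   "rise", det)
    prof_r = compute_onset_profile(movie.red_stack, mask, axis_s,
                                   movie.frame_times_s, movie.stim_time_s,
                                   "loss", det)
    acr_call = classify_pattern(prof_g, "ACR", det=det)
    mf_call = classify_pattern(prof_r, "MF", det=det)
    return acr_call, mf_call
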