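"""Synthetic two-channel fluorescence data with known ground truth.

The generative model is a fusion-pore account of acrosome exocytosis:
small fusion pores between the plasma membrane and the outer acrosomal
membrane admit extracellular Ca2+ into the acrosomal lumen, raising the
green (Ca2+-sensor) fluorescence (ACR); as pores accumulate and coalesce
into full membrane fusion (MF), the ~75 kDa sensor protein escapes and the
red (Ca2+-insensitive) fluorescence decays toward a floor, dragging the
green signal back down with it (the sensor leaves the compartment).

Calcium follows

    d[Ca]/dt = n_pores(t) * pore_flux * (ca_ext - ca) / ca_ext
               - ca_clear_rate * (ca - ca_rest)

and the green channel reads

    F_green(t) = baseline + sensor_fraction(t) * dFmax * H(ca(t)) + noise

with H the Hill saturation of the sensor and sensor_fraction(t) the
remaining red fraction. Two modes expose the same law:

* mechanistic — pores are born as a Poisson process and the piecewise
  linear ODE is integrated exactly between birth events; MF fires when the
  pore count reaches ``n_crit_pores``.
* calibrated — a pore schedule is constructed so that the noise-free trace
  realizes prescribed event kinetics (onset, amplitude, slope, rise
  duration, foot shelf, red-loss timing). Cohort presets use this mode so
  that ground truth matches the configured population statistics.

All event times in ground truth are seconds after stimulus onset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .config import (
    AcquisitionConfig,
    CaSensorModel,
    ConditionPreset,
    MFParams,
    PRESETS,
    PSFParams,
    SLOW_MF_TIME_MEAN_S,
    SLOW_MF_TIME_SD_S,
    SLOW_RISE_MEAN_S,
    SLOW_RISE_SD_S,
    SimCellParams,
    SpatialParams,
)

__all__ = [
    "CellTrace",
    "GroundTruth",
    "HeadMovie",
    "constant_pore_solution",
    "simulate_cell",
    "simulate_cohort",
    "simulate_movie",
    "simulate_movie_cohort",
    "draw_lognormal",
    "draw_truncated_lognormal",
    "draw_truncated_normal",
]

# Green-signal rate of the brief "ignition" phase at pore opening (a.u./s).
# First pores open with the full transmembrane Ca2+ gradient behind them, so
# the signal leaves the baseline abruptly before settling into the
# condition-specific rise kinetics.
IGNITION_RATE_AU_S = 250.0
# Fraction of a PSF foot spent climbing to its shelf.
PSF_CLIMB_FRACTION = 0.4
# Onset threshold convention (in baseline SDs) that slope calibration and
# truth measurement emulate; matches the detection default.
ONSET_K_SIGMA = 3.0
# Foot climb slope relative to the main ACR slope (kept well below the 0.5
# dissimilarity criterion used for detection).
PSF_SLOPE_FRACTION = 0.35


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class CellTrace:
    """One cell's two-channel fluorescence time series."""

    cell_id: str
    condition: str
    t_s: np.ndarray
    f_green_au: np.ndarray
    f_red_au: np.ndarray
    frame_rate_hz: float
    stim_time_s: float


@dataclass
class GroundTruth:
    """True event parameters for one simulated cell.

    Times are seconds after stimulus. Realized values are measured on the
    noise-free frame-sampled trace (the signal actually emitted); ``drawn``
    keeps the sampled targets for reference.
    """

    cell_id: str
    condition: str
    responder_class: str                      # none | fast | slow
    acr_onset_s: Optional[float] = None
    acr_peak_s: Optional[float] = None
    rise_duration_s: Optional[float] = None
    amplitude_dF: Optional[float] = None
    slope_dF_per_s: Optional[float] = None
    psf_onset_s: Optional[float] = None
    psf_duration_s: Optional[float] = None
    psf_amplitude_dF: Optional[float] = None
    mf_onset_s: Optional[float] = None
    mf_duration_s: Optional[float] = None
    mf_dF_over_F0: Optional[float] = None
    acr_mf_delay_s: Optional[float] = None
    ca_independent_mf: bool = False
    pattern_acr: Optional[str] = None
    pattern_mf: Optional[str] = None
    init_region_acr: Optional[str] = None
    init_region_mf: Optional[str] = None
    init_site_s01: Optional[float] = None
    drawn: dict = field(default_factory=dict)

    @property
    def acr_positive(self) -> bool:
        return self.acr_onset_s is not None

    @property
    def mf_positive(self) -> bool:
        return self.mf_onset_s is not None


@dataclass
class HeadMovie:
    """Two-channel image stack of a single sperm head."""

    green_stack: np.ndarray       # (T, H, W) uint16
    red_stack: np.ndarray         # (T, H, W) uint16
    frame_times_s: np.ndarray
    stim_time_s: float
    pixel_size_um: float = 0.1


# --------------------------------------------------------------------------
# Distribution helpers
# --------------------------------------------------------------------------

def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def draw_lognormal(rng: np.random.Generator, mean: float, sd: float,
                   size: int | None = None) -> np.ndarray | float:
    """Lognormal draws parameterized by their (untruncated) mean and SD."""
    mu, sigma = _lognormal_mu_sigma(mean, sd)
    return rng.lognormal(mu, sigma, size=size)


@lru_cache(maxsize=256)
def _fit_truncated_lognormal(mean: float, sd: float,
                             upper: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so the lognormal truncated to (0, upper]
    has the requested mean and SD.

    Event statistics reported from finite recordings are necessarily
    computed from events observed inside the recording window; matching the
    truncated moments (rather than truncating a moment-matched lognormal)
    keeps the realized population mean at the configured value even when
    the spread is large relative to the window.
    """
    if mean >= upper:
        raise ValueError("truncated mean must be below the upper bound")
    log_u = np.log(upper)

    def trunc_stats(mu: float, sigma: float) -> tuple[float, float]:
        z = (log_u - mu) / sigma
        d0 = stats.norm.cdf(z)
        if d0 < 1e-300:
            return upper, 0.0
        m1 = np.exp(mu + 0.5 * sigma**2) * stats.norm.cdf(z - sigma) / d0
        m2 = np.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z - 2 * sigma) / d0
        return float(m1), float(np.sqrt(max(m2 - m1**2, 0.0)))

    def mu_for_mean(sigma: float) -> float:
        # truncated mean is monotone increasing in mu, from 0 to upper
        f = lambda mu: trunc_stats(mu, sigma)[0] - mean
        lo, hi = np.log(mean) - 30.0, log_u + 10.0 * sigma
        return float(optimize.brentq(f, lo, hi, xtol=1e-9))

    # match the mean exactly for every sigma; pick the sigma whose truncated
    # SD comes closest to the target (the mean is the property the recovery
    # checks lean on; the SD is matched as well as the family allows)
    best = (np.inf, None, None)
    for sigma in np.geomspace(0.05, 3.0, 40):
        mu = mu_for_mean(sigma)
        err = abs(trunc_stats(mu, sigma)[1] - sd)
        if err < best[0]:
            best = (err, mu, sigma)
    _, mu_c, sig_c = best
    for sigma in np.geomspace(sig_c / 1.3, sig_c * 1.3, 25):
        mu = mu_for_mean(sigma)
        err = abs(trunc_stats(mu, sigma)[1] - sd)
        if err < best[0]:
            best = (err, mu, sigma)
    return float(best[1]), float(best[2])


def draw_truncated_lognormal(rng: np.random.Generator, mean: float, sd: float,
                             upper: float, size: int) -> np.ndarray:
    """Lognormal truncated to (0, upper] whose truncated mean/SD match."""
    if sd <= 0:
        return np.full(size, min(mean, upper))
    mu, sigma = _fit_truncated_lognormal(round(mean, 6), round(sd, 6),
                                         round(upper, 6))
    # inverse-CDF sampling restricted to the window
    zmax = stats.norm.cdf((np.log(upper) - mu) / sigma)
    u = rng.uniform(0.0, zmax, size=size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


@lru_cache(maxsize=256)
def _truncnorm_loc(mean: float, sd: float, lower: float,
                   upper: float) -> float:
    """Location parameter so the [lower, upper]-truncated normal with scale
    ``sd`` has mean ``mean``."""

    def trunc_mean(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    lo, hi = mean - 6 * sd, mean + 6 * sd
    if trunc_mean(lo) > 0 or trunc_mean(hi) < 0:
        return mean
    return float(optimize.brentq(trunc_mean, lo, hi, xtol=1e-6 * max(sd, 1.0)))


def draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                          lower: float, upper: float,
                          size: int) -> np.ndarray:
    """Normal truncated to [lower, upper] with its truncated mean corrected
    back to ``mean`` (plain truncation would bias strictly-positive draws
    upward when the SD is comparable to the mean)."""
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lower, upper)))
    loc = _truncnorm_loc(round(mean, 6), round(sd, 6),
                         round(lower, 6), round(upper, 6))
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size,
                               random_state=rng)


# --------------------------------------------------------------------------
# Mechanistic calcium kinetics
# --------------------------------------------------------------------------

def constant_pore_solution(t: np.ndarray, n_pores: float, pore_flux: float,
                           sensor: CaSensorModel, ca0: float,
                           ca_clear_rate: float = 0.0) -> np.ndarray:
    """Closed-form [Ca](t) for a constant pore count.

    With J = n_pores * pore_flux the calcium law is linear,
    ca' = a - b*ca with a = J + k*ca_rest and b = J/ca_ext + k, giving
    ca(t) = a/b + (ca0 - a/b) * exp(-b t).
    """
    t = np.asarray(t, dtype=float)
    if sensor.ca_ext_uM == 0.0:
        # no gradient: influx term vanishes, only clearance acts
        if ca_clear_rate == 0.0:
            return np.full_like(t, ca0)
        return sensor.ca_rest_uM + (ca0 - sensor.ca_rest_uM) * np.exp(
            -ca_clear_rate * t)
    J = n_pores * pore_flux
    a = J + ca_clear_rate * sensor.ca_rest_uM
    b = J / sensor.ca_ext_uM + ca_clear_rate
    if b == 0.0:
        return ca0 + a * t
    ceq = a / b
    return ceq + (ca0 - ceq) * np.exp(-b * t)


def _simulate_mechanistic(params: SimCellParams, sensor: CaSensorModel,
                          acq: AcquisitionConfig,
                          rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Pore-birth Poisson process integrated piecewise-exactly.

    Returns the noise-free [Ca](t) on the frame grid and the MF onset time
    (absolute seconds; inf if the critical pore count is never reached).
    """
    t = acq.times()
    ca = np.full(acq.n_frames, sensor.ca_rest_uM)
    t_start = acq.stim_time_s + params.acr_onset_s
    if params.responder_class == "none" or t_start >= acq.duration_s:
        return ca, np.inf
    n_crit = params.mf.n_crit_pores if params.mf is not None else np.inf

    # pore birth times: first pore at ACR onset, later ones Poisson
    births = [t_start]
    t_cur = t_start
    while True:
        t_cur = t_cur + rng.exponential(1.0 / params.pore_birth_rate)
        if t_cur >= acq.duration_s or len(births) >= 10_000:
            break
        births.append(t_cur)
    t_mf = births[int(n_crit) - 1] if len(births) >= n_crit else np.inf

    # integrate exactly on each constant-pore-count interval
    edges = births + [acq.duration_s + acq.frame_period_s]
    ca_left = sensor.ca_rest_uM
    for i in range(len(births)):
        lo, hi = edges[i], edges[i + 1]
        sel = (t >= lo) & (t < hi)
        if sel.any():
            ca[sel] = constant_pore_solution(
                t[sel] - lo, i + 1, params.pore_flux_uM_per_s, sensor,
                ca_left, params.ca_clear_rate)
        ca_left = float(constant_pore_solution(
            np.array([hi - lo]), i + 1, params.pore_flux_uM_per_s, sensor,
            ca_left, params.ca_clear_rate)[0])
    return ca, t_mf


# --------------------------------------------------------------------------
# Calibrated green-rise profile
# --------------------------------------------------------------------------

def _lsq_slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2:
        return 0.0
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        return 0.0
    return float(tc @ (y - y.mean()) / denom)


def _rise_segment(tau: np.ndarray, amp: float, start_level: float,
                  lam: float, duration: float) -> np.ndarray:
    """Green dF on [0, duration]: brief ignition ramp then a saturating
    exponential pinned to reach ``amp`` exactly at ``duration``."""
    rise_total = amp - start_level
    gain = min(120.0, 0.75 * rise_total, max(0.5 * rise_total, 90.0))
    gain = max(gain, 1e-6)
    t0 = min(gain / IGNITION_RATE_AU_S, 0.45 * duration)
    g0 = start_level + IGNITION_RATE_AU_S * t0
    out = np.where(tau <= t0, start_level + IGNITION_RATE_AU_S * tau, 0.0)
    rest = tau > t0
    denom = -np.expm1(-lam * (duration - t0))
    if denom <= 0:
        frac = (tau[rest] - t0) / (duration - t0)
    else:
        frac = -np.expm1(-lam * (tau[rest] - t0)) / denom
    out[rest] = g0 + (amp - g0) * frac
    return out


def _calibrate_lambda(amp: float, start_level: float, duration: float,
                      slope_target: float, frame_period: float,
                      phase_offset: float = 0.0,
                      slope_upper_frac: float = 0.8,
                      detect_floor: float = 0.0) -> tuple[float, float]:
    """Rate constant of the main rise so that the least-squares slope,
    measured the way detection measures it — on the acquisition frame grid
    from the first frame above the starting level to the frame reaching
    ``slope_upper_frac`` of amplitude — equals the target.

    ``phase_offset`` is the delay of the first acquired frame after onset.
    Returns (lambda, realized slope); a target outside what the profile
    family can produce for this amplitude/duration yields the nearest
    achievable slope.
    """
    tau = phase_offset + frame_period * np.arange(
        max(int((duration - phase_offset) / frame_period) + 1, 4))

    def measured(lam: float) -> float:
        y = _rise_segment(np.minimum(tau, duration), amp, start_level,
                          lam, duration)
        lvl = slope_upper_frac * amp
        detectable = np.flatnonzero(
            y > start_level + max(detect_floor, 1e-9))
        i0 = int(detectable[0]) if len(detectable) else 0
        over = np.flatnonzero(y >= lvl)
        i80 = int(over[0]) if len(over) else len(y) - 1
        if i80 <= i0 + 1:
            # the rise completes within one frame of becoming detectable:
            # effectively a step, steeper than any resolvable target
            return amp / frame_period
        return _lsq_slope(tau[i0:i80 + 1], y[i0:i80 + 1])

    lo, hi = 1e-4, 60.0
    s_lo, s_hi = measured(lo), measured(hi)
    if slope_target <= s_lo:
        return lo, s_lo
    if slope_target >= s_hi:
        return hi, s_hi
    for _ in range(48):
        mid = np.sqrt(lo * hi)
        if measured(mid) < slope_target:
            lo = mid
        else:
            hi = mid
    lam = np.sqrt(lo * hi)
    return lam, measured(lam)


def _green_dF_profile(t: np.ndarray, params: SimCellParams,
                      sensor: CaSensorModel, acq: AcquisitionConfig,
                      ) -> np.ndarray:
    """Noise-free green dF (a.u. above the resting Hill level) for the
    calibrated mode, before sensor-loss scaling."""
    dF = np.zeros_like(t, dtype=float)
    if params.responder_class == "none" or sensor.ca_ext_uM == 0.0:
        return dF
    amp = float(params.amp_dF)
    dur = float(params.rise_duration_s)
    t_on = acq.stim_time_s + params.acr_onset_s

    shelf = 0.0
    if params.psf is not None:
        shelf = params.psf.psf_amp_fraction * amp
        t_psf = acq.stim_time_s + params.psf.psf_onset_s
        climb = PSF_CLIMB_FRACTION * params.psf.psf_duration_s
        sel = (t >= t_psf) & (t < t_on)
        dF[sel] = np.minimum((t[sel] - t_psf) / climb, 1.0) * shelf

    dt = acq.frame_period_s
    phase = float(np.ceil(t_on / dt - 1e-9) * dt - t_on)
    lam, _ = _calibrate_lambda(amp, shelf, dur, float(params.slope_dF_per_s),
                               frame_period=dt, phase_offset=phase,
                               detect_floor=ONSET_K_SIGMA * acq.noise_sd)
    rising = (t >= t_on) & (t <= t_on + dur)
    dF[rising] = _rise_segment(t[rising] - t_on, amp, shelf, lam, dur)

    # pores close at the end of the rise; clearance pulls Ca back toward rest
    after = t > t_on + dur
    if after.any():
        f_rest = sensor.rest_fraction
        f_peak = min(f_rest + amp / sensor.dFmax_green_au, 0.999)
        ca_peak = sensor.ca_for_fraction(f_peak)
        ca_dec = sensor.ca_rest_uM + (ca_peak - sensor.ca_rest_uM) * np.exp(
            -params.ca_clear_rate * (t[after] - t_on - dur))
        dF[after] = sensor.dFmax_green_au * (
            np.asarray(sensor.fraction_bound(ca_dec)) - f_rest)
    return dF


def _red_profile(t: np.ndarray, params: SimCellParams,
                 acq: AcquisitionConfig) -> np.ndarray:
    """Noise-free red channel: baseline until MF onset, then exponential
    decay toward the floor."""
    red = np.full_like(t, acq.baseline_red_au, dtype=float)
    if params.mf is None:
        return red
    t_mf = acq.stim_time_s + params.mf.mf_onset_s
    floor = params.mf.red_floor_fraction * acq.baseline_red_au
    sel = t >= t_mf
    red[sel] = floor + (acq.baseline_red_au - floor) * np.exp(
        -(t[sel] - t_mf) / params.mf.decay_tau_s)
    return red


# --------------------------------------------------------------------------
# Truth measurement on the noise-free trace
# --------------------------------------------------------------------------

def _measure_truth(green0: np.ndarray, red0: np.ndarray,
                   params: SimCellParams, sensor: CaSensorModel,
                   acq: AcquisitionConfig, truth: GroundTruth) -> None:
    """Fill realized kinetic parameters from the noise-free frame-sampled
    trace, using the known event times."""
    t = acq.times()
    base_green = float(np.mean(green0[t < acq.stim_time_s]))
    dF = green0 - base_green
    if truth.acr_onset_s is not None:
        i_on = int(np.searchsorted(t, acq.stim_time_s + truth.acr_onset_s))
        i_on = min(i_on, len(t) - 2)
        # slope/peak windows start at the first acquired frame on which the
        # event clears the onset threshold, matching how detection (first
        # sustained frame above k_sigma baseline SDs) measures them
        vis = np.flatnonzero(
            dF[i_on:] > max(ONSET_K_SIGMA * acq.noise_sd, 1e-9))
        if len(vis):
            i_on = min(i_on + int(vis[0]), len(t) - 2)
        # peak located via the same 3-frame running-mean convention the
        # analysis uses, so truth and detection share one peak definition;
        # the amplitude is the raw trace value at that frame
        kernel = np.ones(3) / 3.0
        dF_sm = np.convolve(np.pad(dF, 1, mode="edge"), kernel,
                            mode="valid")
        i_peak = i_on + int(np.argmax(dF_sm[i_on:]))
        amp = float(dF[i_peak])
        truth.acr_peak_s = float(t[i_peak] - acq.stim_time_s)
        truth.amplitude_dF = amp
        # rise duration: to the peak, or to red-loss onset if MF truncates it
        rise = truth.acr_peak_s - truth.acr_onset_s
        if truth.mf_onset_s is not None and truth.mf_onset_s < truth.acr_peak_s:
            rise = truth.mf_onset_s - truth.acr_onset_s
        truth.rise_duration_s = float(rise)
        lvl = 0.8 * amp
        i80 = i_on + int(np.argmax(dF[i_on:] >= lvl)) if amp > 0 else i_on
        i80 = max(i80, i_on + 1)
        truth.slope_dF_per_s = _lsq_slope(t[i_on:i80 + 1], dF[i_on:i80 + 1])
        if truth.psf_onset_s is not None:
            shelf_t = acq.stim_time_s + truth.acr_onset_s - 1e-9
            i_shelf = max(int(np.searchsorted(t, shelf_t)) - 1, 0)
            truth.psf_amplitude_dF = float(dF[i_shelf])
    if truth.mf_onset_s is not None:
        base_red = float(np.mean(red0[t < acq.stim_time_s]))
        loss = base_red - float(red0.min())
        truth.mf_dF_over_F0 = loss / base_red
        if truth.acr_onset_s is not None:
            truth.acr_mf_delay_s = truth.mf_onset_s - truth.acr_onset_s


# --------------------------------------------------------------------------
# Single-cell simulation
# --------------------------------------------------------------------------

def simulate_cell(params: SimCellParams, sensor: CaSensorModel,
                  acq: AcquisitionConfig, seed: int | np.random.SeedSequence,
                  cell_id: str = "cell0", condition: str = "custom",
                  ) -> tuple[CellTrace, GroundTruth]:
    """Simulate one cell's two-channel trace plus its ground truth.

    If ``params`` carries target kinetics (``amp_dF`` etc.) the calibrated
    profile mode is used; otherwise pores are born mechanistically at
    ``pore_birth_rate`` and MF fires at the critical pore count.
    """
    if acq.stim_time_s >= acq.duration_s:
        raise ValueError("recording too short to contain the stimulus")
    rng = np.random.default_rng(seed)
    t = acq.times()
    f_rest = sensor.rest_fraction

    mechanistic = (params.amp_dF is None
                   and params.responder_class != "none")
    if not mechanistic:
        dF = _green_dF_profile(t, params, sensor, acq)
        red0 = _red_profile(t, params, acq)
        t_mf_abs = (acq.stim_time_s + params.mf.mf_onset_s
                    if params.mf is not None else np.inf)
    else:
        ca, t_mf_abs = _simulate_mechanistic(params, sensor, acq, rng)
        dF = sensor.dFmax_green_au * (
            np.asarray(sensor.fraction_bound(ca)) - f_rest)
        mech_mf = params.mf if np.isfinite(t_mf_abs) else None
        if mech_mf is not None:
            mf_shift = dataclasses.replace(
                mech_mf, mf_onset_s=t_mf_abs - acq.stim_time_s)
            red0 = _red_profile(t, dataclasses.replace(params, mf=mf_shift), acq)
        else:
            red0 = np.full_like(t, acq.baseline_red_au)

    sensor_fraction = red0 / acq.baseline_red_au
    green0 = acq.baseline_green_au + sensor_fraction * (
        sensor.dFmax_green_au * f_rest + dF)

    truth = GroundTruth(cell_id=cell_id, condition=condition,
                        responder_class=params.responder_class)
    if params.responder_class != "none" and sensor.ca_ext_uM > 0.0:
        truth.acr_onset_s = float(params.acr_onset_s)
        if params.psf is not None:
            truth.psf_onset_s = float(params.psf.psf_onset_s)
            truth.psf_duration_s = float(params.psf.psf_duration_s)
    if params.mf is not None and np.isfinite(t_mf_abs):
        truth.mf_onset_s = float(t_mf_abs - acq.stim_time_s)
        truth.mf_duration_s = float(params.mf.mf_duration_s)
        truth.ca_independent_mf = not truth.acr_positive
    if params.spatial is not None:
        truth.pattern_acr = params.spatial.pattern_acr
        truth.pattern_mf = params.spatial.pattern_mf
        truth.init_site_s01 = params.spatial.init_site_s01
    _measure_truth(green0, red0, params, sensor, acq, truth)

    green = green0 + rng.normal(0.0, acq.noise_sd, size=len(t))
    red = red0 + rng.normal(0.0, acq.noise_sd, size=len(t))
    trace = CellTrace(cell_id=cell_id, condition=condition, t_s=t,
                      f_green_au=green, f_red_au=red,
                      frame_rate_hz=acq.frame_rate_hz,
                      stim_time_s=acq.stim_time_s)
    return trace, truth


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

def _mf_class_rates(preset: ConditionPreset) -> tuple[float, float]:
    """P(MF | fast) and P(MF | slow), preserving the published ~5:1 ratio of
    class transition rates while matching the overall transition exactly."""
    ffast = preset.frac_fast_among_responders
    target = preset.transition_fraction
    if ffast >= 1.0:
        return min(target, 1.0), 0.0
    base_fast, base_slow = 0.894, 0.18
    k = target / (ffast * base_fast + (1.0 - ffast) * base_slow)
    return min(base_fast * k, 1.0), min(base_slow * k, 1.0)


def simulate_cohort(preset: ConditionPreset | str, n_cells: int,
                    seed: int | np.random.SeedSequence,
                    acq: AcquisitionConfig | None = None,
                    sensor: CaSensorModel | None = None,
                    ) -> tuple[list[CellTrace], list[GroundTruth]]:
    """Simulate ``n_cells`` cells under one condition preset.

    Responder classes are drawn per the preset fractions; kinetic targets
    come from lognormal (times, truncated to the recording window) and
    mean-corrected truncated-normal (amplitudes, slopes) distributions; MF
    is assigned within responders as an exact-count draw weighted by the
    squared ACR slope, realizing the observed association between Ca2+-rise
    rate and fusion competence.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; valid names: {sorted(PRESETS)}")
        preset = PRESETS[preset]
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    acq = acq or AcquisitionConfig()
    sensor = sensor or CaSensorModel()
    if preset.ca_ext_uM != sensor.ca_ext_uM:
        sensor = dataclasses.replace(sensor, ca_ext_uM=preset.ca_ext_uM)

    ss = np.random.SeedSequence(
        seed if isinstance(seed, int) else seed.entropy)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cell_seeds = ss.spawn(n_cells)

    window = acq.duration_s - acq.stim_time_s
    amp_hi = 0.9 * sensor.dFmax_green_au * (1.0 - sensor.rest_fraction)

    is_resp = rng.random(n_cells) < preset.frac_acr
    resp_idx = np.flatnonzero(is_resp)
    n_resp = len(resp_idx)
    is_fast = np.zeros(n_cells, dtype=bool)
    if n_resp:
        is_fast[resp_idx] = (rng.random(n_resp)
                             < preset.frac_fast_among_responders)

    onset = np.zeros(n_cells)
    amp = np.zeros(n_cells)
    slope = np.zeros(n_cells)
    dur = np.zeros(n_cells)
    if n_resp:
        onset[resp_idx] = draw_truncated_lognormal(
            rng, preset.onset_mean_s, preset.onset_sd_s,
            upper=window - 5.0, size=n_resp)
        # events dimmer than ~6x the frame noise would not have been scored
        # as responses, so the responder amplitude distribution starts there
        amp[resp_idx] = draw_truncated_normal(
            rng, preset.amp_mean_au, preset.amp_sd_au,
            lower=120.0, upper=amp_hi, size=n_resp)
        slope[resp_idx] = draw_truncated_normal(
            rng, preset.slope_mean_au_s, preset.slope_sd_au_s,
            lower=3.0, upper=2000.0, size=n_resp)
        dur[resp_idx] = np.clip(draw_lognormal(
            rng, preset.rise_dur_mean_s, preset.rise_dur_sd_s,
            size=n_resp), 2.0, None)
        slow_idx = resp_idx[~is_fast[resp_idx]]
        if len(slow_idx):
            dur[slow_idx] = np.clip(draw_lognormal(
                rng, SLOW_RISE_MEAN_S, SLOW_RISE_SD_S, size=len(slow_idx)),
                130.0, None)
            # slow cells rise gradually: near-linear ramp
            slope[slow_idx] = 1.3 * amp[slow_idx] / dur[slow_idx]

    # --- MF assignment -----------------------------------------------------
    is_mf = np.zeros(n_cells, dtype=bool)
    # the rise must begin a resolvable interval before the red loss: the
    # m-frame sustained onset rule cannot order two events closer than a
    # few frame periods, and the study reports the ordering as universal
    delay_floor = max(1.0, 4.0 * acq.frame_period_s)
    mf_onset = np.zeros(n_cells)
    if preset.frac_acr == 0.0:
        # Ca2+-independent exocytosis (chelated extracellular Ca2+)
        n_mf = int(round(preset.frac_mf * n_cells))
        chosen = rng.choice(n_cells, size=n_mf, replace=False)
        is_mf[chosen] = True
        mf_onset[chosen] = draw_truncated_lognormal(
            rng, preset.mf_onset_mean_s, 60.0, upper=window - 20.0,
            size=n_mf)
    elif n_resp:
        rate_fast, rate_slow = _mf_class_rates(preset)
        for rate, sel in ((rate_fast, resp_idx[is_fast[resp_idx]]),
                          (rate_slow, resp_idx[~is_fast[resp_idx]])):
            m = int(round(rate * len(sel)))
            if m == 0 or len(sel) == 0:
                continue
            w = slope[sel] ** 2
            chosen = rng.choice(sel, size=m, replace=False, p=w / w.sum())
            is_mf[chosen] = True
        fast_mf = np.flatnonzero(is_mf & is_fast)
        slow_mf = np.flatnonzero(is_mf & is_resp & ~is_fast)
        if len(fast_mf):
            mf_onset[fast_mf] = onset[fast_mf] + np.maximum(
                draw_lognormal(rng, preset.mf_delay_mean_s,
                               preset.mf_delay_sd_s, size=len(fast_mf)),
                delay_floor)
        if len(slow_mf):
            mf_onset[slow_mf] = onset[slow_mf] + np.clip(draw_lognormal(
                rng, SLOW_MF_TIME_MEAN_S, SLOW_MF_TIME_SD_S,
                size=len(slow_mf)), 125.0, None)
    mf_dur = np.clip(draw_lognormal(
        rng, preset.mf_duration_mean_s, max(preset.mf_duration_sd_s, 1e-6),
        size=n_cells), 1.5, None) if preset.frac_mf > 0 else np.zeros(n_cells)
    # a fusion scheduled too late for its signal loss to appear within the
    # recording would be censored by the 8-min window; drop it and top the
    # count back up from the remaining responders (the published fractions
    # are themselves counts of fusions observed inside the window)
    unobservable = is_mf & (mf_onset + 0.7 * mf_dur > window - 2.0)
    n_dropped = int(unobservable.sum())
    is_mf[unobservable] = False
    if n_dropped and preset.frac_acr > 0:
        cand = np.flatnonzero(is_resp & is_fast & ~is_mf
                              & (onset < window - 60.0))
        if len(cand):
            m = min(n_dropped, len(cand))
            w = slope[cand] ** 2
            extra = rng.choice(cand, size=m, replace=False, p=w / w.sum())
            delays = np.maximum(draw_lognormal(
                rng, preset.mf_delay_mean_s, preset.mf_delay_sd_s,
                size=m), delay_floor)
            keep = onset[extra] + delays + 0.7 * mf_dur[extra] <= window - 2.0
            is_mf[extra[keep]] = True
            mf_onset[extra[keep]] = onset[extra[keep]] + delays[keep]

    # --- PSF assignment (fast responders only) -----------------------------
    has_psf = np.zeros(n_cells, dtype=bool)
    psf_dur = np.zeros(n_cells)
    fast_idx = np.flatnonzero(is_fast)
    if preset.psf_incidence > 0 and len(fast_idx) and n_resp:
        p_fast = min(preset.psf_incidence * n_resp / len(fast_idx), 1.0)
        has_psf[fast_idx] = rng.random(len(fast_idx)) < p_fast
        psf_sel = np.flatnonzero(has_psf)
        psf_dur[psf_sel] = np.clip(draw_lognormal(
            rng, preset.psf_dur_mean_s, preset.psf_dur_sd_s,
            size=len(psf_sel)), 4.0, None)
        # the foot must start after the stimulus
        psf_dur[psf_sel] = np.minimum(psf_dur[psf_sel],
                                      onset[psf_sel] - 2.0)
        has_psf[psf_sel[psf_dur[psf_sel] < 4.0]] = False
        # a foot is defined against a completed main rise: in footed cells
        # fusion must not cut the rise short of its shelf-to-peak span
        footed_mf = has_psf & is_mf
        if footed_mf.any():
            sel = np.flatnonzero(footed_mf)
            t95 = 1.2 * 0.8 * amp[sel] / np.maximum(slope[sel], 1.0) + 1.0
            mf_onset[sel] = np.maximum(mf_onset[sel], onset[sel] + t95)

    traces: list[CellTrace] = []
    truths: list[GroundTruth] = []
    for i in range(n_cells):
        cls = "none"
        if is_resp[i]:
            cls = "fast" if is_fast[i] else "slow"
        psf = None
        if has_psf[i]:
            psf = PSFParams(psf_onset_s=float(onset[i] - psf_dur[i]),
                            psf_duration_s=float(psf_dur[i]),
                            psf_amp_fraction=preset.psf_amp_fraction)
        mf = None
        if is_mf[i]:
            mf = MFParams(mf_onset_s=float(mf_onset[i]),
                          mf_duration_s=float(mf_dur[i]))
        params = SimCellParams(
            responder_class=cls, acr_onset_s=float(onset[i]),
            amp_dF=float(amp[i]) if cls != "none" else None,
            slope_dF_per_s=float(slope[i]) if cls != "none" else None,
            rise_duration_s=float(dur[i]) if cls != "none" else None,
            psf=psf, mf=mf)
        trace, truth = simulate_cell(
            params, sensor, acq, cell_seeds[i],
            cell_id=f"{preset.name}_{i:04d}", condition=preset.name)
        truth.drawn = {"onset_s": float(onset[i]), "amp_dF": float(amp[i]),
                       "slope_dF_per_s": float(slope[i]),
                       "rise_duration_s": float(dur[i])}
        traces.append(trace)
        truths.append(truth)
    return traces, truths


# --------------------------------------------------------------------------
# Head-movie simulation
# --------------------------------------------------------------------------

MOVIE_ACQ = AcquisitionConfig(frame_rate_hz=2.0, duration_s=90.0,
                              stim_time_s=10.0, noise_sd=20.0,
                              baseline_green_au=100.0,
                              baseline_red_au=1000.0)

# Stagger between the two fronts of an ends-to-center (TB>C) red-loss
# pattern; makes the bottom front the deterministic initiation site.
TBC_STAGGER_S = 0.5


def crescent_mask(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Crescent-shaped head mask plus the true axis coordinate s in [0, 1].

    The apical acrosome is modelled as a thick circular arc, tapered toward
    the top horn (the perforatorium tip, s = 1) so orientation is
    recoverable from the mask geometry alone.
    """
    h, w = shape
    if h < 32 or w < 32:
        raise ValueError("shape too small for a head mask (min 32x32)")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h * 0.62, w * 0.5
    r_mid, half_th = 0.32 * min(h, w), 0.085 * min(h, w)
    ang = np.arctan2(cy - yy, xx - cx)       # 0 = +x, pi/2 = up
    a_lo, a_hi = np.deg2rad(10.0), np.deg2rad(170.0)
    s = (ang - a_lo) / (a_hi - a_lo)
    # taper thickness toward the tip (s -> 1)
    thick = half_th * (1.0 - 0.65 * np.clip(s, 0.0, 1.0) ** 2)
    rr = np.hypot(yy - cy, xx - cx)
    mask = (s >= 0.0) & (s <= 1.0) & (np.abs(rr - r_mid) <= thick)
    if mask.sum() < 50:
        raise ValueError("shape too small for a head mask")
    return mask, np.where(mask, s, np.nan)


def _wavefront_onsets(s: np.ndarray, pattern: str, t0: float,
                      init_site: float, speed: float) -> np.ndarray:
    """Per-pixel absolute onset times for one channel's wavefront."""
    if pattern == "D":
        return np.full_like(s, t0)
    if pattern == "B>T":
        return t0 + np.abs(s - min(init_site, 0.15)) / speed
    if pattern == "T>B":
        return t0 + np.abs(s - max(init_site, 0.85)) / speed
    if pattern == "C>TB":
        return t0 + np.abs(s - 0.5) / speed
    if pattern == "TB>C":
        return t0 + np.minimum(s / speed, TBC_STAGGER_S + (1.0 - s) / speed)
    raise ValueError(f"unknown pattern {pattern!r}")


def _pattern_region(pattern: str) -> str:
    return {"D": "diffuse", "B>T": "bottom", "T>B": "top",
            "C>TB": "center", "TB>C": "bottom"}[pattern]


def simulate_movie(params: SimCellParams, sensor: CaSensorModel | None = None,
                   acq: AcquisitionConfig | None = None,
                   shape: tuple[int, int] = (64, 64),
                   seed: int | np.random.SeedSequence = 0,
                   cell_id: str = "movie0", condition: str = "custom",
                   ) -> tuple[HeadMovie, GroundTruth]:
    """Simulate a two-channel head movie with a propagating wavefront.

    Each in-mask pixel follows the single-cell kinetics with its onset
    shifted by the wavefront arrival time |s - s_init| / speed along the
    rostro-caudal axis coordinate s (bottom = 0, top = 1).
    """
    if params.spatial is None:
        raise ValueError("simulate_movie requires params.spatial")
    sensor = sensor or CaSensorModel()
    acq = acq or MOVIE_ACQ
    rng = np.random.default_rng(seed)
    sp = params.spatial
    mask, s_map = crescent_mask(shape)
    t = acq.times()
    s_pix = s_map[mask]

    # shared single-pixel kinetic profiles on a fine grid, shifted per pixel
    fine = np.arange(0.0, acq.duration_s + 1.0, 0.25 * acq.frame_period_s)
    ref = dataclasses.replace(params, spatial=None)
    dF_fine = _green_dF_profile(fine, ref, sensor, acq)
    t_on_green = acq.stim_time_s + params.acr_onset_s
    green_on = _wavefront_onsets(s_pix, sp.pattern_acr, t_on_green,
                                 sp.init_site_s01, sp.wavefront_speed)
    # pixel time relative to its own onset, mapped onto the reference profile
    rel = t[None, :] - (green_on[:, None] - t_on_green)
    dF_pix = np.interp(rel, fine, dF_fine, left=0.0, right=dF_fine[-1])

    f_rest = sensor.rest_fraction
    if params.mf is not None:
        t_mf0 = acq.stim_time_s + params.mf.mf_onset_s
        red_on = _wavefront_onsets(s_pix, sp.pattern_mf, t_mf0,
                                   sp.init_site_s01, sp.wavefront_speed)
        floor = params.mf.red_floor_fraction * acq.baseline_red_au
        dt_mf = np.clip(t[None, :] - red_on[:, None], 0.0, None)
        red_pix = np.where(
            t[None, :] >= red_on[:, None],
            floor + (acq.baseline_red_au - floor)
            * np.exp(-dt_mf / params.mf.decay_tau_s),
            acq.baseline_red_au)
    else:
        red_pix = np.full((len(s_pix), len(t)), acq.baseline_red_au)
    green_pix = acq.baseline_green_au + (red_pix / acq.baseline_red_au) * (
        sensor.dFmax_green_au * f_rest + dF_pix)

    bg = 30.0
    green_stack = np.full((len(t), *shape), bg, dtype=float)
    red_stack = np.full((len(t), *shape), bg, dtype=float)
    green_stack[:, mask] = green_pix.T
    red_stack[:, mask] = red_pix.T
    green_stack += rng.normal(0.0, acq.noise_sd, green_stack.shape)
    red_stack += rng.normal(0.0, acq.noise_sd, red_stack.shape)

    movie = HeadMovie(
        green_stack=np.clip(green_stack, 0, 65535).astype(np.uint16),
        red_stack=np.clip(red_stack, 0, 65535).astype(np.uint16),
        frame_times_s=t, stim_time_s=acq.stim_time_s)
    truth = GroundTruth(cell_id=cell_id, condition=condition,
                        responder_class=params.responder_class,
                        acr_onset_s=params.acr_onset_s,
                        pattern_acr=sp.pattern_acr, pattern_mf=sp.pattern_mf,
                        init_region_acr=_pattern_region(sp.pattern_acr),
                        init_region_mf=_pattern_region(sp.pattern_mf),
                        init_site_s01=sp.init_site_s01)
    if params.mf is not None:
        truth.mf_onset_s = params.mf.mf_onset_s
        truth.mf_duration_s = params.mf.mf_duration_s
    return movie, truth


_ACR_REGION_LABEL = {"bottom": "B>T", "center": "C>TB", "top": "T>B"}
_MF_REGION_LABEL = {"bottom": "B>T", "top": "T>B"}


def simulate_movie_cohort(n_movies: int, coloc_p: float,
                          seed: int | np.random.SeedSequence,
                          shape: tuple[int, int] = (64, 64),
                          acq: AcquisitionConfig | None = None,
                          ) -> tuple[list[HeadMovie], list[GroundTruth]]:
    """Movies whose ACR/MF initiation sites co-localize with probability
    ``coloc_p`` (the per-condition co-localization study condition)."""
    acq = acq or MOVIE_ACQ
    ss = np.random.SeedSequence(
        seed if isinstance(seed, int) else seed.entropy)
    rng = np.random.default_rng(ss.spawn(1)[0])
    movie_seeds = ss.spawn(n_movies)
    movies, truths = [], []
    for i in range(n_movies):
        match = rng.random() < coloc_p
        if match:
            # regions an MF pattern can share: diffuse, bottom, top
            region = rng.choice(["diffuse", "bottom", "top"])
            if region == "diffuse":
                p_acr = p_mf = "D"
            else:
                p_acr = _ACR_REGION_LABEL[region]
                p_mf = _MF_REGION_LABEL[region]
                if region == "bottom" and rng.random() < 0.5:
                    p_mf = "TB>C"   # also bottom-initiated (staggered front)
        else:
            p_acr = rng.choice(ACR_PATTERNS_ARR)
            acr_region = _pattern_region(p_acr)
            choices = [p for p in MF_PATTERNS_ARR
                       if _pattern_region(p) != acr_region]
            p_mf = rng.choice(choices)
        params = SimCellParams(
            responder_class="fast", acr_onset_s=8.0,
            amp_dF=500.0, slope_dF_per_s=120.0, rise_duration_s=20.0,
            mf=MFParams(mf_onset_s=30.0, mf_duration_s=10.0),
            spatial=SpatialParams(pattern_acr=str(p_acr), pattern_mf=str(p_mf),
                                  init_site_s01=0.0, wavefront_speed=0.08))
        movie, truth = simulate_movie(
            params, acq=acq, shape=shape, seed=movie_seeds[i],
            cell_id=f"movie_{i:03d}")
        movies.append(movie)
        truths.append(truth)
    return movies, truths


ACR_PATTERNS_ARR = np.array(["D", "T>B", "C>TB", "B>T"])
MF_PATTERNS_ARR = np.array(["D", "T>B", "TB>C", "B>T"])
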