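"""Detection unit and property tests: normalization, onset rules against a
brute-force oracle, kinetic measurement fidelity on noise-free cells, foot
detection and red-loss quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acropore.config import DetectionParams, MFParams, SimCellParams
from acropore.events import (analyze_trace, classify_speed, detect_acr,
                             detect_mf, normalize)
from acropore.simulate import CellTrace, simulate_cell, simulate_cohort
from conftest import scan_onset_bruteforce


def make_trace(green, red=None, rate=2.0, stim=30.0):
    green = np.asarray(green, dtype=float)
    red = np.full_like(green, 1000.0) if red is None else np.asarray(red, float)
    t = np.arange(len(green)) / rate
    return CellTrace(cell_id="c", condition="custom", t_s=t,
                     f_green_au=green, f_red_au=red, frame_rate_hz=rate,
                     stim_time_s=stim)


class TestNormalize:
    def test_constant_trace(self):
        tr = make_trace(np.full(200, 5.0))
        norm = normalize(tr)
        assert norm.F0_green == 5.0
        assert np.allclose(norm.dF_green, 0.0)

    def test_nonpositive_baseline_rejected(self):
        tr = make_trace(np.full(200, -1.0))
        with pytest.raises(ValueError, match="F0"):
            normalize(tr)

    def test_window_outside_recording_rejected(self):
        tr = make_trace(np.full(200, 5.0))
        with pytest.raises(ValueError):
            normalize(tr, baseline_window_s=50.0)   # extends past stimulus

    def test_truth_peak_equals_truth_amplitude(self, sensor, acq_quiet,
                                               fast_cell_params):
        """On a noise-free simulated cell, dF at the true peak frame equals
        the true amplitude exactly."""
        tr, truth = simulate_cell(fast_cell_params, sensor, acq_quiet, seed=0)
        norm = normalize(tr)
        i_peak = int(np.searchsorted(
            norm.t_s, truth.acr_peak_s + acq_quiet.stim_time_s))
        assert norm.dF_green[i_peak] == pytest.approx(truth.amplitude_dF,
                                                      rel=1e-9)

    @given(shift=st.floats(1.0, 500.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additive_shift_leaves_dF_parameters(self, shift):
        """Adding a positive constant changes F0 but no dF-based result."""
        rng = np.random.default_rng(3)
        g = 100 + rng.normal(0, 5, 300)
        g[120:] += np.linspace(0, 300, 180)
        a = analyze_trace(make_trace(g))
        b = analyze_trace(make_trace(g + shift))
        assert (a.events.acr is None) == (b.events.acr is None)
        if a.events.acr:
            assert a.events.acr.onset_s == b.events.acr.onset_s
            assert a.events.acr.amplitude_dF == pytest.approx(
                b.events.acr.amplitude_dF)
            assert a.events.acr.slope_dF_per_s == pytest.approx(
                b.events.acr.slope_dF_per_s)


class TestOnsetRule:
    def test_flat_noise_free_trace_yields_none(self):
        norm = normalize(make_trace(np.full(400, 100.0)))
        assert detect_acr(norm) is None
        assert detect_mf(norm) is None

    def test_step_onset_exact_and_oracle_equal(self):
        """A 10-sigma step at frame j is detected at exactly frame j, in
        agreement with the exhaustive scan of the rule."""
        rng = np.random.default_rng(0)
        sigma = 10.0
        g = 500 + rng.normal(0, sigma, 400)
        j = 150
        g[j:] += 10 * sigma
        norm = normalize(make_trace(g))
        ev = detect_acr(norm)
        thr = 3.0 * norm.baseline_sd_green
        oracle = scan_onset_bruteforce(norm.dF_green, thr, 3, norm.stim_idx)
        assert ev is not None and ev.onset_idx == oracle == j

    @pytest.mark.parametrize("kind", ["noise", "ramp", "step", "simulated"])
    def test_oracle_equivalence_random_traces(self, kind):
        """Vectorized onset detection equals the brute-force frame scan on
        randomized traces of several shapes."""
        rng = np.random.default_rng(hash(kind) % 2**31)
        det = DetectionParams()
        for rep in range(40):
            if kind == "simulated":
                traces, _ = simulate_cohort("CD", 1, seed=rep)
                tr = traces[0]
            else:
                g = 300 + rng.normal(0, 15, 360)
                if kind == "ramp":
                    j = rng.integers(80, 250)
                    g[j:] += np.linspace(0, rng.uniform(50, 600),
                                         360 - j)
                elif kind == "step":
                    j = rng.integers(80, 250)
                    g[j:] += rng.uniform(20, 400)
                tr = make_trace(g)
            norm = normalize(tr)
            ev = detect_acr(norm, det=det)
            thr = det.k_sigma * max(norm.baseline_sd_green, 1e-12)
            oracle = scan_onset_bruteforce(norm.dF_green, thr, det.m_frames,
                                           norm.stim_idx)
            got = None if ev is None else ev.onset_idx
            assert got == oracle

    def test_mf_onset_oracle_equivalence(self):
        rng = np.random.default_rng(4)
        det = DetectionParams()
        for rep in range(30):
            r = 1000 + rng.normal(0, 15, 360)
            j = rng.integers(80, 250)
            r[j:] *= np.exp(-np.arange(360 - j) / rng.uniform(4, 40))
            norm = normalize(make_trace(np.full(360, 100.0), red=r))
            ev = detect_mf(norm, det=det)
            thr = det.k_sigma * max(norm.baseline_sd_red, 1e-12)
            oracle = scan_onset_bruteforce(-norm.dF_red, thr, det.m_frames,
                                           norm.stim_idx)
            got = None if ev is None else ev.onset_idx
            # detect_mf additionally requires 80% loss; when it reports an
            # event its onset must equal the scan
            if ev is not None:
                assert got == oracle


class TestNoiseFreeFidelity:
    @pytest.mark.parametrize("amp,slope,dur,mf_on", [
        (450.0, 120.0, 20.0, 85.0),
        (300.0, 40.0, 50.0, 115.0),
        (600.0, 200.0, 10.0, 75.0),
        (250.0, 25.0, 90.0, None),
    ])
    def test_detected_equals_truth(self, sensor, acq_quiet, amp, slope, dur,
                                   mf_on):
        """On noise-free cells every detected kinetic parameter matches
        truth to one frame (times) or 1% (amplitudes, slopes)."""
        mf = (MFParams(mf_onset_s=mf_on, mf_duration_s=12.0)
              if mf_on else None)
        params = SimCellParams(responder_class="fast", acr_onset_s=60.0,
                               amp_dF=amp, slope_dF_per_s=slope,
                               rise_duration_s=dur, mf=mf)
        tr, truth = simulate_cell(params, sensor, acq_quiet, seed=0)
        out = analyze_trace(tr)
        acr = out.events.acr
        frame = 1.0 / acq_quiet.frame_rate_hz
        assert acr is not None
        assert abs(acr.onset_s - truth.acr_onset_s) <= frame + 1e-9
        assert abs(acr.peak_s - truth.acr_peak_s) <= frame + 1e-9
        assert acr.amplitude_dF == pytest.approx(truth.amplitude_dF, rel=0.01)
        assert acr.slope_dF_per_s == pytest.approx(truth.slope_dF_per_s,
                                                   rel=0.01)
        if mf:
            assert out.events.mf is not None
            assert abs(out.events.mf.mf_onset_s - truth.mf_onset_s) <= frame
            assert abs(out.events.mf.duration_s
                       - truth.mf_duration_s) <= 2 * frame


class TestSpeedClass:
    def test_short_rise_is_fast(self, fast_cell_params, sensor, acq_quiet):
        tr, _ = simulate_cell(fast_cell_params, sensor, acq_quiet, seed=0)
        out = analyze_trace(tr)
        assert out.events.acr.speed_class == "fast"

    def test_rise_truncated_by_recording_end_is_slow(self, sensor, acq_quiet):
        """A gradual rise still climbing at the 8-min cutoff is slow even
        though its measured duration may be short."""
        params = SimCellParams(responder_class="slow", acr_onset_s=380.0,
                               amp_dF=400.0, slope_dF_per_s=4.0,
                               rise_duration_s=300.0)
        tr, _ = simulate_cell(params, sensor, acq_quiet, seed=0)
        out = analyze_trace(tr)
        assert out.events.acr is not None
        assert out.events.acr.peak_truncated
        assert out.events.acr.speed_class == "slow"

    def test_boundary_is_configurable(self):
        from acropore.events import ACREvent
        ev = ACREvent(onset_s=0, peak_s=100, rise_duration_s=100,
                      amplitude_dF=1, slope_dF_per_s=1)
        assert classify_speed(ev, slow_min_rise_s=120.0) == "fast"
        assert classify_speed(ev, slow_min_rise_s=90.0) == "slow"

    def test_a23187_split_recovered(self):
        """Detected fast/slow split within 3 binomial SDs of the 40/60
        truth split among responders."""
        fast = total = 0
        for seed in (21, 22, 23):
            traces, truths = simulate_cohort("A23187", 200, seed=seed)
            for tr, tru in zip(traces, truths):
                if not tru.acr_positive:
                    continue
                out = analyze_trace(tr)
                if out.events.acr is not None:
                    total += 1
                    fast += out.events.acr.speed_class == "fast"
        tol = 3 * np.sqrt(0.4 * 0.6 / total)
        assert abs(fast / total - 0.40) <= tol


class TestPSF:
    def test_monophasic_ramp_has_no_foot(self):
        """A direct ramp to peak yields no foot call, with or without
        noise."""
        for noise_seed in (None, 1, 2, 3):
            g = np.full(400, 100.0)
            g[120:160] += np.linspace(0, 400, 40)
            g[160:] += 400
            if noise_seed is not None:
                g = g + np.random.default_rng(noise_seed).normal(0, 20, 400)
            out = analyze_trace(make_trace(g))
            assert out.psf_count == 0

    def test_synthetic_foot_recovered(self, sensor, acq_quiet,
                                      psf_cell_params):
        """A 1/5-amplitude, 15 s shelf before the rise is called once, with
        duration within 2 frames and amplitude within 10% of truth."""
        tr, truth = simulate_cell(psf_cell_params, sensor, acq_quiet, seed=0)
        out = analyze_trace(tr)
        assert out.psf_count == 1
        foot = out.events.psf[0]
        assert abs(foot.duration_s - truth.psf_duration_s) <= 1.0 + 1e-9
        assert foot.amplitude_dF == pytest.approx(truth.psf_amplitude_dF,
                                                  rel=0.10)
        # the main-rise onset is re-measured past the foot
        assert abs(out.events.acr.onset_s - truth.acr_onset_s) <= 0.5

    def test_half_amplitude_shelf_rejected(self, sensor, acq_quiet):
        """A shelf at 1/2 the main amplitude violates the 4-to-7-fold
        criterion and is not a foot."""
        norm_params = SimCellParams(
            responder_class="fast", acr_onset_s=60.0, amp_dF=500.0,
            slope_dF_per_s=120.0, rise_duration_s=20.0)
        tr, _ = simulate_cell(norm_params, sensor, acq_quiet, seed=0)
        g = tr.f_green_au.copy()
        t = tr.t_s
        shelf = (t >= 75.0) & (t < 90.0)
        base = g[shelf].min()
        g[shelf] = np.minimum(g[shelf], base) + 250.0   # ~amp/2 shelf
        out = analyze_trace(make_trace(g, rate=2.0, stim=30.0))
        for foot in out.events.psf:
            assert foot.amplitude_dF <= 0.25 * out.events.acr.amplitude_dF


class TestMF:
    def test_constant_red_yields_none(self):
        norm = normalize(make_trace(np.full(400, 100.0)))
        assert detect_mf(norm) is None

    def test_clean_exponential_decay_quantified(self):
        """Noise-free decay with tau = 5 s to a zero floor: full loss,
        exact onset, duration equal to the 95%-completion time."""
        rate, stim = 2.0, 30.0
        n = 400
        t = np.arange(n) / rate
        r = np.full(n, 1000.0)
        j = t >= 100.0
        r[j] = 1000.0 * np.exp(-(t[j] - 100.0) / 5.0)
        norm = normalize(make_trace(np.full(n, 100.0), red=r,
                                    rate=rate, stim=stim))
        ev = detect_mf(norm)
        assert ev is not None
        assert ev.dF_over_F0 == pytest.approx(1.0, abs=0.01)
        assert ev.mf_onset_s == pytest.approx(100.0 - stim, abs=0.5)
        assert ev.duration_s == pytest.approx(5.0 * np.log(20), abs=1.5)
        assert ev.decay_slope_dF_per_s < 0

    def test_partial_loss_below_threshold_not_mf(self):
        """Losing only half the red signal does not qualify as fusion."""
        n = 400
        t = np.arange(n) / 2.0
        r = np.where(t < 100, 1000.0, 500.0)
        norm = normalize(make_trace(np.full(n, 100.0), red=r))
        assert detect_mf(norm) is None

    def test_green_onset_precedes_red_onset(self, sensor, acq_default):
        """In fused responders the detected Ca2+ rise precedes the red
        loss (non-EGTA ordering)."""
        traces, truths = simulate_cohort("GM1_CD", 150, seed=31)
        for tr, tru in zip(traces, truths):
            out = analyze_trace(tr)
            if out.acr_positive and out.mf_positive:
                assert out.events.mf.acr_mf_delay_s >= 0
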