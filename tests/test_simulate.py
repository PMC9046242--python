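"""Generator unit and property tests: calcium law, trace construction,
cohort statistics and ground-truth consistency."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acropore.config import (AcquisitionConfig, CaSensorModel, MFParams,
                             SimCellParams)
from acropore.simulate import (constant_pore_solution, draw_truncated_lognormal,
                               draw_truncated_normal, simulate_cell,
                               simulate_cohort)
from conftest import euler_pore_ode


class TestCalciumLaw:
    def test_single_pore_closed_form_matches_brute_force(self, sensor):
        """One permanent pore, no clearance: the closed-form saturating
        exponential agrees with a fine-step Euler integration to <0.1%."""
        t = np.arange(0.0, 120.5, 0.5)
        cf = constant_pore_solution(t, 1, 400.0, sensor, sensor.ca_rest_uM)
        bf = euler_pore_ode(120.0, 1e-3, 1, 400.0, sensor,
                            sensor.ca_rest_uM)[::500]
        assert np.max(np.abs(cf - bf) / bf) < 1e-3

    def test_closed_form_with_clearance(self, sensor):
        t = np.arange(0.0, 60.25, 0.25)
        cf = constant_pore_solution(t, 3, 200.0, sensor, 150.0,
                                    ca_clear_rate=0.05)
        bf = euler_pore_ode(60.0, 5e-4, 3, 200.0, sensor, 150.0,
                            clear=0.05)[::500]
        assert np.max(np.abs(cf - bf) / np.abs(bf)) < 1e-3

    def test_zero_external_calcium_blocks_influx(self, sensor):
        s0 = dataclasses.replace(sensor, ca_ext_uM=0.0)
        t = np.linspace(0, 100, 50)
        ca = constant_pore_solution(t, 5, 400.0, s0, s0.ca_rest_uM)
        assert np.allclose(ca, s0.ca_rest_uM)

    @given(ca=st.floats(0.0, 5000.0), delta=st.floats(0.1, 1000.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_hill_monotone_and_bounded(self, ca, delta):
        """Sensor saturation is monotone nondecreasing in Ca2+ and in
        [0, 1)."""
        sensor = CaSensorModel()
        f1, f2 = sensor.fraction_bound(ca), sensor.fraction_bound(ca + delta)
        assert 0.0 <= f1 <= f2 < 1.0

    def test_hill_inverse_roundtrip(self, sensor):
        for ca in (50.0, 256.0, 400.0, 1020.0):
            frac = float(sensor.fraction_bound(ca))
            assert sensor.ca_for_fraction(frac) == pytest.approx(ca, rel=1e-9)


class TestSingleCell:
    def test_non_responder_identity(self, sensor, acq_quiet):
        """No event, no noise: both channels constant at their baselines."""
        tr, truth = simulate_cell(SimCellParams(responder_class="none"),
                                  sensor, acq_quiet, seed=0)
        assert np.ptp(tr.f_green_au) == 0.0
        assert np.ptp(tr.f_red_au) == 0.0
        assert not truth.acr_positive and not truth.mf_positive

    def test_egta_cell_red_loss_without_green_rise(self, sensor, acq_quiet):
        """Chelated external Ca2+: the construct still reports fusion (red
        decay) while the green channel never rises above baseline."""
        s0 = dataclasses.replace(sensor, ca_ext_uM=0.0)
        params = SimCellParams(responder_class="none",
                               mf=MFParams(mf_onset_s=100.0,
                                           mf_duration_s=6.0))
        tr, truth = simulate_cell(params, s0, acq_quiet, seed=1)
        base_g = tr.f_green_au[:10].mean()
        assert tr.f_green_au.max() <= base_g + 1e-6
        assert tr.f_red_au[-1] < 0.1 * tr.f_red_au[0]
        assert truth.mf_positive and not truth.acr_positive
        assert truth.ca_independent_mf

    def test_full_ae_ordering_and_red_floor(self, sensor, acq_quiet,
                                            fast_cell_params):
        """Green rise precedes red loss precedes green return; red ends at
        its floor."""
        acq = acq_quiet
        tr, truth = simulate_cell(fast_cell_params, sensor, acq, seed=2)
        mf = fast_cell_params.mf
        t = tr.t_s
        base_g = tr.f_green_au[:10].mean()
        green_up = t[np.argmax(tr.f_green_au > base_g + 50)]
        red_down = t[np.argmax(tr.f_red_au < tr.f_red_au[0] - 50)]
        assert green_up < red_down
        assert truth.acr_onset_s < truth.mf_onset_s
        floor = mf.red_floor_fraction * acq.baseline_red_au
        assert tr.f_red_au[-1] <= floor + 1.0
        # sensor loss drags the green signal back toward baseline
        assert tr.f_green_au[-1] < base_g + 0.1 * truth.amplitude_dF

    def test_rejects_recording_without_stimulus(self, sensor):
        with pytest.raises(ValueError):
            AcquisitionConfig(duration_s=20.0, stim_time_s=30.0)

    def test_rejects_nonfinite_parameters(self, sensor, acq_quiet):
        with pytest.raises(ValueError):
            SimCellParams(responder_class="fast", acr_onset_s=float("nan"))

    def test_fixed_seed_bit_identical(self, sensor, acq_default,
                                      fast_cell_params):
        a, _ = simulate_cell(fast_cell_params, sensor, acq_default, seed=7)
        b, _ = simulate_cell(fast_cell_params, sensor, acq_default, seed=7)
        assert np.array_equal(a.f_green_au, b.f_green_au)
        assert np.array_equal(a.f_red_au, b.f_red_au)


class TestDistributions:
    def test_truncated_lognormal_matches_moments_in_window(self):
        """Windowed lognormal draws hit the requested truncated mean even
        when the spread is large relative to the window."""
        rng = np.random.default_rng(0)
        x = draw_truncated_lognormal(rng, 231.0, 186.0, upper=445.0,
                                     size=120_000)
        assert x.max() <= 445.0
        assert x.mean() == pytest.approx(231.0, abs=2.5)

    def test_truncated_normal_mean_corrected(self):
        rng = np.random.default_rng(1)
        x = draw_truncated_normal(rng, 60.0, 35.0, lower=3.0, upper=2000.0,
                                  size=120_000)
        assert x.min() >= 3.0
        assert x.mean() == pytest.approx(60.0, abs=0.5)


class TestCohort:
    def test_a23187_acr_fraction(self):
        """Empirical responder fraction within 3 binomial SDs of 75.3%."""
        _, truths = simulate_cohort("A23187", 1000, seed=5)
        frac = np.mean([t.acr_positive for t in truths])
        tol = 3 * np.sqrt(0.753 * 0.247 / 1000)
        assert abs(frac - 0.753) <= tol

    def test_cd_egta_no_true_acr(self):
        """Zero extracellular Ca2+ forces zero true Ca2+-rise events, while
        Ca2+-independent fusion still occurs."""
        _, truths = simulate_cohort("CD_EGTA", 400, seed=6)
        assert sum(t.acr_positive for t in truths) == 0
        n_mf = sum(t.mf_positive for t in truths)
        assert abs(n_mf / 400 - 0.171) <= 3 * np.sqrt(0.171 * 0.829 / 400)
        assert all(t.ca_independent_mf for t in truths if t.mf_positive)

    def test_gm1_onset_mean_converges(self):
        """Mean true onset within 2 sample-SEM of the configured 231 s
        (checked against truth records, not detection)."""
        _, truths = simulate_cohort("GM1_CD", 500, seed=7)
        onsets = np.array([t.acr_onset_s for t in truths if t.acr_positive])
        sem = onsets.std(ddof=1) / np.sqrt(len(onsets))
        assert abs(onsets.mean() - 231.0) <= 2 * sem

    def test_unknown_preset_rejected_with_names(self):
        with pytest.raises(ValueError, match="A23187"):
            simulate_cohort("nope", 5, seed=0)

    def test_cohort_seed_determinism(self):
        a, _ = simulate_cohort("CD", 6, seed=42)
        b, _ = simulate_cohort("CD", 6, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.f_green_au, y.f_green_au)
            assert np.array_equal(x.f_red_au, y.f_red_au)

    def test_psf_truth_amplitude_ratio(self):
        """Whenever a foot is generated its true amplitude is at most 1/4
        of the cell's true rise amplitude."""
        found = 0
        for seed in (8, 9):
            _, truths = simulate_cohort("HiP4_bicarb", 150, seed=seed)
            for t in truths:
                if t.psf_amplitude_dF is not None:
                    found += 1
                    assert t.psf_amplitude_dF <= 0.25 * t.amplitude_dF + 1e-6
                    assert t.psf_onset_s < t.acr_onset_s
        assert found >= 5

    def test_egta_green_quiet_invariant(self):
        """With no external Ca2+ at default noise, the green signal (the
        frame noise averaged out) stays within 3 noise SDs of baseline in
        at least 99% of cells."""
        traces, _ = simulate_cohort("CD_EGTA", 300, seed=10)
        kernel = np.ones(5) / 5
        quiet = 0
        for tr in traces:
            g = np.convolve(tr.f_green_au, kernel, mode="valid")
            base = g[: int(tr.stim_time_s * tr.frame_rate_hz) - 4].mean()
            if g.max() - base <= 3 * 20.0:
                quiet += 1
        assert quiet / len(traces) >= 0.99

    def test_truth_mf_events_observable(self):
        """Every truth-recorded fusion completes its signal loss within the
        recording (the 8-min window censors later events)."""
        traces, truths = simulate_cohort("A23187", 300, seed=11)
        for tr, t in zip(traces, truths):
            if t.mf_positive:
                assert (t.mf_onset_s + 0.7 * t.mf_duration_s
                        <= tr.t_s[-1] - tr.stim_time_s)
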