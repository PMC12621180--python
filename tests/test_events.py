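"""Event detection: smoothing, baseline search, thresholding, EMG fits."""

import numpy as np
import pytest

from vasonet.events import (
    BaselineWindow,
    detect_baseline,
    detect_cell_events,
    detect_events,
    emg_curve,
    fit_event,
    smooth_trace,
    summarize_cells,
)

from conftest import event_table

FR = 10.0


def render_emg(t, mu, sigma, tau, amplitude, baseline=1.0):
    """Transient with a given *peak height* on a flat baseline."""
    fine = np.linspace(mu - 6 * sigma, mu + 6 * tau + 6 * sigma, 4000)
    peak = emg_curve(fine, mu, sigma, tau, 1.0).max()
    return baseline + amplitude * emg_curve(t, mu, sigma, tau, 1.0) / peak


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(smooth_trace(x), x)

    def test_exact_on_cubic_polynomials(self):
        # the 3rd-order filter reproduces any cubic exactly at interior points
        rng = np.random.default_rng(0)
        t = np.linspace(0, 5, 200)
        for _ in range(5):
            c = rng.normal(size=4)
            y = c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3
            sm = smooth_trace(y)
            assert np.max(np.abs(sm[10:-10] - y[10:-10])) < 1e-10

    def test_noise_variance_matches_coefficient_norm(self):
        # oracle: center-point filter weights from an explicit least-squares fit
        window, order = 21, 3
        x = np.arange(window) - window // 2
        design = np.vander(x, order + 1, increasing=True)
        # weight vector for the fitted value at the center point
        pinv = np.linalg.pinv(design)
        weights = design[window // 2] @ pinv
        expected_ratio = float(np.sum(weights**2))
        rng = np.random.default_rng(1)
        noise = rng.standard_normal(200_000)
        ratio = smooth_trace(noise).var() / noise.var()
        assert ratio == pytest.approx(expected_ratio, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.ones(10))


class TestBaseline:
    def test_constant_trace_first_window(self):
        win = detect_baseline(np.ones(500), FR)
        assert win.start == 0.0
        assert win.sd == 0.0
        assert win.mean == 1.0

    def test_quietest_segment_selected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.0, 0.05, 600)
        x[300:400] = 1.0 + rng.normal(0, 0.005, 100)  # a 10-s quiet stretch
        win = detect_baseline(x, FR)
        assert 28.0 <= win.start <= 31.0

    def test_window_respects_stimulus_onset(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 0.05, 600)
        win = detect_baseline(x, FR, stimulus_onset=12.0)
        assert win.end <= 12.0 + 1e-9

    def test_insufficient_prestimulus_data(self):
        with pytest.raises(ValueError):
            detect_baseline(np.ones(300), FR, stimulus_onset=5.0)

    def test_raw_sd_option(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(1.0, 0.05, 400)
        sm = smooth_trace(raw)
        win_raw = detect_baseline(sm, FR, raw=raw)
        win_sm = detect_baseline(sm, FR)
        assert win_raw.sd > win_sm.sd  # smoothing shrinks the noise SD


class TestDetection:
    def test_flat_trace_no_events(self):
        base = BaselineWindow(0, 10, 1.0, 0.01)
        assert detect_events(np.ones(600), base, FR) == []

    def test_single_emg_detected_at_true_peak(self):
        t = np.arange(0, 60, 1 / FR)
        rng = np.random.default_rng(5)
        noise_sd = 0.02
        y = render_emg(t, 30.0, 0.4, 1.0, 10 * noise_sd * 5) + rng.normal(0, noise_sd, t.size)
        events = detect_cell_events(y, FR)
        assert len(events) == 1
        fine = np.linspace(28, 36, 4000)
        true_peak = fine[np.argmax(emg_curve(fine, 30.0, 0.4, 1.0, 1.0))]
        assert abs(events[0].peak_time - true_peak) < 0.2

    def test_two_transients_ten_seconds_apart(self):
        t = np.arange(0, 80, 1 / FR)
        y = render_emg(t, 40.0, 0.4, 1.0, 1.0) + render_emg(t, 50.0, 0.4, 1.0, 1.0) - 1.0
        y += np.random.default_rng(6).normal(0, 0.02, t.size)
        events = detect_cell_events(y, FR)
        assert len(events) == 2

    def test_frequency_invariant_to_amplitude_rescaling(self):
        t = np.arange(0, 120, 1 / FR)
        rng = np.random.default_rng(7)
        y = (
            render_emg(t, 40.0, 0.4, 1.0, 1.0)
            + render_emg(t, 70.0, 0.3, 1.2, 0.8)
            - 1.0
            + rng.normal(0, 0.02, t.size)
        )
        counts = {c: len(detect_cell_events(c * y, FR)) for c in (0.5, 1.0, 3.0)}
        assert len(set(counts.values())) == 1


class TestEmgFit:
    def test_gaussian_limit_fdhm(self):
        # tau -> 0 reduces the EMG to a Gaussian with FDHM = 2 sqrt(2 ln 2) sigma
        fr, sigma = 40.0, 0.4
        t = np.arange(0, 40, 1 / fr)
        y = render_emg(t, 20.0, sigma, 1e-3, 1.0)
        ev = detect_cell_events(y, fr)[0]
        assert ev.fit_ok
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert ev.fdhm == pytest.approx(expected, rel=0.01)

    def test_sigma_tau_recovery(self):
        fr, sigma, tau = 40.0, 0.3, 1.0
        t = np.arange(0, 40, 1 / fr)
        y = render_emg(t, 20.0, sigma, tau, 1.0)
        ev = detect_cell_events(y, fr)[0]
        assert ev.fit_ok
        _, sig_f, tau_f, _ = ev.emg_params
        assert sig_f == pytest.approx(sigma, rel=0.05)
        assert tau_f == pytest.approx(tau, rel=0.05)

    def test_three_frame_blip_falls_back(self):
        trace = np.zeros(200)
        trace[100:103] = 1.0
        base = BaselineWindow(0, 10, 0.0, 0.01)
        ev = fit_event((100, 103), trace, base, FR)
        assert not ev.fit_ok
        assert ev.amplitude == pytest.approx(1.0)


class TestSummaries:
    def test_frequency_per_minute(self):
        ev = event_table([(1, 30.0 + i) for i in range(6)])
        out = summarize_cells(ev, [1], (20.0, 140.0))
        assert out.loc[1, "frequency"] == pytest.approx(3.0)

    def test_zero_events_flagged(self):
        ev = event_table([])
        out = summarize_cells(ev, [1], (0.0, 60.0))
        assert out.loc[1, "event_count"] == 0
        assert out.loc[1, "frequency"] == 0.0
        assert np.isnan(out.loc[1, "mean_amplitude"])

    def test_events_outside_interval_excluded(self):
        ev = event_table([(1, 5.0), (1, 30.0), (1, 200.0)])
        out = summarize_cells(ev, [1], (20.0, 140.0))
        assert out.loc[1, "event_count"] == 1
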