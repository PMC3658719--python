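"""Tare tracking, gain calibration, range filtering and segmentation."""

import numpy as np
import pytest

from nestscale import (AcquisitionConfig, DegenerateInputError,
                       GainCalibration, Pattern, RawSample, TareState,
                       apply_calibration, fit_gain, is_in_range,
                       segment_stream, update_tare, validate_pattern)

from conftest import reference_segment


def _sample(tick, w, stable=False):
    return RawSample(tick=tick, raw_weight=w, stable=stable, nest_id="n1")


class TestUpdateTare:
    def test_constant_buffer_gives_constant_tare(self, acq):
        state = TareState(window=64)
        for t in range(64):
            state = update_tare(state, _sample(t, 10.0), acq)
        assert state.tare == pytest.approx(10.0, abs=1e-9)
        assert state.n_updates == 64

    def test_single_point_fit(self, acq):
        state = update_tare(TareState(window=64), _sample(0, 9.8), acq)
        assert state.tare == 9.8

    def test_wind_spike_ignored_vs_median_oracle(self, acq, rng):
        state = TareState(window=64)
        values = list(rng.normal(10.0, 0.1, 63)) + [250.0]
        rng.shuffle(values)
        for t, v in enumerate(values):
            state = update_tare(state, _sample(t, v), acq)
        assert abs(state.tare - 10.0) < 0.2
        assert abs(state.tare - np.median(values)) < 0.2

    def test_matches_statsmodels_huber_location(self, acq, rng):
        from statsmodels.robust.scale import huber as sm_huber

        state = TareState(window=64)
        values = np.concatenate([rng.normal(10.0, 0.5, 58),
                                 rng.uniform(100, 300, 6)])
        rng.shuffle(values)
        for t, v in enumerate(values):
            state = update_tare(state, _sample(t, v), acq)
        loc, _ = sm_huber(values)
        assert state.tare == pytest.approx(float(loc), abs=0.3)

    def test_contaminated_buffer_robustness(self, acq, rng):
        """<= 20% uniform outliers in [100, 300] move the tare by less
        than 5*sigma/sqrt(window)."""
        mu, sigma, window = 12.0, 0.5, 64
        for _ in range(25):
            n_out = rng.integers(0, int(0.2 * window) + 1)
            vals = np.concatenate([
                rng.normal(mu, sigma, window - n_out),
                rng.uniform(100, 300, n_out),
            ])
            rng.shuffle(vals)
            state = TareState(window=window)
            for t, v in enumerate(vals):
                state = update_tare(state, _sample(t, v), acq)
            assert abs(state.tare - mu) <= 5 * sigma / np.sqrt(window)

    def test_buffer_bounded_by_window(self, acq):
        state = TareState(window=16)
        for t in range(50):
            state = update_tare(state, _sample(t, 10.0 + 0.01 * t), acq)
        assert len(state.buffer) == 16
        # oldest-first ordering: last buffered value is the newest
        assert state.buffer[-1] == pytest.approx(10.49)


class TestCalibration:
    def test_apply_calibration(self):
        assert apply_calibration(160.0, 10.0) == pytest.approx(150.0)
        gc = GainCalibration(gain=1.01, offset=-0.5)
        assert apply_calibration(160.0, 10.0, gc) == pytest.approx(151.1)
        assert apply_calibration(10.0, 10.0) == 0.0

    def test_fit_gain_identity_and_bias(self):
        ident = fit_gain([(100.0, 100.0), (200.0, 200.0)])
        assert ident.gain == pytest.approx(1.0)
        assert ident.offset == pytest.approx(0.0, abs=1e-9)
        biased = fit_gain([(100.0, 99.0), (200.0, 199.0)])
        assert biased.gain == pytest.approx(1.0)
        assert biased.offset == pytest.approx(1.0)

    def test_fit_gain_recovers_noisy_slope_vs_ols_oracle(self, rng):
        true_gain, true_off = 1.02, -0.3
        masses = np.array([50.0, 100.0, 150.0, 200.0, 250.0])
        raws = (masses - true_off) / true_gain + rng.normal(0, 0.05, 5)
        cal = fit_gain(list(zip(masses, raws)))
        assert cal.gain == pytest.approx(true_gain, rel=0.01)
        # closed-form OLS oracle
        sxx = np.sum((raws - raws.mean()) ** 2)
        sxy = np.sum((raws - raws.mean()) * (masses - masses.mean()))
        assert cal.gain == pytest.approx(sxy / sxx, rel=1e-9)
        assert cal.residual_rms < 0.2

    def test_fit_gain_rejects_single_mass(self):
        with pytest.raises(DegenerateInputError):
            fit_gain([(100.0, 99.0), (100.0, 99.1)])


class TestRangeFilter:
    @pytest.mark.parametrize("weight,expected", [
        (150.0, True),   # study species sits inside the extended range
        (400.0, False),  # wind spike
        (50.0, True),    # boundary inclusive
        (300.0, True),
        (49.99, False),
    ])
    def test_is_in_range(self, acq, weight, expected):
        assert is_in_range(weight, acq) is expected


def _stream(values, start_tick=0):
    return [_sample(start_tick + i, v) for i, v in enumerate(values)]


class TestSegmentation:
    def test_single_visit_hand_trace(self, acq, zero_tare):
        values = [0.0] * 10 + [150.0] * 30 + [0.05] * 6
        patterns, state = segment_stream(_stream(values), zero_tare, acq)
        assert len(patterns) == 1
        assert len(patterns[0]) == 30
        assert patterns[0].start_tick == 10
        assert patterns[0].end_tick == 39
        assert not patterns[0].truncated
        # 10 leading + 1 trailing sample after the close update the tare
        assert state.n_updates == 11

    def test_all_below_threshold_updates_tare_only(self, acq, zero_tare):
        patterns, state = segment_stream(_stream([0.0] * 46), zero_tare, acq)
        assert patterns == []
        assert state.n_updates == 46

    def test_subcritical_dip_retained(self, acq, zero_tare):
        values = [150.0] * 15 + [20.0] * 3 + [150.0] * 15 + [0.0] * 6
        patterns, _ = segment_stream(_stream(values), zero_tare, acq)
        assert len(patterns) == 1
        assert len(patterns[0]) == 33
        assert (patterns[0].weights[15:18] == 20.0).all()

    def test_critical_dip_splits_pattern(self, acq, zero_tare):
        values = [150.0] * 20 + [0.0] * 5 + [150.0] * 20 + [0.0] * 6
        patterns, _ = segment_stream(_stream(values), zero_tare, acq)
        assert [len(p) for p in patterns] == [20, 20]

    def test_above_range_samples_dropped(self, acq, zero_tare):
        values = [150.0] * 10 + [400.0] * 2 + [150.0] * 10 + [0.0] * 6
        patterns, _ = segment_stream(_stream(values), zero_tare, acq)
        assert len(patterns) == 1
        assert len(patterns[0]) == 20
        assert patterns[0].weights.max() <= 300.0

    def test_truncated_at_end_of_stream(self, acq, zero_tare):
        patterns, _ = segment_stream(_stream([0.0] * 4 + [150.0] * 25),
                                     zero_tare, acq)
        assert len(patterns) == 1
        assert patterns[0].truncated
        assert len(patterns[0]) == 25
        assert not validate_pattern(patterns[0], acq)
        assert validate_pattern(patterns[0], acq, allow_truncated=True)

    def test_matches_two_pass_reference_on_random_streams(self, acq, rng):
        """Random toy streams: the state machine equals the brute-force
        two-pass reference sample for sample, and tare updates happen
        exactly on the samples outside open patterns."""
        choices = np.array([0.0, 0.0, 0.0, 60.0, 150.0, 151.0, 400.0])
        for _ in range(150):
            n = int(rng.integers(1, 120))
            values = choices[rng.integers(0, len(choices), n)]
            got, state = segment_stream(
                _stream(list(values)), TareState(tare=0.0, window=64), acq)
            exp_patterns, spans, exp_trunc = reference_segment(values)
            assert len(got) == len(exp_patterns)
            for g, e, t in zip(got, exp_patterns, exp_trunc):
                assert g.ticks.tolist() == [i for i, _ in e]
                assert g.weights.tolist() == [w for _, w in e]
                assert g.truncated == t
            in_pattern = sum(e - s + 1 for s, e in spans)
            assert state.n_updates == n - in_pattern

    def test_validate_pattern_minimum_duration(self, acq):
        def mk(n):
            return Pattern(weights=np.full(n, 150.0),
                           stable=np.zeros(n, bool),
                           ticks=np.arange(n))
        assert validate_pattern(mk(30), acq)
        assert not validate_pattern(mk(16), acq)
        assert validate_pattern(mk(17), acq)

    def test_gain_calibration_applied_before_tare(self, acq):
        gc = GainCalibration(gain=2.0, offset=0.0)
        state = TareState(tare=20.0, window=64)
        values = [10.0] * 8 + [100.0] * 20 + [10.0] * 6
        patterns, state = segment_stream(_stream(values), state, acq, gc)
        assert len(patterns) == 1
        # calibrated = 2*100 - 20 = 180
        assert patterns[0].weights == pytest.approx(np.full(20, 180.0))

    def test_rejects_non_increasing_ticks(self, acq, zero_tare):
        bad = [_sample(0, 0.0), _sample(0, 0.0)]
        with pytest.raises(ValueError, match="strictly increasing"):
            segment_stream(bad, zero_tare, acq)
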