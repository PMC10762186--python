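"""Segmentation, the six call features, bout IGI profiles,
classification rules and call-rate binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pagvocal as pv
from pagvocal.calls import (
    Call,
    ClassifierRules,
    ExcludedCallError,
    InsufficientBoutError,
    features_table,
)
from pagvocal.signal import PulseSeries


def series(times, amps=None):
    t = np.asarray(times, dtype=float)
    a = np.ones_like(t) if amps is None else np.asarray(amps, dtype=float)
    return PulseSeries(t, a)


class TestSegmentCalls:
    def test_two_groups(self):
        calls = pv.segment_calls(series([0, 0.01, 0.02, 1.0, 1.01]), 0.1)
        assert [c.n_pulses for c in calls] == [3, 2]

    def test_uniform_gaps_single_call(self):
        calls = pv.segment_calls(series(np.arange(20) * 0.01), 0.1)
        assert len(calls) == 1

    def test_recovers_synthetic_bout(self, detected_grunt_train):
        calls = pv.segment_calls(detected_grunt_train, 0.1)
        assert len(calls) == 6
        assert all(c.n_pulses == 20 for c in calls)

    def test_empty_series(self):
        assert pv.segment_calls(series([]), 0.1) == []

    def test_single_pulse_flagged_non_analysable(self):
        calls = pv.segment_calls(series([0.0, 5.0]), 0.1)
        assert len(calls) == 2
        assert not calls[0].analysable

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        times=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=1, max_size=40,
            unique=True,
        ),
        gap=st.floats(0.01, 5.0),
    )
    def test_partition_exhaustive_and_order_preserving(self, times, gap):
        t = np.sort(np.asarray(times))
        calls = pv.segment_calls(series(t), gap)
        recon = np.concatenate([c.pulse_times for c in calls])
        np.testing.assert_array_equal(recon, t)
        for c in calls:
            if c.n_pulses > 1:
                assert np.all(np.diff(c.pulse_times) <= gap)


class TestCallDurationTotal:
    def test_single_call(self):
        calls = pv.segment_calls(series([0.0, 0.1]), 0.2)
        assert pv.call_duration_total(calls) == pytest.approx(0.1)

    def test_spans_calls(self):
        calls = pv.segment_calls(series([0, 0.1, 1.0, 1.1]), 0.2)
        assert pv.call_duration_total(calls) == pytest.approx(1.1)

    def test_single_pulse_zero(self):
        calls = pv.segment_calls(series([0.5]), 0.2)
        assert pv.call_duration_total(calls) == 0.0
        assert not calls[0].analysable

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pv.call_duration_total([])


class TestExtractFeatures:
    def test_constant_train(self):
        f = pv.extract_features(Call([0, 0.01, 0.02, 0.03], [1, 1, 1, 1]))
        assert f.duration == pytest.approx(0.03)
        assert f.mean_prr == pytest.approx(100.0)
        assert f.cv_prr == pytest.approx(0.0, abs=1e-12)
        assert f.cv_amp == 0.0
        assert f.pct_change_amp == 0.0
        assert f.pct_change_prr == pytest.approx(0.0, abs=1e-10)

    def test_pct_change_prr_from_slowest_gap(self):
        # gaps 10 and 20 ms -> rates 100 and 50 Hz -> (100-50)/50 = 100%
        f = pv.extract_features(Call([0, 0.01, 0.03], [1, 1, 1]))
        assert f.pct_change_prr == pytest.approx(100.0)
        assert f.mean_prr == pytest.approx(75.0)  # arithmetic mean of rates

    def test_amp_features_hand_arithmetic(self):
        f = pv.extract_features(Call([0, 0.01], [0.5, 1.0]))
        assert f.pct_change_amp == pytest.approx(100.0)
        # sample sd of {0.5, 1.0} is 0.35355; mean 0.75
        assert f.cv_amp == pytest.approx(np.std([0.5, 1.0], ddof=1) / 0.75)

    def test_single_pulse_excluded(self):
        with pytest.raises(ExcludedCallError):
            pv.extract_features(Call([0.0], [1.0]))

    def test_amplitude_scale_invariance(self):
        a = pv.extract_features(Call([0, 0.01, 0.025], [0.4, 0.8, 0.6]))
        b = pv.extract_features(Call([0, 0.01, 0.025], [0.2, 0.4, 0.3]))
        assert a.cv_amp == pytest.approx(b.cv_amp)
        assert a.pct_change_amp == pytest.approx(b.pct_change_amp)

    def test_recovery_from_noiseless_hum(self):
        spec = pv.CallSpec("hum", 10.0, 100.0, prr_cv=0.05)
        _, truth = pv.synth_call(spec, seed=5)
        f = pv.extract_features(Call(truth.times, truth.amps))
        assert abs(f.mean_prr - 100.0) / 100.0 < 0.01
        assert abs(f.cv_prr - 0.05) / 0.05 < 0.15
        assert abs(f.duration - 10.0) <= 1.0 / 100.0 + 1e-9


class TestBoutIgiProfile:
    def bout_from_igis(self, igis):
        # two-pulse calls separated by the given igis
        calls, t = [], 0.0
        for igi in list(igis) + [None]:
            calls.append(Call([t, t + 0.05], [1.0, 1.0]))
            if igi is None:
                break
            t = t + 0.05 + igi
        return pv.Bout(tuple(calls))

    def test_stable(self):
        mean, sd, trend = pv.bout_igi_profile(self.bout_from_igis([0.5] * 5))
        assert (mean, sd, trend) == (pytest.approx(0.5), 0.0, "stable")

    def test_rise_fall_pattern(self):
        bout = self.bout_from_igis([0.3, 0.5, 0.8, 0.6, 0.4])
        assert pv.bout_igi_profile(bout)[2] == "rise_fall"

    def test_other_pattern(self):
        bout = self.bout_from_igis([0.8, 0.3, 0.9, 0.2])
        assert pv.bout_igi_profile(bout)[2] == "other"

    def test_too_few_calls_rejected(self):
        with pytest.raises(InsufficientBoutError):
            pv.bout_igi_profile(self.bout_from_igis([0.5]))

    def test_generator_rise_fall_recovered_over_seeds(self):
        hits = 0
        for seed in range(100):
            spec = pv.BoutSpec(6, 0.5, igi_sd=0.02, igi_profile="rise_fall")
            _, truths, _ = pv.synth_bout(spec, seed=seed)
            calls = tuple(Call(t.times, t.amps) for t in truths)
            if pv.bout_igi_profile(pv.Bout(calls))[2] == "rise_fall":
                hits += 1
        assert hits >= 95


class TestClassifyCall:
    def make(self, duration, cv_prr=0.0, cv_amp=0.0):
        return pv.CallFeatures(duration, cv_amp, 100.0, cv_prr, 0.0, 0.0)

    def test_brief_is_grunt(self):
        assert pv.classify_call(self.make(0.2)) == "grunt"

    def test_long_variable_is_growl(self):
        assert pv.classify_call(self.make(3.0, cv_prr=0.4)) == "growl"
        assert pv.classify_call(self.make(3.0, cv_amp=0.4)) == "growl"

    def test_long_stable_splits_on_ramp_flag(self):
        f = self.make(10.0, cv_prr=0.01, cv_amp=0.01)
        assert pv.classify_call(f, has_onset_ramp=True) == "hum_like"
        assert pv.classify_call(f) == "buzz_like"

    def test_agreement_with_generator_labels(self):
        # well-separated specs, ground-truth features, 200 seeded calls
        specs = {"grunt": pv.GRUNT, "growl": pv.GROWL, "buzz": pv.BUZZ}
        rules = ClassifierRules()
        correct = total = 0
        for label, spec in specs.items():
            for seed in range(67):
                _, truth = pv.synth_call(spec, seed=seed)
                f = pv.extract_features(Call(truth.times, truth.amps))
                got = pv.classify_call(f, rules)
                correct += got.startswith(label)
                total += 1
        assert total >= 200
        assert correct / total >= 0.95


class TestCallRatePerMin:
    def test_front_loaded(self):
        calls = [Call([t, t + 0.05], [1, 1]) for t in [1.0, 10.0, 50.0]]
        np.testing.assert_array_equal(
            pv.call_rate_per_min(calls, 180.0), [3, 0, 0]
        )

    def test_edge_onset_goes_to_later_bin(self):
        calls = [Call([60.0, 60.05], [1, 1])]
        np.testing.assert_array_equal(
            pv.call_rate_per_min(calls, 120.0), [0, 1]
        )

    def test_uniform_split(self):
        calls = [Call([t, t + 0.01], [1, 1]) for t in np.arange(60) * 2.0]
        np.testing.assert_array_equal(
            pv.call_rate_per_min(calls, 120.0), [30, 30]
        )


class TestFeaturesTable:
    def test_excludes_single_pulse_rows(self):
        calls = pv.segment_calls(series([0, 0.01, 0.02, 5.0]), 0.1)
        table = features_table(calls)
        assert len(table) == 1
        assert set(pv.calls.FEATURE_NAMES) <= set(table.columns)
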