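import numpy as np
import pytest

from ivlsim.fixtures import generate_renewal_train
from ivlsim.metrics import (ConsistencyVerdict, IVLThresholds, SpikeTrainStats,
                            SubthresholdStats, consistency, detect_spikes,
                            derive_seeds, ivl_score, subthreshold_stats)


def triangular_spike_trace(spike_times, duration=1000.0, dt=0.1,
                           baseline=-70.0, peak=0.0, half_width=1.0):
    """Synthetic voltage trace with triangular spikes at given times (ms)."""
    t = np.arange(0, duration + dt / 2, dt)
    v = np.full_like(t, baseline)
    for ts in spike_times:
        lo = np.searchsorted(t, ts - half_width)
        hi = np.searchsorted(t, ts + half_width)
        tri = np.clip(1.0 - np.abs(t[lo:hi] - ts) / half_width, 0, 1)
        v[lo:hi] = np.maximum(v[lo:hi], baseline + (peak - baseline) * tri)
    return t, v


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 1000, 0.1)
        spk = detect_spikes(t, np.full_like(t, -70.0))
        assert spk.times.size == 0
        assert spk.rate == 0.0
        assert spk.isi_cv == 0.0

    def test_regular_train_rate_and_zero_cv(self):
        times = np.arange(50.0, 1000.0, 100.0)  # 10 spikes over 1 s
        t, v = triangular_spike_trace(times)
        spk = detect_spikes(t, v)
        assert spk.times.size == 10
        assert spk.rate == pytest.approx(10.0, rel=0.01)
        assert spk.isi_cv == pytest.approx(0.0, abs=1e-9)
        # amplitude measured against the subthreshold mean
        assert spk.mean_amplitude == pytest.approx(70.0, abs=1.0)

    def test_poisson_train_has_unit_isi_cv(self):
        # 5 Hz keeps the detector's refractory period negligible (2% of ISIs)
        times = generate_renewal_train(rate=5.0, cv=1.0, duration=210_000.0,
                                       seed=4)
        t, v = triangular_spike_trace(times, duration=210_000.0, dt=0.25)
        spk = detect_spikes(t, v)
        assert spk.times.size > 900
        assert spk.isi_cv == pytest.approx(1.0, abs=0.05)

    def test_nonfinite_samples_rejected(self):
        t = np.arange(0, 10, 0.1)
        v = np.full_like(t, -70.0)
        v[5] = np.nan
        with pytest.raises(ValueError):
            detect_spikes(t, v)

    @pytest.mark.parametrize("cv", [0.5, 1.0, 1.5])
    def test_pipeline_recovers_generative_cv(self, cv):
        """Gamma-renewal trains (shape k => CV 1/sqrt(k)) recovered to 5%."""
        rate = 20.0
        duration = 1000.0 / rate * 1100
        times = generate_renewal_train(rate, cv, duration, seed=17)
        isi = np.diff(times)
        isi_cv = isi.std() / isi.mean()
        assert isi_cv == pytest.approx(cv, rel=0.05)


class TestSubthresholdStats:
    def test_constant_trace(self):
        t = np.arange(0, 100, 0.1)
        s = subthreshold_stats(t, np.full_like(t, -65.0), [])
        assert (s.mean, s.sd) == (-65.0, 0.0)

    def test_sine_wave_sd_closed_form(self):
        a = 3.0
        t = np.arange(0, 1000, 0.01)
        v = -65.0 + a * np.sin(2 * np.pi * t / 100.0)
        s = subthreshold_stats(t, v, [])
        assert s.sd == pytest.approx(a / np.sqrt(2), rel=0.01)
        assert s.mean == pytest.approx(-65.0, abs=0.01)

    def test_invariant_to_spike_peak_heights(self):
        times = np.arange(100.0, 900.0, 200.0)
        t, v1 = triangular_spike_trace(times, peak=-20.0)
        _, v2 = triangular_spike_trace(times, peak=40.0)
        s1 = subthreshold_stats(t, v1, times)
        s2 = subthreshold_stats(t, v2, times)
        assert s1 == s2

    def test_empty_retained_set_rejected(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(ValueError):
            subthreshold_stats(t, np.full_like(t, -60.0), [5.0],
                               exclusion_halfwidth=50.0)


def stats_for(v_mean=-65.0, v_sd=3.0, isi_cv=1.0, rate=10.0, amp=50.0,
              n_spikes=10):
    sub = SubthresholdStats(v_mean, v_sd)
    spk = SpikeTrainStats(np.linspace(0, 1000, n_spikes),
                          np.full(n_spikes, amp), rate, isi_cv)
    return sub, spk


class TestIVLScore:
    def test_all_criteria_pass_scores_four(self):
        sub, spk = stats_for()
        assert ivl_score(sub, spk).score == 4

    def test_amplitude_penalty_subtracts_five(self):
        sub, spk = stats_for(amp=35.0)
        assert ivl_score(sub, spk).score == -1

    def test_all_fail_no_penalty_scores_zero(self):
        sub, spk = stats_for(v_mean=-75.0, v_sd=1.0, isi_cv=0.5, rate=1.0)
        assert ivl_score(sub, spk).score == 0

    def test_boundaries_are_strict(self):
        t = IVLThresholds()
        sub, spk = stats_for(v_mean=t.v_mean, v_sd=t.v_sd, isi_cv=t.isi_cv,
                             rate=t.rate_low)
        s = ivl_score(sub, spk)
        assert not (s.depolarized or s.fluctuating or s.irregular
                    or s.rate_in_band)
        sub, spk = stats_for(rate=t.rate_high)
        assert not ivl_score(sub, spk).rate_in_band

    def test_no_spikes_no_amplitude_penalty(self):
        sub = SubthresholdStats(-65.0, 3.0)
        spk = SpikeTrainStats(np.zeros(0), np.zeros(0), 0.0, 0.0)
        s = ivl_score(sub, spk)
        assert not s.amplitude_penalty
        assert s.score == 2  # depolarized + fluctuating only

    def test_score_monotone_in_fluctuation_and_amplitude(self):
        for sd in (0.0, 1.0, 2.2, 2.3, 5.0):
            lo = ivl_score(*stats_for(v_sd=sd)).score
            hi = ivl_score(*stats_for(v_sd=sd + 0.5)).score
            assert hi >= lo
        below = ivl_score(*stats_for(amp=39.9)).score
        above = ivl_score(*stats_for(amp=40.1)).score
        assert above - below == 5

    def test_maximum_attainable_score_without_penalty(self):
        best = max(ivl_score(*stats_for(v_mean=vm, v_sd=sd, isi_cv=cv,
                                        rate=f)).score
                   for vm in (-75.0, -65.0) for sd in (1.0, 3.0)
                   for cv in (0.5, 1.0) for f in (1.0, 10.0, 30.0))
        assert best == 4


class TestConsistencyRule:
    def test_five_fours_rest_threes_passes(self):
        v = ConsistencyVerdict.from_scores((4, 4, 4, 4, 4, 3, 3, 3, 3, 3))
        assert v.consistent

    def test_one_score_below_three_fails(self):
        v = ConsistencyVerdict.from_scores((4, 4, 4, 4, 3, 3, 3, 3, 3, 2))
        assert not v.consistent

    def test_all_fours_passes(self):
        assert ConsistencyVerdict.from_scores([4] * 10).consistent

    def test_four_fours_fails(self):
        assert not ConsistencyVerdict.from_scores(
            (4, 4, 4, 4, 3, 3, 3, 3, 3, 3)).consistent

    def test_model_driven_consistency_uses_derived_seeds(self):
        class Model:
            def __init__(self):
                self.seeds = []

            def score_ivl(self, params, seed):
                self.seeds.append(seed)
                return 4

        model = Model()
        v = consistency(model, None, n_seeds=10, master_seed=3)
        assert v.consistent
        assert model.seeds == derive_seeds(3, 10)
        assert len(set(model.seeds)) == 10

    def test_seed_derivation_is_prefix_stable(self):
        assert derive_seeds(9, 5) == derive_seeds(9, 10)[:5]
        assert all(0 <= s < 2 ** 31 for s in derive_seeds(9, 10))
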