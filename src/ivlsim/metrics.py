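"""Spike statistics and the in vivo-like (IVL) state metric.

A simulated state qualifies as in vivo-like when it is depolarized,
fluctuating and irregularly spiking at a physiological rate without
entering depolarization block:

    score = (Vm_mean > -70.588 mV) + (Vm_sd > 2.2 mV) + (ISICV > 0.8)
          + (3 Hz < f < 25 Hz) - 5 * (mean spike amplitude < 40 mV)

All threshold comparisons are strict, exactly as stated; the defaults are
configuration-overridable.  A parameter set is *consistently* IVL when, over
ten re-randomized simulations, at least five score 4 and the remainder score
at least 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrainStats",
    "SubthresholdStats",
    "IVLThresholds",
    "IVLScore",
    "ConsistencyVerdict",
    "detect_spikes",
    "isi_coefficient_of_variation",
    "subthreshold_stats",
    "ivl_score",
    "score_trace",
    "consistency_verdict",
    "consistency",
    "derive_seeds",
]


@dataclass(frozen=True)
class SpikeTrainStats:
    times: np.ndarray  # ms, strictly increasing
    amplitudes: np.ndarray  # mV relative to the subthreshold mean
    rate: float  # Hz over the analysis window
    isi_cv: float

    @property
    def mean_amplitude(self) -> float:
        return float(np.mean(self.amplitudes)) if self.amplitudes.size else float("nan")


@dataclass(frozen=True)
class SubthresholdStats:
    mean: float  # mV
    sd: float  # mV


@dataclass(frozen=True)
class IVLThresholds:
    """Criterion thresholds; defaults as used for OLM cells."""

    v_mean: float = -70.588  # mV, resting potential plus ~3 mV in vivo shift
    v_sd: float = 2.2  # mV
    isi_cv: float = 0.8
    rate_low: float = 3.0  # Hz
    rate_high: float = 25.0  # Hz
    amplitude: float = 40.0  # mV, depolarization-block guard


@dataclass(frozen=True)
class IVLScore:
    depolarized: bool
    fluctuating: bool
    irregular: bool
    rate_in_band: bool
    amplitude_penalty: bool
    score: int

    def __int__(self) -> int:
        return self.score


@dataclass(frozen=True)
class ConsistencyVerdict:
    scores: tuple
    consistent: bool

    @classmethod
    def from_scores(cls, scores) -> "ConsistencyVerdict":
        scores = tuple(int(s) for s in scores)
        n4 = sum(s == 4 for s in scores)
        rest_ok = all(s >= 3 for s in scores if s != 4)
        return cls(scores, n4 >= 5 and rest_ok)


def isi_coefficient_of_variation(times) -> float:
    """ISI CV of a spike-time sequence: ~0 regular, ~1 Poisson-like."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return 0.0
    isi = np.diff(times)
    return float(np.std(isi) / np.mean(isi))


def detect_spikes(time: np.ndarray, v: np.ndarray, threshold: float = -10.0,
                  refractory: float = 3.0, peak_window: float = 3.0,
                  exclusion_halfwidth: float = 5.0) -> SpikeTrainStats:
    """Detect spikes as upward threshold crossings separated by the
    refractory period.

    The amplitude of each spike is the voltage peak within ``peak_window``
    ms after the crossing minus the mean of the trace's subthreshold samples
    (samples outside +/- ``exclusion_halfwidth`` ms of any spike).  The rate
    is the spike count over the trace span.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite samples")
    if time.size != v.size or time.size < 2:
        raise ValueError("time and voltage must be equal-length, >= 2 samples")

    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spike_times = []
    for i in idx:
        if not spike_times or time[i] - spike_times[-1] >= refractory:
            spike_times.append(time[i])
    spike_times = np.array(spike_times)

    duration_s = (time[-1] - time[0]) / 1000.0
    rate = spike_times.size / duration_s

    isi_cv = isi_coefficient_of_variation(spike_times)

    if spike_times.size:
        try:
            ref = subthreshold_stats(time, v, spike_times, exclusion_halfwidth).mean
        except ValueError:
            # pathologically dense spiking: no subthreshold samples remain
            ref = float(v.mean())
        dt = time[1] - time[0]
        w = max(1, int(round(peak_window / dt)))
        amps = np.empty(spike_times.size)
        for k, t0 in enumerate(spike_times):
            i0 = int(np.searchsorted(time, t0 - 1e-9))
            amps[k] = v[i0:i0 + w + 1].max() - ref
    else:
        amps = np.zeros(0)

    return SpikeTrainStats(spike_times, amps, rate, isi_cv)


def subthreshold_stats(time: np.ndarray, v: np.ndarray, spike_times,
                       exclusion_halfwidth: float = 5.0) -> SubthresholdStats:
    """Mean and SD of the membrane potential outside spike windows."""
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    spike_times = np.asarray(getattr(spike_times, "times", spike_times), dtype=float)
    keep = np.ones(time.size, dtype=bool)
    for t0 in spike_times:
        keep &= ~((time >= t0 - exclusion_halfwidth) & (time <= t0 + exclusion_halfwidth))
    if not keep.any():
        raise ValueError("spike-exclusion windows removed every sample")
    vv = v[keep]
    return SubthresholdStats(float(vv.mean()), float(vv.std()))


def ivl_score(sub: SubthresholdStats, spk: SpikeTrainStats,
              thresholds: IVLThresholds = IVLThresholds()) -> IVLScore:
    """Evaluate the IVL metric; all comparisons strict.

    With zero spikes the amplitude penalty is not applied (no amplitude
    evidence of depolarization block; the rate criterion already fails).
    """
    t = thresholds
    depol = sub.mean > t.v_mean
    fluct = sub.sd > t.v_sd
    irreg = spk.isi_cv > t.isi_cv
    band = t.rate_low < spk.rate < t.rate_high
    penalty = bool(spk.amplitudes.size) and spk.mean_amplitude < t.amplitude
    score = int(depol) + int(fluct) + int(irreg) + int(band) - 5 * int(penalty)
    return IVLScore(depol, fluct, irreg, band, penalty, score)


def score_trace(time, v, window: tuple[float, float] | None = None,
                thresholds: IVLThresholds = IVLThresholds(),
                threshold: float = -10.0, refractory: float = 3.0,
                exclusion_halfwidth: float = 5.0):
    """Full pipeline on one voltage trace: detect, summarize, score.

    ``window`` restricts the analysis (default: from 1 s into the trace to
    its end, mirroring analysis of the last 9 s of 10 s simulations).
    Returns (SubthresholdStats, SpikeTrainStats, IVLScore).
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if window is None:
        window = (time[0] + 1000.0, time[-1]) if time[-1] - time[0] > 2000.0 \
            else (time[0], time[-1])
    mask = (time >= window[0] - 1e-9) & (time <= window[1] + 1e-9)
    t_w, v_w = time[mask], v[mask]
    spk = detect_spikes(t_w, v_w, threshold, refractory,
                        exclusion_halfwidth=exclusion_halfwidth)
    try:
        sub = subthreshold_stats(t_w, v_w, spk.times, exclusion_halfwidth)
    except ValueError:
        # spiking so dense that no subthreshold samples remain; score on the
        # raw trace (such states fail the rate band regardless)
        sub = SubthresholdStats(float(v_w.mean()), float(v_w.std()))
    return sub, spk, ivl_score(sub, spk, thresholds)


def consistency_verdict(scores) -> ConsistencyVerdict:
    return ConsistencyVerdict.from_scores(scores)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Counter-based per-simulation seed streams from one master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, np.uint32)
    return [int(s) % (2 ** 31) for s in state]


def consistency(model, params, n_seeds: int = 10, master_seed: int = 0,
                **score_kwargs) -> ConsistencyVerdict:
    """Run ``n_seeds`` re-randomized simulations of ``params`` on ``model``
    and apply the consistency rule.

    ``model`` must expose ``score_ivl(params, seed) -> int`` (re-randomizing
    synaptic locations and presynaptic spike times from the seed).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    scores = [int(model.score_ivl(params, s, **score_kwargs))
              for s in derive_seeds(master_seed, n_seeds)]
    return ConsistencyVerdict.from_scores(scores)
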