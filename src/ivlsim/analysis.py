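"""Results-layer analyses: F-I matching, current decomposition, charge and
cross-correlation timing.

The in vitro / in vivo-like comparison protocol: (1) fit a two-point F-I
line from holding currents 60 and 120 pA above rheobase; (2) simulate the
chosen in vivo-like (IVL) bombardment, measure its spike rate f_IVL, and
hold the synapse-free model at I_hold = (f_IVL - b)/m to match rates;
(3) repeat over re-randomized seeds and compare per-channel currents at the
five recording sites (S, D1..D4) over the last 9 s of each 10 s simulation.

Currentscape decomposition splits each channel's current per sample into
the inward (negative) or outward (positive) pool and reports its fraction
of that pool's total.  Cross-correlations use mean/SD normalization so the
values lie in [-1, 1]; inward-carrying channel currents (NaT, CaT, CaL, H,
excitatory synaptic) are reversed in polarity first, with the leak exempt
because it turns outward during spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import derive_seeds, detect_spikes, score_trace
from .simulator import (CurrentStep, SimulationError, StimulusProtocol,
                        TraceSet, simulate)

__all__ = [
    "FILine",
    "CurrentDecomposition",
    "Correlogram",
    "INWARD_CHANNELS",
    "fi_line",
    "holding_current",
    "currentscape",
    "total_charge",
    "polarity_adjust",
    "normalized_xcorr",
    "compare_states",
]

# channels whose membrane current is inward-carrying (negative) and is
# reversed in polarity before cross-correlation; the leak is exempt
INWARD_CHANNELS = frozenset({"NaT", "CaT", "CaL", "H", "syn_exc"})


@dataclass(frozen=True)
class FILine:
    """Two-point line through (I, f) calibration points above rheobase."""

    m: float  # Hz/pA
    b: float  # Hz
    points: tuple  # ((I1, f1), (I2, f2)) in (pA, Hz)

    @classmethod
    def from_points(cls, p1, p2) -> "FILine":
        (i1, f1), (i2, f2) = p1, p2
        if f1 == f2:
            raise ValueError("identical rates at both holding currents "
                             "(slope would be zero)")
        m = (f2 - f1) / (i2 - i1)
        b = f1 - m * i1
        return cls(m, b, ((i1, f1), (i2, f2)))

    def predict(self, i_pa: float) -> float:
        return self.m * i_pa + self.b


def holding_current(f_ivl: float, line: FILine) -> float:
    """I_hold = (f_IVL - b) / m, in pA."""
    return (f_ivl - line.b) / line.m


def _measure_rate(trace: TraceSet, site: str = "S",
                  window_start: float = 1000.0) -> float:
    w = trace.window(window_start)
    spk = detect_spikes(w.time, w.voltage[w.site_index(site)])
    return spk.rate


def fi_line(model, offsets: tuple[float, float] = (60.0, 120.0),
            duration: float = 10000.0, rheo: float | None = None,
            window_start: float = 1000.0) -> FILine:
    """Fit the two-point F-I line at rheobase + 60 and + 120 pA.

    ``model`` must expose ``morphology``, ``channels`` and (if ``rheo`` is
    not given) ``find_rheobase()``.  Raises if either holding current fails
    to elicit spiking.
    """
    if rheo is None:
        rheo = model.find_rheobase()
    points = []
    for off in offsets:
        i_pa = rheo + off
        proto = StimulusProtocol(duration=duration,
                                 steps=[CurrentStep("S", i_pa)],
                                 record_sites=["S"])
        tr = simulate(model.morphology, model.channels, proto)
        f = _measure_rate(tr, "S", window_start)
        if f <= 0:
            raise SimulationError(f"no spiking at holding current {i_pa} pA")
        points.append((i_pa, f))
    return FILine.from_points(*points)


@dataclass
class CurrentDecomposition:
    """Per-sample split of channel currents into inward/outward pool fractions.

    ``inward_fraction``/``outward_fraction`` have shape (n_names, n_t);
    fractions are NaN at samples where the corresponding pool total is zero
    (undefined rather than zero, to avoid spurious contributions in silent
    windows).  At every defined sample each pool's fractions sum to 1, and
    ``inward_fraction * total_inward + outward_fraction * total_outward``
    reconstructs each channel current exactly.
    """

    names: list[str]
    time: np.ndarray
    total_inward: np.ndarray  # pA, <= 0
    total_outward: np.ndarray  # pA, >= 0
    inward_fraction: np.ndarray
    outward_fraction: np.ndarray

    def reconstruct(self, name: str) -> np.ndarray:
        j = self.names.index(name)
        inw = np.where(np.isnan(self.inward_fraction[j]), 0.0,
                       self.inward_fraction[j]) * self.total_inward
        out = np.where(np.isnan(self.outward_fraction[j]), 0.0,
                       self.outward_fraction[j]) * self.total_outward
        return inw + out


def currentscape(traces: TraceSet, site: str,
                 include_synaptic: bool = True) -> CurrentDecomposition:
    """Decompose the site's currents into percent contributions per pool."""
    si = traces.site_index(site)
    names = list(traces.names)
    cur = traces.currents[si]
    if not include_synaptic:
        keep = [k for k, n in enumerate(names) if not n.startswith("syn_")]
        names = [names[k] for k in keep]
        cur = cur[keep]
    neg = np.minimum(cur, 0.0)
    pos = np.maximum(cur, 0.0)
    tot_in = neg.sum(axis=0)
    tot_out = pos.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_in = np.where(tot_in != 0.0, neg / tot_in, np.nan)
        f_out = np.where(tot_out != 0.0, pos / tot_out, np.nan)
    return CurrentDecomposition(names, traces.time.copy(), tot_in, tot_out,
                                f_in, f_out)


def total_charge(trace: np.ndarray, time: np.ndarray) -> float:
    """Signed area under a current trace (pA*ms), trapezoidal rule.

    Sign semantics: more positive = larger outward current, more negative =
    larger inward current.
    """
    return float(np.trapezoid(np.asarray(trace, dtype=float),
                              np.asarray(time, dtype=float)))


def polarity_adjust(currents: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Reverse the polarity of inward-carrying channel currents.

    NaT, CaT, CaL, H and excitatory synaptic currents are negated so their
    activation aligns with voltage/outward-current polarity; outward
    channels are untouched and the leak is exempt (it becomes an outward
    current during spikes).
    """
    return {name: (-np.asarray(x) if name in INWARD_CHANNELS else np.asarray(x))
            for name, x in currents.items()}


@dataclass(frozen=True)
class Correlogram:
    lags: np.ndarray  # ms, symmetric about 0
    values: np.ndarray  # in [-1, 1]

    @property
    def peak_value(self) -> float:
        return float(self.values[np.argmax(np.abs(self.values))])

    @property
    def peak_lag(self) -> float:
        return float(self.lags[np.argmax(np.abs(self.values))])


def normalized_xcorr(a1: np.ndarray, a2: np.ndarray, dt: float,
                     max_lag: float = 20.0) -> Correlogram:
    """Normalized full cross-correlation of two equally sampled series.

    ``a1`` is centred and scaled by (SD * length), ``a2`` centred and scaled
    by SD, so magnitudes lie in [-1, 1] and the lag-0 autocorrelation is
    exactly 1.  Lag convention: a positive lag means ``a1`` lags (follows)
    ``a2``; if ``a2`` is ``a1`` delayed by d, the peak sits at -d.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("series must be 1-D and share the time grid")
    s1, s2 = a1.std(), a2.std()
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("zero-variance input")
    x1 = (a1 - a1.mean()) / (s1 * len(a1))
    x2 = (a2 - a2.mean()) / s2
    # full linear cross-correlation; FFT path for long traces
    from scipy.signal import correlate
    full = correlate(x1, x2, mode="full", method="auto")
    n = a1.size
    lags = (np.arange(full.size) - (n - 1)) * dt
    keep = np.abs(lags) <= max_lag + 1e-9
    return Correlogram(lags[keep], full[keep])


def compare_states(model, ivl_params, n_seeds: int = 10, master_seed: int = 0,
                   duration: float = 10000.0, window_start: float = 1000.0,
                   line: FILine | None = None, max_lag: float = 20.0,
                   xcorr_sites: tuple = ("S", "D4")):
    """Paired IVL / rate-matched in vitro comparison over re-randomized seeds.

    For each derived seed: simulate the IVL bombardment, measure f_IVL,
    simulate the synapse-free model at I_hold = (f_IVL - b)/m, and analyze
    both states at the five recording sites over the analysis window.
    Returns (charge_table, xcorr_table, per_seed) where ``charge_table`` has
    one row per seed x state x site x channel with the trapezoidal total
    charge, ``xcorr_table`` holds current-vs-voltage and soma-vs-distal
    correlogram peaks, and ``per_seed`` records f_IVL, I_hold and skips.
    """
    if line is None:
        line = fi_line(model, duration=duration, window_start=window_start)
    charge_rows = []
    xcorr_rows = []
    seed_rows = []
    channel_names = None
    for seed in derive_seeds(master_seed, n_seeds):
        ivl_tr = model.simulate_ivl(ivl_params, seed, duration=duration)
        f_ivl = _measure_rate(ivl_tr, "S", window_start)
        i_hold = holding_current(f_ivl, line)
        row = {"seed": seed, "f_ivl": f_ivl, "i_hold": i_hold, "skipped": False}
        if i_hold <= 0 or f_ivl <= 0:
            row["skipped"] = True
            seed_rows.append(row)
            continue
        proto = StimulusProtocol(duration=duration,
                                 steps=[CurrentStep("S", i_hold)])
        vitro_tr = simulate(model.morphology, model.channels, proto)
        row["f_vitro"] = _measure_rate(vitro_tr, "S", window_start)
        seed_rows.append(row)

        for state, tr in (("ivl", ivl_tr), ("vitro", vitro_tr)):
            w = tr.window(window_start)
            if channel_names is None:
                channel_names = list(w.names)
            for site in w.sites:
                si = w.site_index(site)
                for j, name in enumerate(w.names):
                    charge_rows.append({
                        "seed": seed, "state": state, "site": site,
                        "channel": name,
                        "charge": total_charge(w.currents[si, j], w.time)})
                if site in xcorr_sites:
                    v = w.voltage[si]
                    adjusted = polarity_adjust(
                        {name: w.currents[si, j] for j, name in enumerate(w.names)})
                    for name, cur in adjusted.items():
                        if cur.std() == 0.0 or v.std() == 0.0:
                            continue
                        cg = normalized_xcorr(cur, v, w.dt, max_lag)
                        xcorr_rows.append({
                            "seed": seed, "state": state, "site": site,
                            "pair": f"{name}*V", "peak": cg.peak_value,
                            "peak_lag": cg.peak_lag})
            # soma vs distal voltage coupling
            v_s = w.voltage[w.site_index(xcorr_sites[0])]
            v_d = w.voltage[w.site_index(xcorr_sites[-1])]
            if v_s.std() > 0 and v_d.std() > 0:
                cg = normalized_xcorr(v_s, v_d, w.dt, max_lag)
                xcorr_rows.append({"seed": seed, "state": state,
                                   "site": f"{xcorr_sites[0]}x{xcorr_sites[-1]}",
                                   "pair": "V*V", "peak": cg.peak_value,
                                   "peak_lag": cg.peak_lag})
    return (pd.DataFrame(charge_rows), pd.DataFrame(xcorr_rows),
            pd.DataFrame(seed_rows))
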