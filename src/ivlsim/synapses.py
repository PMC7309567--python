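"""Dual-exponential synapses and voltage-clamp weight fitting.

The conductance waveform follows the two-state kinetic scheme

    g(t) = weight * factor * (exp(-t/tau_d) - exp(-t/tau_r)),

with ``factor`` chosen so the peak conductance equals ``weight`` exactly,
and the synaptic current i = g (V - E), outward positive.  Events superpose
linearly, which the solver exploits by pooling synapses that share a
compartment and kinetics.

Weight fitting emulates the experimental calibration: a single synaptic
event under an ideal somatic voltage clamp, with all voltage-gated channels
blocked and the leak reversal moved to the clamp potential, incrementing the
weight until the evoked postsynaptic current (PSC) reaches its literature
target amplitude.  Fits that fail to reach the target within 100 increments
are flagged unconverged (distal high-impedance sites can require
implausibly large conductances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "E_EXC",
    "E_INH",
    "SYNAPSE_CLASSES",
    "TABLE2_TARGETS",
    "SynapseSpec",
    "PlacedSynapse",
    "SynapseBank",
    "PSCTarget",
    "WeightFitResult",
    "peak_time",
    "peak_factor",
    "dual_exp_conductance",
    "synaptic_current",
    "optimize_weight",
]

E_EXC = 0.0  # mV
E_INH = -80.0  # mV

# kinetics per presynaptic class: (tau_r ms, tau_d ms, reversal mV)
SYNAPSE_CLASSES: dict[str, tuple[float, float, float]] = {
    "PYR": (2.4, 12.7, E_EXC),
    "IS3": (1.6, 12.0, E_INH),
    "MS": (1.1, 12.1, E_INH),
    "BIS": (1.35, 12.05, E_INH),
}


@dataclass(frozen=True)
class PSCTarget:
    """Literature target for one postsynaptic current class."""

    cls: str
    amplitude: float  # pA, sign consistent with (V_hold - E)
    rise: float  # ms (tau_r)
    decay: float  # ms (tau_d)
    holding: float  # mV


# Target EPSC/IPSC features: amplitude, rise, decay, clamp holding potential.
# IPSC fits clamp at 0 mV, EPSC fits at -60 mV.
TABLE2_TARGETS: dict[str, PSCTarget] = {
    "IS3": PSCTarget("IS3", 13.9, 1.6, 12.0, 0.0),
    "MS": PSCTarget("MS", 23.0, 1.1, 12.1, 0.0),
    "BIS": PSCTarget("BIS", 16.9, 1.35, 12.05, 0.0),
    "PYR": PSCTarget("PYR", -12.14, 2.4, 12.7, -60.0),
}


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: class, kinetics, reversal, weight and location."""

    cls: str
    tau_r: float
    tau_d: float
    reversal: float
    weight: float  # uS
    compartment: int = 0
    position: float = 0.5

    def __post_init__(self):
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError(f"need tau_d > tau_r > 0, got {self.tau_r}, {self.tau_d}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @classmethod
    def of_class(cls, name: str, weight: float, compartment: int = 0) -> "SynapseSpec":
        tr, td, e = SYNAPSE_CLASSES[name]
        return cls(name, tr, td, e, weight, compartment)


@dataclass
class PlacedSynapse:
    """A synapse bound to a compartment together with its event times (ms)."""

    cls: str
    compartment: int
    tau_r: float
    tau_d: float
    reversal: float
    weight: float
    events: np.ndarray = field(default_factory=lambda: np.zeros(0))


class SynapseBank(list):
    """List of :class:`PlacedSynapse`; the unit the solver attaches."""


def peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak of the dual-exponential waveform (set dg/dt = 0)."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def peak_factor(tau_r: float, tau_d: float) -> float:
    """Normalization so the peak conductance equals the weight exactly."""
    if tau_d <= tau_r:
        raise ValueError(f"need tau_d > tau_r, got {tau_r}, {tau_d}")
    tp = peak_time(tau_r, tau_d)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


def dual_exp_conductance(t, spec: SynapseSpec):
    """Conductance (uS) at time ``t`` (ms) since a single event."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time since the event)")
    f = spec.weight * peak_factor(spec.tau_r, spec.tau_d)
    return f * (np.exp(-t / spec.tau_d) - np.exp(-t / spec.tau_r))


def synaptic_current(g, v, e):
    """i = g (V - E) with g in uS and V, E in mV, giving pA (outward positive)."""
    return np.asarray(g, dtype=float) * (np.asarray(v, dtype=float) - e) * 1e3


@dataclass(frozen=True)
class WeightFitResult:
    weight: float  # uS
    achieved: float  # pA (magnitude)
    iterations: int
    converged: bool


def _model_parts(model):
    if hasattr(model, "morphology") and hasattr(model, "channels"):
        return model.morphology, model.channels
    morph, channels = model
    return morph, channels


def optimize_weight(model, site, target: PSCTarget,
                    step: float = 1e-5, tol: float = 0.02,
                    max_iter: int = 100, clamp_site: str | int = "S",
                    event_time: float = 20.0, window: float = 100.0,
                    dt: float = 0.025) -> WeightFitResult:
    """Incrementally raise a synapse's weight until its somatic clamp-current
    amplitude reaches the target.

    The synapse sits at ``site``; the soma (``clamp_site``) is held at the
    target's holding potential by an ideal clamp with all voltage-gated
    channels blocked and the leak reversal set to the holding potential, so
    the baseline clamp current is zero.  The smallest tried weight whose peak
    |PSC| reaches the target within ``tol`` (relative) is returned; after
    ``max_iter`` increments the fit stops and is flagged unconverged.
    """
    from .simulator import StimulusProtocol, VoltageClamp, simulate
    from .morphology import Morphology  # noqa: F401  (type context)

    morph, channels = _model_parts(model)
    tr, td, e = SYNAPSE_CLASSES.get(target.cls, (target.rise, target.decay, None))
    if e is None:
        e = E_EXC if target.amplitude < 0 and target.holding < 0 else E_INH
    tr, td = target.rise, target.decay

    drive = target.holding - e
    if target.amplitude == 0.0:
        return WeightFitResult(0.0, 0.0, 0, True)
    if target.amplitude * drive < 0:
        raise ValueError(
            f"target amplitude {target.amplitude} pA inconsistent with "
            f"V_hold - E = {drive} mV")

    passive = channels.passive_only(e_leak=target.holding)
    comp = site if isinstance(site, (int, np.integer)) else morph.sites[site]
    goal = abs(target.amplitude)

    def amplitude(weight: float) -> float:
        bank = SynapseBank([PlacedSynapse(target.cls, int(comp), tr, td, e,
                                          weight, np.array([event_time]))])
        proto = StimulusProtocol(
            duration=event_time + window, dt=dt,
            clamp=VoltageClamp(clamp_site, target.holding),
            synapses=bank, record_sites=[clamp_site],
            v_init=target.holding)
        trc = simulate(morph, passive, proto)
        i = trc.clamp_current
        pre = i[trc.time < event_time - 1.0]
        baseline = pre[-40:].mean() if pre.size else 0.0
        post = i[trc.time >= event_time]
        return float(np.max(np.abs(post - baseline)))

    weight = 0.0
    achieved = 0.0
    for it in range(1, max_iter + 1):
        weight = it * step
        achieved = amplitude(weight)
        if achieved >= goal * (1.0 - tol):
            return WeightFitResult(weight, achieved, it, True)
    return WeightFitResult(weight, achieved, max_iter, False)
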