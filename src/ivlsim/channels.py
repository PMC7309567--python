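"""Ion channel mechanisms for OLM-like interneuron models.

Every voltage-gated channel follows the Hodgkin-Huxley form

    I = gbar * m^p * h^q * (V - E)

with Boltzmann steady states and bell-shaped voltage-dependent time
constants.  The calcium-dependent potassium channel (KCa) is gated by a
single-exponential intracellular calcium pool fed by the calcium currents
(CaT + CaL).  The nine channel types and their regional maximal conductance
densities follow the published OLM-cell parameterizations (cell 1 / cell 2);
the gating parameter values shipped here are a documented generic
"OLM-like" set and are fully overridable through configuration.

Units: mV, ms, pS/um^2 for densities, uM for calcium.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "VoltageGate",
    "CalciumGate",
    "GatingScheme",
    "ChannelSpec",
    "CalciumPool",
    "ChannelSet",
    "CHANNEL_NAMES",
    "TABLE1_DENSITIES",
    "default_gating",
    "reference_channelset",
]

# canonical ordering used throughout the package (trace layouts, kernels)
CHANNEL_NAMES = ("H", "NaT", "Kdrf", "Kdrs", "KA", "M", "CaT", "CaL", "KCa", "leak")

REGIONS = ("soma", "dend", "axon")


@dataclass(frozen=True)
class VoltageGate:
    """One voltage-dependent gating variable.

    Steady state: 1 / (1 + exp(-(V - v_half)/k)); k < 0 gives a gate that
    opens with hyperpolarization (inactivation gates, H activation).
    Time constant: tau_base + tau_amp / (exp((V - v_peak)/s1) + exp(-(V - v_peak)/s2)).
    """

    v_half: float
    k: float
    tau_base: float = 0.1
    tau_amp: float = 0.0
    v_peak: float = -50.0
    s1: float = 15.0
    s2: float = 15.0

    def steady_state(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.v_half) / self.k))

    def time_constant(self, v):
        v = np.asarray(v, dtype=float)
        return self.tau_base + self.tau_amp / (
            np.exp((v - self.v_peak) / self.s1) + np.exp(-(v - self.v_peak) / self.s2)
        )


@dataclass(frozen=True)
class CalciumGate:
    """Calcium-dependent activation: steady state ca/(ca + kd), fixed tau."""

    kd: float = 0.5  # uM
    tau: float = 5.0  # ms

    def steady_state(self, ca):
        ca = np.maximum(np.asarray(ca, dtype=float), 0.0)
        return ca / (ca + self.kd)


@dataclass(frozen=True)
class GatingScheme:
    p: int = 1
    q: int = 0
    activation: VoltageGate | CalciumGate | None = None
    inactivation: VoltageGate | None = None

    def __post_init__(self):
        if self.p > 0 and self.activation is None:
            raise ValueError("p > 0 requires an activation gate")
        if self.q > 0 and self.inactivation is None:
            raise ValueError("q > 0 requires an inactivation gate")


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    reversal: float  # mV
    gating: GatingScheme = field(default_factory=GatingScheme)
    carries_calcium: bool = False


@dataclass(frozen=True)
class CalciumPool:
    """Single-exponential pool fed by inward calcium current.

    d[Ca]/dt = (ca_rest - [Ca])/tau + k_in * max(0, -I_Ca / area)
    with I_Ca/area in pA/um^2 and [Ca] in uM.
    """

    tau: float = 100.0  # ms
    k_in: float = 0.2  # uM per (pA/um^2 * ms)
    ca_rest: float = 0.05  # uM


def default_gating() -> dict[str, ChannelSpec]:
    """Generic OLM-like channel specifications (gating + reversals).

    NaT is a fast transient sodium channel; Kdrf/Kdrs are fast/slow delayed
    rectifiers; KA inactivates; M is a slow non-inactivating potassium
    channel; H activates with hyperpolarization (reversal -30 mV); CaT is
    low-threshold inactivating, CaL high-threshold; KCa is gated by the
    calcium pool.  All values are configuration defaults, not measurements.
    """
    e_k, e_na, e_ca, e_h = -95.0, 50.0, 120.0, -30.0
    return {
        "H": ChannelSpec("H", e_h, GatingScheme(
            1, 0, VoltageGate(-80.0, -8.0, tau_base=40.0, tau_amp=400.0,
                              v_peak=-80.0, s1=20.0, s2=20.0))),
        "NaT": ChannelSpec("NaT", e_na, GatingScheme(
            3, 1,
            VoltageGate(-35.0, 6.0, tau_base=0.04, tau_amp=0.25,
                        v_peak=-38.0, s1=12.0, s2=12.0),
            VoltageGate(-45.0, -6.0, tau_base=0.4, tau_amp=8.0,
                        v_peak=-55.0, s1=12.0, s2=12.0))),
        "Kdrf": ChannelSpec("Kdrf", e_k, GatingScheme(
            4, 0, VoltageGate(-27.0, 9.0, tau_base=0.3, tau_amp=2.5,
                              v_peak=-35.0, s1=20.0, s2=20.0))),
        "Kdrs": ChannelSpec("Kdrs", e_k, GatingScheme(
            1, 0, VoltageGate(-35.0, 6.0, tau_base=30.0, tau_amp=300.0,
                              v_peak=-40.0, s1=20.0, s2=20.0))),
        "KA": ChannelSpec("KA", e_k, GatingScheme(
            4, 1,
            VoltageGate(-41.0, 8.5, tau_base=0.4, tau_amp=2.0,
                        v_peak=-45.0, s1=20.0, s2=20.0),
            VoltageGate(-72.0, -6.0, tau_base=15.0, tau_amp=50.0,
                        v_peak=-70.0, s1=15.0, s2=15.0))),
        "M": ChannelSpec("M", e_k, GatingScheme(
            1, 0, VoltageGate(-38.0, 6.0, tau_base=20.0, tau_amp=100.0,
                              v_peak=-45.0, s1=20.0, s2=20.0))),
        "CaT": ChannelSpec("CaT", e_ca, GatingScheme(
            2, 1,
            VoltageGate(-50.0, 5.0, tau_base=1.0, tau_amp=4.0,
                        v_peak=-50.0, s1=15.0, s2=15.0),
            VoltageGate(-70.0, -5.0, tau_base=10.0, tau_amp=50.0,
                        v_peak=-70.0, s1=15.0, s2=15.0)),
            carries_calcium=True),
        "CaL": ChannelSpec("CaL", e_ca, GatingScheme(
            2, 0, VoltageGate(-22.0, 6.0, tau_base=0.8, tau_amp=2.0,
                              v_peak=-25.0, s1=15.0, s2=15.0)),
            carries_calcium=True),
        "KCa": ChannelSpec("KCa", e_k, GatingScheme(
            1, 0, CalciumGate(kd=2.0, tau=10.0))),
        "leak": ChannelSpec("leak", -70.0, GatingScheme(0, 0)),
    }


# Regional maximal conductance densities (pS/um^2) of the two published
# OLM cell models.  Region keys absent => density 0 there.
TABLE1_DENSITIES: dict[int, dict[str, dict[str, float]]] = {
    1: {
        "NaT": {"soma": 70.99, "dend": 99.48, "axon": 66.42},
        "Kdrf": {"soma": 115.47, "dend": 50.49, "axon": 155.97},
        "Kdrs": {"soma": 0.0054, "dend": 0.0038, "axon": 0.0082},
        "KA": {"soma": 76.08, "dend": 76.08},
        "CaL": {"dend": 47.19},
        "CaT": {"dend": 1.01},
        "KCa": {"dend": 0.14},
        "M": {"soma": 0.14, "dend": 0.14},
        "H": {"soma": 0.1063, "dend": 0.1063},
    },
    2: {
        "NaT": {"soma": 75.09, "dend": 64.68, "axon": 140.89},
        "Kdrf": {"soma": 91.15, "dend": 52.52, "axon": 144.03},
        "Kdrs": {"soma": 0.0070, "dend": 0.0062, "axon": 0.0024},
        "KA": {"soma": 110.18, "dend": 110.18},
        "CaL": {"dend": 22.01},
        "CaT": {"dend": 3.74},
        "KCa": {"dend": 7.08},
        "M": {"soma": 0.18, "dend": 0.18},
        "H": {"soma": 0.0608, "dend": 0.0608},
    },
}


class ChannelSet:
    """Channel specifications plus per-region maximal conductance densities.

    ``densities[name][region]`` is in pS/um^2; channels absent from a region
    simply have density 0 there.
    """

    def __init__(self, specs: dict[str, ChannelSpec],
                 densities: dict[str, dict[str, float]],
                 calcium: CalciumPool | None = None):
        unknown = set(densities) - set(specs)
        if unknown:
            raise ValueError(f"densities for unknown channels: {sorted(unknown)}")
        for name, per_region in densities.items():
            for region, val in per_region.items():
                if region not in REGIONS:
                    raise ValueError(f"unknown region {region!r} for channel {name}")
                if val < 0:
                    raise ValueError(f"negative density for {name}.{region}")
        self.specs = dict(specs)
        self.densities = {n: dict(d) for n, d in densities.items()}
        self.calcium = calcium or CalciumPool()

    @property
    def names(self) -> list[str]:
        return [n for n in CHANNEL_NAMES if n in self.specs] + \
               [n for n in self.specs if n not in CHANNEL_NAMES]

    def density(self, name: str, region: str) -> float:
        return self.densities.get(name, {}).get(region, 0.0)

    def density_matrix(self, region_labels: list[str]) -> np.ndarray:
        """(n_comp, n_channel) density array in pS/um^2, channel order = names."""
        names = self.names
        out = np.zeros((len(region_labels), len(names)))
        for j, name in enumerate(names):
            for i, region in enumerate(region_labels):
                out[i, j] = self.density(name, region)
        return out

    @property
    def e_leak(self) -> float:
        return self.specs["leak"].reversal

    def copy(self) -> "ChannelSet":
        return ChannelSet(dict(self.specs),
                          copy.deepcopy(self.densities),
                          self.calcium)

    def with_leak_reversal(self, e_leak: float) -> "ChannelSet":
        cs = self.copy()
        cs.specs["leak"] = ChannelSpec("leak", float(e_leak), GatingScheme(0, 0))
        return cs

    def passive_only(self, e_leak: float | None = None) -> "ChannelSet":
        """All voltage-gated channels blocked; leak retained.

        Used during synaptic weight optimization, where the fit runs with
        voltage-gated channels blocked and the leak reversal moved to the
        clamp potential.
        """
        cs = self.copy()
        cs.densities = {"leak": dict(self.densities.get("leak", {}))}
        if e_leak is not None:
            cs.specs["leak"] = ChannelSpec("leak", float(e_leak), GatingScheme(0, 0))
        return cs

    def scaled(self, multipliers: dict[str, float]) -> "ChannelSet":
        """Return a copy with per-channel density multipliers applied."""
        cs = self.copy()
        for name, mult in multipliers.items():
            if name not in cs.densities:
                continue
            cs.densities[name] = {r: v * mult for r, v in cs.densities[name].items()}
        return cs

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        spec_d = {}
        for name, spec in self.specs.items():
            g = spec.gating
            entry = {"reversal": spec.reversal, "p": g.p, "q": g.q,
                     "carries_calcium": spec.carries_calcium}
            if isinstance(g.activation, VoltageGate):
                entry["activation"] = asdict(g.activation)
            elif isinstance(g.activation, CalciumGate):
                entry["calcium_activation"] = asdict(g.activation)
            if g.inactivation is not None:
                entry["inactivation"] = asdict(g.inactivation)
            spec_d[name] = entry
        return {"channels": spec_d,
                "densities": {n: dict(d) for n, d in self.densities.items()},
                "calcium_pool": asdict(self.calcium)}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSet":
        specs = {}
        for name, entry in d["channels"].items():
            act = None
            if "activation" in entry:
                act = VoltageGate(**entry["activation"])
            elif "calcium_activation" in entry:
                act = CalciumGate(**entry["calcium_activation"])
            inact = VoltageGate(**entry["inactivation"]) if "inactivation" in entry else None
            gating = GatingScheme(entry.get("p", 1), entry.get("q", 0), act, inact)
            specs[name] = ChannelSpec(name, entry["reversal"], gating,
                                      entry.get("carries_calcium", False))
        pool = CalciumPool(**d.get("calcium_pool", {}))
        return cls(specs, d.get("densities", {}), pool)

    @classmethod
    def from_yaml(cls, text: str) -> "ChannelSet":
        return cls.from_dict(yaml.safe_load(text))


def reference_channelset(cell_id: int, e_leak: float = -70.0,
                         leak_density: float = 1.0,
                         calcium: CalciumPool | None = None) -> ChannelSet:
    """ChannelSet with the published regional densities for cell 1 or cell 2.

    ``leak_density`` (pS/um^2, uniform) and ``e_leak`` are not part of the
    published table and are explicit parameters here.
    """
    if cell_id not in TABLE1_DENSITIES:
        raise ValueError(f"cell_id must be 1 or 2, got {cell_id}")
    specs = default_gating()
    specs["leak"] = ChannelSpec("leak", e_leak, GatingScheme(0, 0))
    densities = copy.deepcopy(TABLE1_DENSITIES[cell_id])
    densities["leak"] = {r: leak_density for r in REGIONS}
    return ChannelSet(specs, densities, calcium)
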