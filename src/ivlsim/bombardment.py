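"""In vivo-like synaptic bombardment: placement, trains, and parameter search.

An input ensemble is described by (N_E, N_I, f_E, f_I): counts of excitatory
and inhibitory synapses and their presynaptic Poisson rates.  Synapses are
placed uniformly per unit membrane area over the dendritic compartments.
Inhibitory synapses split into thirds across the IS3 / MS / BIS presynaptic
classes; excitatory synapses are PYR.  Synapses share presynaptic trains in
connection groups (common input), with per-cell group sizes.

Two derived scalars summarize an ensemble's drive:

    EI metric    = N_E * f_E - N_I * f_I    (excitation/inhibition balance)
    total input  = N_E * f_E + N_I * f_I

both in synapses x Hz.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import Morphology
from .synapses import SYNAPSE_CLASSES, PlacedSynapse, SynapseBank

__all__ = [
    "InputParameterSet",
    "CellInputConfig",
    "CELL_INPUT_CONFIGS",
    "BombardmentRealization",
    "SparseSearchResult",
    "allocate_inhibitory_classes",
    "generate_trains",
    "poisson_train",
    "ei_metric",
    "total_input",
    "grid_search",
    "sparse_search",
]

INHIBITORY_CLASSES = ("IS3", "MS", "BIS")


@dataclass(frozen=True)
class InputParameterSet:
    """(N_E, N_I, f_E, f_I) bombardment descriptor."""

    n_exc: int
    n_inh: int
    f_exc: float  # Hz
    f_inh: float  # Hz

    def __post_init__(self):
        if self.n_exc < 0 or self.n_inh < 0:
            raise ValueError("synapse counts must be >= 0")
        if self.f_exc < 0 or self.f_inh < 0:
            raise ValueError("rates must be >= 0")

    def astuple(self):
        return (self.n_exc, self.n_inh, self.f_exc, self.f_inh)


def ei_metric(params: InputParameterSet) -> float:
    """N_E * f_E - N_I * f_I (synapses x Hz)."""
    return params.n_exc * params.f_exc - params.n_inh * params.f_inh


def total_input(params: InputParameterSet) -> float:
    """N_E * f_E + N_I * f_I (synapses x Hz)."""
    return params.n_exc * params.f_exc + params.n_inh * params.f_inh


@dataclass(frozen=True)
class CellInputConfig:
    """Grid maxima/resolutions and connection-group sizes for one cell."""

    exc_max: int
    exc_step: int
    inh_max: int
    inh_step: int
    exc_per_connection: int
    inh_per_connection: int
    exc_rate_max: float = 30.0
    exc_rate_step: float = 5.0
    inh_rate_max: float = 100.0
    inh_rate_step: float = 10.0

    def __post_init__(self):
        if self.exc_step <= 0 or self.inh_step <= 0:
            raise ValueError("grid resolutions must be positive")
        if self.inh_step % 3:
            raise ValueError("inhibitory resolution must be divisible by 3 "
                             "(IS3/MS/BIS class split)")

    def exc_grid(self):
        return list(range(0, self.exc_max + 1, self.exc_step))

    def inh_grid(self):
        return list(range(0, self.inh_max + 1, self.inh_step))

    def exc_rate_grid(self):
        n = int(round(self.exc_rate_max / self.exc_rate_step))
        return [k * self.exc_rate_step for k in range(n + 1)]

    def inh_rate_grid(self):
        n = int(round(self.inh_rate_max / self.inh_rate_step))
        return [k * self.inh_rate_step for k in range(n + 1)]


CELL_INPUT_CONFIGS: dict[int, CellInputConfig] = {
    1: CellInputConfig(exc_max=4641, exc_step=35, inh_max=1989, inh_step=24,
                       exc_per_connection=7, inh_per_connection=8),
    2: CellInputConfig(exc_max=6012, exc_step=45, inh_max=3006, inh_step=36,
                       exc_per_connection=9, inh_per_connection=12),
}


def allocate_inhibitory_classes(n_inh: int,
                                cfg: CellInputConfig | None = None) -> dict[str, int]:
    """Split inhibitory synapses into thirds across IS3 / MS / BIS.

    Remainders are assigned round-robin in IS3 -> MS -> BIS order.
    """
    if n_inh < 0:
        raise ValueError("n_inh must be >= 0")
    base = n_inh // 3
    counts = {cls: base for cls in INHIBITORY_CLASSES}
    for k in range(n_inh - 3 * base):
        counts[INHIBITORY_CLASSES[k]] += 1
    return counts


def poisson_train(rate_hz: float, duration_ms: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times (ms) on [0, duration)."""
    if rate_hz <= 0:
        return np.zeros(0)
    rate_per_ms = rate_hz / 1000.0
    n_guess = int(rate_per_ms * duration_ms + 6 * math.sqrt(rate_per_ms * duration_ms) + 16)
    times = np.cumsum(rng.exponential(1.0 / rate_per_ms, size=n_guess))
    while times.size and times[-1] < duration_ms:
        times = np.concatenate([
            times, times[-1] + np.cumsum(rng.exponential(1.0 / rate_per_ms, size=n_guess))])
    return times[times < duration_ms]


@dataclass
class BombardmentRealization:
    """One seeded realization: placements, connection groups and trains."""

    params: InputParameterSet
    placement: np.ndarray  # compartment index per synapse
    classes: list[str]  # presynaptic class per synapse
    connections: list[np.ndarray]  # synapse indices per connection
    trains: list[np.ndarray]  # event times (ms) per connection
    bank: SynapseBank
    seed: int


def _place(rng: np.random.Generator, n: int, dend: np.ndarray,
           weights: np.ndarray) -> np.ndarray:
    return rng.choice(dend, size=n, p=weights)


def generate_trains(params: InputParameterSet, cfg: CellInputConfig,
                    duration: float, seed: int, morph: Morphology,
                    weight_for=None) -> BombardmentRealization:
    """Build a fully seeded bombardment realization on ``morph``.

    Placement is uniform per unit dendritic membrane area; synapses are
    grouped into connections of ``cfg.*_per_connection`` members (the last
    group may be partial) and every connection carries one Poisson train at
    f_E or f_I delivered to all members.  ``weight_for(cls, compartment)``
    supplies per-synapse weights in uS (default 1e-4).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    dend = morph.dendritic_indices
    if dend.size == 0 and (params.n_exc > 0 or params.n_inh > 0):
        raise ValueError("morphology has no dendritic compartments to place "
                         "synapses on")
    rng = np.random.default_rng(seed)
    if weight_for is None:
        weight_for = lambda cls, comp: 1e-4  # noqa: E731

    areas = morph.areas[dend] if dend.size else np.zeros(0)
    area_w = areas / areas.sum() if dend.size else areas

    classes: list[str] = ["PYR"] * params.n_exc
    alloc = allocate_inhibitory_classes(params.n_inh, cfg)
    for cls in INHIBITORY_CLASSES:
        classes += [cls] * alloc[cls]
    n_total = len(classes)
    placement = np.zeros(n_total, dtype=np.int64)
    if params.n_exc:
        placement[:params.n_exc] = _place(rng, params.n_exc, dend, area_w)
    if params.n_inh:
        placement[params.n_exc:] = _place(rng, params.n_inh, dend, area_w)

    # connection grouping: consecutive synapses within each pool
    connections: list[np.ndarray] = []
    rates: list[float] = []
    exc_idx = np.arange(params.n_exc)
    for k in range(0, params.n_exc, cfg.exc_per_connection):
        connections.append(exc_idx[k:k + cfg.exc_per_connection])
        rates.append(params.f_exc)
    inh_idx = np.arange(params.n_exc, n_total)
    for k in range(0, params.n_inh, cfg.inh_per_connection):
        connections.append(inh_idx[k:k + cfg.inh_per_connection])
        rates.append(params.f_inh)

    trains = [poisson_train(r, duration, rng) for r in rates]

    bank = SynapseBank()
    events_per_syn: dict[int, np.ndarray] = {}
    for members, train in zip(connections, trains):
        for s in members:
            events_per_syn[int(s)] = train
    for s in range(n_total):
        cls = classes[s]
        tau_r, tau_d, e_rev = SYNAPSE_CLASSES[cls]
        comp = int(placement[s])
        bank.append(PlacedSynapse(cls, comp, tau_r, tau_d, e_rev,
                                  float(weight_for(cls, comp)),
                                  events_per_syn.get(s, np.zeros(0))))
    return BombardmentRealization(params, placement, classes, connections,
                                  trains, bank, seed)


def grid_search(model, cfg: CellInputConfig, grids: dict | None = None,
                sims_per_point: int = 1, duration: float = 10000.0,
                seed: int = 0) -> pd.DataFrame:
    """Score every grid point; one row per (N_E, N_I, f_E, f_I).

    ``grids`` maps ``n_exc``/``n_inh``/``f_exc``/``f_inh`` to value lists
    (defaults: the full per-cell grids).  ``model`` must expose
    ``score_ivl(params, seed, duration=...) -> int``.  Deterministic given
    ``seed``; rows sorted by parameters.
    """
    from .metrics import derive_seeds
    if grids is None:
        grids = {}
    g_ne = grids.get("n_exc", cfg.exc_grid())
    g_ni = grids.get("n_inh", cfg.inh_grid())
    g_fe = grids.get("f_exc", cfg.exc_rate_grid())
    g_fi = grids.get("f_inh", cfg.inh_rate_grid())
    for name, g, mx in (("n_exc", g_ne, cfg.exc_max), ("n_inh", g_ni, cfg.inh_max),
                        ("f_exc", g_fe, cfg.exc_rate_max), ("f_inh", g_fi, cfg.inh_rate_max)):
        if len(g) == 0:
            raise ValueError(f"empty grid for {name}")
        if max(g) > mx:
            raise ValueError(f"grid for {name} exceeds configured maximum {mx}")

    points = sorted(itertools.product(g_ne, g_ni, g_fe, g_fi))
    rows = []
    for pt_idx, (ne, ni, fe, fi) in enumerate(points):
        params = InputParameterSet(ne, ni, fe, fi)
        seeds = derive_seeds(seed + pt_idx, sims_per_point)
        scores = [int(model.score_ivl(params, s, duration=duration))
                  for s in seeds]
        row = {"n_exc": ne, "n_inh": ni, "f_exc": fe, "f_inh": fi,
               "ei": ei_metric(params), "total": total_input(params),
               "mean_score": float(np.mean(scores)),
               "max_score": int(np.max(scores))}
        for j, s in enumerate(scores):
            row[f"score_{j}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SparseSearchResult:
    found: bool
    params: InputParameterSet | None
    n_evaluated: int
    verdicts: tuple = ()


def sparse_search(model, cfg: CellInputConfig, ei_range: tuple[float, float],
                  bounds: dict | None = None, fine_resolution: int = 1,
                  seed: int = 0, n_seeds: int = 10,
                  evaluate=None, max_candidates: int | None = None,
                  duration: float = 10000.0) -> SparseSearchResult:
    """Fine-resolution search for the sparsest consistently-IVL input set.

    Candidates with EI metric inside ``ei_range`` are enumerated at
    ``fine_resolution`` steps (1 synapse / 1 Hz by default) within
    ``bounds`` (dict of ``n_exc``/``n_inh``/``f_exc``/``f_inh`` (lo, hi)
    ranges), visited in ascending total input (ties broken lexicographically
    by (N_E, N_I, f_E, f_I)), and each is tested with the ten-seed
    consistency rule until one passes.  ``evaluate(params) -> bool`` may
    replace the default model-based consistency test.
    """
    from .metrics import consistency
    lo, hi = ei_range
    if hi < lo:
        raise ValueError("ei_range is empty")
    if bounds is None:
        bounds = {"n_exc": (0, 20), "n_inh": (0, 20),
                  "f_exc": (0, 10), "f_inh": (0, 10)}
    r = int(fine_resolution)

    def _axis(name):
        a, b = bounds[name]
        return range(int(a), int(b) + 1, r)

    candidates = []
    for ne in _axis("n_exc"):
        for ni in _axis("n_inh"):
            for fe in _axis("f_exc"):
                for fi in _axis("f_inh"):
                    p = InputParameterSet(ne, ni, float(fe), float(fi))
                    if lo <= ei_metric(p) <= hi:
                        candidates.append(p)
    candidates.sort(key=lambda p: (total_input(p),) + p.astuple())
    if max_candidates is not None:
        candidates = candidates[:max_candidates]

    verdicts = []
    for k, params in enumerate(candidates, 1):
        if evaluate is not None:
            ok = bool(evaluate(params))
        else:
            ok = consistency(model, params, n_seeds=n_seeds, master_seed=seed,
                             duration=duration).consistent
        verdicts.append((params, ok))
        if ok:
            return SparseSearchResult(True, params, k, tuple(verdicts))
    return SparseSearchResult(False, None, len(candidates), tuple(verdicts))
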