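"""Compartmental membrane-equation solver.

The membrane potential is integrated on the compartment tree with a
Crank-Nicolson scheme (theta = 1/2): the voltage-linear part (ionic and
synaptic conductances, axial coupling) is treated semi-implicitly and solved
by a tree-ordered (Hines) direct elimination, which is unconditionally
stable for the passive subsystem.  Gating variables advance by exponential
Euler against the start-of-step voltage.  Per-channel currents are recorded
at the Crank-Nicolson midpoint voltage of each step, so the discrete charge
balance  C dV/dt + I_ion + I_syn - I_axial - I_inj = 0  holds to round-off.

Units: mV, ms, uS, nA internally; recorded currents are in pA
(inward negative, outward positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSet, VoltageGate, CalciumGate
from .morphology import Morphology

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "CurrentStep",
    "VoltageClamp",
    "StimulusProtocol",
    "TraceSet",
    "SimulationError",
    "simulate",
    "resting_state",
    "electrotonic_profile",
    "rheobase",
]


class SimulationError(RuntimeError):
    """Raised when the integration diverges or a contract is violated."""


@dataclass(frozen=True)
class CurrentStep:
    """Somatic/dendritic current injection (pA) between onset and offset (ms)."""

    site: str | int
    amplitude: float  # pA
    onset: float = 0.0
    offset: float = math.inf


@dataclass(frozen=True)
class VoltageClamp:
    """Ideal (zero series resistance) voltage clamp at one site."""

    site: str | int
    holding: float  # mV


@dataclass
class StimulusProtocol:
    """Stimulation, synaptic drive and recording plan for one simulation."""

    duration: float  # ms
    dt: float = 0.025  # ms
    steps: list[CurrentStep] = field(default_factory=list)
    clamp: VoltageClamp | None = None
    synapses: object | None = None  # SynapseBank
    record_sites: list[str] | str | None = None  # None -> named sites; "all"
    v_init: float | None = None  # None -> leak reversal

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.clamp is not None:
            for s in self.steps:
                if s.site == self.clamp.site:
                    raise ValueError(
                        "voltage clamp and current injection at the same site")


@dataclass
class TraceSet:
    """Time-aligned voltage and per-channel current traces at named sites.

    ``currents`` has shape (n_sites, n_names, n_t) in pA; ``names`` lists the
    channel types followed by ``syn_exc``/``syn_inh`` pools.  Inward currents
    are negative, outward positive.
    """

    time: np.ndarray  # ms
    sites: list[str]
    names: list[str]
    voltage: np.ndarray  # (n_sites, n_t) mV
    currents: np.ndarray  # (n_sites, n_names, n_t) pA
    clamp_current: np.ndarray | None = None  # pA
    dt: float = 0.025
    meta: dict = field(default_factory=dict)

    def site_index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"unknown recording site {site!r}") from None

    def current(self, site: str, name: str) -> np.ndarray:
        return self.currents[self.site_index(site), self.names.index(name)]

    def total_inward(self, site: str) -> np.ndarray:
        """Sum of negative-valued channel + synaptic currents per sample (pA)."""
        c = self.currents[self.site_index(site)]
        return np.minimum(c, 0.0).sum(axis=0)

    def total_outward(self, site: str) -> np.ndarray:
        c = self.currents[self.site_index(site)]
        return np.maximum(c, 0.0).sum(axis=0)

    def window(self, t_start: float, t_stop: float | None = None) -> "TraceSet":
        """Sub-trace restricted to [t_start, t_stop]."""
        t = self.time
        stop = t[-1] if t_stop is None else t_stop
        mask = (t >= t_start - 1e-9) & (t <= stop + 1e-9)
        return TraceSet(t[mask], list(self.sites), list(self.names),
                        self.voltage[:, mask], self.currents[:, :, mask],
                        None if self.clamp_current is None else self.clamp_current[mask],
                        self.dt, dict(self.meta))


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_kernel(n_steps, dt, theta,
                parent, g_ax, c_nf,
                gbar, e_rev, p_exp, q_exp,
                a_vh, a_k, a_tb, a_ta, a_vp, a_s1, a_s2,
                i_vh, i_k, i_tb, i_ta, i_vp, i_s1, i_s2, has_inact,
                ca_act, ca_kd, ca_gtau,
                carries_ca, ca_tau, ca_kin, ca_rest, area,
                syn_comp, syn_e, syn_dr, syn_dd, syn_exc,
                ev_step, ev_group, ev_amt,
                stim_comp, stim_on, stim_off, stim_amp,
                clamp_comp, clamp_v,
                rec_idx,
                v, m, h, ca,
                rec_v, rec_i, rec_syn, rec_clamp):
    n = parent.shape[0]
    nch = e_rev.shape[0]
    ng = syn_comp.shape[0]
    nr = rec_idx.shape[0]

    gfac = np.zeros((n, nch))
    syn_a = np.zeros(ng)
    syn_b = np.zeros(ng)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    vnew = np.zeros(n)
    gs = np.zeros(n)
    ges = np.zeros(n)
    inj = np.zeros(n)

    # initial instantaneous record (gates at their initial values, V at t=0)
    for i in range(n):
        for c in range(nch):
            gb = gbar[i, c]
            if gb == 0.0:
                continue
            gf = gb
            for _ in range(p_exp[c]):
                gf *= m[i, c]
            for _ in range(q_exp[c]):
                gf *= h[i, c]
            gfac[i, c] = gf
    for r in range(nr):
        i = rec_idx[r]
        rec_v[0, r] = v[i]
        for c in range(nch):
            rec_i[0, r, c] = gfac[i, c] * (v[i] - e_rev[c]) * 1000.0

    ep = 0
    ne = ev_step.shape[0]
    for k in range(n_steps):
        # deliver synaptic events scheduled for this step
        while ep < ne and ev_step[ep] == k:
            g = ev_group[ep]
            syn_a[g] += ev_amt[ep]
            syn_b[g] += ev_amt[ep]
            ep += 1

        # gating update (exponential Euler vs start-of-step voltage)
        for i in range(n):
            vi = v[i]
            for c in range(nch):
                gb = gbar[i, c]
                if gb == 0.0:
                    continue
                if p_exp[c] > 0:
                    if ca_act[c]:
                        cai = ca[i]
                        minf = cai / (cai + ca_kd[c])
                        tau = ca_gtau[c]
                    else:
                        minf = 1.0 / (1.0 + math.exp(-(vi - a_vh[c]) / a_k[c]))
                        tau = a_tb[c] + a_ta[c] / (
                            math.exp((vi - a_vp[c]) / a_s1[c])
                            + math.exp(-(vi - a_vp[c]) / a_s2[c]))
                    m[i, c] = minf + (m[i, c] - minf) * math.exp(-dt / tau)
                if q_exp[c] > 0:
                    hinf = 1.0 / (1.0 + math.exp(-(vi - i_vh[c]) / i_k[c]))
                    tauh = i_tb[c] + i_ta[c] / (
                        math.exp((vi - i_vp[c]) / i_s1[c])
                        + math.exp(-(vi - i_vp[c]) / i_s2[c]))
                    h[i, c] = hinf + (h[i, c] - hinf) * math.exp(-dt / tauh)
                gf = gb
                for _ in range(p_exp[c]):
                    gf *= m[i, c]
                for _ in range(q_exp[c]):
                    gf *= h[i, c]
                gfac[i, c] = gf

        # conductance sums
        for i in range(n):
            s = 0.0
            se = 0.0
            for c in range(nch):
                gf = gfac[i, c]
                if gf != 0.0:
                    s += gf
                    se += gf * e_rev[c]
            gs[i] = s
            ges[i] = se
        for g in range(ng):
            gsyn = syn_b[g] - syn_a[g]
            cgi = syn_comp[g]
            gs[cgi] += gsyn
            ges[cgi] += gsyn * syn_e[g]

        # injected currents (nA)
        for i in range(n):
            inj[i] = 0.0
        for s in range(stim_comp.shape[0]):
            if stim_on[s] <= k < stim_off[s]:
                inj[stim_comp[s]] += stim_amp[s]

        # assemble Crank-Nicolson system on the tree
        for i in range(n):
            gax_sum = 0.0
            if parent[i] >= 0:
                gax_sum += g_ax[i]
            # children contributions added below
            diag[i] = c_nf[i] / dt + theta * gs[i]
            rhs[i] = (c_nf[i] / dt - (1.0 - theta) * gs[i]) * v[i] + ges[i] + inj[i]
        for i in range(1, n):
            pi = parent[i]
            gax = g_ax[i]
            diag[i] += theta * gax
            diag[pi] += theta * gax
            rhs[i] += (1.0 - theta) * gax * (v[pi] - v[i])
            rhs[pi] += (1.0 - theta) * gax * (v[i] - v[pi])

        if clamp_comp >= 0:
            cc = clamp_comp
            diag[cc] = 1.0
            rhs[cc] = clamp_v

        # Hines elimination: leaves to root (children have larger indices)
        for i in range(n - 1, 0, -1):
            pi = parent[i]
            gax = theta * g_ax[i]
            if i == clamp_comp:
                # known voltage: move coupling term to parent's RHS
                rhs[pi] += gax * clamp_v
                continue
            if pi == clamp_comp:
                rhs[i] += gax * clamp_v
                continue
            f = gax / diag[i]
            diag[pi] -= f * gax
            rhs[pi] += f * rhs[i]
        vnew[0] = rhs[0] / diag[0]
        for i in range(1, n):
            pi = parent[i]
            if i == clamp_comp:
                vnew[i] = clamp_v
            elif pi == clamp_comp:
                vnew[i] = rhs[i] / diag[i]
            else:
                vnew[i] = (rhs[i] + theta * g_ax[i] * vnew[pi]) / diag[i]

        # divergence guard
        for i in range(n):
            if not math.isfinite(vnew[i]) or vnew[i] > 200.0 or vnew[i] < -200.0:
                return 1, k, i

        # calcium pool update at midpoint voltage
        for i in range(n):
            vm = theta * vnew[i] + (1.0 - theta) * v[i]
            influx = 0.0
            for c in range(nch):
                if carries_ca[c] and gfac[i, c] != 0.0:
                    ica = gfac[i, c] * (vm - e_rev[c])  # nA
                    if ica < 0.0:
                        influx += -ica * 1000.0 / area[i]  # pA/um^2
            target = ca_rest + ca_tau * ca_kin * influx
            ca[i] = target + (ca[i] - target) * math.exp(-dt / ca_tau)

        # record at sites (currents at midpoint voltage of this step)
        for r in range(nr):
            i = rec_idx[r]
            vm = theta * vnew[i] + (1.0 - theta) * v[i]
            rec_v[k + 1, r] = vnew[i]
            for c in range(nch):
                rec_i[k + 1, r, c] = gfac[i, c] * (vm - e_rev[c]) * 1000.0
            rec_syn[k + 1, r, 0] = 0.0
            rec_syn[k + 1, r, 1] = 0.0
        for g in range(ng):
            cgi = syn_comp[g]
            for r in range(nr):
                if rec_idx[r] == cgi:
                    vm = theta * vnew[cgi] + (1.0 - theta) * v[cgi]
                    cur = (syn_b[g] - syn_a[g]) * (vm - syn_e[g]) * 1000.0
                    if syn_exc[g]:
                        rec_syn[k + 1, r, 0] += cur
                    else:
                        rec_syn[k + 1, r, 1] += cur

        # clamp (electrode) current: membrane + synaptic - axial at clamp site
        if clamp_comp >= 0:
            cc = clamp_comp
            vm = clamp_v
            imem = gs[cc] * vm - ges[cc]  # nA outward
            iax = 0.0
            if parent[cc] >= 0:
                pcc = parent[cc]
                vmp = theta * vnew[pcc] + (1.0 - theta) * v[pcc]
                iax += g_ax[cc] * (vmp - vm)
            for j in range(1, n):
                if parent[j] == cc:
                    vmj = theta * vnew[j] + (1.0 - theta) * v[j]
                    iax += g_ax[j] * (vmj - vm)
            rec_clamp[k + 1] = (imem - iax - inj[cc]) * 1000.0  # pA

        # advance
        for i in range(n):
            v[i] = vnew[i]
        for g in range(ng):
            syn_a[g] *= syn_dr[g]
            syn_b[g] *= syn_dd[g]

    return 0, -1, -1


# ---------------------------------------------------------------------------
# packing and driver
# ---------------------------------------------------------------------------

def _gate_params(gate, default_vh=0.0):
    if isinstance(gate, VoltageGate):
        return (gate.v_half, gate.k, gate.tau_base, gate.tau_amp,
                gate.v_peak, gate.s1, gate.s2)
    return (default_vh, 1.0, 1.0, 0.0, 0.0, 15.0, 15.0)


def _pack_channels(channels: ChannelSet, morph: Morphology):
    names = channels.names
    nch = len(names)
    dens = channels.density_matrix(morph.region_label)  # pS/um^2
    gbar = dens * morph.areas[:, None] * 1e-6  # uS
    e_rev = np.zeros(nch)
    p_exp = np.zeros(nch, dtype=np.int64)
    q_exp = np.zeros(nch, dtype=np.int64)
    a = np.zeros((7, nch))
    b = np.zeros((7, nch))
    has_inact = np.zeros(nch, dtype=np.bool_)
    ca_act = np.zeros(nch, dtype=np.bool_)
    ca_kd = np.ones(nch)
    ca_gtau = np.ones(nch)
    carries = np.zeros(nch, dtype=np.bool_)
    for j, name in enumerate(names):
        spec = channels.specs[name]
        e_rev[j] = spec.reversal
        carries[j] = spec.carries_calcium
        g = spec.gating
        p_exp[j] = g.p
        q_exp[j] = g.q
        if isinstance(g.activation, CalciumGate):
            ca_act[j] = True
            ca_kd[j] = g.activation.kd
            ca_gtau[j] = g.activation.tau
        elif g.activation is not None:
            a[:, j] = _gate_params(g.activation)
        if g.inactivation is not None:
            has_inact[j] = True
            b[:, j] = _gate_params(g.inactivation)
    return names, gbar, e_rev, p_exp, q_exp, a, b, has_inact, ca_act, ca_kd, ca_gtau, carries


def _initial_gates(channels: ChannelSet, names, v0: np.ndarray, ca0: np.ndarray):
    n = v0.shape[0]
    nch = len(names)
    m0 = np.ones((n, nch))
    h0 = np.ones((n, nch))
    for j, name in enumerate(names):
        g = channels.specs[name].gating
        if g.p > 0:
            if isinstance(g.activation, CalciumGate):
                m0[:, j] = g.activation.steady_state(ca0)
            else:
                m0[:, j] = g.activation.steady_state(v0)
        if g.q > 0:
            h0[:, j] = g.inactivation.steady_state(v0)
    return m0, h0


def _resolve_site(morph: Morphology, site) -> int:
    if isinstance(site, (int, np.integer)):
        idx = int(site)
        if not 0 <= idx < morph.n:
            raise KeyError(f"compartment index {idx} out of range")
        return idx
    if site in morph.sites:
        return morph.sites[site]
    raise KeyError(f"unknown site {site!r}")


def _pack_synapse_bank(bank, dt: float, n_steps: int):
    """Group synapses by (compartment, kinetics, reversal); merge their events.

    Dual-exponential conductances are linear in their state variables, so
    synapses sharing compartment and kinetics can pool their two-state
    (rise/decay) variables; each event adds weight*factor to both.
    """
    from .synapses import peak_factor
    if bank is None or len(bank) == 0:
        z = np.zeros(0)
        zi = np.zeros(0, dtype=np.int64)
        return (zi, z, z.copy() + 1, z.copy() + 1, np.zeros(0, dtype=np.bool_),
                zi.copy(), zi.copy(), z.copy())
    groups: dict[tuple, int] = {}
    g_comp, g_e, g_tr, g_td = [], [], [], []
    ev_step_l, ev_group_l, ev_amt_l = [], [], []
    for syn in bank:
        key = (syn.compartment, round(syn.tau_r, 9), round(syn.tau_d, 9), syn.reversal)
        if key not in groups:
            groups[key] = len(g_comp)
            g_comp.append(syn.compartment)
            g_e.append(syn.reversal)
            g_tr.append(syn.tau_r)
            g_td.append(syn.tau_d)
        gi = groups[key]
        amt = syn.weight * peak_factor(syn.tau_r, syn.tau_d)
        for t in syn.events:
            step = int(round(t / dt))
            if 0 <= step < n_steps:
                ev_step_l.append(step)
                ev_group_l.append(gi)
                ev_amt_l.append(amt)
    g_comp = np.array(g_comp, dtype=np.int64)
    g_e = np.array(g_e)
    syn_dr = np.exp(-dt / np.array(g_tr))
    syn_dd = np.exp(-dt / np.array(g_td))
    syn_exc = g_e >= -40.0
    ev_step = np.array(ev_step_l, dtype=np.int64)
    ev_group = np.array(ev_group_l, dtype=np.int64)
    ev_amt = np.array(ev_amt_l)
    order = np.argsort(ev_step, kind="stable")
    return (g_comp, g_e, syn_dr, syn_dd, syn_exc,
            ev_step[order], ev_group[order], ev_amt[order])


def simulate(morph: Morphology, channels: ChannelSet,
             protocol: StimulusProtocol, seed: int = 0,
             initial_state: dict | None = None) -> TraceSet:
    """Integrate the model and return voltage/current traces at the
    requested recording sites.

    ``seed`` is accepted for interface uniformity; the solver itself is
    deterministic (randomness lives in the synaptic event schedules carried
    by the protocol).  ``initial_state`` may carry ``v``, ``m``, ``h``,
    ``ca`` arrays (e.g. from :func:`resting_state`).
    """
    dt = protocol.dt
    n_steps = int(round(protocol.duration / dt))
    if n_steps <= 0:
        raise ValueError("duration shorter than one step")

    (names, gbar, e_rev, p_exp, q_exp, act, inact, has_inact,
     ca_act, ca_kd, ca_gtau, carries) = _pack_channels(channels, morph)

    c_nf = (np.array([c.specific_capacitance for c in morph.compartments])
            * morph.areas * 1e-5)  # nF
    g_ax = morph.axial_conductances()
    parent = morph.parent_index

    pool = channels.calcium
    v0 = np.full(morph.n, channels.e_leak if protocol.v_init is None
                 else protocol.v_init, dtype=float)
    ca0 = np.full(morph.n, pool.ca_rest)
    m0, h0 = _initial_gates(channels, names, v0, ca0)
    if initial_state is not None:
        v0 = initial_state["v"].copy()
        m0 = initial_state["m"].copy()
        h0 = initial_state["h"].copy()
        ca0 = initial_state["ca"].copy()

    # stimuli
    stim_comp, stim_on, stim_off, stim_amp = [], [], [], []
    for s in protocol.steps:
        stim_comp.append(_resolve_site(morph, s.site))
        stim_on.append(max(0, int(round(s.onset / dt))))
        stim_off.append(n_steps if math.isinf(s.offset)
                        else int(round(s.offset / dt)))
        stim_amp.append(s.amplitude * 1e-3)  # pA -> nA
    stim_comp = np.array(stim_comp, dtype=np.int64)
    stim_on = np.array(stim_on, dtype=np.int64)
    stim_off = np.array(stim_off, dtype=np.int64)
    stim_amp = np.array(stim_amp, dtype=float)

    clamp_comp, clamp_v = -1, 0.0
    if protocol.clamp is not None:
        clamp_comp = _resolve_site(morph, protocol.clamp.site)
        clamp_v = float(protocol.clamp.holding)
        v0[clamp_comp] = clamp_v

    # recording sites
    if protocol.record_sites == "all":
        rec_idx = np.arange(morph.n, dtype=np.int64)
        site_names = [f"C{i}" for i in range(morph.n)]
        inv = {v: k for k, v in morph.sites.items()}
        site_names = [inv.get(i, f"C{i}") for i in range(morph.n)]
    else:
        wanted = (list(morph.sites) if protocol.record_sites is None
                  else list(protocol.record_sites))
        rec_idx = np.array([_resolve_site(morph, s) for s in wanted], dtype=np.int64)
        site_names = [s if isinstance(s, str) else f"C{s}" for s in wanted]

    syn_pack = _pack_synapse_bank(protocol.synapses, dt, n_steps)

    nt = n_steps + 1
    nr = rec_idx.shape[0]
    rec_v = np.zeros((nt, nr))
    rec_i = np.zeros((nt, nr, len(names)))
    rec_syn = np.zeros((nt, nr, 2))
    rec_clamp = np.zeros(nt)

    status, bad_step, bad_comp = _run_kernel(
        n_steps, dt, 0.5,
        parent, g_ax, c_nf,
        gbar, e_rev, p_exp, q_exp,
        act[0], act[1], act[2], act[3], act[4], act[5], act[6],
        inact[0], inact[1], inact[2], inact[3], inact[4], inact[5], inact[6],
        has_inact, ca_act, ca_kd, ca_gtau,
        carries, pool.tau, pool.k_in, pool.ca_rest, morph.areas,
        *syn_pack,
        stim_comp, stim_on, stim_off, stim_amp,
        clamp_comp, clamp_v,
        rec_idx,
        v0, m0, h0, ca0,
        rec_v, rec_i, rec_syn, rec_clamp)
    if status != 0:
        raise SimulationError(
            f"integration diverged at t = {bad_step * dt:.3f} ms "
            f"in compartment {bad_comp}")

    time = np.arange(nt) * dt
    currents = np.concatenate([rec_i, rec_syn], axis=2).transpose(1, 2, 0)
    meta = {"final_state": {"v": v0, "m": m0, "h": h0, "ca": ca0}}
    return TraceSet(time, site_names, list(names) + ["syn_exc", "syn_inh"],
                    rec_v.T.copy(), currents.copy(),
                    rec_clamp if clamp_comp >= 0 else None, dt, meta)


def resting_state(morph: Morphology, channels: ChannelSet,
                  settle: float = 1000.0, dt: float = 0.025) -> dict:
    """Settle the unstimulated model and return its state arrays."""
    proto = StimulusProtocol(duration=settle, dt=dt, record_sites="all")
    tr = simulate(morph, channels, proto)
    return tr.meta["final_state"]


def _frozen_conductance(morph: Morphology, channels: ChannelSet,
                        state: dict) -> np.ndarray:
    """Per-compartment total membrane conductance (uS) at a frozen state."""
    (names, gbar, e_rev, p_exp, q_exp, *_rest) = _pack_channels(channels, morph)
    m, h = state["m"], state["h"]
    g = np.zeros(morph.n)
    for j in range(len(names)):
        g += gbar[:, j] * m[:, j] ** p_exp[j] * h[:, j] ** q_exp[j]
    return g


def _steady_deflection(morph: Morphology, g_m: np.ndarray, inject: int) -> np.ndarray:
    """Linearized steady-state voltage deflection for unit current at one site."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla
    n = morph.n
    g_ax = morph.axial_conductances()
    rows, cols, vals = [], [], []
    diag = g_m.copy()
    for i in range(1, n):
        p = morph.parent_index[i]
        diag[i] += g_ax[i]
        diag[p] += g_ax[i]
        rows += [i, p]
        cols += [p, i]
        vals += [-g_ax[i], -g_ax[i]]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    a = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    b = np.zeros(n)
    b[inject] = 1.0  # nA
    return spla.spsolve(a, b)


def electrotonic_profile(morph: Morphology, channels: ChannelSet,
                         direction: str = "out_of_soma",
                         amplitude: float = 1.0,
                         settle: float = 1000.0) -> np.ndarray:
    """Per-compartment log10 voltage attenuation for a small steady signal.

    A subthreshold steady deflection (``amplitude`` mV at the injection
    site) is applied at the soma (``out_of_soma``) or at each terminal
    (``into_soma``); the returned value per compartment is the accumulated
    log10 of (voltage at the injection-side neighbour / voltage here) along
    the path, 0 at the injection site.  The computation linearizes the model
    around its resting state, which is valid only for small deflections.
    """
    if direction not in ("out_of_soma", "into_soma"):
        raise ValueError("direction must be 'out_of_soma' or 'into_soma'")
    if amplitude > 5.0:
        raise ValueError("deflection amplitude risks recruiting spiking; "
                         "use an amplitude of 1 mV scale")
    state = resting_state(morph, channels, settle=settle)
    g_m = _frozen_conductance(morph, channels, state)

    att = np.zeros(morph.n)
    if direction == "out_of_soma":
        dv = _steady_deflection(morph, g_m, 0)
        dv *= amplitude / dv[0]
        for i in range(1, morph.n):
            p = morph.parent_index[i]
            att[i] = att[p] + math.log10(abs(dv[p]) / abs(dv[i]))
        return att

    # into_soma: inject at the most distal terminal of each compartment's subtree
    terminals = morph.terminals()
    # deepest terminal per compartment
    deepest = np.arange(morph.n)
    depth = morph.path_distance.copy()
    best = depth.copy()
    for i in range(morph.n - 1, 0, -1):
        p = morph.parent_index[i]
        if best[i] > best[p]:
            best[p] = best[i]
            deepest[p] = deepest[i]
    for term in terminals:
        dv = _steady_deflection(morph, g_m, int(term))
        dv *= amplitude / dv[term]
        # walk from terminal to root, accumulating along the path
        path = [int(term)]
        while morph.parent_index[path[-1]] >= 0:
            path.append(int(morph.parent_index[path[-1]]))
        acc = 0.0
        prev = int(term)
        for node in path[1:]:
            acc += math.log10(abs(dv[prev]) / abs(dv[node]))
            if deepest[node] == term or node == 0:
                att[node] = acc
            prev = node
        att[term] = 0.0
    return att


def spike_count(trace: TraceSet, site: str = "S", threshold: float = -10.0,
                refractory: float = 3.0) -> int:
    """Count upward threshold crossings separated by at least ``refractory`` ms."""
    v = trace.voltage[trace.site_index(site)]
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return 0
    times = trace.time[crossings]
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return len(kept)


def rheobase(morph: Morphology, channels: ChannelSet,
             search_range: tuple[float, float] = (0.0, 500.0),
             duration: float = 1000.0, settle: float = 200.0,
             tol: float = 1.0, dt: float = 0.025) -> float:
    """Minimal somatic holding current (pA) eliciting at least one spike.

    Bisection between the bracketing bounds to ``tol`` pA; raises if the
    upper bound never spikes or the lower bound already does (range does not
    bracket the threshold).
    """
    lo, hi = map(float, search_range)
    if hi <= lo:
        raise ValueError("search range must satisfy lo < hi")
    state = resting_state(morph, channels, settle=settle, dt=dt)

    def spikes_at(i_pa: float) -> bool:
        proto = StimulusProtocol(
            duration=duration, dt=dt,
            steps=[CurrentStep("S", i_pa, onset=0.0)],
            record_sites=["S"])
        tr = simulate(morph, channels, proto, initial_state=state)
        return spike_count(tr, "S") >= 1

    if not spikes_at(hi):
        raise SimulationError(
            f"no spike at range maximum {hi} pA; model may never spike")
    if spikes_at(lo):
        raise SimulationError(
            f"spike already at range minimum {lo} pA; range does not bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi
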