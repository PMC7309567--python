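# Methods

## Model

`ivlsim` simulates reduced conductance-based models of hippocampal CA1
oriens lacunosum moleculare (OLM) interneurons and compares their
per-channel ionic currents between a quiescent, current-clamped "in vitro"
condition and a synaptically bombarded "in vivo-like" (IVL) condition.

### Membrane equation and solver

Each morphology is a tree of cylindrical compartments (soma root). Per
compartment the membrane equation is

    C dV/dt = -sum_c gbar_c m_c^p h_c^q (V - E_c) - g_syn (V - E_syn)
              + sum_neighbors g_ax (V_j - V) + I_inj

with units mV, ms, uS, nA internally (traces are reported in pA, inward
negative). The voltage-linear part is advanced by Crank-Nicolson
(theta = 1/2); the resulting symmetric tree system is solved exactly each
step by a tree-ordered (Hines) elimination, unconditionally stable for the
passive subsystem. Gating variables advance by exponential Euler against the
start-of-step voltage, which confines them to [0, 1] by construction.
Default step 0.025 ms. Per-channel currents are recorded at the
Crank-Nicolson midpoint voltage of each step, so the discrete charge balance
(capacitive + ionic + synaptic - axial - injected = 0) holds to round-off;
the test suite asserts this at 1e-6 relative.

An independent validation path (`fixtures.oracle_integrate`) integrates the
same equations with an explicit midpoint (RK2) scheme at 1/100 of the
production step and is used only in tests; the production solver matches it
within 0.1 mV on a 200 ms subthreshold bombardment of the fixture cell.

### Channels

Nine voltage/calcium-gated channel types plus leak: H (hyperpolarization-
activated, E = -30 mV), NaT, Kdrf, Kdrs, KA, M, CaT, CaL, KCa. All follow
the Hodgkin-Huxley form with Boltzmann steady states
`x_inf = 1/(1 + exp(-(V - Vh)/k))` and bell-shaped time constants
`tau(V) = tau_base + tau_amp / (exp((V - Vp)/s1) + exp(-(V - Vp)/s2))`.
The exact kinetic equations of the original models live in earlier model
papers and are out of scope here; the shipped "OLM-like" parameter set is a
documented generic default, chosen so the qualitative properties the
analyses rely on hold (fast transient Na with inactivation; fast/slow
delayed rectifiers; inactivating A-type; slow non-inactivating M; H
activated by hyperpolarization; low-threshold inactivating CaT; high-
threshold CaL; calcium-gated KCa), and every parameter is overridable
through `ChannelSet` configuration (YAML-serializable).

Calcium handling is a single-exponential pool per compartment fed by the
inward CaT + CaL current density:
`d[Ca]/dt = (ca_rest - [Ca])/tau + k_in * max(0, -I_Ca/area)` with package
defaults tau = 100 ms, k_in = 0.2 uM per (pA/um^2 ms), ca_rest = 0.05 uM.
KCa activates as `[Ca]/([Ca] + Kd)` with Kd = 2 uM, tau = 10 ms. The fixture
cells lengthen the pool decay to 300 ms (see below).

The regional maximal conductance densities of the two published OLM cell
models (cell 1 / cell 2) ship as `TABLE1_DENSITIES` (pS/um^2; soma,
dendrites, axon; CaT/CaL/KCa dendrites-only). Leak density, leak reversal,
axial resistivity (150 Ohm cm) and specific capacitance (1 uF/cm^2) are not
part of that table and are explicit configuration with the defaults stated
here. Dendritic H is uniform by default.

### Synapses

Dual-exponential conductances `g(t) = w * factor * (exp(-t/tau_d) -
exp(-t/tau_r))`, with `factor` normalizing the peak to the weight exactly
and `i = g (V - E)`, outward positive. Four presynaptic classes drive OLM
cells: PYR (excitatory, E = 0 mV) and IS3 / MS / BIS (inhibitory,
E = -80 mV), with target PSC amplitudes 13.9 / 23.0 / 16.9 / -12.14 pA and
the corresponding rise/decay constants packaged in `TABLE2_TARGETS`. Because
the waveform is linear in its two state variables, synapses sharing a
compartment and kinetics are pooled in the solver; events increment the pool.

Weight fitting mirrors the experimental calibration: one synaptic event
under an ideal (zero series resistance) somatic voltage clamp at 0 mV for
IPSC targets and -60 mV for EPSC targets, with all voltage-gated channels
blocked and the leak reversal moved to the clamp potential (baseline clamp
current is then exactly zero). The weight rises in fixed increments
(default 1e-5 uS, spanning the plausible single-synapse conductance range
within the iteration cap) until the peak |PSC| over a 100 ms post-event
window reaches the target within 2% relative; after 100 increments the fit
stops and is flagged unconverged. "Reaches within tol" is implemented as
`amplitude >= target * (1 - tol)`, which makes the returned weight correct
to one increment on an ideally clamped site. Fitted weights grow with path
distance from the soma, as expected from electrotonic decay.

### Bombardment and the IVL metric

An input ensemble is (N_E, N_I, f_E, f_I). Placement is uniform per unit
dendritic membrane area; inhibitory synapses split into thirds across
IS3/MS/BIS (remainders round-robin). Synapses share presynaptic trains in
connection groups (7 excitatory / 8 inhibitory synapses per connection for
cell 1, 9 / 12 for cell 2; the last group may be partial). Each connection
carries one homogeneous Poisson train — the simplest process consistent
with specifying only a rate; a renewal-process hook exists in
`fixtures.generate_renewal_train` for tests. All randomness flows from
`numpy.random.default_rng(seed)`; per-simulation seeds derive from a master
seed through `SeedSequence`, so runs are bit-reproducible and adding seeds
never perturbs earlier ones.

A 10 s simulation is scored on its last 9 s:

    score = (Vm_mean > -70.588 mV) + (Vm_sd > 2.2 mV) + (ISICV > 0.8)
          + (3 Hz < rate < 25 Hz) - 5 * (mean spike amplitude < 40 mV)

with strict inequalities throughout. Spikes are upward crossings of -10 mV
separated by >= 3 ms; subthreshold statistics exclude +/-5 ms around each
spike; the spike amplitude is the peak within 3 ms of the crossing minus
the subthreshold mean. The detector parameters are not prescribed by the
metric itself; these defaults separate full spikes (> 40 mV amplitudes)
from plateau depolarizations and are all overridable. With zero spikes the
amplitude penalty is not applied (no amplitude evidence of depolarization
block; the rate criterion already fails). A parameter set is *consistently*
IVL when at least five of ten re-randomized simulations score 4 and the
remaining ones score at least 3.

Two scalars summarize an ensemble: EI metric = N_E f_E - N_I f_I and total
input = N_E f_E + N_I f_I (synapses x Hz). `sparse_search` enumerates
candidate ensembles inside an EI window at 1-synapse / 1-Hz resolution and
visits them in ascending total input (ties broken lexicographically),
returning the first consistently-IVL set; the EI window itself is an input,
since how the original full-grid search condensed to its printed windows is
not algorithmically specified.

### State comparison protocol

1. Two-point F-I line from holding currents 60 and 120 pA above rheobase
   (rheobase by bisection to 1 pA); justified by the near-linear F-I of the
   fixtures above rheobase (R^2 >= 0.95 over four points).
2. Per seed: simulate the IVL ensemble, measure f_IVL, hold the synapse-free
   model at I_hold = (f_IVL - b)/m.
3. Repeat over ten derived seeds; analyze both members of each pair at the
   five recording sites (S, D1-D4) over the last 9 s.

Analyses: trapezoidal total charge per channel (sign semantics preserved:
outward more positive, inward more negative); currentscape decomposition
(per sample, each channel's current joins the inward or outward pool by its
sign; fractions are of the pool total, NaN where a pool is empty — marked
undefined rather than zero to avoid spurious 100% artifacts in silent
windows; fractions times pool totals reconstruct each current exactly); and
normalized cross-correlations (first series centred and scaled by SD times
length, second by SD, full linear correlation, trimmed to +/-20 ms).
Inward-carrying channel currents (NaT, CaT, CaL, H, excitatory synaptic)
are reversed in polarity before correlation; the leak is exempt because it
becomes an outward current during spikes. Lag-sign convention:
`normalized_xcorr(a1, a2)` puts the peak at -d when a2 is a1 delayed by d
("positive lag = a1 lags a2"); this is fixed by the shift-theorem test.
Synaptic currents are included in the decomposition pools by default (the
decomposition describes the total membrane current); `include_synaptic=False`
restricts it to intrinsic channels.

## Fixture cells (synthetic reference models)

The two reduced fixtures are soma + 200 um unbranched dendritic cables
(10 um compartments, 21 total) carrying the published five recording-site
diameters (cell 1: 9.84/1.92/0.82/0.94/0.75 um; cell 2:
4.44/1.26/1.01/0.74/0.60 um) at 0/50/100/150/200 um path distances — the
distances are a package choice; the published ones belong to the full
reconstructions. They are NOT reproductions of those reconstructions and do
not match their surface areas, input resistances or time constants
(explicitly out of scope). Channel densities start from the published
regional values and are rescaled by the documented per-channel multipliers
in `FIXTURE_MULTIPLIERS` so that a ~1000 um^2 cable reproduces the
behaviours the protocol needs: sustained 5-30 Hz firing at rheobase +
60/120 pA, near-linear F-I, and attainable IVL scores. The largest
multipliers (Kdrs, KCa) compensate for the reduced membrane area: the slow
adaptation conductances set the shallow F-I gain, with the 300 ms calcium
pool acting as the slow afterhyperpolarization. Leak is 1.1 pS/um^2 at
-75 mV, giving resting potentials near -70 mV.

Each fixture packages one demonstration input set — cell 1:
(N_E, N_I, f_E, f_I) = (140, 40, 2, 8); cell 2: (150, 60, 2.5, 9) — that
passes the ten-seed consistency rule (regression-tested, and verified
across several master seeds). These are far sparser than the published
ensembles because the reduced cable has far less membrane and far higher
input impedance than the reconstructed cells.

## What the synthetic data do and do not show

The generator exercises every pipeline stage with realistic spike
statistics, fluctuation magnitudes and charge budgets, so green tests
demonstrate the correctness of the algorithms (solver, metric, searches,
decompositions) and the direction of the headline effect (dendritic
h-current charge consistently larger under bombardment) on the reduced
models. They do not certify the published cell-specific magnitudes —
figure-level current contributions, input resistances, or fitted
conductance ranges — which require the original reconstructed morphologies
and their exact kinetics. Desk-scale grids here replace the original
cluster-scale searches; scripts expose the full grids but the shipped
analyses sample them sparsely.

## Numerical choices and edge cases

- Initialization: V uniform at the leak reversal, gates at steady state for
  that voltage; analysis windows discard a configurable prefix (default the
  first 1 s of 10 s runs). Rheobase and F-I measurements start from a
  settled resting state.
- Divergence guard: |V| > 200 mV or non-finite aborts with the offending
  time and compartment.
- Electrotonic profiles linearize around the settled resting state and
  refuse deflection amplitudes above 5 mV (risk of recruiting spiking).
- Voltage clamp is ideal (zero series resistance); clamp and current
  injection at the same site are mutually exclusive.
- Synaptic events snap to the nearest step boundary.
- Zero-variance series are rejected by the correlation routines rather than
  returning NaNs.
- Problem sizes in the shipped analyses (10 s simulations, ten seeds,
  21-compartment cells) keep the full protocol tractable on a single CPU.

## Known limitations

- Generic channel kinetics: directional and structural conclusions
  transfer; quantitative per-channel magnitudes do not.
- The unbranched cable cannot express branch-point effects or the published
  electrotonic asymmetry between the two cells.
- Ideal clamp ignores space-clamp error beyond what the cable itself
  imposes; distal fits are bounded by the 100-increment cap instead.
- Homogeneous Poisson input only; rhythmic/theta-modulated schedules are
  deliberately out of scope.
- No axonal spike-initiation zone: the axon region carries densities but
  the fixtures do not instantiate axonal compartments.
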