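# ivlsim

Conductance-based multi-compartment simulation of hippocampal OLM
(oriens lacunosum moleculare) interneurons under in vivo-like synaptic
bombardment, with per-channel ionic current decomposition.

Dendritic patch-clamp recordings from interneurons in behaving animals are
essentially infeasible, so the contribution of individual ion channel
currents (H, NaT, Kdrf, Kdrs, KA, M, CaT, CaL, KCa) across somatic and
dendritic compartments in vivo is unknown. This package reimplements, as a
tested pipeline on reduced reference cells, the computational strategy for
that question: drive a compartmental model with Poisson synaptic ensembles
until its somatic voltage looks "in vivo-like", then compare every channel's
current against a rate-matched, synapse-free "in vitro" simulation.

It is aimed at computational neuroscientists who want the machinery —
solver, synapse fitting, bombardment searches, scoring, current analyses —
as importable, seeded, unit-tested building blocks rather than a bundle of
one-off scripts.

## The core quantities

A bombardment ensemble is `(N_E, N_I, f_E, f_I)` (synapse counts and
presynaptic rates), summarized by

    EI metric   = N_E f_E − N_I f_I        Total input = N_E f_E + N_I f_I

A 10 s simulation is scored on its last 9 s with the IVL metric

    score = (V̄_m > −70.588 mV) + (σ_Vm > 2.2 mV) + (ISICV > 0.8)
          + (3 Hz < f < 25 Hz) − 5·(S̄_amp < 40 mV)

(score 4 = in vivo-like; the last term flags depolarization block). A
parameter set is *consistently* IVL when ≥ 5 of 10 re-randomized runs score
4 and the rest score ≥ 3. Matched in vitro runs hold the soma at
`I_hold = (f_IVL − b)/m`, with `(m, b)` the two-point F-I line fitted at
rheobase + 60 and + 120 pA. Per-channel analyses: trapezoidal total charge,
currentscape-style percent contributions to total inward/outward current,
and normalized cross-correlations (inward currents polarity-reversed,
leak exempt).

## Layout

    src/ivlsim/        library: morphology, channels, simulator, synapses,
                       bombardment, metrics, analysis, fixtures, workflow, cli
    analysis/          numbered drivers reproducing the experiment end to end
    tests/             pytest suite (unit, property and acceptance tests)
    scripts/acceptance.py   recomputes the headline worked-example numbers
    docs/methods.md    model equations, defaults, design choices, limitations

## Worked example

Score the packaged bombardment ensembles on both reduced reference cells
(ten re-randomizations each):

    python analysis/03_check_ivl_state.py

prints

    cell 1: params (140, 40, 2.0, 8.0) EI -40.0, total 600.0
      scores (4, 4, 4, 4, 4, 4, 4, 4, 4, 3) -> consistent: True
    cell 2: params (150, 60, 2.5, 9.0) EI -165.0, total 915.0
      scores (4, 4, 4, 4, 4, 4, 4, 4, 4, 4) -> consistent: True

i.e. 140 excitatory synapses at 2 Hz plus 40 inhibitory synapses at 8 Hz
keep cell 1 depolarized, fluctuating and irregularly spiking in the 3–25 Hz
band in nine to ten of ten seeds — a consistently in vivo-like state.

The full paired comparison (`python analysis/04_compare_states.py`) then
reports, per seed, the bombardment rate, the matched holding current and
the rate it actually produces:

         seed     f_ivl     i_hold   f_vitro
    821328062 10.888889 110.192308 10.555556
    745650761 10.333333 107.307692 10.000000
    ...
    seeds with larger dendritic H-charge under bombardment: 10/10

Matched in vitro rates land within ~3% of `f_IVL`, and in all ten seeds the
dendritic h-current carries more total charge under bombardment than in the
rate-matched quiescent state — the headline direction: subthreshold,
hyperpolarization-activated H channels are engaged more strongly by
dendritic synaptic bombardment, while spike-coupled currents dominate the
somatic in vitro condition.

`analysis/01_fit_synapses.py` and `analysis/02_calibrate_fi.py` produce the
upstream calibrations (per-compartment synaptic weights rising with
distance from the soma; near-linear F-I above rheobase, e.g. cell 1:
0.203 Hz/pA, R² = 0.997), and `analysis/05_summarize_timing.py` aggregates
correlogram peaks (the h-current is the one channel anti-correlated with
voltage: peak ≈ −0.86 under bombardment).

A `ivlsim` console command exposes the same stages
(`simulate`, `score`, `search-ivl`, `compare-states`, `make-fixture`,
`analyze-traces`); see `ivlsim --help`.

## Caveats

The two shipped reference cells are reduced soma-plus-cable models carrying
the published recording-site diameters, regional conductance layout and
input-population structure; they are not the original reconstructed
morphologies, and channel kinetics are a documented generic
parameterization. Quantitative, cell-specific current magnitudes therefore
do not transfer; the algorithms, identities and the directional h-current
result do. See `docs/methods.md` for the full account.
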