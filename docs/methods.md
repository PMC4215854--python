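# Methods

## The problem and the pipeline

Oriens-lacunosum/moleculare (O-LM) interneurons of hippocampal CA1 express
the hyperpolarization-activated mixed-cation current I_h, but whether HCN
channels sit only on the soma or also on the dendrites is experimentally
open.  `olmens` implements a desk-scale version of the ensemble-modeling
workflow used to probe that question: build a brute-force grid of
conductance-based multi-compartment model variants, simulate a
current-clamp protocol matched to the experimental one, rank every model
against a dataset of recordings with a z-score-normalized distance,
extract a subset of "appropriate O-LM models" with principled cutoffs,
and examine pairwise conductance histograms of the retained subset for
compensatory (co-regulated) conductance balances and dendritic-I_h
signatures.

The original study ran ~9.3x10^5 models on a compute cluster against
reconstructed morphologies and real recordings from ten mouse O-LM cells.
Neither the reconstructions nor the recordings are shipped here, so the
package substitutes (a) a calibrated surrogate morphology and (b) a
synthetic surrogate cohort with the published aggregate statistics, and
validates each analysis stage with planted-structure generators whose
ground truth is known.  Cluster-scale empirical numbers (the 60,000/90,000
cutoff ranks, the 323,977 accepted models, the I_h-placement split) are
grid-and-data-dependent outcomes and are deliberately not reproduced.

## Model

Each model is a passive cable tree plus nine voltage-gated conductances:
somatic and dendritic fast Na (treated as separate grid parameters), fast
and slow delayed-rectifier K (KDRf, KDRs), A-type K, L- and T-type Ca,
Ca-activated K (AHP), HCN/h, and M-type K, with fixed reversals E_Na = 50,
E_K = -95, E_h = -32.9 mV, a K-selective leak, and an ohmic leak.  E_Ca is
a fixed convention (+120 mV); no Nernst update is applied.  Membrane
dynamics per compartment:

    Cm dV/dt = -sum_c gbar_c * prod_g x_g^p (V - E_c) - g_L(V - E_L)
               - g_KL(V - E_K) + I_axial + I_inj

Gates follow first-order kinetics with Boltzmann steady states and
bell-shaped voltage-dependent time constants; the AHP gate depends on a
single-pool intracellular calcium concentration,
dCa/dt = -phi*i_Ca - (Ca - Ca_rest)/tau_Ca (phi = 3e-4 mM cm^2/(mA ms),
tau_Ca = 100 ms, Ca_rest = 50 nM).  Gating parameter values are a
config-driven default set in the style of published hippocampal
interneuron models; every parameter is overridable
(`model_core.default_channels(overrides=...)`).  The defaults were fixed
from qualitative physiology of the mid-grid reference model: tonic ~10 Hz
regular firing under +90 pA from a -74 mV holding potential, an h-mediated
depolarizing sag under -90 pA that grows with g_h (up to ~8 mV at the top
grid density), and failure-to-fire/depolarization-block phenotypes at
low-K grid corners.

### Grid

Maximum conductance densities take the published per-channel value lists
(pS/um^2), 3-5 levels per channel, crossed with the I_h placement (soma
only vs. soma+dendrites, uniform within the carrying compartments) and the
morphology.  `build_grid` enumerates the Cartesian product lazily
(morphology outermost, then I_h placement, then channels in canonical
order, last channel fastest); each grid point has a stable integer id
equal to its enumeration index.

### Surrogate morphology

The reconstructed morphologies are replaced by a calibrated shape family:
a 20x20 um soma cylinder, two 150-um trunks (2 um diameter), each
bifurcating into two terminal branches (1.5 um) whose length is solved by
a 1-D Brent search so that the analytic (sealed-end cable) somatic input
resistance matches the published value for the corresponding passive set
(474 MOhm for morphology 1, 530 MOhm for morphology 2), within 5% also in
the discretized simulator.  With spatially uniform passive properties the
membrane time constant is Rm*Cm regardless of geometry (57.3 ms for
passive set 1), so geometry calibration targets R_in only.  Note that for
passive set 2 the printed time constant (66 ms) is not consistent with
Rm*Cm of its printed passive values (35.1 ms); the package derives the
time constant from the passive values and makes no claim about the second
morphology's tau.

### Discretization and integration

Sections are split into the smallest odd number of segments of length at
most `lambda_fraction` x lambda_100, with lambda_100 =
(1/2) sqrt(d / (pi f Ra Cm)) at f = 100 Hz.  The default
`lambda_fraction = 0.25` gives ~70 compartments on the surrogate
morphology; accuracy-insensitive analyses use 0.5 (~35).  Integration is
Crank-Nicolson (theta = 1/2) on the membrane/cable terms with the tree
system solved exactly per step by Hines elimination, and staggered
exponential gate updates from tables of x_inf(V) and exp(-dt/tau(V))
precomputed on a 0.05 mV grid (dt = 0.025 ms, output every 0.1 ms).
Batches of models sharing a morphology and passive set are integrated
together in a single numba kernel.  |V| > 200 mV marks numerical
divergence and raises an instability error naming dt.  Halving dt changes
somatic traces by < 0.5 mV max-norm on the reference model (asserted in
tests); the passive isopotential step response matches the analytic RC
curve within 0.1%.

### Protocols and bias fitting

The standard protocol is 1 s settling, a 1 s +/-90 pA somatic step, and
1 s recovery, from a holding potential of -74 mV maintained by a constant
bias current.  `fit_bias_current` finds that bias by batched secant
iteration on the settled voltage (settling = |dV/dt| < 0.01 mV/ms over the
final 100 ms of a 1.2 s settle), constrained to the admissible window
[-28, +12] pA (the experimental mean -8 pA +/- 5 SD); models that fire
during settling at every admissible bias are rejected as "premature
firing", and models whose required bias exceeds the window are rejected
as "too much positive bias current" — both boundaries are probed before
rejecting.  Both step traces of an accepted model share the fitted bias.

The mixed VC/IC protocol clamps the soma at -74 mV through a stiff series
conductance (1 uS; clamp current exposed for diagnostics) while a tonic
hyperpolarizing current is injected 30 um out on a dendrite, recording the
soma and three positions along the injected branch.  The published -5/-2
nA amplitudes belong to the full reconstructions, whose proximal dendrites
are far thicker; on the surrogate the default is -1 nA, which drives the
distal branch to about -85..-95 mV.  The qualitative signature — a
dendritic sag only when I_h is present in the dendrites at sufficient
density, and none for soma-only I_h or g_h = 0 — is amplitude-independent
over the probed range.

## Measures and distance

`features.default_registry()` builds 103 measures compositionally: 11 for
the hyperpolarizing trace (resting Vm, trough voltage and latency, in-step
steady state, sag amplitude `PulsePotSag` = steady state minus trough, sag
time constant from a single-exponential fit of the recovery, total
deflection, input resistance, and three recovery-period measures) and 92
for the depolarizing trace (per period Ini/Pulse/Recov: spike count and
rate, and Mean and Mode statistics of 14 per-spike/per-interval
quantities — amplitude, peak, threshold, half/base width, rise/fall time,
max/min dV/dt, AHP depth/time, post-spike minimum, ISI, ISI ratio — plus
first-spike latency and ISI CV for the pulse).  The exact composition of
the published 92-measure list is not public; only the counts and the
prefix/suffix nomenclature are, so the registry reproduces those and the
distance engine is registry-agnostic.  Spikes are upward crossings of
-20 mV separated by >= 2 ms; steady states are 100-ms tail means; the Mode
statistic is the center of the fullest of 10 histogram bins.  Measures
undefined on a trace (spike statistics with no spikes, sag tau with no
trough) are flagged invalid, never zero-filled.

The model-to-trace distance is the root-mean-square of per-measure
z-scores, normalized by the per-measure SD over the experimental dataset,
over measures valid in both vectors; a model's aggregate distance is the
mean over all experimental traces.  The root-mean (not root-sum) form
keeps vectors with different numbers of valid measures comparable, and on
complete vectors yields the identical ranking.  SDs below
1e-6|mean| + 1e-12 are floored and flagged.  The engine is verified
against a plain-loop oracle to 1e-12 on random toy databases.

## Subset criteria

* General: first differences of the aggregate distance vs. rank are
  smoothed with a window of 1% of the database; the plateau slope is the
  median over the middle 50% of ranks; the cutoff is the first rank past
  the initial transient where the smoothed difference exceeds 3x the
  plateau slope for a persistent window.  The original cutoff was chosen
  by eye; this detector replaces visual judgment, logs its diagnostics,
  and accepts a manual override rank.  On planted-breakpoint sequences it
  detects the true rank within the persistence window in >= 95% of seeded
  runs.
* Failure-to-fire (restricted): cutoff = rank before the first model with
  <= 2 spikes during the +90 pA step.
* Sag-tau (restricted comparator): first rank where a persistent run of
  models leaves the [min, max] range of the experimental sag-tau
  distribution, minus one; missing taus count as out-of-range.

Per-morphology subsets pool by union; the pooled size is the sum of the
per-morphology cutoffs.

## Co-regulation analysis

Dimensional stacking renders the grid as a nested 2-D image (first half of
the parameter ordering on x, second on y; mixed-radix nesting, first
parameter most significant).  Clutter is the sum of *squared*
adjacent-pixel differences; squared, not absolute, because the total
absolute variation of a separable/additive surface is the same for every
monotone nesting, which would make all orderings tie exactly where the
metric must discriminate.  The ordering search is exhaustive up to 6
parameters and greedy-insertion beyond; candidates are visited in
decreasing main-effect-sensitivity order so the many axis-swap ties
resolve toward sensitivity-first (and toward name order for constant
surfaces).  Non-member pixels are painted with a background value just
above the maximum distance.

Pairwise conductance histograms count retained models per grid-value
cell, reported as percentages of the subset.  The original study
classified interactions visually; to make the outcome assertable, a ridge
score — the count-weighted correlation of the two parameters' level ranks
— backs the classification: co-regulation if |score| >= 0.4 with monotone
conditional modes, local preference if a dominant cell holds >= 2x the
uniform share without the monotone ridge, otherwise no interaction.  The
score is always reported with the label.  The screen covers all pairs
among the top-5 stack parameters plus a boundary control (AHP by default).
On planted ensembles (retention forcing rank-covariation of one pair) the
screen flags exactly the planted pair in >= 95% of seeded runs, and the
control never interacts.

## Synthetic cohort

The surrogate dataset emulates the published aggregate structure: 10
cells, 56 sweeps total (5-6 per cell, both polarities in every cell),
drawn bias currents N(-8, 4) pA clipped to the admissible window, 0.3 mV
additive Gaussian measurement noise, and log-normal multiplicative jitter
(sigma = 0.2 in log space; 0.45 for g_h) on all maximal conductances
around a reference cell.  The surrogate cells carry their own h-current
formulation (a squared, slower, more steeply hyperpolarization-activated
gate) because the grid models' h saturates near 8 mV of sag, well short of
the experimental 14.2 mV — the same mismatch the original study reports
between its models and its recordings.  A two-stage calibration (bisection
of g_h on the reference's sag, then secant correction on the jittered
cohort mean) brings the cohort `PulsePotSag` mean within 10% of 14.2 mV
(internally targeting 5% for margin); results carry `calibrated=False`
plus the achieved statistics when the loop cannot converge.  The sag SD
target (3.1 mV) is retained in config but is *not* reachable by
conductance jitter alone — sag saturates in g_h, compressing variability
to ~1-2 mV — so passing tests demonstrate calibrated means, not the full
experimental dispersion.  Everything is deterministic in the seed; the
jitter/bias draws are independent of the calibration path.

What the cohort does not emulate: electrode/bridge artifacts, junction
potential drift, per-cell sweep-count structure of the real dataset,
within-cell nonstationarity, and any feature of the real cells beyond the
published aggregate statistics.  Tests passing against this cohort show
the pipeline's machinery is correct under the stated statistical
structure, not that the biophysical models capture real O-LM behavior.

## Problem sizes

Desk-scale defaults: ~70-compartment surrogate morphology (35 for coarse
analyses), 18-54-model demonstration grids in the pipeline, a 2,187-model
planted ensemble for co-regulation recovery, 50 seeds for detection-rate
properties, and the 10-cell/56-trace cohort.  The full 933,120-model
production design is expressible (`pipeline.published_defaults()`,
`model_core.published_grid_design()`) and the grid enumerates lazily in
memory, but running it is cluster-scale work by design.

## Known limitations

* Channel kinetics are a literature-style default set, not a fit to O-LM
  voltage-clamp data; conclusions about specific conductance balances
  transfer only qualitatively.
* The cohort sag SD falls short of the experimental dispersion (above).
* The morphology-2 printed time constant is internally inconsistent with
  its printed passive values; the package follows the passive values.
* The general-cutoff detector needs a few thousand ranked models to
  estimate a plateau; on the mini demonstration grids it returns a
  no-cutoff verdict and retains the full ranking.
* Single-pool calcium with a fixed E_Ca; no temperature/Q10 scaling; no
  synaptic input or stochastic gating.
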