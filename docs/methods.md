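# Methods

## The model in one paragraph

`dblsim` simulates a mouse CA1 pyramidal neuron reduced to three electrically
coupled compartments — soma, proximal dendrite, distal dendrite — each with a
capacitance, leak, and a set of voltage- and calcium-gated channels, plus a
submembrane Ca²⁺ pool per compartment.  On top of this standard
conductance-based core sits an activity-dependent mechanism: an exponential
moving average (EMA) of the somatic depolarization above rest feeds three
saturating Hill functions (one per ion species), whose outputs offset the Na⁺
and K⁺ reversal potentials and translate the channels' voltage dependence
("kinetic shift").  The mechanism is phenomenological: it stands in for a
transient change of the local ionic microenvironment and of membrane
properties that conventional models hold fixed.  With all Hill amplitudes at
zero the model is an ordinary fixed-parameter HH-type cell, bit for bit.

## The mechanism

Once per integration step, from the somatic voltage at the start of the step:

    x      = v_soma − v_rest
    cnt    = min(step index, t_step_eff)
    EMA   ←  a·x + (1 − a)·EMA,          a = F/(cnt + 1)
    f_i    = B_i·C_i·EMA/(C_i + EMA),     i ∈ {Na, K, Ca}
    dE_Na  = −α_ENa·f_Na      (E_Na falls)
    dE_K   = +α_EK·f_K        (E_K rises)
    sh_i   = +α_i·f_i         (gating curves translate toward depolarized v)

Choices that the equations leave open, and how this package resolves them:

* **Sign of the K⁺ reversal shift.**  Applied with a uniform minus sign the
  shift would hyperpolarize E_K, which contradicts the physical picture the
  mechanism encodes (K⁺ accumulating outside during activity) and suppresses
  the baseline elevation it exists to produce.  Both reversal shifts here
  *reduce the magnitude* of their gradients: E_Na down, E_K up.  A
  `literal_eq1_signs` switch restores the uniform-minus variant for
  comparison; it is not used by any default.
* **One EMA stream.**  The species index enters only through the Hill
  coefficients, so a single EMA of the somatic voltage drives all three
  species.
* **Clamping.**  The Hill function is singular at EMA = −C; the EMA is
  clamped at zero from below so hyperpolarized excursions contribute no
  drive.
* **Step-count window vs. time window.**  `t_step = 1000` counts *integration
  steps* at the reference dt of 0.025 ms (a ≈ 25 ms window, effective
  averaging time constant ≈ 12.5 ms).  When a run uses a different dt the
  step count is rescaled to preserve the time window, which is the physically
  meaningful quantity.
* **Spatial rule.**  The EMA is driven by the somatic voltage only (the
  mechanism was fitted against somatic recordings) and the resulting shifts
  are applied globally to all compartments.

The two built-in coefficient sets (`CELL_203030003_R`, `CELL_170518_4E`) are
per-cell fits taken as given; this package deliberately ships no automatic
fitting (the original calibration was manual, and the mechanism layer — not
any particular fit — is the subject here).

## Surrogate channel set

The published kinetics behind the original fits live in simulator-specific
channel files that are not reproduced in print; this package therefore
defines a compact, fully serializable surrogate set (closed-form sigmoid/bell
curve families; coefficients in `dblsim.channels`):

| channel | gates | role |
|---|---|---|
| Na  | m³ (−38/4 mV), h (−55/−5 mV, fast recovery) | spike generation |
| K_DR | n² (−12/8 mV) | spike repolarization, AHP |
| K_A | a (−28/7.5), b (−80/−7, τ 20 ms) | transient brake near rest |
| K_M | n (−35/6, τ 60 ms) | slow adaptation |
| CaH | m² (−18/6) | Ca²⁺ influx for the AHP channel |
| K_AHP | Ca-gated (K_d 2 µM) | spike-train adaptation |
| I_h | r (−88/−8), fixed reversal −30 mV | resting conductance, sag |
| Nap | m (−52/5), τ 300 ms activating / 1 ms deactivating | alternative-mechanism experiment only |

Kinetic-shift routing: sh_Na applies to Na (and Nap) gates, sh_K to K_DR,
K_A and K_M, sh_Ca to CaH; the Ca-dependence of K_AHP and the h-current are
unshifted (the mechanism indexes only Na, K and Ca).  Kinetics are defined
directly at the ~35 °C recording temperature; there is no Q10 machinery.

Coefficients are calibration parameters.  The calibration targets were: rest
at −70 mV (exact, by construction — see below), AP peak near +35 mV
(achieved: first-spike peaks +30 to +38 mV across protocols), input
resistance within the experimental range (≈ 93 MΩ against 141 ± 60 MΩ), and
a first-spike threshold near −55 mV at 0.1 nA.  The last target is *not*
met: the surrogate set initiates spikes near −43 mV.  Placing the Na
activation curve low enough for a −55 mV threshold creates a persistent
window current that destabilizes both the conventional resting state and the
shifted firing regime of this reduced geometry, so the more depolarized
threshold was accepted; all threshold *comparisons* (the +11 mV static-shift
experiment, within-train rises, threshold-vs-current curves) are differences
and do not depend on the absolute value.

### Two conductance profiles

No single conductance profile of this reduced cell can both (a) enter
depolarization block at 0.4 nA when the mechanism is off and (b) sustain
full-amplitude firing at 0.4 nA when it is on: the strong delayed-rectifier
momentum that makes the shifted model's limit cycle robust produces deep
afterhyperpolarizations that always let Na⁺ inactivation recover in the
conventional model.  The package therefore ships two profiles, mirroring the
practice of retuning peak conductances per experiment:

* `default_cell()` — the fitted profile used with the mechanism.  Its
  mechanism-off counterpart fires slow, deep-AHP trains with a flat baseline
  (the "conventional model cannot raise the DBL" comparison).
* `conventional_cell()` — a minimal Na/K_DR/K_A cell with a nearly isolated
  soma, tuned to fire full APs at 0.1–0.2 nA and to collapse into a
  depolarized plateau (block) at 0.3–0.4 nA (the block demonstration).

Key default parameters: E_Na(0) = +55 mV; E_K(0) = −112 mV for the fitted
profile (a low K⁺ reversal consistent with a gluconate-based internal
solution and ~2 mM external K⁺; it also gives the second fitted parameter
set, whose K⁺ Hill product is largest, enough repolarization headroom to
keep firing rather than latching into a silent depolarized state) and
−105 mV for the reference profile; Ca²⁺ pool: 1 µm shell, τ = 80 ms, resting
50 nM against 2 mM external, with the Ca²⁺ reversal recomputed from the pool
by the Nernst relation every step.

## Numerics

* Voltages: Crank–Nicolson (second-order, implicit), one tridiagonal solve
  per step across the three-compartment chain.  All membrane currents are
  ohmic in v given the gates, so the update is exact linear algebra.
* Gates: exponential Euler against their local steady state and time
  constant, evaluated at the shifted voltage v − sh.
* Ca²⁺ pools: exponential relaxation toward the influx-driven target.
* dt = 0.025 ms by default (dt ∈ (0, 0.1] accepted); the EMA window rescales
  with dt as described above.
* The resting state is an exact fixed point: leak reversals are solved per
  compartment so that all channel currents cancel at v_rest with gates at
  steady state and the Ca²⁺ pool at its *equilibrium* (not nominal) level.
* |v| > 200 mV raises a divergence error carrying the offending time.
* Runs are deterministic: identical inputs give bit-identical outputs; all
  stochastic protocols draw from seeded generators.
* The hot loop is numba-compiled (compiled once per process).

## Stimulation protocols

Current steps follow the two laboratory protocols: 0–0.4 nA in 50 pA steps
for 400 ms, and 0–0.45 nA for 500 ms, each amplitude from a fresh cell and
mechanism state.

The in-vivo-like drive models two excitatory pathways: 40 AMPA synapses of
0.6 nS peak on the distal compartment (entorhinal input) and 20 AMPA (0.5 nS)
plus 20 NMDA (0.25 nS) synapses on the proximal compartment
(Schaffer-collateral input).  Every synapse fires independent Poisson
background at 4 Hz; SC synapses additionally receive synchronous bursts of
10 activations at 100 Hz whose onsets are Poisson at 4 Hz, superimposed on
the background.  Synaptic conductances are peak-normalized double
exponentials (AMPA 0.5/3 ms, NMDA 5/50 ms, reversal 0 mV) — standard
hippocampal values, since the originals are unpublished; NMDA receptors
carry the sigmoidal Mg²⁺ block 1/(1 + ([Mg]/3.57 mM)·e^(−0.062 v)) at 1 mM
Mg²⁺.  Synapses within a pathway share kinetics, so the integrator merges
each pathway into one weighted event stream (a synchronous burst event is a
single event of weight n_syn); this is exact, not an approximation.

For the mechanism-on/off spectral comparison the off model's Na⁺ densities
are scaled by bisection until its mean spike count over calibration runs
matches the on model's (the off model is otherwise less excitable under
identical drive); the scale is recomputed at run time, not stored.

## Feature extraction and spectra

Defaults (all configurable): spikes are local maxima above −10 mV separated
by ≥ 2 ms; the DBL is the mean of the minimum voltage between consecutive
spike *peaks* and is undefined below two spikes; the spike threshold is the
voltage at the last upward crossing of dV/dt = 20 mV/ms before the peak
(derivative criterion, linearly interpolated); depolarization block is a
spikeless stretch above −30 mV lasting ≥ 100 ms inside the stimulus window.
The acquisition chain applies a causal 4-pole Bessel low-pass (2 kHz) and
resamples to 10 kHz, emulating the recording hardware; note a causal Bessel
has slightly sub-unity passband gain and nonzero group delay, so re-filtering
is only near-idempotent (exact at DC).  Ensemble spectra are Welch PSDs
(2 s Hann segments, 50% overlap), each normalized to unit total power before
averaging, so they compare power *distributions* across conditions.

Operational readings where the qualitative contract needed a number: "fires
full-amplitude spikes instead of blocking" is read as at least two spikes
whose peak amplitude (relative to rest) is within 20% of the first spike's;
"interspike intervals decrease" is read as Spearman ρ < 0 across the train
(the default Nap run is in fact strictly decreasing); mean-threshold-vs-
current curves are required non-decreasing within a 1 mV tolerance, because
at higher currents the train includes one or two early spikes fired before
the EMA has built, which pull the mean down by up to ~1 mV even though the
late-train thresholds themselves ride ~3–8 mV above the first spike.

## Nernst inversion

The `nernst` module converts reversal-potential shifts predicted by the
mechanism into local concentration changes: a conservative transfer of Δ mM
across the membrane (intracellular change Δ, extracellular change Δ/ρ with
volume ratio ρ, default 1) is solved by bisection so that the Nernst
potential moves by exactly the requested amount.  Baseline pools (Na⁺ 20 mM
in / 140 mM out; K⁺ 133 mM in / 2.2 mM out) are reconstructed for internal
consistency — a ~20 mM transfer roughly doubles internal Na⁺ and raises
external K⁺ about ten-fold — and are configuration, not constants.

## Problem sizes

The test suite runs the step sweeps at eight amplitudes (0.05–0.4 nA) per
parameter set and a six-run reduced ensemble of the 10 s synaptic protocol
per model variant; `scripts/acceptance.py` runs the full twenty-run
ensembles.  These sizes are the package's defaults for routine verification;
all are plain arguments.

## What the synthetic conditions do and do not show

The generator-side protocols emulate the *study conditions*: step amplitudes,
durations, synapse counts, rates and burst structure.  They do not emulate
morphological detail (three compartments stand in for a full arbor; density
gradients are per-compartment constants), inhibition, synaptic plasticity,
channel stochasticity, or electrode/access artifacts.  Passing tests
therefore show that the mechanism layer produces the documented phenotypes in
a reduced but biophysically regular host cell — not that the surrogate
kinetics match any particular recorded neuron.  Known quantitative
limitations: the DBL-vs-current curve of the fitted profile rises by only a
few millivolts across the sweep (experimentally the rise spans tens of
millivolts; the reduced cell's EMA self-stabilizes), the absolute spike
threshold sits ~10 mV above the stated calibration target (above), and the
fitted profile's mechanism-off baseline is deeper than typical recordings.
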