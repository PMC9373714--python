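# Methods

## Model overview

The package simulates a 28-neuron NAc–mPFC circuit receiving dopamine from
an unsimulated VTA. Every neuron is a compartmental Hodgkin–Huxley model;
every synapse is a two-state kinetic receptor. The circuit, all channel
kinetics and the dopamine-modulation endpoints are defined in YAML
parameter files (`src/dopanet/params/`) that are the single source of
truth; the code contains no hidden constants beyond physical ones.

### Membrane equation and units

Per compartment: `C_m dV/dt = I_stim − ΣI_ion − ΣI_comp − ΣI_syn`.
All currents are densities. Units: mV, ms, µF/cm², mS/cm², µA/cm², mM;
GHK permeabilities in cm/s. With these units the membrane equation is
dimensionally closed without conversion factors.

### Ion channels

Gates follow the Boltzmann form `m∞(V) = 1/(1+exp((V−V_half)/k))` with a
*signed* slope (negative for activation, positive for inactivation; the
inward rectifier is the deliberate exception, an activation gate with a
positive slope). Time constants are either constants or tabulated τ(V)
breakpoints, linearly interpolated and clamped outside the table. Three
current modes exist: ohmic, partially inactivating
(`I = g·m^x·(a·h−(1−a))·(V−E)`, shipped KAs uses a = 0.9), and GHK calcium
flux. The GHK expression switches to its two-term series expansion when
|zFV/RT| < 1e−4, making the current continuous through V = 0 (the two
branches agree to ~1e−8 relative at the switch point).

### Calcium pools

Each compartment carrying GHK channels owns a submembrane shell:

```
dCa/dt = k·(−I_Ca)/(2·F·d) − p·K_t·Ca/(Ca+K_d) + (Ca_rest − Ca)/τ_R
```

with d = 0.1 µm, K_t = K_d = 1e−4, τ_R = 43 ms, k = 1000, p = 0.02.
Unit convention: the influx term takes I_Ca in mA/cm² and d in µm; with
k = 1000 the result is mM/ms and spike-driven transients stay in the
sub-µM range. The engine's currents are µA/cm² and are scaled by 1e−3 at
the pool boundary. `Ca_rest` is not stated by the shared convention of the
source models; it defaults to the initial value (0.001 mM) and is flagged
as an assumption in the parameter files. In the shipped channel sets no
conductance reads the pool (calcium-dependent potassium currents are
represented by voltage-gated approximations), so the pool is a recorded
observable rather than a feedback variable — a known simplification.

### Compartment coupling

Rall's formula gives the conductance of compartment *a* receiving from *b*:
`g = d_a·d_b² / (r_L·l_a·(d_a²·l_b + d_b²·l_a))`, evaluated in cm and
expressed per cm² of the receiving membrane; the coupling current is
`g·(V_a − V_b)`. The formula is directional: each compartment computes its
own incoming conductance, so pairwise currents are not exactly
antisymmetric. This asymmetry is intrinsic to the formulation; a test
audits that the two directional conductances remain the same order of
magnitude rather than forcing symmetry.

### Synapses

Destexhe-type kinetics with the classic parameters (AMPA α = 1.1 /mM/ms,
β = 0.19 /ms; NMDA 0.072/0.0066; GABA_a 5.0/0.18; T_max = 1 mM, V_p = 2 mV,
K_p = 5 mV). Transmitter release is an instantaneous sigmoid of the
presynaptic *somatic* potential. NMDA carries the magnesium block
`B(V) = 1/(1+exp(−(V+15)/16.3))`. One weight ω ∈ (0,1) is drawn per
directed cell pair per edge group and shared between AMPA and NMDA on
glutamatergic edges. Glutamate lands on the pyramidal proximal dendrite
and on MSN dendrites (spread round-robin across the 10 spines); GABA lands
on somata. There are no transmission delays and no synaptic plasticity.

### Dopamine

Dopamine is a scalar percentage k. Each modulated parameter interpolates
linearly between its 0 % value a (the value stored in the cell's parameter
file) and its 100 % value b (given in `dopamine_rules.yaml` as a scale or
shift of a). Rules cover exactly: pyramidal soma/distal Ca and CaN
permeability (×0.70 / ×0.60 at 100 %), proximal KS conductance (×0.65),
proximal NaP activation V_half (−5 mV) and inactivation V_half (+5 mV);
MSN soma/dendrite KAs conductance (×1.30) and Cav1.2 permeability (×0.70).
The magnitudes follow the D1 modulation pattern of Durstewitz-type PFC
models and the D2 pattern of Wolf-type MSN models; the exact endpoint
values are calibration assumptions. In `uniform_range` mode one k is drawn
per modulated neuron per trial and held for the whole trial. Dopamine
never touches receptor parameters, so miniature synaptic currents are
unmodulated by construction (verified by a diff audit in the tests).
Whether "activating and deactivating parameters" of NaP means half-voltages,
slopes or time constants is underdetermined; the rules target V_half shifts
and are config-overridable.

## Numerics

The integrator is the Bogacki–Shampine 2(3) explicit pair run at a fixed
step (default 0.02 ms, i.e. 50 kHz). The embedded second-order solution
yields an error estimate that is logged in the recording metadata and never
used for step control, so trials are bitwise reproducible from their seed
tuple. All state variables (voltages, gates, receptor fractions, calcium)
are integrated jointly. Gates are clamped into [0,1] and calcium floored
at 1e−9 mM inside current evaluations as a defensive guard; the smallest
time constants (0.05 ms) keep the explicit scheme comfortably stable at
dt = 0.02 ms. A convergence test audits third-order error decay on a
subthreshold trajectory.

The readable per-object operations in `channels`, `synapses` and `cells`
define the model; `engine.py` flattens a built network into
structure-of-arrays form and evaluates the same equations in numba-compiled
loops (one 4 s network trial ≈ 10–15 s on one CPU). A consistency test
asserts that the compiled right-hand side matches the composed module
operations to 1e−9 relative on a two-neuron network in a generic state.

Randomness: a root seed plus (condition, trial) indices derive three named
streams — connection weights, stimulus currents, dopamine draws — through
`numpy.random.SeedSequence`. Stimulus currents are uniform draws within a
per-population interval, applied as a density to every compartment of the
neuron (a distributed background-drive reading of "stimulus current";
soma-only injection is ineffective against the dendritic load of the MSN),
zero outside the 500–3500 ms window, redrawn every integration step in the
network default. The single-cell demo protocols redraw every 20 ms instead,
emulating slower in-vivo-like input fluctuations; this is what makes the
isolated pyramidal cell's burst clusters visible.

## Analysis conventions

* Spikes: upward 0 mV crossings with a 2 ms lockout (both config-exposed).
* Bursts: open at ISI ≤ 40 ms, extend while ISI ≤ 100 ms, close at the
  first ISI > 100 ms; at least two spikes. Boundary cases use ≤/> exactly
  as stated.
* Mean peak potential: mean of local voltage maxima within ±2 ms of each
  spike (translation-equivariant; undefined for an empty train).
* Peak statistics of a current: the largest |I| within ±2 ms of each spike;
  peak frequency equals spike frequency by construction.
* Outlier filter: keep values inside the inclusive [25th, 75th] percentile
  band, linear-interpolation percentile definition.
* LFP: arithmetic mean (not sum) of the 28 somatic potentials so values
  stay in mV and are population-size invariant, then anti-aliased polyphase
  decimation to exactly 500 Hz.
* PSD: 2048-point transform (Hann, mean removed) giving a fixed 1024-point
  one-sided grid on [0, 250) Hz — a one-sided 2048-point transform has 1025
  bins; the grid keeps the first 1024. Signals longer than 2048 samples are
  Welch-averaged over 50 %-overlapping segments; the canonical 4 s trace
  (2000 samples at 500 Hz) is a single zero-padded segment. Inputs shorter
  than 256 samples are rejected.
* STFT: 100 ms (50-sample) Hann windows, 50 % overlap, PSD scaling, times
  at window centres.
* dBm view: `P_dBm = 10·log10(P_W)` applied to the PSD value as-is;
  nonpositive power is floored to machine epsilon with a warning.
* DiffRatio: per-frequency two-sample t-test on dBm values across trials;
  n_diff = #{p_i < α}, α = 0.1, DiffRatio = n_diff/1024. The default test
  is the pooled Student's t-test, which is exactly calibrated under
  normality at the 3–6-trial group sizes used here; Welch's variant is
  available but measurably conservative at those sizes (empirical type-I
  error ≈ 0.088 at n = 4). Undefined p-values (zero-variance identical
  groups) count as not significant. Tests are across trials, not across
  time windows.
* ΔP: elementwise dBm difference; the [−20, 20] dBm range is a display
  convention only, raw values are preserved.

## What the default circuit reproduces — and what it does not

With the shipped calibration, the 0 % (MDD) vs 100 % (normal) contrast
reproduces, at reduced scale: a large increase in pyramidal firing rate and
burst count with dopamine; a *decrease* in pyramidal mean membrane
potential (disynaptic inhibition through the now strongly active PV cells);
MSN rate differences that are small and not sign-consistent across seeds;
higher PV rates at high dopamine; a large DiffRatio between the MDD and
normal LFP spectra; and strong high-frequency (100–250 Hz) LFP enhancement
with dopamine. It does not reproduce two secondary observations: the mean
peak action-potential amplitude here *decreases* slightly at high rates
(sodium-channel inactivation at sustained fast firing), and the 30–50 Hz
sub-band power increases with dopamine rather than decreasing. Both are
plausible consequences of the calibration assumptions rather than the
model structure, and both are outside the directional properties the test
suite asserts.

## Provenance and calibration

The original parameter tables for this circuit are not available. Channel
complements, kinetics, geometries and densities were transcribed or adapted
from the cited source-model families (Wolf-type MSN; Durstewitz/Wang-type
PFC neurons and interneurons; Destexhe synapses) and then calibrated so the
four cell classes express their qualitative firing classes (burst-patterned
pyramidal firing, fast tonic PV firing, delayed sparse MSN firing) under
the default stimulus. Stimulus intervals and synaptic conductance
densities are likewise calibration assumptions, marked as such in the
parameter files. Tests therefore assert structure, invariants and
directional behaviour — never specific kinetic numbers.

Problem sizes used throughout (4 s trials, dt = 0.02 ms, 3 trials per
condition, 28 neurons) are the package's standard desk-scale conditions;
group-level statistics with hundreds of cells per condition would require
proportionally more trials.

## Known limitations

* D1-type MSNs, cholinergic/calretinin/somatostatin interneurons and VTA
  spiking dynamics are out of scope; dopamine is an input, not a dynamical
  variable.
* No synaptic plasticity, no direct dopamine action on synapses, no
  transmission delays, no gap junctions, no GABA_b.
* Calcium pools do not feed back onto conductances (no explicit KCa).
* The partially-inactivating current form has a negative-conductance
  residual at small a; with the shipped a = 0.9 the effect is negligible,
  but users lowering a should be aware of it.
* Temperature is fixed at 35 °C; no Q10 scaling.
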