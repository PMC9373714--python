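# dopanet

A biophysical simulator of the mesocorticolimbic **VTA–NAc–mPFC** circuit
for studying how dopamine concentration shapes neural activity in major
depressive disorder (MDD), together with the full analysis pipeline:
spike/burst statistics, spike-aligned current peaks, and local-field-potential
(LFP) spectral group comparisons.

It is written for computational neuroscientists and computational
psychiatrists who want a desk-scale, fully reproducible model of the
"low dopamine → hypoactive prefrontal pyramidal cells → disturbed
excitation–inhibition balance" hypothesis, with every parameter exposed in
editable YAML files.

## The model

The circuit contains 28 Hodgkin–Huxley neurons: 16 mPFC pyramidal cells
(soma–proximal–distal chains, 8 channel types), 2+2 mPFC PV/CB
interneurons, 4 NAc D2-type medium spiny neurons (1 soma + 10 spiny
dendrites, 15 channel types, star topology) and 2+2 NAc PV/CB interneurons.
Each compartment obeys

```
C_m dV/dt = I_stim − ΣI_ion − ΣI_compartment − ΣI_synapse
```

with Boltzmann-gated conductances `I = g·m^x·h^y·(V−E)`, a
partially-inactivating variant `I = g·m^x·(a·h−(1−a))·(V−E)`, and
calcium currents through the Goldman–Hodgkin–Katz flux equation coupled to a
submembrane calcium shell. Compartments couple through Rall's cable
formula; synapses are Destexhe-type two-state kinetic receptors
(`dr/dt = α[T](1−r) − βr`) for AMPA, NMDA (with the magnesium block
`B(V) = 1/(1+exp(−(V+15)/16.3))`) and GABA_a, with connection weights drawn
uniformly from (0, 1).

The VTA is not simulated as spiking units. Dopamine enters as a scalar
level *k* ∈ [0, 100] % that linearly interpolates a small set of channel
parameters between their 0 % value *a* and their 100 % value *b*:
`value(k) = a + (b−a)·k/100`. On pyramidal cells dopamine shifts
persistent-sodium (NaP) gating, scales down the slowly inactivating
potassium (KS) conductance and the HVA calcium conductances; on MSNs it
scales up the slow A-type potassium (KAs) conductance and scales down
Cav1.2. The MDD condition is *k* = 0.

Analysis follows the experiment's conventions: bursts open at an
inter-spike interval ≤ 40 ms and close above 100 ms; the LFP is the mean of
the 28 somatic potentials resampled to 500 Hz; PSDs live on a 1024-point
grid over [0, 250) Hz; **DiffRatio** is the fraction of those 1024
frequencies whose two-group t-test p-value falls below α = 0.1, and
**ΔP = 10·log10(P_DA/P_control)** maps the dBm difference between a
dopamine condition and the MDD baseline.

## Worked example

```bash
python examples/02_dopamine_contrast.py
```

prints (2 trials per condition, 4 s each):

```
MDD (0% DA):
  median rates (Hz): {'CB': 1.33, 'MSN': 6.0, 'PV': 35.0, 'PYR': 0.33}
  pyramidal: median 0.0 bursts, mean Vm -61.4 mV
normal (100% DA):
  median rates (Hz): {'CB': 74.0, 'MSN': 6.33, 'PV': 114.3, 'PYR': 13.67}
  pyramidal: median 1.0 bursts, mean Vm -64.9 mV
```

Pyramidal firing collapses from ~14 Hz to well under 1 Hz in the
no-dopamine (MDD) condition and burst firing disappears, while MSN rates
barely move — the hallmark contrast between MDD and normal groups. The
pyramidal mean membrane potential is *lower* at full dopamine because the
now strongly active PV interneurons feed GABAergic inhibition back onto the
pyramidal somata. `examples/03_lfp_spectra.py` shows the spectral face of
the same contrast:

```
DiffRatio (MDD vs normal): 0.688 (704/1024 frequencies significantly different)
   30- 50 Hz: power 0.0821 (MDD) vs 0.0956 (normal); mean Delta-P +14.1 dBm/Hz
   50-100 Hz: power 0.0106 (MDD) vs 0.0941 (normal); mean Delta-P +18.6 dBm/Hz
  100-250 Hz: power 0.00138 (MDD) vs 0.0342 (normal); mean Delta-P +17.1 dBm/Hz
```

The other examples cover the single-cell firing classes
(`01_single_cell_firing_classes.py`: burst-patterned pyramidal firing, fast
tonic PV firing) and the firing-rate-vs-dopamine regression with the
interquartile outlier filter (`04_dopamine_regression.py`).

A thin CLI mirrors the library
(`dopanet build | simulate | analyze | spectra | reproduce | describe | fixtures`);
try `dopanet describe --template MSN`.

## Parameters

All kinetics live in `src/dopanet/params/*.yaml` (one file per cell class,
plus receptor kinetics, dopamine-modulation endpoints and the network
manifest). Values marked as assumptions there are calibration choices, not
published numbers; see `docs/methods.md` for the full provenance and
modelling notes.
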