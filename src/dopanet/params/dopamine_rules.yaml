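# Dopamine-modulated channel parameters.  Each rule interpolates one
# parameter linearly between its 0%-dopamine value `a` (the value stored in
# the neuron parameter file) and its 100% value `b`:
#     value(k%) = a + (b - a) * k/100.
# `at_100` gives b either as {scale: s} (b = s*a) or {shift: dv} (b = a+dv).
#
# Endpoints follow the D1 modulation pattern of the Durstewitz-type PFC
# model (persistent-sodium gating shifted toward more availability, slowly
# inactivating potassium and high-voltage calcium conductances reduced) and
# the D2 pattern of the Wolf-type MSN model (slow A-type potassium enhanced,
# Cav1.2 reduced).  Magnitudes are assumptions (source tables unavailable).
#
# A compartment value ending in `*` matches all compartments whose name
# starts with the prefix.  Dopamine never touches receptor (synaptic)
# parameters.
rules:
  # mPFC pyramidal neurons, D1-type modulation
  - {kind: PYR, compartment: soma,     channel: Ca,     path: g_max, at_100: {scale: 0.70}}
  - {kind: PYR, compartment: soma,     channel: CaN,    path: g_max, at_100: {scale: 0.60}}
  - {kind: PYR, compartment: distal,   channel: Ca,     path: g_max, at_100: {scale: 0.70}}
  - {kind: PYR, compartment: distal,   channel: CaN,    path: g_max, at_100: {scale: 0.60}}
  - {kind: PYR, compartment: proximal, channel: KS,     path: g_max, at_100: {scale: 0.65}}
  - {kind: PYR, compartment: proximal, channel: NaP,    path: activation.v_half,   at_100: {shift: -5.0}}
  - {kind: PYR, compartment: proximal, channel: NaP,    path: inactivation.v_half, at_100: {shift: 5.0}}
  # NAc D2-type medium spiny neurons
  - {kind: MSN, compartment: soma,       channel: KAs,    path: g_max, at_100: {scale: 1.30}}
  - {kind: MSN, compartment: "dendrite*", channel: KAs,   path: g_max, at_100: {scale: 1.30}}
  - {kind: MSN, compartment: soma,       channel: CaL1.2, path: g_max, at_100: {scale: 0.70}}
  - {kind: MSN, compartment: "dendrite*", channel: CaL1.2, path: g_max, at_100: {scale: 0.70}}
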