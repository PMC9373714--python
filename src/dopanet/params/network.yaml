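# Default 28-neuron NAc-mPFC circuit manifest.
#
# Stated conventions: 28 neurons total; mPFC pyramidal:interneuron ratio
# 4:1.  The per-population split (mPFC 16 PYR + 2 PV + 2 CB, NAc 4 MSN +
# 2 PV + 2 CB) and the full edge list are assumptions consistent with those
# conventions.  VTA is not simulated: dopamine enters as the scalar
# schedule below.  Stimulus intervals (uA/cm^2, uniform, injected at the
# soma, redrawn every integration step inside the 500-3500 ms window) are
# assumptions calibrated to reproduce the qualitative firing classes
# (burst-patterned pyramidal firing, fast tonic PV firing).
name: default-28
populations:
  - {region: mPFC, kind: PYR, count: 16}
  - {region: mPFC, kind: PV,  count: 2}
  - {region: mPFC, kind: CB,  count: 2}
  - {region: NAc,  kind: MSN, count: 4}
  - {region: NAc,  kind: PV,  count: 2}
  - {region: NAc,  kind: CB,  count: 2}

# Glutamatergic edges originate from PYR (AMPA+NMDA); GABAergic edges from
# interneurons (GABAa).  MSN output projects to VTA, which is not simulated.
# Glutamate targets: pyramidal proximal dendrite / MSN dendrites;
# GABA targets: somata.
edges:
  - {pre: mPFC/PYR, post: mPFC/PV,  receptors: [AMPA, NMDA]}
  - {pre: mPFC/PYR, post: mPFC/CB,  receptors: [AMPA, NMDA]}
  - {pre: mPFC/PYR, post: NAc/MSN,  receptors: [AMPA, NMDA]}
  - {pre: mPFC/PYR, post: NAc/PV,   receptors: [AMPA, NMDA]}
  - {pre: mPFC/PYR, post: NAc/CB,   receptors: [AMPA, NMDA]}
  - {pre: mPFC/PV,  post: mPFC/PYR, receptors: [GABAa]}
  - {pre: mPFC/CB,  post: mPFC/PYR, receptors: [GABAa]}
  - {pre: NAc/PV,   post: NAc/MSN,  receptors: [GABAa]}
  - {pre: NAc/CB,   post: NAc/MSN,  receptors: [GABAa]}

stimulus:
  window: [500.0, 3500.0]   # ms
  redraw_ms: 0.02           # redraw every integration step
  intervals:
    mPFC/PYR: [1.5, 3.5]
    mPFC/PV:  [1.5, 3.0]
    mPFC/CB:  [1.5, 3.0]
    NAc/MSN:  [5.0, 8.0]
    NAc/PV:   [1.5, 3.0]
    NAc/CB:   [1.5, 3.0]

dopamine: {mode: fixed, level: 100.0}

protocol:
  duration: 4000.0   # ms
  dt: 0.02           # ms
  trials: 3

seed: 1234
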