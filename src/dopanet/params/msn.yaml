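# D2-type medium spiny neuron of NAc (MSN): 1 soma + 10 identical
# spiny-dendrite compartments (star topology), 15 voltage-gated channel
# types.  Kinetics adapted from the Wolf-type MSN model family: a strong
# inward rectifier holds the cell near -85 mV, fast and slow A-type
# potassium channels delay firing, and six calcium channel types use GHK
# flux.  The KAs channel uses the partially-inactivating current form with
# fraction a = 0.9.  Densities are assumptions (source tables unavailable).
kind: MSN
v_init: -85.0
capacitance: 1.0
axial_resistivity: 100.0

compartments:
  - {name: soma,     length: 16.0,  diameter: 16.0}
  - {name: dendrite, length: 190.0, diameter: 2.25, copies: 10}

adjacency:
  - [soma, dendrite]

calcium_pools:
  soma:     {ca_init: 0.001, ca_rest: 0.001}
  dendrite: {ca_init: 0.001, ca_rest: 0.001}

channels:
  soma:
    - name: leak
      mode: ohmic
      g_max: 0.08
      e_rev: -70.0
    - name: NaF
      mode: ohmic
      g_max: 60.0
      e_rev: 55.0
      activation: {power: 3, v_half: -28.0, slope: -6.5, tau: 0.08}
      inactivation:
        power: 1
        v_half: -52.0
        slope: 6.5
        tau: {v: [-100.0, -70.0, -55.0, -40.0, -20.0, 0.0, 40.0], tau: [2.5, 4.0, 5.0, 2.5, 1.0, 0.5, 0.4]}
    - name: NaP
      mode: ohmic
      g_max: 0.03
      e_rev: 55.0
      activation: {power: 1, v_half: -47.8, slope: -4.5, tau: 1.0}
    - name: KAf
      mode: ohmic
      g_max: 9.0
      e_rev: -90.0
      activation: {power: 2, v_half: -33.0, slope: -7.5, tau: 0.8}
      inactivation: {power: 1, v_half: -70.4, slope: 7.6, tau: 20.0}
    - name: KAs       # slow A-type, partially inactivating; DA scales g_max
      mode: partial
      partial_fraction: 0.9
      g_max: 2.5
      e_rev: -90.0
      activation:
        power: 2
        v_half: -25.6
        slope: -13.3
        tau: {v: [-100.0, -60.0, -20.0, 40.0], tau: [20.0, 15.0, 8.0, 5.0]}
      inactivation: {power: 1, v_half: -78.8, slope: 10.4, tau: 1100.0}
    - name: KIR
      mode: ohmic
      g_max: 1.2
      e_rev: -90.0
      activation: {power: 1, v_half: -82.0, slope: 13.0, tau: 0.5}
    - name: KRP       # persistent potassium
      mode: ohmic
      g_max: 0.8
      e_rev: -90.0
      activation: {power: 1, v_half: -13.5, slope: -11.8, tau: 10.0}
    - name: BK
      mode: ohmic
      g_max: 6.0
      e_rev: -90.0
      activation: {power: 1, v_half: -10.0, slope: -7.0, tau: 0.3}
    - name: SK
      mode: ohmic
      g_max: 0.8
      e_rev: -90.0
      activation: {power: 1, v_half: -20.0, slope: -6.0, tau: 60.0}
    - name: CaL1.2    # Cav1.2 L-type; DA scales p_max
      mode: ghk
      g_max: 4.0e-06
      activation: {power: 2, v_half: -8.9, slope: -6.7, tau: 1.2}
      inactivation: {power: 1, v_half: -45.0, slope: 12.0, tau: 300.0}
    - name: CaL1.3
      mode: ghk
      g_max: 1.5e-06
      activation: {power: 1, v_half: -33.0, slope: -6.7, tau: 1.5}
      inactivation: {power: 1, v_half: -45.0, slope: 12.0, tau: 300.0}
    - name: CaN
      mode: ghk
      g_max: 2.0e-06
      activation: {power: 2, v_half: -12.0, slope: -7.5, tau: 1.2}
      inactivation: {power: 1, v_half: -40.0, slope: 12.0, tau: 70.0}
    - name: CaQ
      mode: ghk
      g_max: 1.5e-06
      activation: {power: 2, v_half: -9.0, slope: -6.6, tau: 1.2}
    - name: CaR
      mode: ghk
      g_max: 2.0e-06
      activation: {power: 3, v_half: -10.3, slope: -6.6, tau: 1.5}
      inactivation: {power: 1, v_half: -33.3, slope: 9.0, tau: 22.0}
    - name: CaT
      mode: ghk
      g_max: 1.0e-06
      activation: {power: 3, v_half: -51.7, slope: -6.5, tau: 2.0}
      inactivation: {power: 1, v_half: -80.0, slope: 6.4, tau: 100.0}
  dendrite:
    - name: leak
      mode: ohmic
      g_max: 0.08
      e_rev: -70.0
    - name: NaF
      mode: ohmic
      g_max: 25.0
      e_rev: 55.0
      activation: {power: 3, v_half: -28.0, slope: -6.5, tau: 0.08}
      inactivation:
        power: 1
        v_half: -52.0
        slope: 6.5
        tau: {v: [-100.0, -70.0, -55.0, -40.0, -20.0, 0.0, 40.0], tau: [2.5, 4.0, 5.0, 2.5, 1.0, 0.5, 0.4]}
    - name: KAf
      mode: ohmic
      g_max: 3.0
      e_rev: -90.0
      activation: {power: 2, v_half: -33.0, slope: -7.5, tau: 0.8}
      inactivation: {power: 1, v_half: -70.4, slope: 7.6, tau: 20.0}
    - name: KAs
      mode: partial
      partial_fraction: 0.9
      g_max: 1.8
      e_rev: -90.0
      activation:
        power: 2
        v_half: -25.6
        slope: -13.3
        tau: {v: [-100.0, -60.0, -20.0, 40.0], tau: [20.0, 15.0, 8.0, 5.0]}
      inactivation: {power: 1, v_half: -78.8, slope: 10.4, tau: 1100.0}
    - name: KIR
      mode: ohmic
      g_max: 1.0
      e_rev: -90.0
      activation: {power: 1, v_half: -82.0, slope: 13.0, tau: 0.5}
    - name: CaL1.2
      mode: ghk
      g_max: 3.0e-06
      activation: {power: 2, v_half: -8.9, slope: -6.7, tau: 1.2}
      inactivation: {power: 1, v_half: -45.0, slope: 12.0, tau: 300.0}
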