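# mPFC layer-V pyramidal neuron (PYR): soma - proximal dendrite - distal
# dendrite chain, 8 voltage-gated channel types.  Kinetics adapted from the
# Durstewitz/Wang family of PFC models; geometry and conductance densities
# are assumptions calibrated to reproduce burst-patterned firing under the
# default stimulus (assumption: source tables unavailable).
kind: PYR
v_init: -68.0
capacitance: 1.0          # uF/cm^2
axial_resistivity: 150.0  # ohm*cm

compartments:
  - {name: soma,     length: 18.0,  diameter: 18.0}
  - {name: proximal, length: 150.0, diameter: 2.5}
  - {name: distal,   length: 200.0, diameter: 1.6}

adjacency:
  - [soma, proximal]
  - [proximal, distal]

calcium_pools:
  soma:   {ca_init: 0.001, ca_rest: 0.001}   # ca_rest assumed = initial value
  distal: {ca_init: 0.001, ca_rest: 0.001}

channels:
  soma:
    - name: leak
      mode: ohmic
      g_max: 0.10
      e_rev: -72.0
    - name: NaF
      mode: ohmic
      g_max: 50.0
      e_rev: 55.0
      activation: {power: 3, v_half: -30.0, slope: -7.0, tau: 0.08}
      inactivation:
        power: 1
        v_half: -53.0
        slope: 7.0
        tau: {v: [-100.0, -70.0, -55.0, -40.0, -20.0, 0.0, 40.0], tau: [3.0, 4.5, 5.5, 3.0, 1.0, 0.6, 0.5]}
    - name: KDR
      mode: ohmic
      g_max: 12.0
      e_rev: -90.0
      activation:
        power: 2
        v_half: -25.0
        slope: -9.0
        tau: {v: [-100.0, -40.0, -10.0, 40.0], tau: [4.0, 3.0, 1.2, 0.8]}
    - name: KM
      mode: ohmic
      g_max: 0.3
      e_rev: -90.0
      activation: {power: 1, v_half: -35.0, slope: -9.0, tau: 60.0}
    - name: Ca        # HVA calcium, GHK flux
      mode: ghk
      g_max: 4.0e-06  # p_max, cm/s
      activation: {power: 2, v_half: -10.0, slope: -7.0, tau: 1.5}
    - name: CaN       # N-type calcium, GHK flux
      mode: ghk
      g_max: 3.0e-06
      activation: {power: 2, v_half: -12.0, slope: -7.5, tau: 1.2}
      inactivation: {power: 1, v_half: -40.0, slope: 12.0, tau: 70.0}
  proximal:
    - name: leak
      mode: ohmic
      g_max: 0.10
      e_rev: -72.0
    - name: NaF
      mode: ohmic
      g_max: 25.0
      e_rev: 55.0
      activation: {power: 3, v_half: -30.0, slope: -7.0, tau: 0.08}
      inactivation:
        power: 1
        v_half: -53.0
        slope: 7.0
        tau: {v: [-100.0, -70.0, -55.0, -40.0, -20.0, 0.0, 40.0], tau: [3.0, 4.5, 5.5, 3.0, 1.0, 0.6, 0.5]}
    - name: KDR
      mode: ohmic
      g_max: 5.0
      e_rev: -90.0
      activation:
        power: 2
        v_half: -25.0
        slope: -9.0
        tau: {v: [-100.0, -40.0, -10.0, 40.0], tau: [4.0, 3.0, 1.2, 0.8]}
    - name: NaP       # persistent sodium; DA shifts its gating
      mode: ohmic
      g_max: 0.30
      e_rev: 55.0
      activation: {power: 1, v_half: -46.0, slope: -4.5, tau: 0.8}
      inactivation: {power: 1, v_half: -52.0, slope: 8.0, tau: 2000.0}
    - name: KS        # slowly inactivating potassium; DA scales g_max
      mode: ohmic
      g_max: 2.2
      e_rev: -90.0
      activation: {power: 1, v_half: -44.0, slope: -6.0, tau: 120.0}
      inactivation: {power: 1, v_half: -62.0, slope: 7.5, tau: 800.0}
  distal:
    - name: leak
      mode: ohmic
      g_max: 0.10
      e_rev: -72.0
    - name: KDR
      mode: ohmic
      g_max: 2.0
      e_rev: -90.0
      activation:
        power: 2
        v_half: -25.0
        slope: -9.0
        tau: {v: [-100.0, -40.0, -10.0, 40.0], tau: [4.0, 3.0, 1.2, 0.8]}
    - name: Ca
      mode: ghk
      g_max: 3.0e-06
      activation: {power: 2, v_half: -10.0, slope: -7.0, tau: 1.5}
    - name: CaN
      mode: ghk
      g_max: 2.0e-06
      activation: {power: 2, v_half: -12.0, slope: -7.5, tau: 1.2}
      inactivation: {power: 1, v_half: -40.0, slope: 12.0, tau: 70.0}
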