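# Calbindin-positive interneuron (CB): single compartment, 6 voltage-gated
# channel types.  A slower, adapting interneuron than PV: carries an A-type
# potassium channel, an M-like slow potassium channel and a small
# hyperpolarization-activated cation current.  Densities are assumptions.
kind: CB
v_init: -66.0
capacitance: 1.0
axial_resistivity: 150.0

compartments:
  - {name: soma, length: 15.0, diameter: 15.0}

adjacency: []

channels:
  soma:
    - name: leak
      mode: ohmic
      g_max: 0.09
      e_rev: -70.0
    - name: NaF
      mode: ohmic
      g_max: 50.0
      e_rev: 55.0
      activation: {power: 3, v_half: -33.0, slope: -6.5, tau: 0.08}
      inactivation:
        power: 1
        v_half: -54.0
        slope: 7.0
        tau: {v: [-100.0, -70.0, -55.0, -40.0, -20.0, 0.0, 40.0], tau: [2.5, 4.0, 5.0, 2.5, 1.0, 0.5, 0.4]}
    - name: KDR
      mode: ohmic
      g_max: 12.0
      e_rev: -90.0
      activation:
        power: 2
        v_half: -25.0
        slope: -9.0
        tau: {v: [-100.0, -40.0, -10.0, 40.0], tau: [4.0, 3.0, 1.2, 0.8]}
    - name: KA
      mode: ohmic
      g_max: 1.0
      e_rev: -90.0
      activation: {power: 2, v_half: -40.0, slope: -8.5, tau: 1.0}
      inactivation: {power: 1, v_half: -70.0, slope: 7.0, tau: 25.0}
    - name: KM
      mode: ohmic
      g_max: 0.2
      e_rev: -90.0
      activation: {power: 1, v_half: -35.0, slope: -9.0, tau: 80.0}
    - name: H
      mode: ohmic
      g_max: 0.15
      e_rev: -30.0
      activation: {power: 1, v_half: -80.0, slope: 8.0, tau: 400.0}
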