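# Parvalbumin-positive fast-spiking interneuron (PV): single compartment,
# 3 voltage-gated channel types (Wang-Buzsaki-flavoured kinetics with a
# Kv3-like fast delayed rectifier).  Densities are assumptions calibrated
# for fast tonic firing under the default stimulus.
kind: PV
v_init: -65.0
capacitance: 1.0
axial_resistivity: 150.0

compartments:
  - {name: soma, length: 15.0, diameter: 15.0}

adjacency: []

channels:
  soma:
    - name: leak
      mode: ohmic
      g_max: 0.10
      e_rev: -67.0
    - name: NaF
      mode: ohmic
      g_max: 80.0
      e_rev: 55.0
      activation: {power: 3, v_half: -32.0, slope: -6.0, tau: 0.05}
      inactivation:
        power: 1
        v_half: -55.0
        slope: 6.5
        tau: {v: [-100.0, -70.0, -55.0, -40.0, -20.0, 0.0, 40.0], tau: [2.0, 3.0, 3.5, 2.0, 0.8, 0.35, 0.3]}
    - name: KDR     # Kv3-like: fast activation and deactivation
      mode: ohmic
      g_max: 40.0
      e_rev: -90.0
      activation:
        power: 2
        v_half: -15.0
        slope: -8.0
        tau: {v: [-100.0, -40.0, -10.0, 40.0], tau: [1.5, 1.2, 0.5, 0.4]}
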