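# Destexhe-type two-state kinetic receptor parameters.
# alpha: binding rate (1/(mM*ms)); beta: unbinding rate (1/ms);
# t_max (mM), v_p, k_p (mV): transmitter-release sigmoid.
# g_max: conductance density on the postsynaptic compartment (mS/cm^2),
# applied per edge before the random (0,1) connection weight
# (assumption: densities calibrated for the default 28-neuron circuit).
AMPA:  {g_max: 0.35,  e_rev: 0.0,   alpha: 1.1,   beta: 0.19,   t_max: 1.0, v_p: 2.0, k_p: 5.0}
NMDA:  {g_max: 0.12,  e_rev: 0.0,   alpha: 0.072, beta: 0.0066, t_max: 1.0, v_p: 2.0, k_p: 5.0}
GABAa: {g_max: 0.30,  e_rev: -80.0, alpha: 5.0,   beta: 0.18,   t_max: 1.0, v_p: 2.0, k_p: 5.0}
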