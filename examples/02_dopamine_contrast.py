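"""MDD (0% dopamine) vs normal (100%) contrast in the full 28-neuron circuit.

Runs the default NAc-mPFC network at the two extreme dopamine levels
(2 trials each here, to keep the example fast) and prints the per-class
median firing rates, pyramidal burst counts and mean membrane potentials.

Expected directions: pyramidal firing rate and burst count are markedly
higher at 100% dopamine, the pyramidal mean membrane potential is lower
(stronger feedback inhibition), and MSN rates barely move.
"""

import numpy as np

from dopanet.analysis import (detect_bursts, detect_spikes, firing_rate,
                              mean_membrane_potential)
from dopanet.io import load_manifest
from dopanet.neuromod import DopamineSchedule
from dopanet.simulate import SimulationProtocol, run_trial

config = load_manifest()
proto = SimulationProtocol(duration=4000.0, dt=0.02)
window = (500.0, 3500.0)

for level in (0.0, 100.0):
    rates = {}
    bursts, vms = [], []
    for trial in range(2):
        rec = run_trial(config, proto, trial_index=trial,
                        condition_index=int(level),
                        da_schedule=DopamineSchedule(mode="fixed", level=level))
        for i, kind in enumerate(rec.neuron_kinds()):
            train = detect_spikes(rec.v_soma[i], rec.dt)
            rates.setdefault(kind, []).append(firing_rate(train, window))
            if kind == "PYR":
                bursts.append(detect_bursts(train).count)
                vms.append(mean_membrane_potential(rec.v_soma[i]))
    label = "MDD (0% DA)" if level == 0.0 else "normal (100% DA)"
    med = {k: float(np.median(v)) for k, v in sorted(rates.items())}
    print(f"{label}:")
    print(f"  median rates (Hz): {med}")
    print(f"  pyramidal: median {np.median(bursts):.1f} bursts, "
          f"mean Vm {np.median(vms):.1f} mV")
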