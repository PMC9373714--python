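"""Fixed-step integration of the full network and trial orchestration.

The integrator is an explicit Bogacki-Shampine 2(3) pair run at a fixed
step (default 0.02 ms); the embedded second-order solution provides a
logged error estimate only and never adapts the step, so every trial is
bitwise reproducible from its seed tuple.  Each trial derives three named
random streams -- connection weights, stimulus currents, dopamine level --
from a single (root seed, condition, trial) tuple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .engine import CompiledNetwork, compile_network
from .errors import ConfigError, NumericalBlowupError
from .network import Network, NetworkConfig, build_network
from .neuromod import (DopamineSchedule, apply_modulation, load_dopamine_rules,
                       sample_da_level)

__all__ = [
    "SimulationProtocol",
    "Recording",
    "rk_step",
    "run_trial",
    "run_experiment",
    "QUARTILE_RANGES",
    "FIXED_LEVELS",
]

#: Dopamine gradient designs: four uniform quartile ranges, five fixed levels.
QUARTILE_RANGES = ((0.0, 25.0), (25.0, 50.0), (50.0, 75.0), (75.0, 100.0))
FIXED_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)

MODULATED_KINDS = ("PYR", "MSN")


@dataclass
class SimulationProtocol:
    """Trial design: duration/step, recording selection, trial count."""

    duration: float = 4000.0      # ms
    dt: float = 0.02              # ms
    trials: int = 3
    record_all_compartments: bool = False
    probes: List[dict] = field(default_factory=list)
    spike_threshold: float = 0.0  # mV, used downstream by spike detection

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("duration must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @classmethod
    def from_config(cls, config: NetworkConfig, **overrides) -> "SimulationProtocol":
        raw = dict(config.protocol)
        raw.update(overrides)
        return cls(
            duration=float(raw.get("duration", 4000.0)),
            dt=float(raw.get("dt", 0.02)),
            trials=int(raw.get("trials", 3)),
            record_all_compartments=bool(raw.get("record_all_compartments", False)),
            probes=list(raw.get("probes", [])),
            spike_threshold=float(raw.get("spike_threshold", 0.0)),
        )


@dataclass
class Recording:
    """Traces and metadata from one trial; all traces share the time grid."""

    time: np.ndarray                       # ms, n_samples
    v_soma: np.ndarray                     # (n_neurons, n_samples) mV
    traces: Dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    spike_threshold: float = 0.0

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_neurons(self) -> int:
        return self.v_soma.shape[0]

    def neuron_kinds(self) -> List[str]:
        return list(self.metadata.get("kinds", []))


def rk_step(state: np.ndarray, deriv_fn, dt: float) -> np.ndarray:
    """One fixed-step Bogacki-Shampine 2(3) step (third-order accurate).

    Raises :class:`NumericalBlowupError` naming the first non-finite entry.
    """
    y = np.asarray(state, dtype=float)
    k1 = np.asarray(deriv_fn(y))
    k2 = np.asarray(deriv_fn(y + 0.5 * dt * k1))
    k3 = np.asarray(deriv_fn(y + 0.75 * dt * k2))
    y_new = y + dt * (2.0 * k1 + 3.0 * k2 + 4.0 * k3) / 9.0
    if not np.all(np.isfinite(y_new)):
        bad = int(np.where(~np.isfinite(y_new))[0][0])
        raise NumericalBlowupError(f"non-finite state component {bad} after rk_step")
    return y_new


def trial_seeds(root_seed: int, condition: int, trial: int) -> Tuple[int, int, int]:
    """Deterministic (weights, stimulus, dopamine) seed tuple for one cell."""
    ss = np.random.SeedSequence([int(root_seed), int(condition), int(trial)])
    w, s, d = ss.spawn(3)
    return tuple(int(x.generate_state(1)[0] % (2 ** 31)) for x in (w, s, d))


def _generate_stimulus(config: NetworkConfig, protocol: SimulationProtocol,
                       pop_keys: Sequence[str],
                       rng: np.random.Generator) -> np.ndarray:
    """Per-step, per-neuron stimulus matrix (uA/cm^2), zero outside the window."""
    stim_model = config.stimulus
    n_steps = protocol.n_steps
    n_neur = len(pop_keys)
    repeat = max(1, int(round(stim_model.redraw_ms / protocol.dt)))
    n_draws = int(np.ceil(n_steps / repeat))
    lo = np.array([stim_model.intervals[k][0] for k in pop_keys])
    hi = np.array([stim_model.intervals[k][1] for k in pop_keys])
    draws = rng.uniform(lo, hi, size=(n_draws, n_neur))
    stim = np.repeat(draws, repeat, axis=0)[:n_steps]
    t = np.arange(n_steps) * protocol.dt
    t_on, t_off = stim_model.window
    stim[(t < t_on) | (t >= t_off), :] = 0.0
    return np.ascontiguousarray(stim)


def _modulated_templates(network: Network, k_per_neuron: np.ndarray, rules):
    """Per-neuron template list with dopamine modulation applied."""
    cache: Dict[Tuple[str, float], object] = {}
    out = []
    for neuron in network.neurons:
        k = float(k_per_neuron[neuron.index])
        key = (neuron.kind, k)
        if key not in cache:
            if neuron.kind in MODULATED_KINDS:
                mod = apply_modulation({neuron.kind: network.templates[neuron.kind]},
                                       k, rules)
                cache[key] = mod[neuron.kind]
            else:
                cache[key] = network.templates[neuron.kind]
        out.append(cache[key])
    return out


def _probe_arrays(compiled: CompiledNetwork, probes: Sequence[dict]):
    kinds, idxs, names = [], [], []
    for p in probes:
        ptype = p["type"]
        if ptype == "channel":
            kinds.append(0)
            idxs.append(compiled.channel_index(p["neuron"], p["compartment"],
                                               p["channel"]))
            names.append(f"chan:{p['neuron']}:{p['compartment']}:{p['channel']}")
        elif ptype in ("epsc", "ipsc"):
            kinds.append(1 if ptype == "epsc" else 2)
            idxs.append(compiled.comp_index(p["neuron"], p["compartment"]))
            names.append(f"{ptype}:{p['neuron']}:{p['compartment']}")
        else:
            raise ConfigError(f"unknown probe type {ptype!r}")
    return (np.asarray(kinds, dtype=np.int64), np.asarray(idxs, dtype=np.int64),
            names)


def run_trial(network_or_config: Union[Network, NetworkConfig],
              protocol: SimulationProtocol,
              trial_index: int = 0,
              condition_index: int = 0,
              da_schedule: Optional[DopamineSchedule] = None,
              root_seed: Optional[int] = None,
              rules=None) -> Recording:
    """Simulate one trial; bitwise reproducible given the seed tuple.

    If a :class:`NetworkConfig` is given, connection weights are drawn with
    the trial's weight stream; a prebuilt :class:`Network` keeps its weights.
    The dopamine level is sampled once per modulated neuron at t = 0 and
    held constant for the whole trial.
    """
    if isinstance(network_or_config, Network):
        network = network_or_config
        config = network.config
    else:
        config = network_or_config
        network = None
    if root_seed is None:
        root_seed = config.seed
    if da_schedule is None:
        da_schedule = config.da_schedule

    w_seed, s_seed, d_seed = trial_seeds(root_seed, condition_index, trial_index)
    if network is None:
        network = build_network(config, rng=np.random.default_rng(w_seed))
    if rules is None:
        rules = load_dopamine_rules(network.templates)

    rng_da = np.random.default_rng(d_seed)
    k_per_neuron = np.empty(network.n_neurons)
    for neuron in network.neurons:
        if neuron.kind in MODULATED_KINDS:
            k_per_neuron[neuron.index] = sample_da_level(da_schedule, rng_da)
        else:
            k_per_neuron[neuron.index] = np.nan

    templates = _modulated_templates(network, np.nan_to_num(k_per_neuron, nan=0.0),
                                     rules)
    compiled = compile_network(templates, network.edges)

    pop_keys = [n.population for n in network.neurons]
    stim = _generate_stimulus(config, protocol, pop_keys,
                              np.random.default_rng(s_seed))

    if protocol.record_all_compartments:
        rec_v_idx = np.arange(compiled.comp_cm.shape[0], dtype=np.int64)
        rec_labels = list(compiled.comp_labels)
    else:
        rec_v_idx = compiled.soma_comp.copy()
        rec_labels = [compiled.comp_labels[i] for i in rec_v_idx]
    probe_kind, probe_idx, probe_names = _probe_arrays(compiled, protocol.probes)

    y = compiled.initial_state()
    v_out, probe_out, max_err = compiled.run(
        y, protocol.n_steps, protocol.dt, stim, rec_v_idx,
        probe_kind if probe_kind.size else None,
        probe_idx if probe_idx.size else None,
    )

    time = np.arange(protocol.n_steps + 1) * protocol.dt
    soma_rows = [rec_labels.index(compiled.comp_labels[i])
                 for i in compiled.soma_comp]
    traces = {name: probe_out[j] for j, name in enumerate(probe_names)}
    if protocol.record_all_compartments:
        for j, label in enumerate(rec_labels):
            traces[f"v:{label}"] = v_out[j]
    recording = Recording(
        time=time,
        v_soma=np.ascontiguousarray(v_out[soma_rows]),
        traces=traces,
        metadata={
            "kinds": [n.kind for n in network.neurons],
            "regions": [n.region for n in network.neurons],
            "populations": pop_keys,
            "k_percent": [None if np.isnan(k) else float(k) for k in k_per_neuron],
            "seeds": {"weights": w_seed, "stimulus": s_seed, "dopamine": d_seed},
            "root_seed": int(root_seed),
            "condition_index": int(condition_index),
            "trial_index": int(trial_index),
            "duration_ms": protocol.duration,
            "dt_ms": protocol.dt,
            "max_embedded_error": float(max_err),
        },
        spike_threshold=protocol.spike_threshold,
    )
    return recording


def run_experiment(config: NetworkConfig,
                   design: str = "quartile",
                   protocol: Optional[SimulationProtocol] = None,
                   trials: Optional[int] = None,
                   root_seed: Optional[int] = None) -> Tuple[List[Recording], List[dict]]:
    """Run a full condition x trial design; returns (recordings, ledger rows).

    ``design``: "quartile" (uniform DA ranges, default 3 trials each) or
    "fixed5" (five fixed DA levels, default 6 trials each).  Failed cells
    are recorded in the ledger without aborting the rest.
    """
    if protocol is None:
        protocol = SimulationProtocol.from_config(config)
    if design == "quartile":
        conditions = [DopamineSchedule(mode="uniform_range", range=r)
                      for r in QUARTILE_RANGES]
        labels = [f"range:{int(lo)}-{int(hi)}" for lo, hi in QUARTILE_RANGES]
        n_trials = trials if trials is not None else 3
    elif design == "fixed5":
        conditions = [DopamineSchedule(mode="fixed", level=lv) for lv in FIXED_LEVELS]
        labels = [f"fixed:{int(lv)}" for lv in FIXED_LEVELS]
        n_trials = trials if trials is not None else 6
    else:
        raise ConfigError(f"unknown design {design!r}; expected quartile or fixed5")

    from .io import recording_checksum

    recordings: List[Recording] = []
    ledger: List[dict] = []
    for ci, (schedule, label) in enumerate(zip(conditions, labels)):
        for ti in range(n_trials):
            entry = {"condition": label, "condition_index": ci, "trial": ti,
                     "seeds": trial_seeds(root_seed if root_seed is not None
                                          else config.seed, ci, ti)}
            try:
                rec = run_trial(config, protocol, trial_index=ti,
                                condition_index=ci, da_schedule=schedule,
                                root_seed=root_seed)
                rec.metadata["condition"] = label
                entry["checksum"] = recording_checksum(rec)
                entry["status"] = "ok"
                recordings.append(rec)
            except NumericalBlowupError as exc:
                entry["status"] = "failed"
                entry["error"] = str(exc)
            ledger.append(entry)
    return recordings, ledger
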