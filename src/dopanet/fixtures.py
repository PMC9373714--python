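"""Deterministic miniature inputs for tests and demos.

Everything here is synthetic and generated at run time: a two-neuron
network manifest, sinusoid and white-noise traces, a hand-constructed spike
train, and sets of white-noise spectra.  All outputs are fully determined
by their seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .errors import ConfigError
from .network import EdgeGroupSpec, NetworkConfig, Population, StimulusModel
from .neuromod import DopamineSchedule

__all__ = [
    "FixtureSpec",
    "two_neuron_config",
    "sinusoid_trace",
    "constructed_spike_train",
    "white_noise_traces",
    "generate_fixture",
]

#: Spike times (ms) whose 40/100 ms burst decomposition is two bursts:
#: {0, 30, 60} and {200, 230}.
BURST_EXAMPLE_TIMES = (0.0, 30.0, 60.0, 200.0, 230.0, 400.0)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str                      # two_neuron_net | sinusoid | spike_train | noise_spectra
    seed: int = 0
    params: dict = field(default_factory=dict)


def two_neuron_config(seed: int = 0, duration: float = 1000.0,
                      stim_pyr=(1.0, 2.0), stim_pv=(0.5, 1.0)) -> NetworkConfig:
    """A minimal PYR<->PV loop for engine-consistency and smoke tests."""
    cfg = NetworkConfig(
        name="two-neuron-fixture",
        populations=[Population("mPFC", "PYR", 1), Population("mPFC", "PV", 1)],
        edges=[
            EdgeGroupSpec("mPFC/PYR", "mPFC/PV", ("AMPA", "NMDA")),
            EdgeGroupSpec("mPFC/PV", "mPFC/PYR", ("GABAa",)),
        ],
        stimulus=StimulusModel(
            intervals={"mPFC/PYR": tuple(stim_pyr), "mPFC/PV": tuple(stim_pv)},
            window=(duration / 4.0, duration),
        ),
        da_schedule=DopamineSchedule(mode="fixed", level=100.0),
        protocol={"duration": duration, "dt": 0.02, "trials": 1},
        seed=seed,
    )
    cfg.warnings.clear()  # 1:1 ratio is deliberate in this fixture
    return cfg


#: Demo stimulus intervals (uA/cm^2) per cell class for single-cell
#: protocols.  The demo uses a 20 ms redraw period to emulate in-vivo-like
#: fluctuating background drive (the network default redraws every step).
DEMO_STIMULUS = {"PYR": (0.0, 2.0), "PV": (2.0, 4.0),
                 "CB": (3.5, 5.5), "MSN": (5.0, 8.0)}


def single_cell_demo_config(kind: str, duration: float = 4000.0,
                            da_level: float = 100.0,
                            seed: int = 7) -> NetworkConfig:
    """One isolated neuron under the demo stimulus protocol.

    The stimulus window is the canonical 500-3500 ms; dopamine is a fixed
    level (default: the normal, 100% condition).
    """
    if kind not in DEMO_STIMULUS:
        raise ConfigError(f"no demo protocol for kind {kind!r}")
    region = "NAc" if kind == "MSN" else "mPFC"
    cfg = NetworkConfig(
        name=f"single-{kind.lower()}-demo",
        populations=[Population(region, kind, 1)],
        edges=[],
        stimulus=StimulusModel(
            intervals={f"{region}/{kind}": DEMO_STIMULUS[kind]},
            window=(500.0, min(3500.0, duration)),
            redraw_ms=20.0,
        ),
        da_schedule=DopamineSchedule(mode="fixed", level=da_level),
        protocol={"duration": duration, "dt": 0.02, "trials": 1},
        seed=seed,
    )
    cfg.warnings.clear()
    return cfg


def sinusoid_trace(freq_hz: float, duration_ms: float, rate_hz: float,
                   amplitude: float = 1.0, offset: float = 0.0) -> np.ndarray:
    n = int(round(duration_ms / 1000.0 * rate_hz))
    t = np.arange(n) / rate_hz
    return offset + amplitude * np.sin(2.0 * np.pi * freq_hz * t)


def constructed_spike_train() -> np.ndarray:
    return np.asarray(BURST_EXAMPLE_TIMES, dtype=float)


def white_noise_traces(n_trials: int, n_samples: int, seed: int,
                       scale: float = 1.0, mean: float = 0.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return mean + scale * rng.standard_normal((n_trials, n_samples))


def generate_fixture(spec: FixtureSpec, out_dir: str) -> List[str]:
    """Write one fixture to ``out_dir``; returns the created file paths."""
    os.makedirs(out_dir, exist_ok=True)
    written: List[str] = []
    if spec.kind == "two_neuron_net":
        cfg = two_neuron_config(seed=spec.seed, **spec.params)
        path = os.path.join(out_dir, "two_neuron_net.json")
        payload = {
            "name": cfg.name,
            "populations": [[p.region, p.kind, p.count] for p in cfg.populations],
            "edges": [[e.pre, e.post, list(e.receptors)] for e in cfg.edges],
            "seed": cfg.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        written.append(path)
    elif spec.kind == "sinusoid":
        p = {"freq_hz": 40.0, "duration_ms": 2000.0, "rate_hz": 500.0}
        p.update(spec.params)
        trace = sinusoid_trace(**p)
        path = os.path.join(out_dir, "sinusoid.csv")
        np.savetxt(path, trace, header=json.dumps(p), comments="# ")
        written.append(path)
    elif spec.kind == "spike_train":
        path = os.path.join(out_dir, "spike_train.csv")
        np.savetxt(path, constructed_spike_train(),
                   header="spike times (ms), two bursts under the 40/100 ms rule",
                   comments="# ")
        written.append(path)
    elif spec.kind == "noise_spectra":
        p = {"n_trials": 6, "n_samples": 2000}
        p.update(spec.params)
        traces = white_noise_traces(seed=spec.seed, **p)
        path = os.path.join(out_dir, "noise_traces.csv")
        np.savetxt(path, traces, header=json.dumps({**p, "seed": spec.seed}),
                   comments="# ")
        written.append(path)
    else:
        raise ConfigError(f"unknown fixture kind {spec.kind!r}")
    return written
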