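"""Assembly of the 28-neuron NAc-mPFC circuit.

Populations are instantiated from neuron templates; directed synapse groups
are expanded into per-cell-pair edges with one connection weight drawn from
U(0,1) per pair (shared by AMPA and NMDA when both are present on a
glutamatergic edge).  The VTA is represented only by the dopamine schedule.

Default wiring (config-overridable, an assumption beyond the stated total of
28 neurons and the 4:1 mPFC pyramidal:interneuron ratio): pyramidal cells
project glutamate to both regions' interneurons and to the MSNs; mPFC
interneurons inhibit pyramidal cells; NAc interneurons inhibit MSNs; MSN
output targets the (unsimulated) VTA.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cells import NeuronTemplate, build_template
from .errors import ConfigError
from .neuromod import DopamineSchedule
from .synapses import ReceptorSpec, SynapseEdge

__all__ = [
    "Population",
    "EdgeGroupSpec",
    "StimulusModel",
    "NetworkConfig",
    "Neuron",
    "Network",
    "build_network",
    "sample_stimuli",
]

GLUTAMATERGIC = ("PYR",)
GABAERGIC = ("PV", "CB", "MSN")


@dataclass(frozen=True)
class Population:
    region: str
    kind: str
    count: int

    @property
    def key(self) -> str:
        return f"{self.region}/{self.kind}"


@dataclass(frozen=True)
class EdgeGroupSpec:
    pre: str                 # population key "region/kind"
    post: str
    receptors: Tuple[str, ...]


@dataclass
class StimulusModel:
    """Uniform random somatic stimulus per population.

    ``intervals`` maps population keys to [min, max] current densities
    (uA/cm^2); outside ``window`` the stimulus is zero; values are redrawn
    every ``redraw_ms`` (default: one integration step).
    """

    intervals: Dict[str, Tuple[float, float]]
    window: Tuple[float, float] = (500.0, 3500.0)
    redraw_ms: float = 0.02

    def __post_init__(self):
        for key, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ConfigError(f"stimulus interval for {key} has min > max")
        t_on, t_off = self.window
        if t_on >= t_off:
            raise ConfigError("stimulus window must satisfy t_on < t_off")
        if self.redraw_ms <= 0:
            raise ConfigError("stimulus redraw period must be positive")


@dataclass
class NetworkConfig:
    name: str
    populations: List[Population]
    edges: List[EdgeGroupSpec]
    stimulus: StimulusModel
    da_schedule: DopamineSchedule
    protocol: dict
    seed: int
    warnings: List[str] = field(default_factory=list)
    source: Optional[str] = None

    @classmethod
    def from_dict(cls, doc: dict, source: Optional[str] = None) -> "NetworkConfig":
        try:
            pops = [Population(p["region"], p["kind"], int(p["count"]))
                    for p in doc["populations"]]
            edges = [EdgeGroupSpec(e["pre"], e["post"], tuple(e["receptors"]))
                     for e in doc["edges"]]
            stim_raw = doc["stimulus"]
            stim = StimulusModel(
                intervals={k: tuple(map(float, v)) for k, v in stim_raw["intervals"].items()},
                window=tuple(map(float, stim_raw.get("window", (500.0, 3500.0)))),
                redraw_ms=float(stim_raw.get("redraw_ms", 0.02)),
            )
            da_raw = doc.get("dopamine", {"mode": "fixed", "level": 100.0})
            if da_raw.get("mode", "fixed") == "fixed":
                da = DopamineSchedule(mode="fixed", level=float(da_raw.get("level", 100.0)))
            else:
                da = DopamineSchedule(mode="uniform_range",
                                      range=tuple(map(float, da_raw["range"])))
            cfg = cls(
                name=doc.get("name", "unnamed"),
                populations=pops,
                edges=edges,
                stimulus=stim,
                da_schedule=da,
                protocol=dict(doc.get("protocol", {})),
                seed=int(doc.get("seed", 0)),
                source=source,
            )
        except KeyError as exc:
            raise ConfigError(f"{source or 'manifest'}: missing field {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        keys = {p.key for p in self.populations}
        for e in self.edges:
            if e.pre not in keys or e.post not in keys:
                raise ConfigError(f"edge {e.pre}->{e.post} references unknown population")
            pre_kind = e.pre.split("/")[1]
            if pre_kind in GLUTAMATERGIC and set(e.receptors) - {"AMPA", "NMDA"}:
                raise ConfigError(f"glutamatergic edge {e.pre}->{e.post} with {e.receptors}")
            if pre_kind in GABAERGIC and set(e.receptors) != {"GABAa"}:
                raise ConfigError(f"GABAergic edge {e.pre}->{e.post} must use GABAa only")
        for p in self.populations:
            if p.key not in self.stimulus.intervals:
                raise ConfigError(f"no stimulus interval for population {p.key}")
        n_pyr = sum(p.count for p in self.populations if p.region == "mPFC" and p.kind == "PYR")
        n_int = sum(p.count for p in self.populations
                    if p.region == "mPFC" and p.kind in ("PV", "CB"))
        if n_int and n_pyr != 4 * n_int:
            msg = (f"mPFC pyramidal:interneuron ratio is {n_pyr}:{n_int}, "
                   "the stated convention is 4:1")
            self.warnings.append(msg)
            _warnings.warn(msg, stacklevel=2)

    @property
    def total_neurons(self) -> int:
        return sum(p.count for p in self.populations)

    def to_dict(self) -> dict:
        """Manifest-shaped dict; load -> dump -> load is idempotent."""
        da = ({"mode": "fixed", "level": self.da_schedule.level}
              if self.da_schedule.mode == "fixed"
              else {"mode": "uniform_range", "range": list(self.da_schedule.range)})
        return {
            "name": self.name,
            "populations": [{"region": p.region, "kind": p.kind, "count": p.count}
                            for p in self.populations],
            "edges": [{"pre": e.pre, "post": e.post, "receptors": list(e.receptors)}
                      for e in self.edges],
            "stimulus": {
                "window": list(self.stimulus.window),
                "redraw_ms": self.stimulus.redraw_ms,
                "intervals": {k: list(v) for k, v in self.stimulus.intervals.items()},
            },
            "dopamine": da,
            "protocol": dict(self.protocol),
            "seed": self.seed,
        }


@dataclass
class Neuron:
    index: int
    region: str
    kind: str
    population: str


@dataclass
class Network:
    """An assembled circuit: neurons, templates, receptors, weighted edges."""

    config: NetworkConfig
    neurons: List[Neuron]
    templates: Dict[str, NeuronTemplate]
    receptors: Dict[str, ReceptorSpec]
    edges: List[SynapseEdge]
    weight_seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def neurons_of_kind(self, kind: str, region: Optional[str] = None) -> List[Neuron]:
        return [n for n in self.neurons
                if n.kind == kind and (region is None or n.region == region)]

    def weight_table(self) -> pd.DataFrame:
        """Dense edge table (pre, post, compartment, receptor, weight)."""
        return pd.DataFrame(
            {
                "pre": [e.pre for e in self.edges],
                "post": [e.post for e in self.edges],
                "post_compartment": [e.post_compartment for e in self.edges],
                "receptor": [e.receptor.kind for e in self.edges],
                "weight": [e.weight for e in self.edges],
            }
        )

    def audit_transmitters(self) -> None:
        """Every GABA edge must come from an interneuron/MSN, glutamate from PYR."""
        kind_of = {n.index: n.kind for n in self.neurons}
        for e in self.edges:
            pre_kind = kind_of[e.pre]
            if e.receptor.kind == "GABAa" and pre_kind not in GABAERGIC:
                raise ConfigError(f"GABAergic edge from non-GABAergic cell {pre_kind}")
            if e.receptor.kind in ("AMPA", "NMDA") and pre_kind not in GLUTAMATERGIC:
                raise ConfigError(f"glutamatergic edge from non-glutamatergic cell {pre_kind}")


def _glut_target(template: NeuronTemplate, pre_rank: int) -> str:
    """Compartment receiving glutamate on a given cell class."""
    names = template.compartment_names
    if template.kind == "PYR":
        return "proximal"
    if template.kind == "MSN":
        dendrites = [n for n in names if n != "soma"]
        return dendrites[pre_rank % len(dendrites)]
    return names[0]


def build_network(config: NetworkConfig,
                  rng: Optional[np.random.Generator] = None,
                  templates: Optional[Dict[str, NeuronTemplate]] = None,
                  receptors: Optional[Dict[str, ReceptorSpec]] = None) -> Network:
    """Instantiate neurons and draw connection weights.

    ``rng`` (or ``config.seed``) fully determines the weight matrix: one
    U(0,1) draw per directed cell pair per edge group, in manifest order.
    """
    from .io import load_receptor_file

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if templates is None:
        kinds = sorted({p.kind for p in config.populations})
        templates = {k: build_template(k) for k in kinds}
    if receptors is None:
        receptors = load_receptor_file()

    neurons: List[Neuron] = []
    members: Dict[str, List[int]] = {}
    idx = 0
    for pop in config.populations:
        members[pop.key] = []
        for _ in range(pop.count):
            neurons.append(Neuron(index=idx, region=pop.region, kind=pop.kind,
                                  population=pop.key))
            members[pop.key].append(idx)
            idx += 1

    edges: List[SynapseEdge] = []
    for group in config.edges:
        pre_ids = members[group.pre]
        post_ids = members[group.post]
        post_kind = group.post.split("/")[1]
        post_template = templates[post_kind]
        for pre_rank, pre in enumerate(pre_ids):
            for post in post_ids:
                w = float(rng.uniform(0.0, 1.0))
                w = w if w > 0.0 else np.nextafter(0.0, 1.0)
                for rk in group.receptors:
                    spec = receptors[rk]
                    target = (_glut_target(post_template, pre_rank)
                              if rk in ("AMPA", "NMDA")
                              else post_template.compartment_names[0])
                    edges.append(SynapseEdge(pre=pre, post=post,
                                             post_compartment=target,
                                             receptor=spec, weight=w))

    net = Network(config=config, neurons=neurons, templates=templates,
                  receptors=receptors, edges=edges, weight_seed=config.seed)
    net.audit_transmitters()
    return net


def sample_stimuli(model: StimulusModel, t: float, rng: np.random.Generator,
                   population_keys: Sequence[str]) -> np.ndarray:
    """Per-neuron stimulus current at time ``t`` (zero outside the window)."""
    t_on, t_off = model.window
    out = np.zeros(len(population_keys))
    if t < t_on or t > t_off:
        return out
    for i, key in enumerate(population_keys):
        lo, hi = model.intervals[key]
        out[i] = rng.uniform(lo, hi)
    return out
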