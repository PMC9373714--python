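"""Neuron templates: compartment graphs, Rall coupling and the membrane equation.

Four cell classes are modelled:

* ``MSN`` -- D2-type medium spiny neuron of NAc: one soma plus 10 identical
  spiny-dendrite compartments in a star topology, 15 channel types.
* ``PYR`` -- mPFC pyramidal neuron: soma--proximal--distal chain (basal
  dendrites are not modelled), 8 channel types.
* ``PV``/``CB`` -- parvalbumin / calbindin interneurons: single compartment,
  3 / 6 channel types.

The per-compartment membrane equation is

    C_m dV/dt = I_stimuli - sum(I_ion) - sum(I_compartment) - sum(I_synapse)

with every current expressed as a density (uA/cm^2) so that C_m in uF/cm^2
yields dV/dt in mV/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .channels import CalciumPool, ChannelSpec
from .errors import ConfigError, ParameterError, TopologyError

__all__ = [
    "CompartmentSpec",
    "NeuronTemplate",
    "coupling_conductance",
    "membrane_derivative",
    "build_template",
    "KINDS",
    "CHANNEL_TYPE_COUNTS",
]

KINDS = ("MSN", "PYR", "PV", "CB")

#: Number of distinct voltage-gated channel types per cell class.
CHANNEL_TYPE_COUNTS = {"MSN": 15, "PYR": 8, "PV": 3, "CB": 6}


@dataclass
class CompartmentSpec:
    """Geometry, passive properties and channel complement of one compartment.

    length/diameter in um, c_m in uF/cm^2, r_l (axial resistivity) in ohm*cm.
    """

    name: str
    length: float
    diameter: float
    c_m: float = 1.0
    r_l: float = 150.0
    channels: List[ChannelSpec] = field(default_factory=list)
    ca_pool: Optional[CalciumPool] = None

    def __post_init__(self):
        for attr in ("length", "diameter", "c_m", "r_l"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"compartment {self.name}: {attr} must be positive")


@dataclass
class NeuronTemplate:
    """A cell class as a small compartment graph with channels attached."""

    kind: str
    compartments: List[CompartmentSpec]
    adjacency: List[Tuple[str, str]]
    v_init: float = -70.0

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ConfigError(f"{self.kind}: duplicate compartment names")
        for a, b in self.adjacency:
            if a not in names or b not in names:
                raise ConfigError(f"{self.kind}: adjacency references unknown compartment ({a}, {b})")

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(f"{self.kind} has no compartment {name!r}")

    @property
    def compartment_names(self) -> List[str]:
        return [c.name for c in self.compartments]

    @property
    def channel_types(self) -> List[str]:
        seen: List[str] = []
        for c in self.compartments:
            for ch in c.channels:
                if ch.name not in seen:
                    seen.append(ch.name)
        return seen

    def neighbors(self, name: str) -> List[str]:
        out = []
        for a, b in self.adjacency:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out

    def validate_class_invariants(self) -> None:
        """Check the structural invariants of the cell class."""
        n = len(self.compartments)
        if self.kind == "MSN":
            if n != 11:
                raise ConfigError(f"MSN must have 11 compartments, got {n}")
            deg = {c.name: len(self.neighbors(c.name)) for c in self.compartments}
            if deg.get("soma") != 10 or any(
                d != 1 for name, d in deg.items() if name != "soma"
            ):
                raise ConfigError("MSN must be a star of 10 dendrites around the soma")
        elif self.kind == "PYR":
            if n != 3 or len(self.adjacency) != 2:
                raise ConfigError("PYR must be a soma-proximal-distal chain")
        elif self.kind in ("PV", "CB"):
            if n != 1:
                raise ConfigError(f"{self.kind} must be single-compartment")
        else:
            raise ConfigError(f"unknown cell kind {self.kind!r}")
        expected = CHANNEL_TYPE_COUNTS[self.kind]
        got = len(self.channel_types)
        if got != expected:
            raise ConfigError(
                f"{self.kind} must carry {expected} channel types, got {got}"
            )


def coupling_conductance(a: CompartmentSpec, b: CompartmentSpec,
                         adjacency: Optional[Sequence[Tuple[str, str]]] = None) -> float:
    """Rall coupling conductance of compartment ``a`` receiving from ``b``.

    g = (d_a * d_b^2) / (r_L * l_a * (d_a^2 * l_b + d_b^2 * l_a))

    evaluated in cm with ``a``'s axial resistivity, returned in mS/cm^2 of
    the receiving compartment's membrane.  The coupling current into ``a``
    is g * (V_a - V_b) (it vanishes at equal potentials and pulls ``a``
    toward ``b``).  For identical compartments this reduces to
    d / (2 * r_L * l^2).
    """
    if adjacency is not None:
        pair_ok = any({a.name, b.name} == {x, y} for x, y in adjacency)
        if not pair_ok:
            raise TopologyError(f"compartments {a.name} and {b.name} are not adjacent")
    um = 1e-4  # um -> cm
    d_a, d_b = a.diameter * um, b.diameter * um
    l_a, l_b = a.length * um, b.length * um
    g_s_per_cm2 = (d_a * d_b ** 2) / (a.r_l * l_a * (d_a ** 2 * l_b + d_b ** 2 * l_a))
    return 1e3 * g_s_per_cm2  # S/cm^2 -> mS/cm^2


def _total(x) -> float:
    if np.ndim(x) == 0:
        return float(x)
    return float(np.sum(x))


def membrane_derivative(c_m: float, i_stimulus=0.0, i_ion=0.0,
                        i_compartment=0.0, i_synapse=0.0):
    """dV/dt (mV/ms) from the four current groups (densities, uA/cm^2).

    Sequence arguments are summed; positive stimulus depolarises, positive
    ionic/coupling/synaptic currents are outward and hyperpolarise.
    """
    if c_m <= 0:
        raise ParameterError("membrane capacitance must be positive")
    return (
        _total(i_stimulus) - _total(i_ion) - _total(i_compartment) - _total(i_synapse)
    ) / c_m


def build_template(kind: str, params_dir: Optional[str] = None) -> NeuronTemplate:
    """Load the shipped parameter file for ``kind`` and validate it.

    ``params_dir`` overrides the packaged parameter directory (useful for
    experiments with edited channel tables).
    """
    if kind not in KINDS:
        raise ConfigError(f"unknown cell kind {kind!r}; expected one of {KINDS}")
    from .io import load_neuron_file, packaged_param_path

    path = packaged_param_path(f"{kind.lower()}.yaml", params_dir)
    template = load_neuron_file(path)
    if template.kind != kind:
        raise ConfigError(f"{path} declares kind {template.kind!r}, expected {kind!r}")
    template.validate_class_invariants()
    return template
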