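"""Kinetic two-state receptor models (AMPA, NMDA, GABA_a).

Transmitter release is an instantaneous sigmoid function of the presynaptic
somatic potential,

    [T](V_pre) = T_max / (1 + exp(-(V_pre - V_p)/K_p)),

and the open-receptor fraction r follows first-order binding kinetics

    dr/dt = alpha*[T]*(1 - r) - beta*r.

AMPA and GABA_a currents are ohmic in r; the NMDA current is additionally
scaled by the voltage-dependent magnesium block

    B(V) = 1 / (1 + exp(-(V + 15)/16.3)).

Per-target currents from several presynaptic partners are combined as a
weighted sum with connection weights drawn uniformly from (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ParameterError, WrongModeError

__all__ = [
    "ReceptorSpec",
    "ReceptorState",
    "SynapseEdge",
    "transmitter_concentration",
    "receptor_derivative",
    "ampa_gaba_current",
    "mg_block",
    "nmda_current",
    "weighted_synaptic_sum",
]

RECEPTOR_KINDS = ("AMPA", "NMDA", "GABAa")


@dataclass(frozen=True)
class ReceptorSpec:
    """Kinetic parameters of one ligand-gated receptor type.

    alpha in 1/(mM*ms), beta in 1/ms, t_max in mM, v_p/k_p in mV,
    g_max as a conductance density on the postsynaptic compartment
    (mS/cm^2, before the connection weight is applied).
    """

    kind: str
    g_max: float
    e_rev: float
    alpha: float
    beta: float
    t_max: float = 1.0
    v_p: float = 2.0
    k_p: float = 5.0

    def __post_init__(self):
        if self.kind not in RECEPTOR_KINDS:
            raise ParameterError(f"unknown receptor kind {self.kind!r}")
        for name in ("alpha", "beta", "t_max", "k_p"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"receptor parameter {name} must be positive")
        if self.g_max < 0:
            raise ParameterError("g_max must be nonnegative")


@dataclass
class ReceptorState:
    """Fraction of receptors in the open state, r in [0, 1]."""

    r: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError("receptor open fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SynapseEdge:
    """A directed synapse: presynaptic neuron -> (postsynaptic neuron, compartment)."""

    pre: int
    post: int
    post_compartment: str
    receptor: ReceptorSpec
    weight: float

    def __post_init__(self):
        if not 0.0 < self.weight <= 1.0:
            # random draws live in the open interval (0, 1); weight 1 is
            # allowed so tests can disable the weighting.
            raise ParameterError("synaptic weight must lie in (0, 1]")


def transmitter_concentration(v_pre, spec: ReceptorSpec):
    """Transmitter concentration (mM) released for presynaptic potential v_pre."""
    arg = -(np.asarray(v_pre, dtype=float) - spec.v_p) / spec.k_p
    out = spec.t_max / (1.0 + np.exp(np.clip(arg, -500.0, 500.0)))
    return float(out) if np.ndim(v_pre) == 0 else out


def receptor_derivative(state, t_conc, spec: ReceptorSpec):
    """dr/dt = alpha*[T]*(1 - r) - beta*r, in 1/ms.

    ``state`` may be a :class:`ReceptorState` or a bare r value/array.
    """
    r = state.r if isinstance(state, ReceptorState) else np.asarray(state, dtype=float)
    return spec.alpha * np.asarray(t_conc, float) * (1.0 - r) - spec.beta * r


def ampa_gaba_current(state, v_post, spec: ReceptorSpec):
    """Ohmic receptor current g_max * r * (v_post - e_rev) for AMPA/GABA_a."""
    if spec.kind not in ("AMPA", "GABAa"):
        raise WrongModeError(f"ampa_gaba_current got a {spec.kind} receptor")
    r = state.r if isinstance(state, ReceptorState) else np.asarray(state, dtype=float)
    return spec.g_max * r * (np.asarray(v_post, float) - spec.e_rev)


def mg_block(v):
    """Voltage-dependent magnesium unblock of the NMDA receptor, in (0, 1)."""
    arg = -(np.asarray(v, dtype=float) + 15.0) / 16.3
    out = 1.0 / (1.0 + np.exp(np.clip(arg, -500.0, 500.0)))
    return float(out) if np.ndim(v) == 0 else out


def nmda_current(state, v_post, spec: ReceptorSpec):
    """NMDA current g_max * r * B(v_post) * (v_post - e_rev)."""
    if spec.kind != "NMDA":
        raise WrongModeError(f"nmda_current got a {spec.kind} receptor")
    r = state.r if isinstance(state, ReceptorState) else np.asarray(state, dtype=float)
    return spec.g_max * r * mg_block(v_post) * (np.asarray(v_post, float) - spec.e_rev)


def weighted_synaptic_sum(edges: Sequence[SynapseEdge], currents: Sequence[float]):
    """Total synaptic current onto a target: sum_k weight_k * I_k."""
    if len(edges) != len(currents):
        raise AlignmentError(
            f"{len(edges)} edges but {len(currents)} currents"
        )
    if not edges:
        return 0.0
    w = np.array([e.weight for e in edges], dtype=float)
    return float(w @ np.asarray(currents, dtype=float))
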