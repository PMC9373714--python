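"""Voltage-gated ionic current kinetics.

All channels are described by Boltzmann steady-state gating,

    m_inf(V) = 1 / (1 + exp((V - V_half) / k)),    dm/dt = (m_inf - m) / tau_m,

with a signed slope ``k`` (activation gates carry a negative slope,
inactivation gates a positive one; inward rectifiers are the documented
exception).  Three current modes are supported:

``ohmic``
    I = g_max * m^x * h^y * (V - E_rev), with y = 0 meaning "no
    inactivation gate" (the h term is identically 1).
``partial``
    A partially inactivating current
    I = g_max * m^x * (a*h - (1 - a)) * (V - E_rev), a in [0, 1];
    a = 1 recovers the ohmic form.
``ghk``
    Calcium flux through the Goldman-Hodgkin-Katz constant-field equation,
    driven by a per-compartment intracellular calcium pool.

Units: membrane potential mV, time ms, conductance density mS/cm^2,
current density uA/cm^2, concentration mM, permeability cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import InvalidStateError, ParameterError, WrongModeError

__all__ = [
    "TauTable",
    "GateSpec",
    "GHKParams",
    "CalciumPool",
    "ChannelSpec",
    "steady_state_gate",
    "gate_tau",
    "gate_derivative",
    "ohmic_current",
    "partial_inactivation_current",
    "ghk_current",
    "ca_permeability",
    "ca_pool_derivative",
]

#: |zFV/RT| below which the GHK flux switches to its series expansion.
GHK_SERIES_THRESHOLD = 1e-4


@dataclass(frozen=True)
class TauTable:
    """Tabulated voltage-dependent time constant, linearly interpolated.

    Outside the tabulated voltage range the end values are held constant.
    """

    v: tuple
    tau: tuple

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if v.ndim != 1 or v.shape != tau.shape or v.size < 2:
            raise ParameterError("tau table needs matching 1-D v/tau arrays (>= 2 points)")
        if not np.all(np.diff(v) > 0):
            raise ParameterError("tau table voltages must be strictly increasing")
        if not np.all(tau > 0):
            raise ParameterError("tau table values must be positive")

    def __call__(self, v):
        return np.interp(v, np.asarray(self.v, float), np.asarray(self.tau, float))


@dataclass(frozen=True)
class GateSpec:
    """One Boltzmann gate of a voltage-gated channel.

    ``power`` is the exponent the gate enters the current with; ``slope`` is
    signed; ``tau`` is a constant (ms) or a :class:`TauTable`.
    """

    power: int
    v_half: float
    slope: float
    tau: Union[float, TauTable]
    role: str = "activation"

    def __post_init__(self):
        if self.power < 0:
            raise ParameterError("gate power must be >= 0")
        if not math.isfinite(self.v_half):
            raise ParameterError("v_half must be finite")
        if self.slope == 0 or not math.isfinite(self.slope):
            raise ParameterError("gate slope must be nonzero and finite")
        if self.role not in ("activation", "inactivation"):
            raise ParameterError(f"unknown gate role {self.role!r}")
        if isinstance(self.tau, (int, float)) and self.tau <= 0:
            raise ParameterError("constant tau must be positive")


@dataclass(frozen=True)
class GHKParams:
    """Physical constants for the GHK calcium flux.

    Defaults: divalent calcium at 35 degrees C with 5 mM external calcium.
    """

    p_max: float = 1.0
    z: int = 2
    faraday: float = 96489.0          # C/mol
    gas_const: float = 8.31           # J/(K*mol)
    temperature: float = 35.0 + 273.15  # K
    ca_out: float = 5.0               # mM

    def __post_init__(self):
        for name in ("p_max", "faraday", "gas_const", "temperature", "ca_out"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"GHK parameter {name} must be positive")
        if self.z != 2:
            raise ParameterError("GHK flux here is calcium-specific: z must be 2")

    @property
    def xi_per_volt(self) -> float:
        """zF/RT in 1/V."""
        return self.z * self.faraday / (self.gas_const * self.temperature)


@dataclass
class CalciumPool:
    """Submembrane calcium shell with pump, buffering and relaxation.

    dCa/dt = k * (-I_Ca) / (2*F*d) - p*K_t*Ca/(Ca + K_d) + (Ca_rest - Ca)/tau_R

    The influx term takes I_Ca in mA/cm^2 and the shell depth d in um; with
    the scale factor k = 1000 this yields mM/ms.  ``ca_rest`` is not stated
    by the source models' shared convention and defaults to the initial
    concentration (an assumption, flagged in the parameter files).
    """

    ca_in: float = 0.001        # mM, state variable
    shell_depth: float = 0.1    # um
    k_t: float = 1e-4           # mM/ms
    k_d: float = 1e-4           # mM
    tau_r: float = 43.0         # ms
    scale_k: float = 1000.0
    pump_p: float = 0.02
    ca_rest: float = 0.001      # mM
    faraday: float = 96489.0    # C/mol

    def __post_init__(self):
        if self.ca_in <= 0:
            raise InvalidStateError("intracellular calcium must stay positive")
        for name in ("shell_depth", "k_t", "k_d", "tau_r", "scale_k", "faraday"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"calcium pool parameter {name} must be positive")


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated conductance on one compartment.

    ``g_max`` is a conductance density (mS/cm^2) for ohmic/partial modes and
    the maximum permeability (cm/s) for GHK mode.  GHK channels carry no
    reversal potential; their driving force comes from the flux equation.
    """

    name: str
    g_max: float
    mode: str = "ohmic"                       # ohmic | partial | ghk
    e_rev: Optional[float] = None             # mV
    activation: Optional[GateSpec] = None
    inactivation: Optional[GateSpec] = None
    partial_fraction: Optional[float] = None  # a in [0, 1], partial mode only
    ghk: Optional[GHKParams] = None

    def __post_init__(self):
        if self.mode not in ("ohmic", "partial", "ghk"):
            raise ParameterError(f"unknown channel mode {self.mode!r}")
        if self.g_max < 0:
            raise ParameterError("g_max must be nonnegative")
        if self.mode == "partial":
            a = self.partial_fraction
            if a is None or not (0.0 <= a <= 1.0):
                raise ParameterError("partial mode requires partial_fraction in [0, 1]")
            if self.e_rev is None:
                raise ParameterError("partial mode requires e_rev")
        if self.mode == "ohmic" and self.e_rev is None:
            raise ParameterError("ohmic mode requires e_rev")
        if self.mode == "ghk":
            if self.ghk is None:
                raise ParameterError("ghk mode requires GHKParams")
            if self.e_rev is not None:
                raise ParameterError("ghk mode takes no reversal potential")

    @property
    def x(self) -> int:
        return self.activation.power if self.activation is not None else 0

    @property
    def y(self) -> int:
        return self.inactivation.power if self.inactivation is not None else 0


# ---------------------------------------------------------------------------
# gating

def steady_state_gate(v, gate: GateSpec):
    """Boltzmann steady state 1/(1 + exp((v - v_half)/slope)), in (0, 1)."""
    arg = (np.asarray(v, dtype=float) - gate.v_half) / gate.slope
    out = 1.0 / (1.0 + np.exp(np.clip(arg, -500.0, 500.0)))
    return float(out) if np.isscalar(v) else out


def gate_tau(v, gate: GateSpec):
    """Time constant of a gate at voltage ``v`` (ms)."""
    if isinstance(gate.tau, TauTable):
        out = gate.tau(v)
        return float(out) if np.isscalar(v) else out
    return gate.tau


def gate_derivative(m, v, gate: GateSpec):
    """First-order relaxation rate dm/dt = (m_inf(v) - m)/tau(v) in 1/ms."""
    return (steady_state_gate(v, gate) - np.asarray(m, dtype=float)) / gate_tau(v, gate)


# ---------------------------------------------------------------------------
# currents

def _gate_factor(spec: ChannelSpec, m, h):
    f = 1.0
    if spec.activation is not None and spec.activation.power > 0:
        f = f * np.asarray(m, dtype=float) ** spec.activation.power
    if spec.inactivation is not None and spec.inactivation.power > 0:
        f = f * np.asarray(h, dtype=float) ** spec.inactivation.power
    return f


def ohmic_current(spec: ChannelSpec, m, h, v):
    """I = g_max * m^x * h^y * (v - e_rev); y = 0 means no h term."""
    if spec.mode != "ohmic":
        raise WrongModeError(f"ohmic_current got a {spec.mode!r}-mode channel {spec.name}")
    return spec.g_max * _gate_factor(spec, m, h) * (np.asarray(v, float) - spec.e_rev)


def partial_inactivation_current(spec: ChannelSpec, m, h, v):
    """I = g_max * m^x * (a*h - (1 - a)) * (v - e_rev) with a in [0, 1]."""
    if spec.mode != "partial":
        raise WrongModeError(
            f"partial_inactivation_current got a {spec.mode!r}-mode channel {spec.name}"
        )
    a = spec.partial_fraction
    mx = 1.0
    if spec.activation is not None and spec.activation.power > 0:
        mx = np.asarray(m, dtype=float) ** spec.activation.power
    return spec.g_max * mx * (a * np.asarray(h, float) - (1.0 - a)) * (
        np.asarray(v, float) - spec.e_rev
    )


def ghk_current(p, v, ca_in, params: GHKParams):
    """GHK constant-field calcium flux (uA/cm^2 for p in cm/s, Ca in mM).

    I = p * z*F*xi * (Ca_in - Ca_out*exp(-xi)) / (1 - exp(-xi)),
    xi = zFV/RT.  Near v = 0 the 0/0 form is replaced by the two-term series
    I = p*z*F*(dCa + xi*(Ca_out + dCa/2)), dCa = Ca_in - Ca_out, which is the
    L'Hopital limit plus its first correction; the branches agree to ~1e-8
    relative at the switch point |xi| = 1e-4.
    """
    scalar = np.ndim(v) == 0 and np.ndim(ca_in) == 0
    ca = np.asarray(ca_in, dtype=float)
    if np.any(ca <= 0) or params.ca_out <= 0:
        raise InvalidStateError("GHK flux requires positive calcium concentrations")
    xi = params.xi_per_volt * np.asarray(v, dtype=float) * 1e-3
    zf = params.z * params.faraday

    xi_b, ca_b = np.broadcast_arrays(np.atleast_1d(xi), np.atleast_1d(ca))
    dca_b = ca_b - params.ca_out
    small = np.abs(xi_b) < GHK_SERIES_THRESHOLD
    exp_term = np.exp(-np.clip(xi_b, -500.0, 500.0))
    denom = np.where(small, 1.0, 1.0 - exp_term)  # dummy denom where series is used
    direct = p * zf * xi_b * (ca_b - params.ca_out * exp_term) / denom
    series = p * zf * (dca_b + xi_b * (params.ca_out + dca_b / 2.0))
    out = np.where(small, series, direct)
    return float(out[0]) if scalar else out.reshape(np.broadcast(np.asarray(v), ca).shape)


def ca_permeability(p_max, m, x, n=1.0, y=0):
    """Instantaneous permeability p_max * m^x * n^y, bounded by [0, p_max]."""
    p = p_max
    if x > 0:
        p = p * np.asarray(m, dtype=float) ** x
    if y > 0:
        p = p * np.asarray(n, dtype=float) ** y
    return p


def ca_pool_derivative(pool: CalciumPool, i_ca, ca_in=None):
    """Rate of change of shell calcium (mM/ms) for calcium current ``i_ca``.

    ``i_ca`` is in mA/cm^2 (inward currents are negative and raise calcium).
    ``ca_in`` overrides the pool's stored state when integrating externally.
    """
    ca = pool.ca_in if ca_in is None else ca_in
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise InvalidStateError("intracellular calcium must stay positive")
    influx = pool.scale_k * (-np.asarray(i_ca, float)) / (2.0 * pool.faraday * pool.shell_depth)
    pump = pool.pump_p * pool.k_t * ca / (ca + pool.k_d)
    relax = (pool.ca_rest - ca) / pool.tau_r
    out = influx - pump + relax
    return float(out) if out.ndim == 0 else out
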