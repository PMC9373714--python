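"""Flattened network representation and compiled ODE kernels.

The readable, per-object operations live in :mod:`dopanet.channels`,
:mod:`dopanet.synapses` and :mod:`dopanet.cells`; this module packs a built
network into structure-of-arrays form and evaluates the identical equations
inside numba-compiled loops so that full 4-second, 0.02-ms-step trials run
in seconds.  A dedicated test checks the flattened right-hand side against
the composed module operations on a small network.

State vector layout: [V (compartments) | gates | receptor r | pool Ca].

Gate time constants -- constant or tabulated -- are sampled once onto a
common uniform voltage grid (1 mV spacing on [-120, 60] mV) and linearly
interpolated inside the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .cells import NeuronTemplate, coupling_conductance
from .channels import GateSpec, TauTable
from .errors import NumericalBlowupError

__all__ = ["CompiledNetwork", "compile_network"]

V_GRID_LO = -120.0
V_GRID_HI = 60.0
V_GRID_STEP = 1.0
N_VGRID = int((V_GRID_HI - V_GRID_LO) / V_GRID_STEP) + 1

MODE_OHMIC, MODE_PARTIAL, MODE_GHK = 0, 1, 2
KIND_AMPA, KIND_NMDA, KIND_GABA = 0, 1, 2
_KIND_CODE = {"AMPA": KIND_AMPA, "NMDA": KIND_NMDA, "GABAa": KIND_GABA}

CA_FLOOR = 1e-9  # mM; kernel-level guard against a nonpositive shell


# ---------------------------------------------------------------------------
# kernels

@njit(cache=True)
def _rhs(y, stim, dy,
         # compartments
         comp_cm,
         # gates
         gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
         # channels
         chan_comp, chan_mode, chan_g, chan_erev, chan_a,
         chan_x, chan_y, chan_act, chan_inact, chan_pool,
         chan_xi_per_mv, chan_caout, chan_zf,
         # coupling
         cpl_self, cpl_other, cpl_g,
         # edges
         edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
         edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
         # pools
         pool_d, pool_kt, pool_kd, pool_taur, pool_k, pool_p, pool_rest,
         pool_far,
         # scratch
         i_acc, pool_acc):
    n_comp = comp_cm.shape[0]
    n_gate = gate_comp.shape[0]
    n_chan = chan_comp.shape[0]
    n_edge = edge_pre_comp.shape[0]
    n_pool = pool_d.shape[0]
    o_gate = n_comp
    o_edge = n_comp + n_gate
    o_pool = o_edge + n_edge

    for c in range(n_comp):
        i_acc[c] = 0.0
    for p in range(n_pool):
        pool_acc[p] = 0.0

    # gate kinetics
    for g in range(n_gate):
        v = y[gate_comp[g]]
        arg = (v - gate_vhalf[g]) / gate_slope[g]
        if arg > 40.0:
            minf = 0.0
        elif arg < -40.0:
            minf = 1.0
        else:
            minf = 1.0 / (1.0 + np.exp(arg))
        pos = (v - V_GRID_LO) / V_GRID_STEP
        if pos < 0.0:
            pos = 0.0
        elif pos > N_VGRID - 1.001:
            pos = N_VGRID - 1.001
        i0 = int(pos)
        frac = pos - i0
        tau = gate_tau_grid[g, i0] * (1.0 - frac) + gate_tau_grid[g, i0 + 1] * frac
        dy[o_gate + g] = (minf - y[o_gate + g]) / tau

    # channel currents
    for ch in range(n_chan):
        c = chan_comp[ch]
        v = y[c]
        gate_f = 1.0
        ai = chan_act[ch]
        if ai >= 0:
            m = y[o_gate + ai]
            if m < 0.0:
                m = 0.0
            elif m > 1.0:
                m = 1.0
            for _ in range(chan_x[ch]):
                gate_f *= m
        h = 1.0
        hi = chan_inact[ch]
        if hi >= 0:
            h = y[o_gate + hi]
            if h < 0.0:
                h = 0.0
            elif h > 1.0:
                h = 1.0
        mode = chan_mode[ch]
        if mode == MODE_OHMIC:
            hf = 1.0
            for _ in range(chan_y[ch]):
                hf *= h
            cur = chan_g[ch] * gate_f * hf * (v - chan_erev[ch])
        elif mode == MODE_PARTIAL:
            a = chan_a[ch]
            cur = chan_g[ch] * gate_f * (a * h - (1.0 - a)) * (v - chan_erev[ch])
        else:  # GHK calcium flux
            hf = 1.0
            for _ in range(chan_y[ch]):
                hf *= h
            p_inst = chan_g[ch] * gate_f * hf
            ca = y[o_pool + chan_pool[ch]]
            if ca < CA_FLOOR:
                ca = CA_FLOOR
            xi = chan_xi_per_mv[ch] * v
            zf = chan_zf[ch]
            caout = chan_caout[ch]
            if xi > 40.0:
                cur = p_inst * zf * xi * ca
            elif xi < -40.0:
                cur = p_inst * zf * xi * (ca - caout * np.exp(-xi)) \
                    if xi > -500.0 else 0.0
            elif -1e-4 < xi < 1e-4:
                dca = ca - caout
                cur = p_inst * zf * (dca + xi * (caout + dca / 2.0))
            else:
                e = np.exp(-xi)
                cur = p_inst * zf * xi * (ca - caout * e) / (1.0 - e)
            pool_acc[chan_pool[ch]] += cur
        i_acc[c] += cur

    # compartment coupling: current into `self` is g*(V_self - V_other)
    for k in range(cpl_self.shape[0]):
        i_acc[cpl_self[k]] += cpl_g[k] * (y[cpl_self[k]] - y[cpl_other[k]])

    # synapses
    for e in range(n_edge):
        v_pre = y[edge_pre_comp[e]]
        arg = -(v_pre - edge_vp[e]) / edge_kp[e]
        if arg > 40.0:
            t_conc = 0.0
        elif arg < -40.0:
            t_conc = edge_tmax[e]
        else:
            t_conc = edge_tmax[e] / (1.0 + np.exp(arg))
        r = y[o_edge + e]
        dy[o_edge + e] = edge_alpha[e] * t_conc * (1.0 - r) - edge_beta[e] * r
        if r < 0.0:
            r = 0.0
        elif r > 1.0:
            r = 1.0
        v_post = y[edge_post_comp[e]]
        cur = edge_g[e] * r * (v_post - edge_erev[e])
        if edge_kind[e] == KIND_NMDA:
            barg = -(v_post + 15.0) / 16.3
            if barg > 40.0:
                block = 0.0
            elif barg < -40.0:
                block = 1.0
            else:
                block = 1.0 / (1.0 + np.exp(barg))
            cur *= block
        i_acc[edge_post_comp[e]] += cur

    # membrane equation
    for c in range(n_comp):
        dy[c] = (stim[c] - i_acc[c]) / comp_cm[c]

    # calcium pools (influx term expects mA/cm^2: 1e-3 converts)
    for p in range(n_pool):
        ca = y[o_pool + p]
        if ca < CA_FLOOR:
            ca = CA_FLOOR
        influx = pool_k[p] * (-pool_acc[p] * 1e-3) / (2.0 * pool_far[p] * pool_d[p])
        pump = pool_p[p] * pool_kt[p] * ca / (ca + pool_kd[p])
        dy[o_pool + p] = influx - pump + (pool_rest[p] - ca) / pool_taur[p]


@njit(cache=True)
def _measure(y, out_idx_kind, out_idx_a,
             comp_cm,
             gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
             chan_comp, chan_mode, chan_g, chan_erev, chan_a,
             chan_x, chan_y, chan_act, chan_inact, chan_pool,
             chan_xi_per_mv, chan_caout, chan_zf,
             edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
             edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
             out):
    """Instantaneous currents for recorded probes.

    kind 0: channel current (index = channel id);
    kind 1: excitatory synaptic current summed onto a compartment;
    kind 2: inhibitory synaptic current summed onto a compartment.
    """
    n_comp = comp_cm.shape[0]
    n_gate = gate_comp.shape[0]
    n_edge = edge_pre_comp.shape[0]
    o_gate = n_comp
    o_edge = n_comp + n_gate
    o_pool = o_edge + n_edge
    for k in range(out_idx_kind.shape[0]):
        kind = out_idx_kind[k]
        idx = out_idx_a[k]
        if kind == 0:
            ch = idx
            c = chan_comp[ch]
            v = y[c]
            gate_f = 1.0
            ai = chan_act[ch]
            if ai >= 0:
                m = min(max(y[o_gate + ai], 0.0), 1.0)
                for _ in range(chan_x[ch]):
                    gate_f *= m
            h = 1.0
            hi = chan_inact[ch]
            if hi >= 0:
                h = min(max(y[o_gate + hi], 0.0), 1.0)
            mode = chan_mode[ch]
            if mode == MODE_OHMIC:
                hf = 1.0
                for _ in range(chan_y[ch]):
                    hf *= h
                cur = chan_g[ch] * gate_f * hf * (v - chan_erev[ch])
            elif mode == MODE_PARTIAL:
                a = chan_a[ch]
                cur = chan_g[ch] * gate_f * (a * h - (1.0 - a)) * (v - chan_erev[ch])
            else:
                hf = 1.0
                for _ in range(chan_y[ch]):
                    hf *= h
                p_inst = chan_g[ch] * gate_f * hf
                ca = max(y[o_pool + chan_pool[ch]], CA_FLOOR)
                xi = chan_xi_per_mv[ch] * v
                zf = chan_zf[ch]
                caout = chan_caout[ch]
                if -1e-4 < xi < 1e-4:
                    dca = ca - caout
                    cur = p_inst * zf * (dca + xi * (caout + dca / 2.0))
                else:
                    e = np.exp(-min(max(xi, -500.0), 500.0))
                    cur = p_inst * zf * xi * (ca - caout * e) / (1.0 - e)
            out[k] = cur
        else:
            total = 0.0
            for e in range(n_edge):
                if edge_post_comp[e] != idx:
                    continue
                is_inhib = edge_kind[e] == KIND_GABA
                if (kind == 2) != is_inhib:
                    continue
                v_pre = y[edge_pre_comp[e]]
                r = min(max(y[o_edge + e], 0.0), 1.0)
                v_post = y[edge_post_comp[e]]
                cur = edge_g[e] * r * (v_post - edge_erev[e])
                if edge_kind[e] == KIND_NMDA:
                    barg = -(v_post + 15.0) / 16.3
                    block = 1.0 / (1.0 + np.exp(min(max(barg, -40.0), 40.0)))
                    cur *= block
                total += cur
            out[k] = total


@njit(cache=True)
def _run(y, n_steps, dt, stim_steps, comp_neuron,
         comp_cm,
         gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
         chan_comp, chan_mode, chan_g, chan_erev, chan_a,
         chan_x, chan_y, chan_act, chan_inact, chan_pool,
         chan_xi_per_mv, chan_caout, chan_zf,
         cpl_self, cpl_other, cpl_g,
         edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
         edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
         pool_d, pool_kt, pool_kd, pool_taur, pool_k, pool_p, pool_rest,
         pool_far,
         rec_v_idx, v_out,
         probe_kind, probe_idx, probe_out):
    """Fixed-step Bogacki-Shampine 2(3) integration with FSAL.

    Records V for ``rec_v_idx`` and probe currents every step.  Returns
    (status, max embedded-error estimate); status >= 0 is the step index at
    which a non-finite state appeared, -1 means success.
    """
    n_state = y.shape[0]
    n_comp = comp_cm.shape[0]
    stim = np.zeros(n_comp)
    i_acc = np.zeros(n_comp)
    pool_acc = np.zeros(pool_d.shape[0])
    k1 = np.zeros(n_state)
    k2 = np.zeros(n_state)
    k3 = np.zeros(n_state)
    k4 = np.zeros(n_state)
    y_tmp = np.zeros(n_state)
    max_err = 0.0

    # initial records
    for j in range(rec_v_idx.shape[0]):
        v_out[j, 0] = y[rec_v_idx[j]]
    if probe_kind.shape[0] > 0:
        _measure(y, probe_kind, probe_idx, comp_cm,
                 gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
                 chan_comp, chan_mode, chan_g, chan_erev, chan_a,
                 chan_x, chan_y, chan_act, chan_inact, chan_pool,
                 chan_xi_per_mv, chan_caout, chan_zf,
                 edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
                 edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
                 probe_out[:, 0])

    have_k1 = False
    for step in range(n_steps):
        # distributed background drive: the per-neuron stimulus density is
        # applied to every compartment of that neuron
        for c in range(n_comp):
            stim[c] = stim_steps[step, comp_neuron[c]]

        if not have_k1:
            _rhs(y, stim, k1, comp_cm,
                 gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
                 chan_comp, chan_mode, chan_g, chan_erev, chan_a,
                 chan_x, chan_y, chan_act, chan_inact, chan_pool,
                 chan_xi_per_mv, chan_caout, chan_zf,
                 cpl_self, cpl_other, cpl_g,
                 edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
                 edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
                 pool_d, pool_kt, pool_kd, pool_taur, pool_k, pool_p,
                 pool_rest, pool_far, i_acc, pool_acc)
        for i in range(n_state):
            y_tmp[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(y_tmp, stim, k2, comp_cm,
             gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
             chan_comp, chan_mode, chan_g, chan_erev, chan_a,
             chan_x, chan_y, chan_act, chan_inact, chan_pool,
             chan_xi_per_mv, chan_caout, chan_zf,
             cpl_self, cpl_other, cpl_g,
             edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
             edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
             pool_d, pool_kt, pool_kd, pool_taur, pool_k, pool_p,
             pool_rest, pool_far, i_acc, pool_acc)
        for i in range(n_state):
            y_tmp[i] = y[i] + 0.75 * dt * k2[i]
        _rhs(y_tmp, stim, k3, comp_cm,
             gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
             chan_comp, chan_mode, chan_g, chan_erev, chan_a,
             chan_x, chan_y, chan_act, chan_inact, chan_pool,
             chan_xi_per_mv, chan_caout, chan_zf,
             cpl_self, cpl_other, cpl_g,
             edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
             edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
             pool_d, pool_kt, pool_kd, pool_taur, pool_k, pool_p,
             pool_rest, pool_far, i_acc, pool_acc)
        for i in range(n_state):
            y[i] = y[i] + dt * (2.0 * k1[i] + 3.0 * k2[i] + 4.0 * k3[i]) / 9.0
        _rhs(y, stim, k4, comp_cm,
             gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
             chan_comp, chan_mode, chan_g, chan_erev, chan_a,
             chan_x, chan_y, chan_act, chan_inact, chan_pool,
             chan_xi_per_mv, chan_caout, chan_zf,
             cpl_self, cpl_other, cpl_g,
             edge_pre_comp, edge_post_comp, edge_kind, edge_g, edge_erev,
             edge_alpha, edge_beta, edge_tmax, edge_vp, edge_kp,
             pool_d, pool_kt, pool_kd, pool_taur, pool_k, pool_p,
             pool_rest, pool_far, i_acc, pool_acc)
        # embedded 2nd-order error estimate (logged, never used for control)
        for i in range(n_state):
            err = dt * (-5.0 * k1[i] / 72.0 + k2[i] / 12.0 + k3[i] / 9.0
                        - k4[i] / 8.0)
            aerr = abs(err)
            if aerr > max_err:
                max_err = aerr
        # FSAL: k4 at the accepted state is next step's k1
        for i in range(n_state):
            k1[i] = k4[i]
        have_k1 = True

        for j in range(rec_v_idx.shape[0]):
            v_out[j, step + 1] = y[rec_v_idx[j]]
        if probe_kind.shape[0] > 0:
            _measure(y, probe_kind, probe_idx, comp_cm,
                     gate_comp, gate_vhalf, gate_slope, gate_tau_grid,
                     chan_comp, chan_mode, chan_g, chan_erev, chan_a,
                     chan_x, chan_y, chan_act, chan_inact, chan_pool,
                     chan_xi_per_mv, chan_caout, chan_zf,
                     edge_pre_comp, edge_post_comp, edge_kind, edge_g,
                     edge_erev, edge_alpha, edge_beta, edge_tmax, edge_vp,
                     edge_kp, probe_out[:, step + 1])

        if step % 500 == 499:
            ok = True
            for i in range(n_state):
                if not np.isfinite(y[i]):
                    ok = False
                    break
            if not ok:
                return step, max_err
    for i in range(n_state):
        if not np.isfinite(y[i]):
            return n_steps - 1, max_err
    return -1, max_err


# ---------------------------------------------------------------------------
# compilation from a built Network

def _tau_on_grid(gate: GateSpec) -> np.ndarray:
    grid = np.linspace(V_GRID_LO, V_GRID_HI, N_VGRID)
    if isinstance(gate.tau, TauTable):
        return np.asarray(gate.tau(grid), dtype=float)
    return np.full(N_VGRID, float(gate.tau))


@dataclass
class CompiledNetwork:
    """Structure-of-arrays form of a network, ready for the numba kernels."""

    n_neurons: int
    comp_labels: List[str]                 # "<neuron>:<compartment>"
    comp_neuron: np.ndarray
    comp_cm: np.ndarray
    soma_comp: np.ndarray                  # soma compartment index per neuron
    v_init: np.ndarray
    arrays: dict = field(default_factory=dict)
    gate_labels: List[str] = field(default_factory=list)
    chan_labels: List[str] = field(default_factory=list)
    pool_labels: List[str] = field(default_factory=list)
    n_edges: int = 0
    state_size: int = 0

    def initial_state(self) -> np.ndarray:
        a = self.arrays
        n_comp = self.comp_cm.shape[0]
        y = np.zeros(self.state_size)
        y[:n_comp] = self.v_init
        # gates start at steady state for the initial potential
        for g in range(a["gate_comp"].shape[0]):
            v = self.v_init[a["gate_comp"][g]]
            arg = (v - a["gate_vhalf"][g]) / a["gate_slope"][g]
            y[n_comp + g] = 1.0 / (1.0 + np.exp(np.clip(arg, -500, 500)))
        o_pool = n_comp + len(self.gate_labels) + self.n_edges
        y[o_pool:] = a["pool_init"]
        return y

    def state_label(self, i: int) -> str:
        n_comp = self.comp_cm.shape[0]
        n_gate = len(self.gate_labels)
        if i < n_comp:
            return f"V[{self.comp_labels[i]}]"
        if i < n_comp + n_gate:
            return f"gate[{self.gate_labels[i - n_comp]}]"
        if i < n_comp + n_gate + self.n_edges:
            return f"r[edge {i - n_comp - n_gate}]"
        return f"Ca[{self.pool_labels[i - n_comp - n_gate - self.n_edges]}]"

    def rhs(self, y: np.ndarray, stim_per_comp: np.ndarray) -> np.ndarray:
        """Single right-hand-side evaluation (used by tests and rk_step)."""
        a = self.arrays
        dy = np.zeros_like(y)
        i_acc = np.zeros(self.comp_cm.shape[0])
        pool_acc = np.zeros(a["pool_d"].shape[0])
        _rhs(y, stim_per_comp, dy, self.comp_cm,
             a["gate_comp"], a["gate_vhalf"], a["gate_slope"], a["gate_tau_grid"],
             a["chan_comp"], a["chan_mode"], a["chan_g"], a["chan_erev"], a["chan_a"],
             a["chan_x"], a["chan_y"], a["chan_act"], a["chan_inact"], a["chan_pool"],
             a["chan_xi_per_mv"], a["chan_caout"], a["chan_zf"],
             a["cpl_self"], a["cpl_other"], a["cpl_g"],
             a["edge_pre_comp"], a["edge_post_comp"], a["edge_kind"], a["edge_g"],
             a["edge_erev"], a["edge_alpha"], a["edge_beta"], a["edge_tmax"],
             a["edge_vp"], a["edge_kp"],
             a["pool_d"], a["pool_kt"], a["pool_kd"], a["pool_taur"], a["pool_k"],
             a["pool_p"], a["pool_rest"], a["pool_far"], i_acc, pool_acc)
        return dy

    def run(self, y: np.ndarray, n_steps: int, dt: float,
            stim_steps: np.ndarray,
            rec_v_idx: np.ndarray,
            probe_kind: Optional[np.ndarray] = None,
            probe_idx: Optional[np.ndarray] = None
            ) -> Tuple[np.ndarray, np.ndarray, float]:
        """Integrate in place; returns (v_out, probe_out, max_error_estimate)."""
        a = self.arrays
        if probe_kind is None:
            probe_kind = np.zeros(0, dtype=np.int64)
            probe_idx = np.zeros(0, dtype=np.int64)
        v_out = np.zeros((rec_v_idx.shape[0], n_steps + 1), dtype=np.float64)
        probe_out = np.zeros((probe_kind.shape[0], n_steps + 1), dtype=np.float64)
        status, max_err = _run(
            y, n_steps, dt, stim_steps, self.comp_neuron,
            self.comp_cm,
            a["gate_comp"], a["gate_vhalf"], a["gate_slope"], a["gate_tau_grid"],
            a["chan_comp"], a["chan_mode"], a["chan_g"], a["chan_erev"], a["chan_a"],
            a["chan_x"], a["chan_y"], a["chan_act"], a["chan_inact"], a["chan_pool"],
            a["chan_xi_per_mv"], a["chan_caout"], a["chan_zf"],
            a["cpl_self"], a["cpl_other"], a["cpl_g"],
            a["edge_pre_comp"], a["edge_post_comp"], a["edge_kind"], a["edge_g"],
            a["edge_erev"], a["edge_alpha"], a["edge_beta"], a["edge_tmax"],
            a["edge_vp"], a["edge_kp"],
            a["pool_d"], a["pool_kt"], a["pool_kd"], a["pool_taur"], a["pool_k"],
            a["pool_p"], a["pool_rest"], a["pool_far"],
            rec_v_idx, v_out, probe_kind, probe_idx, probe_out)
        if status >= 0:
            bad = np.where(~np.isfinite(y))[0]
            label = self.state_label(int(bad[0])) if bad.size else "unknown"
            raise NumericalBlowupError(
                f"non-finite state at step {status} (t={status * dt:.2f} ms), "
                f"first offending variable: {label}"
            )
        return v_out, probe_out, max_err

    def channel_index(self, neuron: int, compartment: str, channel: str) -> int:
        label = f"{neuron}:{compartment}:{channel}"
        return self.chan_labels.index(label)

    def comp_index(self, neuron: int, compartment: str) -> int:
        return self.comp_labels.index(f"{neuron}:{compartment}")


def compile_network(neuron_templates: Sequence[NeuronTemplate],
                    edges, soma_name: str = "soma") -> CompiledNetwork:
    """Flatten per-neuron templates plus synapse edges into kernel arrays.

    ``neuron_templates`` holds one (possibly dopamine-modulated) template per
    neuron; ``edges`` is a sequence of :class:`dopanet.synapses.SynapseEdge`.
    """
    comp_labels: List[str] = []
    comp_neuron: List[int] = []
    comp_cm: List[float] = []
    v_init: List[float] = []
    comp_index: Dict[Tuple[int, str], int] = {}
    soma_comp: List[int] = []

    gate_comp, gate_vhalf, gate_slope, gate_tau = [], [], [], []
    gate_labels: List[str] = []
    chan = {k: [] for k in ("comp", "mode", "g", "erev", "a", "x", "y",
                            "act", "inact", "pool", "xi", "caout", "zf")}
    chan_labels: List[str] = []
    pool = {k: [] for k in ("d", "kt", "kd", "taur", "k", "p", "rest", "far",
                            "init")}
    pool_labels: List[str] = []
    cpl_self, cpl_other, cpl_g = [], [], []

    for n, template in enumerate(neuron_templates):
        pool_of_comp: Dict[str, int] = {}
        for comp in template.compartments:
            ci = len(comp_labels)
            comp_index[(n, comp.name)] = ci
            comp_labels.append(f"{n}:{comp.name}")
            comp_neuron.append(n)
            comp_cm.append(comp.c_m)
            v_init.append(template.v_init)
            if comp.name == soma_name or len(template.compartments) == 1:
                if len(soma_comp) == n:
                    soma_comp.append(ci)
            if comp.ca_pool is not None:
                pi = len(pool_labels)
                pool_of_comp[comp.name] = pi
                pool_labels.append(f"{n}:{comp.name}")
                p = comp.ca_pool
                pool["d"].append(p.shell_depth)
                pool["kt"].append(p.k_t)
                pool["kd"].append(p.k_d)
                pool["taur"].append(p.tau_r)
                pool["k"].append(p.scale_k)
                pool["p"].append(p.pump_p)
                pool["rest"].append(p.ca_rest)
                pool["far"].append(p.faraday)
                pool["init"].append(p.ca_in)
        for comp in template.compartments:
            ci = comp_index[(n, comp.name)]
            for ch in comp.channels:
                ai = hi = -1
                if ch.activation is not None:
                    ai = len(gate_labels)
                    gate_labels.append(f"{n}:{comp.name}:{ch.name}:m")
                    gate_comp.append(ci)
                    gate_vhalf.append(ch.activation.v_half)
                    gate_slope.append(ch.activation.slope)
                    gate_tau.append(_tau_on_grid(ch.activation))
                if ch.inactivation is not None:
                    hi = len(gate_labels)
                    gate_labels.append(f"{n}:{comp.name}:{ch.name}:h")
                    gate_comp.append(ci)
                    gate_vhalf.append(ch.inactivation.v_half)
                    gate_slope.append(ch.inactivation.slope)
                    gate_tau.append(_tau_on_grid(ch.inactivation))
                mode = {"ohmic": MODE_OHMIC, "partial": MODE_PARTIAL,
                        "ghk": MODE_GHK}[ch.mode]
                if mode == MODE_GHK and comp.name not in pool_of_comp:
                    raise ValueError(
                        f"GHK channel {ch.name} on {comp.name} without a calcium pool"
                    )
                chan_labels.append(f"{n}:{comp.name}:{ch.name}")
                chan["comp"].append(ci)
                chan["mode"].append(mode)
                chan["g"].append(ch.g_max)
                chan["erev"].append(ch.e_rev if ch.e_rev is not None else 0.0)
                chan["a"].append(ch.partial_fraction if ch.partial_fraction is not None else 1.0)
                chan["x"].append(ch.x)
                chan["y"].append(ch.y)
                chan["act"].append(ai)
                chan["inact"].append(hi)
                chan["pool"].append(pool_of_comp.get(comp.name, -1))
                if mode == MODE_GHK:
                    chan["xi"].append(ch.ghk.xi_per_volt * 1e-3)  # per mV
                    chan["caout"].append(ch.ghk.ca_out)
                    chan["zf"].append(ch.ghk.z * ch.ghk.faraday)
                else:
                    chan["xi"].append(0.0)
                    chan["caout"].append(0.0)
                    chan["zf"].append(0.0)
            for other in template.neighbors(comp.name):
                oc = template.compartment(other)
                cpl_self.append(comp_index[(n, comp.name)])
                cpl_other.append(comp_index[(n, other)])
                cpl_g.append(coupling_conductance(comp, oc))

    edge_pre_comp, edge_post_comp = [], []
    edge_arrays = {k: [] for k in ("kind", "g", "erev", "alpha", "beta",
                                   "tmax", "vp", "kp")}
    for e in edges:
        edge_pre_comp.append(soma_comp[e.pre])
        edge_post_comp.append(comp_index[(e.post, e.post_compartment)])
        spec = e.receptor
        edge_arrays["kind"].append(_KIND_CODE[spec.kind])
        edge_arrays["g"].append(spec.g_max * e.weight)
        edge_arrays["erev"].append(spec.e_rev)
        edge_arrays["alpha"].append(spec.alpha)
        edge_arrays["beta"].append(spec.beta)
        edge_arrays["tmax"].append(spec.t_max)
        edge_arrays["vp"].append(spec.v_p)
        edge_arrays["kp"].append(spec.k_p)

    def _i(x):
        return np.asarray(x, dtype=np.int64)

    def _f(x):
        return np.asarray(x, dtype=np.float64)

    arrays = {
        "gate_comp": _i(gate_comp), "gate_vhalf": _f(gate_vhalf),
        "gate_slope": _f(gate_slope),
        "gate_tau_grid": (np.vstack(gate_tau) if gate_tau
                          else np.zeros((0, N_VGRID))),
        "chan_comp": _i(chan["comp"]), "chan_mode": _i(chan["mode"]),
        "chan_g": _f(chan["g"]), "chan_erev": _f(chan["erev"]),
        "chan_a": _f(chan["a"]), "chan_x": _i(chan["x"]),
        "chan_y": _i(chan["y"]), "chan_act": _i(chan["act"]),
        "chan_inact": _i(chan["inact"]), "chan_pool": _i(chan["pool"]),
        "chan_xi_per_mv": _f(chan["xi"]), "chan_caout": _f(chan["caout"]),
        "chan_zf": _f(chan["zf"]),
        "cpl_self": _i(cpl_self), "cpl_other": _i(cpl_other),
        "cpl_g": _f(cpl_g),
        "edge_pre_comp": _i(edge_pre_comp), "edge_post_comp": _i(edge_post_comp),
        "edge_kind": _i(edge_arrays["kind"]), "edge_g": _f(edge_arrays["g"]),
        "edge_erev": _f(edge_arrays["erev"]), "edge_alpha": _f(edge_arrays["alpha"]),
        "edge_beta": _f(edge_arrays["beta"]), "edge_tmax": _f(edge_arrays["tmax"]),
        "edge_vp": _f(edge_arrays["vp"]), "edge_kp": _f(edge_arrays["kp"]),
        "pool_d": _f(pool["d"]), "pool_kt": _f(pool["kt"]),
        "pool_kd": _f(pool["kd"]), "pool_taur": _f(pool["taur"]),
        "pool_k": _f(pool["k"]), "pool_p": _f(pool["p"]),
        "pool_rest": _f(pool["rest"]), "pool_far": _f(pool["far"]),
        "pool_init": _f(pool["init"]),
    }

    net = CompiledNetwork(
        n_neurons=len(neuron_templates),
        comp_labels=comp_labels,
        comp_neuron=_i(comp_neuron),
        comp_cm=_f(comp_cm),
        soma_comp=_i(soma_comp),
        v_init=_f(v_init),
        arrays=arrays,
        gate_labels=gate_labels,
        chan_labels=chan_labels,
        pool_labels=pool_labels,
        n_edges=len(edge_pre_comp),
    )
    net.state_size = (len(comp_labels) + len(gate_labels)
                      + len(edge_pre_comp) + len(pool_labels))
    return net
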