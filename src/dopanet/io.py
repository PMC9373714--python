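"""Configuration loading, recording container I/O and run ledgers.

All editable model parameters (channel kinetics, receptor kinetics,
dopamine-modulation endpoints, the network manifest) live in YAML files under
``dopanet/params/``.  Values that are assumptions rather than published
numbers are flagged with ``assumption:`` notes inside those files; the loader
surfaces them via :func:`load_manifest`'s returned metadata.
"""

from __future__ import annotations

import json
import hashlib
import importlib.resources
import os
from dataclasses import asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .channels import CalciumPool, ChannelSpec, GateSpec, GHKParams, TauTable
from .cells import CompartmentSpec, NeuronTemplate
from .errors import ConfigError
from .synapses import ReceptorSpec

__all__ = [
    "packaged_param_path",
    "load_neuron_file",
    "load_receptor_file",
    "load_manifest",
    "manifest_hash",
    "save_recording",
    "load_recording",
    "RunLedger",
]


def packaged_param_path(filename: str, params_dir: Optional[str] = None) -> str:
    """Absolute path of a parameter file, packaged or from an override dir."""
    if params_dir is not None:
        path = os.path.join(params_dir, filename)
    else:
        path = str(importlib.resources.files("dopanet").joinpath("params", filename))
    if not os.path.exists(path):
        raise ConfigError(f"parameter file not found: {path}")
    return path


def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise ConfigError(f"{ctx}: missing required field {key!r}")
    return mapping[key]


def _parse_tau(raw, ctx: str):
    if isinstance(raw, (int, float)):
        return float(raw)
    if isinstance(raw, dict):
        try:
            return TauTable(v=tuple(raw["v"]), tau=tuple(raw["tau"]))
        except Exception as exc:
            raise ConfigError(f"{ctx}: bad tau table ({exc})") from exc
    raise ConfigError(f"{ctx}: tau must be a number or a v/tau table")


def _parse_gate(raw: Optional[dict], role: str, ctx: str) -> Optional[GateSpec]:
    if raw is None:
        return None
    try:
        return GateSpec(
            power=int(_require(raw, "power", ctx)),
            v_half=float(_require(raw, "v_half", ctx)),
            slope=float(_require(raw, "slope", ctx)),
            tau=_parse_tau(_require(raw, "tau", ctx), ctx),
            role=role,
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"{ctx}: invalid gate ({exc})") from exc


def _parse_channel(raw: dict, ctx: str) -> ChannelSpec:
    name = _require(raw, "name", ctx)
    ctx = f"{ctx}/{name}"
    mode = raw.get("mode", "ohmic")
    ghk = None
    if mode == "ghk":
        g = raw.get("ghk", {}) or {}
        ghk = GHKParams(
            p_max=float(raw.get("g_max", 1.0)),
            ca_out=float(g.get("ca_out", 5.0)),
            temperature=float(g.get("temperature_c", 35.0)) + 273.15,
        )
    try:
        return ChannelSpec(
            name=name,
            g_max=float(_require(raw, "g_max", ctx)),
            mode=mode,
            e_rev=(float(raw["e_rev"]) if raw.get("e_rev") is not None else None),
            activation=_parse_gate(raw.get("activation"), "activation", ctx),
            inactivation=_parse_gate(raw.get("inactivation"), "inactivation", ctx),
            partial_fraction=(
                float(raw["partial_fraction"]) if raw.get("partial_fraction") is not None else None
            ),
            ghk=ghk,
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"{ctx}: invalid channel ({exc})") from exc


def load_neuron_file(path: str) -> NeuronTemplate:
    """Parse one neuron-template YAML file into a :class:`NeuronTemplate`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ctx = os.path.basename(path)
    kind = _require(doc, "kind", ctx)
    c_m = float(doc.get("capacitance", 1.0))
    r_l = float(doc.get("axial_resistivity", 150.0))
    pools_raw = doc.get("calcium_pools", {}) or {}
    chan_raw = doc.get("channels", {}) or {}

    # expand compartments with `copies: N` into name_1..name_N
    comps: List[CompartmentSpec] = []
    base_of: Dict[str, str] = {}
    expanded: Dict[str, List[str]] = {}
    for entry in _require(doc, "compartments", ctx):
        base = _require(entry, "name", ctx)
        copies = int(entry.get("copies", 1))
        names = [base] if copies == 1 else [f"{base}_{i}" for i in range(1, copies + 1)]
        expanded[base] = names
        for nm in names:
            base_of[nm] = base
            pool = None
            if base in pools_raw:
                praw = pools_raw[base] or {}
                pool = CalciumPool(
                    ca_in=float(praw.get("ca_init", 0.001)),
                    ca_rest=float(praw.get("ca_rest", 0.001)),
                )
            comps.append(
                CompartmentSpec(
                    name=nm,
                    length=float(_require(entry, "length", f"{ctx}:{base}")),
                    diameter=float(_require(entry, "diameter", f"{ctx}:{base}")),
                    c_m=c_m,
                    r_l=r_l,
                    channels=[
                        _parse_channel(c, f"{ctx}:{nm}") for c in chan_raw.get(base, [])
                    ],
                    ca_pool=pool,
                )
            )

    adjacency: List[Tuple[str, str]] = []
    for a, b in doc.get("adjacency", []):
        for an in expanded.get(a, [a]):
            for bn in expanded.get(b, [b]):
                adjacency.append((an, bn))

    return NeuronTemplate(
        kind=kind,
        compartments=comps,
        adjacency=adjacency,
        v_init=float(doc.get("v_init", -70.0)),
    )


def load_receptor_file(path: Optional[str] = None) -> Dict[str, ReceptorSpec]:
    """Load the AMPA/NMDA/GABAa kinetic block."""
    if path is None:
        path = packaged_param_path("receptors.yaml")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for kind, raw in doc.items():
        if kind.startswith("_"):
            continue
        ctx = f"{os.path.basename(path)}:{kind}"
        out[kind] = ReceptorSpec(
            kind=kind,
            g_max=float(_require(raw, "g_max", ctx)),
            e_rev=float(_require(raw, "e_rev", ctx)),
            alpha=float(_require(raw, "alpha", ctx)),
            beta=float(_require(raw, "beta", ctx)),
            t_max=float(raw.get("t_max", 1.0)),
            v_p=float(raw.get("v_p", 2.0)),
            k_p=float(raw.get("k_p", 5.0)),
        )
    missing = {"AMPA", "NMDA", "GABAa"} - set(out)
    if missing:
        raise ConfigError(f"{path}: missing receptor kinds {sorted(missing)}")
    return out


def load_manifest(path: Optional[str] = None):
    """Load and validate a network/run manifest.

    Returns a :class:`dopanet.network.NetworkConfig`.  Warnings about stated
    conventions (e.g. a pyramidal:interneuron ratio away from 4:1) are
    attached to ``config.warnings``.
    """
    from .network import NetworkConfig  # deferred to avoid an import cycle

    if path is None:
        path = packaged_param_path("network.yaml")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return NetworkConfig.from_dict(doc, source=path)


def dump_manifest(config, path: str) -> None:
    """Write a NetworkConfig back to manifest YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def manifest_hash(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# recordings

def save_recording(recording, path: str) -> None:
    """Write a Recording to a .npz archive (arrays + JSON metadata)."""
    arrays = {
        "time": recording.time,
        "v_soma": recording.v_soma,
        "spike_threshold": np.asarray(recording.spike_threshold),
    }
    for key, arr in recording.traces.items():
        arrays[f"trace__{key}"] = arr
    arrays["meta_json"] = np.frombuffer(
        json.dumps(recording.metadata).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_recording(path: str):
    from .simulate import Recording  # deferred

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        traces = {
            k[len("trace__"):]: data[k] for k in data.files if k.startswith("trace__")
        }
        return Recording(
            time=data["time"],
            v_soma=data["v_soma"],
            traces=traces,
            metadata=meta,
            spike_threshold=float(data["spike_threshold"]),
        )


class RunLedger:
    """Append-only JSON-lines ledger of simulated cells and their checksums."""

    def __init__(self, path: str):
        self.path = path

    def append(self, entry: dict) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def entries(self) -> List[dict]:
        if not os.path.exists(self.path):
            return []
        with open(self.path) as fh:
            return [json.loads(line) for line in fh if line.strip()]


def recording_checksum(recording) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(recording.v_soma).tobytes())
    return h.hexdigest()[:16]
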