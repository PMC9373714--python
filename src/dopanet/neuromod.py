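"""Dopamine as a direct scalar input.

The VTA is not simulated as spiking units; instead a dopamine level k (in
percent of the "normal" concentration) linearly interpolates every modulated
channel parameter between its 0% value ``a`` and its 100% value ``b``:

    value(k) = a + (b - a) * k/100.

Rules target only intrinsic channel parameters (conductances/permeabilities
and persistent-sodium gating); dopamine never alters receptor kinetics, so
mEPSC/mIPSC parameters are untouched by construction.
"""

from __future__ import annotations

import copy
import dataclasses
import fnmatch
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .cells import NeuronTemplate
from .errors import ConfigError, RangeError
from .io import packaged_param_path

__all__ = [
    "ModulationRule",
    "DopamineSchedule",
    "interpolate_parameter",
    "sample_da_level",
    "apply_modulation",
    "load_dopamine_rules",
]


@dataclass(frozen=True)
class ModulationRule:
    """One dopamine-modulated parameter with its 0% and 100% endpoints."""

    kind: str
    compartment: str       # exact name or prefix glob like "dendrite*"
    channel: str
    path: str              # e.g. "g_max" or "activation.v_half"
    value_at_0: float
    value_at_100: float

    def __post_init__(self):
        if not (np.isfinite(self.value_at_0) and np.isfinite(self.value_at_100)):
            raise ConfigError("modulation endpoints must be finite")


@dataclass(frozen=True)
class DopamineSchedule:
    """Fixed dopamine level or a uniform range, in percent of normal."""

    mode: str = "fixed"             # fixed | uniform_range
    level: float = 100.0            # fixed mode
    range: tuple = (0.0, 100.0)     # uniform_range mode

    def __post_init__(self):
        if self.mode not in ("fixed", "uniform_range"):
            raise ConfigError(f"unknown dopamine schedule mode {self.mode!r}")
        if self.mode == "fixed" and not (0.0 <= self.level <= 100.0):
            raise RangeError("dopamine level must lie in [0, 100] percent")
        if self.mode == "uniform_range":
            lo, hi = self.range
            if not (0.0 <= lo < hi <= 100.0):
                raise RangeError("dopamine range must satisfy 0 <= lo < hi <= 100")


def interpolate_parameter(a: float, b: float, k_percent: float) -> float:
    """Linear interpolation a + (b - a)*k/100 with exact endpoints."""
    if not 0.0 <= k_percent <= 100.0:
        raise RangeError(f"dopamine level {k_percent} outside [0, 100] percent")
    return a + (b - a) * (k_percent / 100.0)


def sample_da_level(schedule: DopamineSchedule, rng: np.random.Generator) -> float:
    """Draw one dopamine level (percent) from the schedule."""
    if schedule.mode == "fixed":
        return float(schedule.level)
    lo, hi = schedule.range
    return float(rng.uniform(lo, hi))


def _set_by_path(obj, path_parts: Sequence[str], value):
    """Return a copy of a (possibly nested, frozen) dataclass with one field replaced."""
    head = path_parts[0]
    if not hasattr(obj, head):
        raise ConfigError(f"parameter path element {head!r} not found on {type(obj).__name__}")
    if len(path_parts) == 1:
        return dataclasses.replace(obj, **{head: value})
    child = getattr(obj, head)
    if child is None:
        raise ConfigError(f"parameter path element {head!r} is not set on {type(obj).__name__}")
    return dataclasses.replace(obj, **{head: _set_by_path(child, path_parts[1:], value)})


def _get_by_path(obj, path_parts: Sequence[str]):
    for head in path_parts:
        if obj is None or not hasattr(obj, head):
            raise ConfigError(f"parameter path element {head!r} not found on {type(obj).__name__}")
        obj = getattr(obj, head)
    return obj


def apply_modulation(templates: Dict[str, NeuronTemplate], k_percent: float,
                     rules: Sequence[ModulationRule]) -> Dict[str, NeuronTemplate]:
    """Apply every rule at dopamine level ``k_percent`` to deep-copied templates.

    Rules always interpolate from their stored endpoints, never from the
    current value, so applying twice at the same k is idempotent.  Parameters
    not named by any rule are bitwise unchanged.
    """
    if not 0.0 <= k_percent <= 100.0:
        raise RangeError(f"dopamine level {k_percent} outside [0, 100] percent")
    out = {kind: copy.deepcopy(t) for kind, t in templates.items()}
    for rule in rules:
        if rule.kind not in out:
            continue
        template = out[rule.kind]
        matched = False
        for comp in template.compartments:
            if not fnmatch.fnmatchcase(comp.name, rule.compartment):
                continue
            for i, ch in enumerate(comp.channels):
                if ch.name != rule.channel:
                    continue
                value = interpolate_parameter(rule.value_at_0, rule.value_at_100, k_percent)
                new_ch = _set_by_path(ch, rule.path.split("."), value)
                if new_ch.mode == "ghk" and rule.path == "g_max":
                    # keep the GHK permeability attachment in sync
                    new_ch = dataclasses.replace(
                        new_ch, ghk=dataclasses.replace(new_ch.ghk, p_max=value)
                    )
                comp.channels[i] = new_ch
                matched = True
        if not matched:
            raise ConfigError(
                f"modulation rule matched nothing: {rule.kind}/{rule.compartment}/"
                f"{rule.channel}.{rule.path}"
            )
    return out


def load_dopamine_rules(templates: Dict[str, NeuronTemplate],
                        path: Optional[str] = None) -> List[ModulationRule]:
    """Load the dopamine rule file, resolving scale/shift endpoints per compartment.

    Each raw rule's ``at_100`` block gives the 100% endpoint relative to the
    template's stored value (``scale`` or ``shift``); because scaled
    endpoints depend on the per-compartment baseline, one raw rule expands
    to one :class:`ModulationRule` per matching compartment.
    """
    if path is None:
        path = packaged_param_path("dopamine_rules.yaml")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules: List[ModulationRule] = []
    for raw in doc.get("rules", []):
        kind = raw["kind"]
        if kind not in templates:
            continue  # rule targets a cell class absent from this network
        template = templates[kind]
        spec100 = raw.get("at_100", {})
        matched = False
        for comp in template.compartments:
            if not fnmatch.fnmatchcase(comp.name, raw["compartment"]):
                continue
            for ch in comp.channels:
                if ch.name != raw["channel"]:
                    continue
                a = float(_get_by_path(ch, raw["path"].split(".")))
                if "value" in spec100:
                    b = float(spec100["value"])
                elif "scale" in spec100:
                    b = a * float(spec100["scale"])
                elif "shift" in spec100:
                    b = a + float(spec100["shift"])
                else:
                    raise ConfigError(f"{path}: at_100 needs value, scale or shift")
                rules.append(
                    ModulationRule(
                        kind=kind,
                        compartment=comp.name,
                        channel=ch.name,
                        path=raw["path"],
                        value_at_0=a,
                        value_at_100=b,
                    )
                )
                matched = True
        if not matched:
            raise ConfigError(
                f"{path}: rule matched nothing: {kind}/{raw['compartment']}/{raw['channel']}"
            )
    return rules
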