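"""YAML run configurations: model choice, parameter overrides, events.

Schema (all keys optional except ``model``)::

    model: molecular                 # minimal | molecular | extended
    t_end: 600.0
    n_points: 2001
    method: LSODA
    params:                          # absolute overrides of named fields
      k_bias: 0.001
    multipliers:                     # wild-type-normalised multipliers
      k_soff: 0.2
    mutants: [cdc16-116@36]          # names from the mutant catalog
    events:
      - {time: 200.0, kind: induce_byr4, payload: {rate: 0.01}}

Unknown keys anywhere are rejected; negative rates fail validation with
the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import ModelDefinition, ParameterSet, get_model
from .scans import apply_mutants
from .simulate import EventSpec

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]

_TOP_KEYS = {"model", "t_end", "n_points", "method", "params",
             "multipliers", "mutants", "events"}
_EVENT_KEYS = {"time", "kind", "payload"}
_PARAM_FIELDS = {f.name for f in dataclasses.fields(ParameterSet)}


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass
class RunConfig:
    model: ModelDefinition
    params: ParameterSet
    t_end: float = 600.0
    n_points: int = 2001
    method: str = "LSODA"
    events: list = field(default_factory=list)

    def as_dict(self) -> dict:
        base = self.model.default_params()
        overrides = {
            name: getattr(self.params, name)
            for name in _PARAM_FIELDS
            if getattr(self.params, name) != getattr(base, name)
        }
        d: dict = {"model": self.model.model_id, "t_end": self.t_end,
                   "n_points": self.n_points, "method": self.method}
        if overrides:
            d["params"] = overrides
        if self.events:
            d["events"] = [{"time": e.time, "kind": e.kind,
                            **({"payload": dict(e.payload)} if e.payload else {})}
                           for e in self.events]
        return d


def _parse(doc: dict, source: str) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown keys {sorted(unknown)}")
    if "model" not in doc:
        raise ConfigError(f"{source}: missing required key 'model'")
    model = get_model(doc["model"])
    params = model.default_params()

    for name, value in (doc.get("params") or {}).items():
        if name not in _PARAM_FIELDS:
            raise ConfigError(f"{source}: params.{name} is not a parameter")
        params = params.updated(**{name: float(value)})
    for name, mult in (doc.get("multipliers") or {}).items():
        if name not in _PARAM_FIELDS:
            raise ConfigError(f"{source}: multipliers.{name} is not a parameter")
        params = params.scaled(name, float(mult))
    mutants = doc.get("mutants") or []
    try:
        params = apply_mutants(params, mutants)
    except KeyError as exc:
        raise ConfigError(f"{source}: {exc.args[0]}") from None
    try:
        params.validate()
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from None

    events = []
    for k, ev in enumerate(doc.get("events") or []):
        unknown = set(ev) - _EVENT_KEYS
        if unknown:
            raise ConfigError(f"{source}: events[{k}] unknown keys {sorted(unknown)}")
        try:
            events.append(EventSpec(float(ev["time"]), ev["kind"],
                                    dict(ev.get("payload") or {})))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{source}: events[{k}]: {exc}") from None

    return RunConfig(model=model, params=params,
                     t_end=float(doc.get("t_end", 600.0)),
                     n_points=int(doc.get("n_points", 2001)),
                     method=str(doc.get("method", "LSODA")),
                     events=events)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse(doc, str(path))


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=False)
    return path
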