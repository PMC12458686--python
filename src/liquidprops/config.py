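"""YAML configuration loading for the CLI.

A config file mirrors the SystemSpec/EnsembleSpec/ProtocolSpec dataclasses
field-for-field, e.g.::

    system:
      catalog: polar_liquid     # or explicit fields
      n: 64
    ensemble:
      ensemble: NPT
      T_target: 300.0
      P_target: 1.0
      thermostat: langevin
      dt: 0.5
    protocol:
      equilibration_len: 5.0
      production_len: 50.0
      n_restarts: 5
      seed: 1
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .engine import EnsembleSpec
from .system import (Bond, SystemSpec, harmonic_diatomic, ideal_gas,
                     lj_fluid, polar_liquid, table_system)
from .workflow import ProtocolSpec

_CATALOG = {
    "lj_fluid": lj_fluid,
    "ideal_gas": ideal_gas,
    "polar_liquid": polar_liquid,
    "harmonic_diatomic": harmonic_diatomic,
    "table_system": table_system,
}


def system_from_dict(d: dict) -> SystemSpec:
    d = dict(d)
    if "catalog" in d:
        name = d.pop("catalog")
        if name not in _CATALOG:
            raise ValueError(f"unknown catalog system {name!r}; "
                             f"choose from {sorted(_CATALOG)}")
        return _CATALOG[name](**d)
    if "bonds" in d:
        d["bonds"] = [Bond(*b) if isinstance(b, (list, tuple)) else Bond(**b)
                      for b in d["bonds"]]
    if "template" in d:
        d["template"] = np.asarray(d["template"], dtype=float)
    return SystemSpec(**d)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    if "system" in cfg:
        out["system"] = system_from_dict(cfg["system"])
    if "ensemble" in cfg:
        out["ensemble"] = EnsembleSpec(**cfg["ensemble"])
    if "protocol" in cfg:
        proto = dict(cfg["protocol"])
        for key in ("rdf_species", "msd_fit"):
            if key in proto and proto[key] is not None:
                proto[key] = tuple(proto[key])
        out["protocol"] = ProtocolSpec(**proto)
    out["raw"] = cfg
    return out
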