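"""Config-file plumbing: YAML/JSON model parameters and result records.

Config schema::

    genetic_architecture:
      v_ao: 1.0
      v_adee: 1.0
      cov_a: 0.5
      v_eo: 1.0
      v_edee: 1.0
    selection:
      beta_o: 0.1
      beta_dee: 0.0

JSON files with the same keys load identically (YAML is a superset).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import yaml

from .model import GeneticArchitecture, ResponsePrediction, SelectionRegime

__all__ = ["load_model_config", "save_model_config", "response_record"]

_ARCH_KEYS = ("v_ao", "v_adee", "cov_a", "v_eo", "v_edee")
_SEL_KEYS = ("beta_o", "beta_dee")


def load_model_config(path: Union[str, Path]) -> Tuple[GeneticArchitecture, SelectionRegime]:
    """Read a parameter config file (.yaml/.yml/.json)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "genetic_architecture" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'genetic_architecture' key")
    arch_raw = data["genetic_architecture"]
    unknown = set(arch_raw) - set(_ARCH_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown genetic_architecture key(s) {sorted(unknown)}")
    arch = GeneticArchitecture(**arch_raw)
    sel_raw = data.get("selection", {})
    unknown = set(sel_raw) - set(_SEL_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown selection key(s) {sorted(unknown)}")
    sel = SelectionRegime(**sel_raw)
    return arch, sel


def save_model_config(
    path: Union[str, Path], arch: GeneticArchitecture, sel: SelectionRegime
) -> None:
    path = Path(path)
    data = {
        "genetic_architecture": {k: getattr(arch, k) for k in _ARCH_KEYS},
        "selection": {k: getattr(sel, k) for k in _SEL_KEYS},
    }
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def response_record(pred: ResponsePrediction) -> dict:
    """Flat serializable record (totals + all decomposition terms)."""
    return pred.to_record()
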