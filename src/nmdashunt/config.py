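"""Structured-config (YAML/JSON) construction of model objects.

Every CLI run resolves its parameters through these helpers so that the full
parameter set - defaults included - can be echoed into the run log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .cable import MembraneParams, Morphology, build_ball_and_stick
from .chain import ChainModel, ChainNode, two_compartment
from .nmda import NMDAParams, SingleCompartment
from .synth import IOTruth, PairedTruth

__all__ = [
    "load_config",
    "build_nmda_params",
    "build_compartment",
    "build_chain",
    "build_membrane",
    "build_morphology",
    "build_io_truth",
    "build_paired_truth",
    "resolved_dict",
]


def load_config(path) -> dict:
    """Load a YAML (or JSON) mapping from ``path``."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def _build(cls, cfg: dict | None):
    cfg = dict(cfg or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(cfg) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**cfg)


def build_nmda_params(cfg: dict | None = None) -> NMDAParams:
    return _build(NMDAParams, cfg)


def build_compartment(cfg: dict | None = None) -> SingleCompartment:
    return _build(SingleCompartment, cfg)


def build_membrane(cfg: dict | None = None) -> MembraneParams:
    return _build(MembraneParams, cfg)


def build_chain(cfg: dict | None = None) -> ChainModel:
    """Chain from config: either two-compartment shorthand or explicit nodes.

    Shorthand keys (``g_dL``, ``g_dI``, ``g_a``, ``g_sL``, ``g_sI``,
    ``e_leak``, ``e_inh``) build the canonical two-node circuit; otherwise
    provide ``nodes`` (list of node mappings) plus ``axial`` and optionally
    ``nmda_node`` / ``record_node``.
    """
    cfg = dict(cfg or {})
    if "nodes" not in cfg:
        return two_compartment(**cfg)
    nodes = tuple(_build(ChainNode, n) for n in cfg.pop("nodes"))
    return ChainModel(nodes=nodes, **cfg)


def build_morphology(cfg: dict | None = None) -> Morphology:
    return build_ball_and_stick(**(cfg or {}))


def build_io_truth(cfg: dict | None = None) -> IOTruth:
    return _build(IOTruth, cfg)


def build_paired_truth(cfg: dict | None = None) -> PairedTruth:
    cfg = dict(cfg or {})
    cfg["control"] = build_io_truth(cfg.get("control"))
    return _build(PairedTruth, cfg)


def resolved_dict(obj) -> dict:
    """Dataclass -> plain dict, for echoing resolved parameters."""
    return dataclasses.asdict(obj)


def dump_json(data, path) -> None:
    """Deterministic JSON output (sorted keys, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
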