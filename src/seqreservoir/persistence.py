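"""Saving and loading trained reservoir models.

A model bundle is a directory holding ``arrays.npz`` (masks, weights, the
homeostatic thresholds and, if present, the neuron assignment) plus a
``manifest.json`` with the schema version and every parameter block, so a
bundle is reproducible and reloadable bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .network import Reservoir
from .params import NeuronParams, PlasticityParams, SynapseParams
from .protocol import AssignmentMap
from .topology import NetworkTopology, PATHWAYS, TopologyConfig

SCHEMA_VERSION = 1


def save_state(path, net: Reservoir, assignment: AssignmentMap | None = None,
               extra: dict | None = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for pw in PATHWAYS:
        arrays[f"mask_{pw}"] = net.topology.masks[pw]
        arrays[f"weights_{pw}"] = net.weights[pw]
    arrays["theta"] = net.state.theta
    if assignment is not None:
        arrays["assignment"] = assignment.assignment
        arrays["mean_rates"] = assignment.mean_rates
    np.savez_compressed(path / "arrays.npz", **arrays)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "topology": dataclasses.asdict(net.topology.config),
        "exc_params": dataclasses.asdict(net.exc_params),
        "inh_params": dataclasses.asdict(net.inh_params),
        "syn_params": dataclasses.asdict(net.syn),
        "plast_params": dataclasses.asdict(net.plast),
        "dt": net.dt,
        "labels": assignment.labels if assignment is not None else None,
        "extra": extra or {},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_state(path) -> tuple:
    """Load a model bundle; returns (net, assignment-or-None, manifest)."""
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as err:
        raise ValueError(f"cannot parse model manifest in {path}: {err}") from err
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {manifest.get('schema_version')!r}"
                         f" (expected {SCHEMA_VERSION})")
    try:
        with np.load(path / "arrays.npz") as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as err:
        raise ValueError(f"cannot read model arrays in {path}: {err}") from err

    topo_cfg = TopologyConfig(**manifest["topology"])
    masks = {pw: arrays[f"mask_{pw}"].astype(bool) for pw in PATHWAYS}
    from .topology import PLASTIC
    topo = NetworkTopology(config=topo_cfg, masks=masks, plastic=dict(PLASTIC))
    weights = {pw: arrays[f"weights_{pw}"] for pw in PATHWAYS}
    net = Reservoir(
        topo, weights,
        exc_params=NeuronParams(**manifest["exc_params"]),
        inh_params=NeuronParams(**manifest["inh_params"]),
        syn_params=SynapseParams(**manifest["syn_params"]),
        plast_params=PlasticityParams(**manifest["plast_params"]),
        dt=manifest["dt"])
    net.state.theta = arrays["theta"]
    assignment = None
    if manifest.get("labels") is not None and "assignment" in arrays:
        assignment = AssignmentMap(labels=list(manifest["labels"]),
                                   assignment=arrays["assignment"],
                                   mean_rates=arrays["mean_rates"])
        assignment.unassignable = [
            lab for k, lab in enumerate(assignment.labels)
            if not np.any(assignment.assignment == k)]
    return net, assignment, manifest
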