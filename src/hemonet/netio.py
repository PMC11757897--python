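"""Network file format (JSON), result writers (CSV) and DOT export.

The on-disk network document is a JSON object::

    {
      "nodes":   [{"id": 1, "kind": "inlet", "pressure": 0.5}, ...],
      "vessels": [{"ends": [1, 4], "length": 1.0, "diameter": 10.0,
                   "inlet_haematocrit": 0.45}, ...],
      "meta":    {"units": "lengths in L, diameters in um, pressures normalised"}
    }

Documents are schema-validated with pydantic on read; writing is
deterministic (sorted keys, fixed float formatting) so that re-running a
pipeline reproduces byte-identical files.  Unknown top-level fields are
preserved inside ``meta`` on a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .topology import NetworkValidationError, Node, VascularNetwork, Vessel

__all__ = ["read_network", "write_network", "network_to_document",
           "write_results", "to_dot", "NetworkDocumentError"]

FORMAT_VERSION = 1


class NetworkDocumentError(ValueError):
    """The JSON document does not describe a valid network."""


class NodeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: int | str
    kind: str
    pressure: Optional[float] = None

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("inlet", "outlet", "interior"):
            raise ValueError(f"kind must be inlet/outlet/interior, got {v!r}")
        return v


class VesselModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ends: tuple[int | str, int | str]
    length: float
    diameter: float
    inlet_haematocrit: Optional[float] = None


class NetworkDocument(BaseModel):
    model_config = ConfigDict(extra="allow")
    nodes: list[NodeModel]
    vessels: list[VesselModel]
    meta: dict = {}


def network_to_document(network: VascularNetwork) -> dict:
    """Canonical (sorted, version-stamped) JSON-ready dict for a network."""
    return {
        "meta": {**dict(network.meta), "version": FORMAT_VERSION,
                 "units": "lengths in multiples of L; diameters in um; "
                          "pressures dimensionless"},
        "nodes": [
            {"id": n.id, "kind": n.kind,
             **({"pressure": n.pressure} if n.pressure is not None else {})}
            for n in network.nodes],
        "vessels": [
            {"ends": [v.start, v.end], "length": v.length, "diameter": v.diameter,
             **({"inlet_haematocrit": v.inlet_haematocrit}
                if v.inlet_haematocrit is not None else {})}
            for v in network.vessels],
    }


def write_network(network: VascularNetwork, path) -> None:
    doc = network_to_document(network)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_network(path) -> VascularNetwork:
    """Read and validate a network document; errors carry JSON paths."""
    raw = json.loads(Path(path).read_text())
    try:
        doc = NetworkDocument.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join("/" + "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
                         for err in e.errors())
        raise NetworkDocumentError(f"invalid network document: {locs}") from e
    meta = dict(doc.meta)
    # preserve unknown top-level fields in meta
    for k, v in (doc.model_extra or {}).items():
        meta.setdefault(k, v)
    meta.pop("version", None)
    meta.pop("units", None)
    nodes = [Node(m.id, m.kind, m.pressure) for m in doc.nodes]
    vessels = [Vessel(m.ends[0], m.ends[1], m.length, m.diameter, m.inlet_haematocrit)
               for m in doc.vessels]
    try:
        return VascularNetwork(nodes, vessels, meta=meta)
    except NetworkValidationError as e:
        raise NetworkDocumentError(str(e)) from e


def write_results(frame: pd.DataFrame, path, *, seed: int | None = None,
                  tolerances: dict | None = None, comment: str = "") -> None:
    """Write a tidy result table as CSV with a provenance header comment."""
    if frame is None or len(frame) == 0:
        raise ValueError("refusing to write an empty result table")
    header = ["# hemonet results"]
    if comment:
        header.append(f"# {comment}")
    if seed is not None:
        header.append(f"# seed: {seed}")
    for k, v in (tolerances or {}).items():
        header.append(f"# {k}: {v}")
    body = frame.to_csv(index=False, float_format="%.12g")
    Path(path).write_text("\n".join(header) + "\n" + body)


def to_dot(network: VascularNetwork) -> str:
    """GraphViz DOT rendering for quick visual checks."""
    lines = ["graph hemonet {"]
    for n in network.nodes:
        shape = {"inlet": "triangle", "outlet": "invtriangle",
                 "interior": "circle"}[n.kind]
        label = f"{n.id}" if n.pressure is None else f"{n.id}\\nP={n.pressure:g}"
        lines.append(f'  "{n.id}" [shape={shape}, label="{label}"];')
    for v in network.vessels:
        attrs = [f'label="L={v.length:g}, D={v.diameter:g}"']
        if v.inlet_haematocrit is not None:
            attrs.append("color=red")
        lines.append(f'  "{v.start}" -- "{v.end}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines)
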