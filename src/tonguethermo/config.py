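"""YAML/JSON serialization for generator and pipeline configuration.

Round-trips GroupParams, CorrelationSpec, PhenotypeSpec and ThresholdTable
through plain mappings so a whole study configuration can live in one
version-controlled file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .cohort import CorrelationSpec, GroupParams, PhenotypeSpec
from .segmentation import ChannelThresholds, ThresholdTable

__all__ = ["to_mapping", "from_mapping", "save_config", "load_config"]


def to_mapping(obj) -> dict:
    if isinstance(obj, GroupParams):
        return {"kind": "group_params",
                "normal": {k: list(v) for k, v in obj.normal.items()},
                "diabetic": {k: list(v) for k, v in obj.diabetic.items()}}
    if isinstance(obj, CorrelationSpec):
        return {"kind": "correlation", "names": list(obj.names),
                "matrix": obj.matrix.tolist()}
    if isinstance(obj, PhenotypeSpec):
        from dataclasses import asdict
        d = asdict(obj)
        d["ellipse_axes"] = list(d["ellipse_axes"])
        return {"kind": "phenotype", **d}
    if isinstance(obj, ThresholdTable):
        return {"kind": "thresholds",
                **{name: {"r": list(row.r), "g": list(row.g), "b": list(row.b)}
                   for name, row in obj.rows.items()}}
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def from_mapping(payload: dict):
    kind = payload.get("kind")
    body = {k: v for k, v in payload.items() if k != "kind"}
    if kind == "group_params":
        return GroupParams(
            normal={k: tuple(v) for k, v in body["normal"].items()},
            diabetic={k: tuple(v) for k, v in body["diabetic"].items()})
    if kind == "correlation":
        return CorrelationSpec(tuple(body["names"]), np.asarray(body["matrix"]))
    if kind == "phenotype":
        body["ellipse_axes"] = tuple(body["ellipse_axes"])
        body["hotspot_count"] = int(body["hotspot_count"])
        body["coldspot_count"] = int(body["coldspot_count"])
        return PhenotypeSpec(**body)
    if kind == "thresholds":
        return ThresholdTable({
            name: ChannelThresholds(name, tuple(v["r"]), tuple(v["g"]),
                                    tuple(v["b"]))
            for name, v in body.items()})
    raise ValueError(f"unknown config kind {kind!r}")


def save_config(obj, path: str | Path) -> None:
    path = Path(path)
    payload = to_mapping(obj)
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_config(path: str | Path):
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} \
        else json.loads(text)
    return from_mapping(payload)
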