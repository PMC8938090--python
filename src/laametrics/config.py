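"""Pipeline configuration and unit conventions.

All geometry is interpreted in millimetres, time in seconds, wall shear
stress in pascal, flow rate in ml/s, volumes in ml. A single config object
owns these declarations plus the tunable numerical parameters of the
pipeline, and every stage logs its inputs, parameters and seed so that
cohorts are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging

import numpy as np
import yaml

logger = logging.getLogger("laametrics")

#: Canonical unit declarations; stages consult these rather than hard-coding.
UNITS = {
    "length": "mm",
    "time": "s",
    "wss": "Pa",
    "flow": "ml/s",
    "volume": "ml",
    "area": "mm^2",
    "velocity": "m/s",
}


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages."""

    length_unit: str = "mm"
    #: spacing of the resampled centreline polyline (mm)
    centreline_spacing: float = 0.5
    #: voxel pitch of the interior distance field used for centreline
    #: extraction (mm); 1 mm resolves LAA lumina of 4 mm radius and above
    centreline_voxel_pitch: float = 1.0
    #: cap applied to relative residence time where (1-2*OSI)*TAWSS underflows
    rrt_max: float = 1e3
    #: beat window (1-based, inclusive) used for time averaging; the first
    #: simulated beat is a stabilisation transient and is discarded
    beat_window: tuple[int, int] = (2, 3)
    #: percentile band kept by the trimmed aggregation
    trim_percentiles: tuple[float, float] = (10.0, 90.0)
    #: washout model for the stagnation fraction: "mixing" or "piston"
    stagnation_model: str = "mixing"
    #: area-weighted (True) vs unweighted (False) node aggregation
    area_weighted: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "beat_window" in raw:
            raw["beat_window"] = tuple(raw["beat_window"])
        if "trim_percentiles" in raw:
            raw["trim_percentiles"] = tuple(raw["trim_percentiles"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def array_hash(*arrays) -> str:
    """Short content hash of one or more numpy arrays, for provenance logs."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def log_stage(stage: str, *, seed=None, input_hash=None, **params) -> None:
    """Log one pipeline stage invocation with its parameters and seed."""
    rec = {"stage": stage}
    if input_hash is not None:
        rec["input_hash"] = input_hash
    if seed is not None:
        rec["seed"] = int(seed)
    rec.update({k: v for k, v in params.items() if v is not None})
    logger.info("%s", json.dumps(rec, default=str, sort_keys=True))
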