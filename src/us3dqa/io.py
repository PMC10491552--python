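"""Persistence of acquisition streams and configs.

Frame streams are stored as multi-page TIFF plus a JSON sidecar with the
timestamps, geometry and seed; tracking streams as CSV with header
``t,x,y,z,rx,ry,rz``; phantom/acquisition configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .acquisition import AcquisitionConfig, FrameStream, TrackingStream
from .imaging import ImageGeometry

__all__ = [
    "write_frame_stream",
    "read_frame_stream",
    "write_tracking_stream",
    "read_tracking_stream",
    "write_config",
    "read_config",
]

TRACKING_HEADER = "t,x,y,z,rx,ry,rz"


def write_frame_stream(stream: FrameStream, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stream.frames)
    sidecar = {
        "timestamps_s": stream.timestamps.tolist(),
        "geometry": dataclasses.asdict(stream.geometry),
        "seed": stream.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frame_stream(path) -> FrameStream:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FrameStream(
        frames,
        np.asarray(meta["timestamps_s"], dtype=float),
        ImageGeometry(**meta["geometry"]),
        seed=meta.get("seed"),
    )


def write_tracking_stream(stream: TrackingStream, path) -> None:
    data = np.column_stack(
        [stream.timestamps, stream.positions, stream.orientations]
    )
    np.savetxt(path, data, delimiter=",", header=TRACKING_HEADER, comments="")


def read_tracking_stream(path) -> TrackingStream:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return TrackingStream(data[:, 0], data[:, 1:4], data[:, 4:7])


def write_config(config: AcquisitionConfig, path, seed: int | None = None) -> None:
    d = dataclasses.asdict(config)
    if seed is not None:
        d["seed"] = seed
    Path(path).write_text(yaml.safe_dump(d))


def read_config(path) -> AcquisitionConfig:
    d = yaml.safe_load(Path(path).read_text())
    return AcquisitionConfig(**d)
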