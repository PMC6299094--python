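"""Reading and writing of the standard on-disk formats.

Image stacks are multi-page TIFFs with a JSON sidecar holding calibration
and provenance (pixel size, frame rate, seed, ground truth); tables are
CSVs with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth, ImageStack
from .microrheology import MSDCurve, TrajectorySet

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_trajectories",
    "read_trajectories",
    "write_msd",
    "read_msd",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image_stack(stack: ImageStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_rate_hz": stack.frame_rate,
    }
    for key, val in stack.metadata.items():
        if isinstance(val, GroundTruth):
            meta["truth"] = val.to_dict()
        elif isinstance(val, (int, float, str, bool, list)) or val is None:
            meta[key] = val
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image_stack(path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return ImageStack(
        frames=np.asarray(frames),
        pixel_size=meta.pop("pixel_size_um"),
        frame_rate=meta.pop("frame_rate_hz"),
        metadata=meta,
    )


def write_trajectories(ts: TrajectorySet, path) -> Path:
    path = Path(path)
    ts.to_dataframe().to_csv(path, index=False)
    return path


def read_trajectories(path) -> TrajectorySet:
    return TrajectorySet.from_dataframe(pd.read_csv(path))


def write_msd(curve: MSDCurve, path) -> Path:
    path = Path(path)
    curve.to_dataframe().to_csv(path, index=False)
    return path


def read_msd(path) -> MSDCurve:
    df = pd.read_csv(path)
    return MSDCurve(
        lags_frames=df["lag_frames"].to_numpy(),
        lags_s=df["lag_s"].to_numpy(),
        msd=df["msd_um2"].to_numpy(),
        n_terms=df["n_terms"].to_numpy(),
        sem=df["sem"].to_numpy() if "sem" in df else None,
    )
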