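"""File round-trips: TIFF with JSON sidecar metadata, CSV tables, summaries.

TIFF carries only pixels; voxel size (µm), frame interval (s) and channel
names travel in a ``<name>.json`` sidecar next to each ``<name>.tif``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .images import VolumeStack, TimeLapse
from .segmentation import DendriteMask, PunctaSet
from .spatial import NNDResult, BranchProfile


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_stack(stack: VolumeStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "kind": "volume", "voxel_size_um": list(stack.voxel_size),
        "channel_name": stack.channel_name}, indent=2))


def load_stack(path) -> VolumeStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return VolumeStack(intensities=tifffile.imread(path),
                       voxel_size=np.array(meta["voxel_size_um"]),
                       channel_name=meta.get("channel_name", ""))


def save_movie(movie: TimeLapse, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "kind": "timelapse", "voxel_size_um": list(movie.voxel_size),
        "frame_interval_s": movie.frame_interval}, indent=2))


def load_movie(path) -> TimeLapse:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return TimeLapse(frames=tifffile.imread(path),
                     frame_interval=meta["frame_interval_s"],
                     voxel_size=np.array(meta["voxel_size_um"]))


def save_mask(mask: DendriteMask, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "kind": "mask", "voxel_size_um": list(mask.voxel_size),
        "provenance": mask.provenance}, indent=2))


def load_mask(path) -> DendriteMask:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return DendriteMask(mask=tifffile.imread(path) > 0,
                        voxel_size=np.array(meta["voxel_size_um"]),
                        provenance=meta.get("provenance", {}))


def puncta_to_csv(puncta: PunctaSet, path) -> None:
    cent = puncta.centroids_um
    cols = {"id": np.arange(1, puncta.n_puncta + 1)}
    for i, ax in enumerate("xyz"[:cent.shape[1]]):
        cols[f"{ax}_um"] = cent[:, i]
    cols["volume_um3"] = puncta.volumes_um3()
    cols["intensity"] = puncta.intensities
    pd.DataFrame(cols).to_csv(path, index=False)


def nnd_to_json(result: NNDResult, path) -> None:
    Path(path).write_text(json.dumps(result.summary(), indent=2))


def profile_to_csv(profile: BranchProfile, path) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def events_to_csv(events_df: pd.DataFrame, path) -> None:
    events_df.to_csv(path, index=False)
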