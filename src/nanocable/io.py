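"""Trajectory (HDF5) and movie (TIFF) persistence."""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import tifffile

from .params import SimulationParams
from .render import DensityImage
from .simulator import Trajectory


def save_trajectory(path, traj: Trajectory) -> None:
    """HDF5 layout: /params (attributes), /frames/<i>/positions plus the
    per-frame time and connector counts as attributes."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for k, v in dataclasses.asdict(traj.params).items():
            grp.attrs[k] = v
        frames = f.create_group("frames")
        for i, (t, pos, counts) in enumerate(
                zip(traj.times, traj.positions, traj.connector_counts)):
            g = frames.create_group(str(i))
            g.attrs["time"] = t
            g.attrs["n_crosslinkers_bound"] = counts[0]
            g.attrs["n_motors_bound"] = counts[1]
            g.create_dataset("positions", data=pos.reshape(-1, 2),
                             compression="gzip")


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        params = SimulationParams(**{k: (v.item() if hasattr(v, "item") else v)
                                     for k, v in f["params"].attrs.items()})
        traj = Trajectory(params)
        B = params.beads_per_filament
        keys = sorted(f["frames"].keys(), key=int)
        for k in keys:
            g = f["frames"][k]
            pos = np.asarray(g["positions"]).reshape(-1, B, 2)
            traj.times.append(float(g.attrs["time"]))
            traj.positions.append(pos)
            traj.connector_counts.append(
                (int(g.attrs["n_crosslinkers_bound"]),
                 int(g.attrs["n_motors_bound"])))
    return traj


def save_movie(path, frames: list[DensityImage]) -> None:
    """Multi-frame 32-bit float TIFF; pixel pitch stored as resolution."""
    stack = np.stack([f.pixels for f in frames]).astype(np.float32)
    pitch = frames[0].pixel_pitch
    tifffile.imwrite(path, stack,
                     resolution=(1.0 / pitch, 1.0 / pitch),
                     metadata={"unit": "um",
                               "frame_time_s": frames[0].frame_time})


def load_movie(path, pixel_pitch: float | None = None,
               frame_interval: float = 0.0) -> list[DensityImage]:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if pixel_pitch is None:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                pixel_pitch = den / num if num else 1.0
            else:
                pixel_pitch = 1.0
    return [DensityImage(np.asarray(frame, float), pixel_pitch,
                         frame_time=i * frame_interval)
            for i, frame in enumerate(stack)]
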