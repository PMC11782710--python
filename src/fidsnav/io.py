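"""Disk formats: NIfTI volumes, CSV trajectories, YAML/JSON configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import FieldTrajectory, MotionTrajectory, PhantomVolume
from .transforms import RigidTransform

_TRAJ_COLUMNS = ["time_s", "rot_x_deg", "rot_y_deg", "rot_z_deg",
                 "trans_x_mm", "trans_y_mm", "trans_z_mm"]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_volume(path, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vox


def save_phantom(directory, phantom: PhantomVolume) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("proton_density", "r2star_map", "ff_map", "offres_map"):
        save_volume(d / f"{name}.nii.gz", getattr(phantom, name),
                    phantom.voxel_size_mm)
    save_volume(d / "mask.nii.gz", phantom.mask.astype(np.float32),
                phantom.voxel_size_mm)


def save_motion_csv(path, traj: MotionTrajectory) -> None:
    df = pd.DataFrame(
        np.column_stack([traj.times_s, traj.params_array()]),
        columns=_TRAJ_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_motion_csv(path) -> MotionTrajectory:
    df = pd.read_csv(path)
    transforms = [RigidTransform.from_params(row) for row in
                  df[_TRAJ_COLUMNS[1:]].to_numpy()]
    return MotionTrajectory(df["time_s"].to_numpy(), transforms)


def save_field_csv(path, traj: FieldTrajectory) -> None:
    cols = ["time_s"] + [f"df0_ch{c}_hz" for c in range(traj.n_channels)]
    df = pd.DataFrame(np.column_stack([traj.times_s, traj.df0_hz]), columns=cols)
    df.to_csv(path, index=False)


def load_field_csv(path) -> FieldTrajectory:
    df = pd.read_csv(path)
    return FieldTrajectory(df["time_s"].to_numpy(),
                           df.drop(columns="time_s").to_numpy())


def load_config(path):
    """YAML or JSON config file -> dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
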