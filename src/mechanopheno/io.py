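"""File I/O: 16-bit TIFF images, CSV tables, YAML sidecars.

Conventions: images are written as uint16 grayscale TIFF (single page per
channel/time point, multi-page for stacks); trajectories and vector
fields go to CSV with stable column names and float formatting, so
repeated runs with one seed are byte-identical; every generated scene
gets a YAML sidecar echoing the full spec and seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .migration import Trajectory
from .tfm import DisplacementField, TractionField

FLOAT_FMT = "%.6g"


def write_tiff(path, image: np.ndarray) -> None:
    """Write an image (or a (t, y, x) stack) as 16-bit grayscale TIFF."""
    arr = np.asarray(image)
    arr = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_yaml(path, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajs:
        for k in range(len(tr)):
            rows.append((tr.cell_id, int(tr.frames[k]), tr.t[k],
                         tr.x[k], tr.y[k]))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "t_min",
                                       "x_um", "y_um"])


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("frame")
        out.append(Trajectory(int(cid), g["frame"].to_numpy(),
                              g["t_min"].to_numpy(), g["x_um"].to_numpy(),
                              g["y_um"].to_numpy()))
    return out


def write_trajectories(path, trajs: list[Trajectory]) -> None:
    write_table(path, trajectories_to_frame(trajs))


def read_trajectories(path) -> list[Trajectory]:
    return frame_to_trajectories(pd.read_csv(path))


def fields_to_frame(disp: DisplacementField,
                    traction: TractionField | None = None) -> pd.DataFrame:
    """Node-wise CSV layout of a displacement (+ optional traction) field."""
    X, Y = np.meshgrid(disp.grid_x, disp.grid_y)
    data = {"x_um": X.ravel(), "y_um": Y.ravel(),
            "u_um": disp.u.ravel(), "v_um": disp.v.ravel(),
            "valid": disp.valid_mask.ravel().astype(int)}
    if traction is not None:
        data.update(tx_pa=traction.t_x.ravel(), ty_pa=traction.t_y.ravel(),
                    mag_pa=traction.magnitude.ravel())
    return pd.DataFrame(data)


def curve_to_frame(depth_m: np.ndarray, force_n: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"depth_m": depth_m, "force_n": force_n})
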