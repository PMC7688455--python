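"""File I/O for clouds, trajectories, transforms and grids.

Formats
-------
- Point clouds: PLY (ascii or binary little-endian, via trimesh) and PCD
  (ascii or binary, parsed in-package).  Coordinates round-trip at float32
  precision; colors, when present, as 8-bit RGB.
- Trajectories: CSV with header ``t,x,y,z`` (seconds, mm).
- Rigid transforms: JSON ``{"R": 9 row-major floats, "t": 3 floats,
  "units": "mm"}``.
- Occupancy grids: CSV of occupied ``i,j,k`` plus a JSON sidecar header
  (origin, resolution, dims); template frame vectors as a sparse MTX
  matrix (frames x voxels).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .calib import RigidTransform
from .cloud import FrameCloud
from .errors import FormatError
from .phantom import TumorTrajectory
from .voxel import OccupancyGrid, TemplateBox
from .watertight import WatertightCloud

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_trajectory",
    "write_trajectory",
    "read_transform",
    "write_transform",
    "write_watertight_ply",
    "write_grid",
    "read_grid",
    "write_frame_vectors",
]


# ---------------------------------------------------------------- clouds

def read_cloud(path: str | Path) -> FrameCloud:
    """Read a PLY or PCD point cloud into a FrameCloud (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".pcd":
        return _read_pcd(path)
    try:
        mesh = trimesh.load(str(path), process=False)
    except Exception as exc:  # trimesh raises various types for bad files
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    pts = np.asarray(mesh.vertices, dtype=float).reshape(-1, 3)
    colors = None
    visual = getattr(mesh, "colors", None)
    if visual is None and hasattr(mesh, "visual"):
        visual = getattr(mesh.visual, "vertex_colors", None)
    if visual is not None and len(visual) == len(pts):
        colors = np.asarray(visual, dtype=float)[:, :3] / 255.0
    return FrameCloud(points=pts, colors=colors)


def write_cloud(cloud: FrameCloud, path: str | Path) -> None:
    """Write a FrameCloud as binary PLY or ascii PCD (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".pcd":
        _write_pcd(cloud, path)
        return
    colors = None
    if cloud.colors is not None:
        colors = np.clip(cloud.colors * 255.0, 0, 255).astype(np.uint8)
        colors = np.column_stack([colors, np.full(len(colors), 255, np.uint8)])
    pc = trimesh.PointCloud(cloud.points.astype(np.float32), colors=colors)
    path.write_bytes(pc.export(file_type="ply"))


def _read_pcd(path: Path) -> FrameCloud:
    raw = path.read_bytes()
    header_end = 0
    fields, sizes, types, counts = [], [], [], []
    n_points, data_mode = None, None
    lines = raw.split(b"\n")
    for lineno, line in enumerate(lines, start=1):
        text = line.decode("ascii", errors="replace").strip()
        header_end += len(line) + 1
        if text.startswith("#") or not text:
            continue
        key, _, rest = text.partition(" ")
        key = key.upper()
        if key == "FIELDS":
            fields = rest.split()
        elif key == "SIZE":
            sizes = [int(x) for x in rest.split()]
        elif key == "TYPE":
            types = rest.split()
        elif key == "COUNT":
            counts = [int(x) for x in rest.split()]
        elif key == "POINTS":
            n_points = int(rest)
        elif key == "DATA":
            data_mode = rest.strip()
            break
        elif key in ("VERSION", "WIDTH", "HEIGHT", "VIEWPOINT"):
            continue
        else:
            raise FormatError(f"unknown PCD header keyword {key!r}", line=lineno)
    if data_mode is None or n_points is None or not fields:
        raise FormatError("incomplete PCD header (missing FIELDS/POINTS/DATA)")
    if not counts:
        counts = [1] * len(fields)
    if any(f not in fields for f in ("x", "y", "z")):
        raise FormatError("PCD file lacks x/y/z fields")

    if n_points == 0:
        return FrameCloud(points=np.empty((0, 3)))
    if data_mode == "ascii":
        body = raw[header_end:].decode("ascii", errors="replace")
        rows = [r for r in body.splitlines() if r.strip()]
        if len(rows) < n_points:
            raise FormatError(
                f"PCD declares {n_points} points but has {len(rows)} data rows"
            )
        data = np.array([[float(v) for v in r.split()] for r in rows[:n_points]])
        cols = {f: data[:, i] for i, f in enumerate(fields)}
    elif data_mode == "binary":
        type_map = {("F", 4): "<f4", ("F", 8): "<f8", ("U", 1): "<u1", ("U", 4): "<u4", ("I", 4): "<i4"}
        dtype = np.dtype(
            [(f, type_map[(t, s)], (c,)) for f, t, s, c in zip(fields, types, sizes, counts)]
        )
        body = raw[header_end:]
        if len(body) < n_points * dtype.itemsize:
            raise FormatError("truncated binary PCD payload")
        rec = np.frombuffer(body, dtype=dtype, count=n_points)
        cols = {f: rec[f].reshape(n_points, -1)[:, 0].astype(float) for f in fields}
    else:
        raise FormatError(f"unsupported PCD DATA mode {data_mode!r}")

    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    colors = None
    if all(f in cols for f in ("r", "g", "b")):
        colors = np.column_stack([cols["r"], cols["g"], cols["b"]]) / 255.0
    return FrameCloud(points=pts, colors=colors)


def _write_pcd(cloud: FrameCloud, path: Path) -> None:
    has_color = cloud.colors is not None
    fields = "x y z" + (" r g b" if has_color else "")
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {fields}\n"
        f"SIZE {'4 ' * (6 if has_color else 3)}".rstrip() + "\n"
        f"TYPE {'F ' * 3}{'U U U ' if has_color else ''}".rstrip() + "\n"
        f"COUNT {'1 ' * (6 if has_color else 3)}".rstrip() + "\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    rows = []
    pts = cloud.points.astype(np.float32)
    for i in range(n):
        row = f"{pts[i, 0]:.6f} {pts[i, 1]:.6f} {pts[i, 2]:.6f}"
        if has_color:
            rgb = np.clip(cloud.colors[i] * 255.0, 0, 255).astype(int)
            row += f" {rgb[0]} {rgb[1]} {rgb[2]}"
        rows.append(row)
    path.write_text(header + "\n".join(rows) + ("\n" if rows else ""))


def write_watertight_ply(wc: WatertightCloud, path: str | Path) -> None:
    """Write a closed shell as ascii PLY with an integer ``component`` property.

    Component codes: 0=surface, 1=back, 2=shoulder wall, 3=end wall,
    4=waist wall.
    """
    pts = wc.all_points().astype(np.float32)
    comp = wc.component_labels()
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(pts)}",
        "property float x",
        "property float y",
        "property float z",
        "property int component",
        "end_header",
    ]
    for p, c in zip(pts, comp):
        lines.append(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------- trajectories

def write_trajectory(traj: TumorTrajectory | tuple, path: str | Path) -> None:
    """Write a trajectory as CSV with header ``t,x,y,z`` (s, mm)."""
    if isinstance(traj, TumorTrajectory):
        times, positions = traj.times, traj.positions
    else:
        times, positions = traj
    df = pd.DataFrame(
        {
            "t": np.asarray(times, float),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": positions[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> TumorTrajectory:
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"trajectory CSV missing columns {sorted(missing)}")
    return TumorTrajectory(
        times=df["t"].to_numpy(float),
        positions=df[["x", "y", "z"]].to_numpy(float),
    )


# ------------------------------------------------------------- transforms

def write_transform(transform: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=2) + "\n")


def read_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------ grids

def write_grid(grid: OccupancyGrid, csv_path: str | Path, header_path: str | Path) -> None:
    """Occupied i,j,k coordinates as CSV plus a JSON geometry header."""
    idx = np.argwhere(grid.occupancy)
    pd.DataFrame(idx, columns=["i", "j", "k"]).to_csv(csv_path, index=False)
    header = {
        "origin_mm": [float(x) for x in grid.origin],
        "resolution_mm": grid.resolution,
        "dims": [int(d) for d in grid.dims],
    }
    Path(header_path).write_text(json.dumps(header, indent=2) + "\n")


def read_grid(csv_path: str | Path, header_path: str | Path) -> OccupancyGrid:
    header = json.loads(Path(header_path).read_text())
    idx = pd.read_csv(csv_path)[["i", "j", "k"]].to_numpy(int)
    occ = np.zeros(tuple(header["dims"]), dtype=bool)
    if len(idx):
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return OccupancyGrid(
        origin=np.asarray(header["origin_mm"], float),
        resolution=float(header["resolution_mm"]),
        occupancy=occ,
    )


def write_frame_vectors(template: TemplateBox, path: str | Path) -> None:
    """Template frame vectors as a sparse (frames x voxels) MTX matrix."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(str(path), sparse.csr_matrix(template.frame_vectors))
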