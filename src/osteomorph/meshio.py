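"""Triangle-mesh input/output (PLY) built on trimesh.

Meshes are carried in memory as :class:`trimesh.Trimesh`; coordinates
are treated as dimensionless after import (physical voxel size is
metadata only).  Non-triangular faces are triangulated on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

__all__ = ["MeshFormatError", "read_mesh", "write_mesh", "write_point_ply"]


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or is empty."""


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an ascii or binary little-endian PLY into a Trimesh.

    Quads and larger polygons are fan-triangulated; vertex units are
    preserved untouched.  A malformed header or truncated body raises
    :class:`MeshFormatError` naming the file, an empty face list raises
    it as an empty-mesh error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(path, file_type=path.suffix.lstrip(".") or "ply",
                            force="mesh", process=False)
    except Exception as exc:  # trimesh raises various parse errors
        raise MeshFormatError(f"{path}: cannot parse mesh file: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path}: empty mesh (no faces)")
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshFormatError(f"{path}: non-finite vertex coordinates")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as ascii PLY."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


def write_point_ply(points: np.ndarray, path: str | Path,
                    quality: np.ndarray | None = None) -> None:
    """Write a point cloud as ascii PLY with an optional per-vertex
    ``quality`` scalar (the channel heat-map viewers color by)."""
    points = np.asarray(points, dtype=float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if quality is not None:
            fh.write("property float quality\n")
        fh.write("end_header\n")
        for i, p in enumerate(points):
            line = f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            if quality is not None:
                line += f" {quality[i]:.6g}"
            fh.write(line + "\n")
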