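"""Readers and writers for meshes, landmark configurations and design tables.

File formats follow the conventions of 3D facial surface studies: surfaces are
exchanged as ASCII PLY (the working format after conversion from scanner
output) or Wavefront OBJ; landmark configurations and study designs are plain
CSV. All coordinates are millimetres throughout — no unit autodetection is
attempted. Vertex and landmark order is never permuted by I/O, because row
order carries the point correspondence across subjects.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MeshFormatError",
    "IntegrityError",
    "SurfaceMesh",
    "AnchorSet",
    "ANCHOR_NAMES",
    "LandmarkConfiguration",
    "DesignTable",
    "read_mesh",
    "write_mesh",
    "write_colored_mesh",
    "read_anchors",
    "write_anchors",
    "read_configuration",
    "write_configuration",
    "read_design",
    "write_design",
]


class MeshFormatError(ValueError):
    """Raised for malformed or unsupported mesh files."""


class IntegrityError(ValueError):
    """Raised when a design table violates study-design constraints."""


# Fixed digitization order of the five anchoring landmarks.
ANCHOR_NAMES = (
    "right_exocanthion",
    "left_exocanthion",
    "pronasale",
    "right_cheilion",
    "left_cheilion",
)


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm. ``colors`` is an optional (n, 3) uint8 RGB array."""

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if len(self.vertices) < 3:
            raise MeshFormatError("mesh needs at least 3 vertices")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshFormatError("faces must be an (m, 3) array of triangles")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshFormatError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise MeshFormatError("degenerate triangle: repeated vertex index")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8)
            if self.colors.shape != (len(self.vertices), 3):
                raise MeshFormatError("colors must be (n_vertices, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class AnchorSet:
    """The five anchoring landmarks, in the fixed digitization order:
    right exocanthion, left exocanthion, pronasale, right cheilion,
    left cheilion."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (5, 3):
            raise ValueError("anchor set must contain exactly 5 points (5, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("anchor coordinates must be finite")
        centered = self.coords - self.coords.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise ValueError("anchor points are collinear or coincident")


@dataclass
class LandmarkConfiguration:
    """One subject-stage face as k ordered 3D quasi-landmarks in mm."""

    subject_id: str
    stage: str
    group: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (k, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def k(self) -> int:
        return len(self.coords)


@dataclass
class DesignTable:
    """Long-format study design: one row per observation (subject_id, stage,
    group, file). Stage levels are kept in the declared order."""

    table: pd.DataFrame
    stages: tuple[str, ...] = ("T0", "T1", "T2")

    def __post_init__(self) -> None:
        required = {"subject_id", "stage", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise IntegrityError(f"design table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise IntegrityError("no observations in design table")
        t = self.table
        bad = set(t["stage"]) - set(self.stages)
        if bad:
            raise IntegrityError(f"unknown stage labels: {sorted(bad)}")
        dup = t.duplicated(subset=["subject_id", "stage"])
        if dup.any():
            row = t[dup].iloc[0]
            raise IntegrityError(
                f"duplicate observation for subject {row['subject_id']!r} "
                f"stage {row['stage']!r}"
            )
        varying = t.groupby("subject_id")["group"].nunique()
        if (varying > 1).any():
            subj = varying[varying > 1].index[0]
            raise IntegrityError(f"group varies within subject {subj!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subjects(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    @property
    def stage_labels(self) -> np.ndarray:
        return self.table["stage"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()


# ---------------------------------------------------------------------------
# Mesh I/O — minimal ASCII PLY and OBJ (v/f records) dialects.


def _parse_ascii_ply(lines: list[str], path: str) -> SurfaceMesh:
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
    n_vert = n_face = 0
    vertex_props: list[str] = []
    in_vertex_element = False
    header_end = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise MeshFormatError(
                    f"{path}: binary PLY ('{tok[1]}') is unsupported; convert to ascii"
                )
        elif tok[0] == "element":
            in_vertex_element = tok[1] == "vertex"
            if tok[1] == "vertex":
                n_vert = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and in_vertex_element:
            vertex_props.append(tok[-1])
        elif tok[0] == "end_header":
            header_end = i
            break
    if header_end is None:
        raise MeshFormatError(f"{path}: missing end_header")
    for axis in ("x", "y", "z"):
        if axis not in vertex_props:
            raise MeshFormatError(f"{path}: vertex element lacks property '{axis}'")
    has_color = all(c in vertex_props for c in ("red", "green", "blue"))
    idx = {p: j for j, p in enumerate(vertex_props)}

    body = lines[header_end:]
    if len(body) < n_vert + n_face:
        raise MeshFormatError(f"{path}: truncated body")
    verts = np.empty((n_vert, 3))
    colors = np.empty((n_vert, 3), dtype=np.uint8) if has_color else None
    for j in range(n_vert):
        tok = body[j].split()
        lineno = header_end + 1 + j
        if len(tok) < len(vertex_props):
            raise MeshFormatError(f"{path}:{lineno}: short vertex record")
        try:
            verts[j] = [float(tok[idx[a]]) for a in ("x", "y", "z")]
            if has_color:
                colors[j] = [int(tok[idx[c]]) for c in ("red", "green", "blue")]
        except ValueError as exc:
            raise MeshFormatError(f"{path}:{lineno}: bad vertex record: {exc}") from exc
    faces = np.empty((n_face, 3), dtype=int)
    for j in range(n_face):
        tok = body[n_vert + j].split()
        lineno = header_end + 1 + n_vert + j
        try:
            cnt = int(tok[0])
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{path}:{lineno}: bad face record") from exc
        if cnt != 3 or len(tok) < 4:
            raise MeshFormatError(f"{path}:{lineno}: only triangle faces supported")
        faces[j] = [int(t) for t in tok[1:4]]
    return SurfaceMesh(verts, faces, colors)


def _parse_obj(lines: list[str], path: str) -> SurfaceMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, line in enumerate(lines, start=1):
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        if tok[0] == "v":
            try:
                verts.append([float(t) for t in tok[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: bad vertex: {exc}") from exc
        elif tok[0] == "f":
            if len(tok) < 4:
                raise MeshFormatError(f"{path}:{lineno}: face needs 3 vertices")
            try:
                # "f 1 2 3" or "f 1/1/1 2/2/2 3/3/3"; OBJ indices are 1-based
                faces.append([int(t.split("/")[0]) - 1 for t in tok[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: bad face: {exc}") from exc
        # other record types (vn, vt, usemtl, ...) are ignored
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=int).reshape(-1, 3))


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an ASCII PLY or OBJ surface. Vertex order is preserved exactly."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:3] == b"ply" and b"format ascii" not in raw[:200]:
        raise MeshFormatError(f"{path}: binary PLY is unsupported; convert to ascii")
    lines = raw.decode("utf-8", errors="replace").splitlines()
    first = lines[0].strip() if lines else ""
    if first == "ply" or path.suffix.lower() == ".ply":
        return _parse_ascii_ply(lines, str(path))
    return _parse_obj(lines, str(path))


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write an ASCII PLY, with per-vertex RGB if the mesh carries colors."""
    path = Path(path)
    buf = _io.StringIO()
    has_color = mesh.colors is not None
    buf.write("ply\nformat ascii 1.0\n")
    buf.write(f"element vertex {mesh.n_vertices}\n")
    buf.write("property float x\nproperty float y\nproperty float z\n")
    if has_color:
        buf.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
    buf.write(f"element face {len(mesh.faces)}\n")
    buf.write("property list uchar int vertex_indices\nend_header\n")
    for j in range(mesh.n_vertices):
        x, y, z = mesh.vertices[j]
        buf.write(f"{x:.8f} {y:.8f} {z:.8f}")
        if has_color:
            r, g, b = mesh.colors[j]
            buf.write(f" {r} {g} {b}")
        buf.write("\n")
    for f in mesh.faces:
        buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    path.write_text(buf.getvalue())


def write_colored_mesh(
    mesh: SurfaceMesh,
    scalars: np.ndarray,
    path: str | Path,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    mask: np.ndarray | None = None,
    mask_color: tuple[int, int, int] = (255, 105, 180),
    missing_color: tuple[int, int, int] = (128, 128, 128),
) -> None:
    """Export a per-vertex scalar field as a colored ASCII PLY heatmap.

    Scalars are min-max normalized into ``cmap`` unless an explicit
    (vmin, vmax) range is given. Non-finite scalars render neutral gray.
    If ``mask`` is given, True vertices are painted ``mask_color``
    (default pink) and the scalar field is ignored for them.
    """
    import matplotlib

    scalars = np.asarray(scalars, dtype=float)
    if scalars.shape != (mesh.n_vertices,):
        raise ValueError(
            f"scalars length {scalars.shape} does not match "
            f"{mesh.n_vertices} vertices"
        )
    finite = np.isfinite(scalars)
    lo = vmin if vmin is not None else (scalars[finite].min() if finite.any() else 0.0)
    hi = vmax if vmax is not None else (scalars[finite].max() if finite.any() else 1.0)
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((scalars - lo) / span, 0.0, 1.0)
    colormap = matplotlib.colormaps[cmap]
    rgba = colormap(np.where(finite, norm, 0.0))
    colors = (rgba[:, :3] * 255).round().astype(np.uint8)
    colors[~finite] = missing_color
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (mesh.n_vertices,):
            raise ValueError("mask length does not match vertex count")
        colors[mask] = mask_color
    write_mesh(SurfaceMesh(mesh.vertices, mesh.faces, colors), path)


# ---------------------------------------------------------------------------
# Landmark and design CSV I/O.


def read_anchors(path: str | Path) -> AnchorSet:
    """Read the five anchoring landmarks from a CSV with columns x,y,z."""
    coords = read_configuration(path)
    if len(coords) != 5:
        raise ValueError(f"{path}: expected 5 anchor rows, found {len(coords)}")
    return AnchorSet(coords)


def write_anchors(anchors: AnchorSet, path: str | Path) -> None:
    write_configuration(anchors.coords, path)


def read_configuration(path: str | Path) -> np.ndarray:
    """Read a k×3 landmark coordinate matrix (mm) from CSV with header x,y,z."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["x", "y", "z"] or len(cols) != 3:
        raise ValueError(f"{path}: expected exactly columns x,y,z, found {list(df.columns)}")
    arr = df.to_numpy()
    if arr.dtype == object:
        raise ValueError(f"{path}: non-numeric cell in coordinate table")
    bad = ~np.isfinite(arr.astype(float))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-finite coordinate at line {row}")
    return arr.astype(float)


def write_configuration(coords: np.ndarray, path: str | Path) -> None:
    coords = np.asarray(coords, dtype=float)
    pd.DataFrame(coords, columns=["x", "y", "z"]).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_design(path: str | Path, stages: tuple[str, ...] = ("T0", "T1", "T2")) -> DesignTable:
    """Read a study design CSV (subject_id, stage, group[, file])."""
    try:
        df = pd.read_csv(Path(path), dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise IntegrityError(f"{path}: no observations") from exc
    if len(df) == 0:
        raise IntegrityError(f"{path}: no observations")
    return DesignTable(df, stages=stages)


def write_design(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, index=False)
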