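"""Template (anthropometric-mask) mapping onto target facial surfaces.

A fixed template of k quasi-landmarks covering the facial region of interest
is transferred to each subject's mesh in three deterministic steps:

1. least-squares similarity alignment (rotation + uniform scale +
   translation, no reflection) of the template's five anchoring landmarks
   onto the subject's digitized anchors (right/left exocanthion, pronasale,
   right/left cheilion, in fixed order);
2. a 3-D thin-plate-spline warp with kernel U(r) = r driven by the five
   anchor pairs, bending the whole template toward the subject;
3. projection of every warped landmark to the closest point on the subject's
   mesh surface (point-to-triangle; equidistant ties resolve to the lowest
   triangle index).

Because template ordering is preserved, landmark i corresponds across
subjects by construction, and structures outside the mask (hair, ears) are
excluded because the template never covers them. Pre-mapped configurations
from external dense-registration tools can bypass this module entirely via
``core`` I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import RBFInterpolator

from .io import AnchorSet, LandmarkConfiguration, SurfaceMesh, write_configuration, read_configuration
from .procrustes import SymmetryMap

__all__ = [
    "RegistrationError",
    "SimilarityTransform",
    "Template",
    "similarity_align_anchors",
    "tps_warp",
    "map_template",
]


class RegistrationError(RuntimeError):
    """Raised when template-to-mesh registration fails a sanity gate."""


@dataclass
class SimilarityTransform:
    """x -> scale * x @ rotation.T + translation, with det(rotation) = +1."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-10:
            raise ValueError("rotation must have determinant +1 (no reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass
class Template:
    """Anthropometric mask: k ordered quasi-landmarks with anchors, region
    labels, bilateral symmetry map and (optionally) a triangulation."""

    coords: np.ndarray
    anchor_indices: np.ndarray
    region_labels: np.ndarray
    symmetry: SymmetryMap
    faces: np.ndarray | None = None
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.anchor_indices = np.asarray(self.anchor_indices, dtype=int).reshape(5)
        self.region_labels = np.asarray(self.region_labels)
        if len(set(self.anchor_indices.tolist())) != 5:
            raise ValueError("anchor indices must be 5 distinct landmarks")
        if len(self.region_labels) != len(self.coords):
            raise ValueError("one region label per landmark required")
        if self.symmetry.k != len(self.coords):
            raise ValueError("symmetry map size does not match template")

    @property
    def k(self) -> int:
        return len(self.coords)

    @property
    def anchors(self) -> AnchorSet:
        return AnchorSet(self.coords[self.anchor_indices])

    def save(self, json_path: str | Path, coords_path: str | Path) -> None:
        """Store as coords CSV plus JSON metadata (anchors, regions, symmetry)."""
        write_configuration(self.coords, coords_path)
        meta = {
            "coords_file": str(Path(coords_path).name),
            "anchor_indices": self.anchor_indices.tolist(),
            "region_labels": self.region_labels.tolist(),
            "symmetry_pairs": self.symmetry.pairs.tolist(),
            "symmetry_midline": self.symmetry.midline.tolist(),
            "faces": self.faces.tolist() if self.faces is not None else None,
        }
        Path(json_path).write_text(json.dumps(meta))

    @classmethod
    def load(cls, json_path: str | Path) -> "Template":
        meta = json.loads(Path(json_path).read_text())
        coords = read_configuration(Path(json_path).parent / meta["coords_file"])
        return cls(
            coords=coords,
            anchor_indices=np.array(meta["anchor_indices"]),
            region_labels=np.array(meta["region_labels"]),
            symmetry=SymmetryMap(np.array(meta["symmetry_pairs"]).reshape(-1, 2),
                                 np.array(meta["symmetry_midline"], dtype=int)),
            faces=np.array(meta["faces"], dtype=int) if meta["faces"] else None,
        )


def similarity_align_anchors(source: AnchorSet, target: AnchorSet) -> SimilarityTransform:
    """Least-squares similarity transform mapping source anchors onto target
    anchors (Umeyama's closed form; rotation restricted to det = +1)."""
    src = source.coords
    dst = target.coords
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    src_c = src - mu_s
    dst_c = dst - mu_d
    cov = dst_c.T @ src_c / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        d[-1] = -1.0
    rotation = u @ np.diag(d) @ vt
    var_src = (src_c**2).sum() / len(src)
    if var_src < 1e-12:
        raise ValueError("degenerate anchor configuration: coincident points")
    scale = float((s * d).sum() / var_src)
    translation = mu_d - scale * rotation @ mu_s
    return SimilarityTransform(scale=scale, rotation=rotation, translation=translation)


def tps_warp(control_src: np.ndarray, control_dst: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """3-D thin-plate-spline interpolant with kernel U(r) = r plus an affine
    part, exact at the control points; evaluated at ``queries``.

    Requires >= 5 distinct, non-coplanar control points (unisolvency of the
    degree-1 polynomial part). Affine control motions are reproduced exactly
    with zero bending.
    """
    src = np.asarray(control_src, dtype=float)
    dst = np.asarray(control_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("control point sets must be matching (n, 3) arrays")
    if len(src) < 5:
        raise ValueError("need at least 5 control points")
    if len(np.unique(src.round(decimals=12), axis=0)) != len(src):
        raise ValueError("duplicate control points make the TPS system singular")
    hom = np.hstack([np.ones((len(src), 1)), src])
    if np.linalg.matrix_rank(hom) < 4:
        raise ValueError("control points are coplanar: TPS affine part is not unique")
    try:
        interp = RBFInterpolator(src, dst, kernel="linear", degree=1)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError(f"singular TPS system: {exc}") from exc
    return interp(np.asarray(queries, dtype=float))


def _project_to_surface(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    closest, _, _ = trimesh.proximity.closest_point_naive(tm, points)
    return np.asarray(closest, dtype=float)


def map_template(
    template: Template,
    mesh: SurfaceMesh,
    anchors: AnchorSet,
    subject_id: str = "",
    stage: str = "",
    group: str = "",
    anchor_gate_mm: float = 30.0,
    project: bool = True,
) -> LandmarkConfiguration:
    """Map the template onto a target mesh given its five digitized anchors.

    Pipeline: similarity-align template anchors to subject anchors, TPS-warp
    all template landmarks using the five anchor pairs as controls, then
    project each warped landmark to the closest surface point. Output
    preserves template ordering, so landmark i corresponds across subjects.

    Raises :class:`RegistrationError` if any digitized anchor lies farther
    than ``anchor_gate_mm`` from the mesh surface.
    """
    on_surface = _project_to_surface(anchors.coords, mesh)
    gaps = np.linalg.norm(on_surface - anchors.coords, axis=1)
    if np.any(gaps > anchor_gate_mm):
        worst = int(np.argmax(gaps))
        raise RegistrationError(
            f"anchor {worst} is {gaps[worst]:.1f} mm from the mesh "
            f"(gate {anchor_gate_mm} mm): check anchor digitization"
        )
    sim = similarity_align_anchors(template.anchors, anchors)
    moved = sim.apply(template.coords)
    moved_anchors = moved[template.anchor_indices]
    warped = tps_warp(moved_anchors, anchors.coords, moved)
    final = _project_to_surface(warped, mesh) if project else warped
    return LandmarkConfiguration(
        subject_id=subject_id, stage=stage, group=group, coords=final
    )
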