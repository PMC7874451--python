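"""Symmetric-component Generalized Procrustes Analysis.

Faces are internally symmetric about the midsagittal plane, so each landmark
configuration is paired with its reflected-and-relabeled copy: the
configuration is mirrored across x = 0 and bilateral landmarks swap slots so
that left landmarks are averaged with reflected right landmarks. Originals
and reflections are superimposed jointly by GPA (translation, unit-size
scaling, det=+1 rotations); the landmark-wise average of each original with
its reflection is the symmetric component of shape, on which all downstream
statistics operate.

Conventions
-----------
* Shapes are scaled to unit centroid size every iteration (classic GPA,
  no variable-scaling partial-Procrustes step).
* Reflections enter only through :func:`reflect_relabel`; the rotation
  solver is restricted to det = +1.
* Procrustes distance is the Euclidean norm of the coordinate difference
  between shapes already in the common superimposition frame — the standard
  small-variation surrogate for full Procrustes distance, and the convention
  that makes distance matrices and coordinate-space sums of squares exactly
  consistent. The discrepancy from the chord distance is O(PD³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymmetryMap",
    "ProcrustesResult",
    "centroid_size",
    "center",
    "normalize",
    "optimal_rotation",
    "reflect_relabel",
    "symmetrize",
    "gpa",
    "symmetric_component",
    "procrustes_distance",
    "opa_distance",
    "to_form",
]


@dataclass
class SymmetryMap:
    """Pairing of bilateral landmark indices plus self-paired midline indices.

    ``pairs[i] = (left, right)`` lists homologous bilateral landmarks;
    ``midline`` lists landmarks lying on the symmetry plane. Together they
    must partition ``range(k)``; the induced permutation is an involution.
    """

    pairs: np.ndarray
    midline: np.ndarray
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.midline = np.asarray(self.midline, dtype=int).reshape(-1)
        all_idx = np.concatenate([self.pairs.ravel(), self.midline])
        self.k = len(all_idx)
        if sorted(all_idx) != list(range(self.k)):
            raise ValueError("symmetry map must partition 0..k-1")

    @property
    def permutation(self) -> np.ndarray:
        """Involution p with p[left]=right, p[right]=left, p[mid]=mid."""
        p = np.arange(self.k)
        p[self.pairs[:, 0]] = self.pairs[:, 1]
        p[self.pairs[:, 1]] = self.pairs[:, 0]
        return p


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 landmarks")
    size = float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum()))
    if size == 0.0:
        raise ValueError("zero centroid size: all landmarks coincide")
    return size


def center(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def normalize(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = center(coords)
    return c / np.sqrt((c**2).sum())


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det = +1) minimizing ||source @ R - target||_F.

    Both inputs should be centered. Reflections are never returned; bilateral
    symmetry is handled by explicit reflect-relabel, not by the solver.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(3)
    flip[-1] = d
    return (u * flip) @ vt


def reflect_relabel(coords: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Mirror across x = 0, then swap bilateral landmark slots.

    Row i of the output is the reflected coordinate of landmark ``p[i]``
    (its bilateral partner), so left slots carry reflected-right landmarks
    and vice versa; midline slots keep their own reflected coordinates.
    Applying twice is the identity.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) != sym.k:
        raise ValueError(f"symmetry map is for k={sym.k}, got {len(coords)} landmarks")
    reflected = coords * np.array([-1.0, 1.0, 1.0])
    return reflected[sym.permutation]


def symmetrize(coords: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Landmark-wise average of a configuration with its reflected relabeling."""
    return 0.5 * (np.asarray(coords, dtype=float) + reflect_relabel(coords, sym))


@dataclass
class ProcrustesResult:
    """Superimposed shapes plus alignment bookkeeping.

    ``shapes`` holds the Procrustes shape coordinates of the original
    configurations (n, k, 3); when reflections were included,
    ``reflected_shapes`` holds their superimposed reflected-relabeled
    counterparts, indexed alongside. Centroid sizes are in mm.
    """

    shapes: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    reflected_shapes: np.ndarray | None = None


def gpa(
    configs,
    include_reflections: bool = False,
    sym: SymmetryMap | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes Analysis.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the current mean shape; the mean is re-estimated
    and renormalized to unit size until its displacement falls below ``tol``.
    With ``include_reflections``, the superimposed set contains the n
    originals plus their reflected relabelings (2n items aligned in one
    common frame), as required for symmetric-component extraction.
    """
    arrs = [np.asarray(c, dtype=float) for c in configs]
    if not arrs:
        raise ValueError("need at least one configuration")
    k = arrs[0].shape[0]
    if any(a.shape != (k, 3) for a in arrs):
        raise ValueError("all configurations must share the same (k, 3) shape")
    n = len(arrs)
    sizes = np.array([centroid_size(a) for a in arrs])

    items = [normalize(a) for a in arrs]
    if include_reflections:
        if sym is None:
            raise ValueError("include_reflections requires a SymmetryMap")
        items = items + [normalize(reflect_relabel(a, sym)) for a in arrs]

    x = np.stack(items)  # (m, k, 3), m = n or 2n
    mean = x[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(x)):
            x[i] = x[i] @ optimal_rotation(x[i], mean)
        new_mean = normalize(x.mean(axis=0))
        # fix the arbitrary global orientation: rotate mean as little as possible
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning
        )
    return ProcrustesResult(
        shapes=x[:n].copy(),
        mean_shape=mean,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        reflected_shapes=x[n:].copy() if include_reflections else None,
    )


def symmetric_component(result: ProcrustesResult) -> np.ndarray:
    """Per-configuration symmetric component: the landmark-wise average of
    each superimposed original with its superimposed reflected relabeling."""
    if result.reflected_shapes is None:
        raise ValueError(
            "symmetric_component requires a GPA run with include_reflections"
        )
    return 0.5 * (result.shapes + result.reflected_shapes)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two shapes in the common superimposition
    frame (the linearized Procrustes distance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def opa_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations: both are
    normalized to unit centroid size and b is optimally rotated onto a."""
    an = normalize(a)
    bn = normalize(b)
    return procrustes_distance(an, bn @ optimal_rotation(bn, an))


def to_form(shape: np.ndarray, size: float) -> np.ndarray:
    """Form coordinates: shape coordinates multiplied by centroid size (mm)."""
    if size <= 0:
        raise ValueError("centroid size must be positive")
    return np.asarray(shape, dtype=float) * float(size)
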