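"""Landmark geometry: Procrustes superimposition, PCA morphospace, theoretical grids.

Shapes are configurations of homologous 3D landmarks. Generalized Procrustes
analysis (GPA) removes translation, scale (to unit centroid size) and rotation
by iterated least-squares superimposition, then projects the aligned
configurations orthogonally onto the tangent space at the mean shape.  A PCA of
the flattened tangent coordinates gives the empirical morphospace; hypothetical
shapes anywhere in that space are reconstructed linearly from scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "ProcrustesAlignment",
    "MorphospaceModel",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "pca_morphospace",
    "reconstruct_shape",
    "theoretical_grid",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark matrix (n_landmarks x 3) with labels.

    ``clade`` distinguishes the two groups sharing (or not) a form-function
    mapping; by convention ``groupA`` plays the placental role (model-fitting
    group) and ``groupB`` the marsupial role (transfer group).
    """

    coordinates: np.ndarray
    species_id: str = ""
    clade: str = "groupA"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_landmarks, 3) matrix")
        if self.coordinates.shape[0] < 4:
            raise ValueError("need at least 4 landmarks")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates in specimen {self.species_id!r}")
        if self.clade not in ("groupA", "groupB"):
            raise ValueError("clade must be 'groupA' or 'groupB'")

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]

    def flatten(self) -> np.ndarray:
        return self.coordinates.reshape(-1)


@dataclass
class ProcrustesAlignment:
    """Result of GPA: tangent-space configurations plus the sizes removed."""

    aligned: list[LandmarkConfiguration]
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray  # (n_landmarks, 3)
    n_iterations: int = 0

    def flattened(self) -> np.ndarray:
        """Specimens x (3*n_landmarks) matrix of tangent coordinates."""
        return np.array([c.flatten() for c in self.aligned])


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid.

    Equals the Frobenius norm of the row-centered coordinate matrix.
    """
    coords = config.coordinates if isinstance(config, LandmarkConfiguration) else np.asarray(config, dtype=float)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide (zero centroid size)")
    return size


def _preshape(coords: np.ndarray) -> np.ndarray:
    """Center and scale a configuration to unit centroid size."""
    centered = coords - coords.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size <= 0.0:
        raise ValueError("degenerate configuration (zero centroid size)")
    return centered / size

def _optimal_rotation(x: np.ndarray, target: np.ndarray, allow_reflections: bool) -> np.ndarray:
    """Rotation R minimizing ||x R - target||_F (Kabsch)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if not allow_reflections and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def gpa(
    sample: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflections: bool = False,
    tangent_projection: bool = True,
) -> ProcrustesAlignment:
    """Generalized Procrustes analysis with scaling to unit centroid size.

    Iterates rotation-to-the-mean until the mean shape changes by less than
    ``tol`` (Frobenius norm), then orthogonally projects the aligned unit-size
    configurations onto the tangent space at the mean.

    Parameters
    ----------
    sample:
        At least two configurations with identical landmark counts.
    allow_reflections:
        If True, improper rotations are permitted in the superimposition.
    tangent_projection:
        Apply the orthogonal tangent-space projection about the mean
        (standard practice; disable to keep spherical preshape coordinates).
    """
    if len(sample) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    counts = {c.n_landmarks for c in sample}
    if len(counts) != 1:
        raise ValueError(f"mismatched landmark counts: {sorted(counts)}")

    sizes = np.array([centroid_size(c) for c in sample])
    shapes = [_preshape(c.coordinates) for c in sample]

    mean = _preshape(shapes[0])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        shapes = [x @ _optimal_rotation(x, mean, allow_reflections) for x in shapes]
        new_mean = _preshape(np.mean(shapes, axis=0))
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            break

    arr = np.array(shapes)
    if tangent_projection:
        # Orthogonal projection onto the affine tangent plane at the mean:
        # x -> x + (1 - <x, m>) m  with unit-norm preshapes.
        m = mean.reshape(-1)
        flat = arr.reshape(len(shapes), -1)
        dots = flat @ m
        flat = flat + np.outer(1.0 - dots, m)
        arr = flat.reshape(arr.shape)
        mean = arr.mean(axis=0)

    aligned = [
        LandmarkConfiguration(arr[i], species_id=c.species_id, clade=c.clade)
        for i, c in enumerate(sample)
    ]
    return ProcrustesAlignment(aligned=aligned, centroid_sizes=sizes, mean_shape=mean, n_iterations=n_iter)


def procrustes_distance(a: LandmarkConfiguration | np.ndarray, b: LandmarkConfiguration | np.ndarray) -> float:
    """Distance between two superimposed shapes (Euclidean in tangent space)."""
    xa = a.coordinates if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    xb = b.coordinates if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    return float(np.sqrt(((xa - xb) ** 2).sum()))


@dataclass
class MorphospaceModel:
    """PCA of flattened aligned coordinates: mean, axes, eigenvalues, scores."""

    mean_shape: np.ndarray  # flattened, length 3*n_landmarks
    eigenvectors: np.ndarray  # (3*n_landmarks, n_components), orthonormal columns
    eigenvalues: np.ndarray  # non-negative, non-increasing
    scores: np.ndarray  # (n_specimens, n_components)
    n_landmarks: int = 0

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def project(self, flat_shape: np.ndarray) -> np.ndarray:
        """Scores of a flattened shape vector (or matrix of them)."""
        x = np.asarray(flat_shape, dtype=float)
        return (x - self.mean_shape) @ self.eigenvectors


def pca_morphospace(alignment: ProcrustesAlignment) -> MorphospaceModel:
    """Eigendecomposition of the covariance of flattened tangent coordinates.

    Components are ordered by decreasing eigenvalue; each eigenvector is
    flipped so that its largest-magnitude loading is positive, giving a
    platform-independent sign convention.
    """
    data = alignment.flattened()
    n = data.shape[0]
    if n < 3:
        raise ValueError("PCA morphospace needs at least 3 specimens")
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD route: eigenvalues of the covariance are s^2/(n-1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > max(eigenvalues[0], 1.0) * 1e-14 if eigenvalues.size else slice(0)
    eigenvalues = eigenvalues[keep]
    vecs = vt[keep].T
    # deterministic sign convention
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1.0
    scores = centered @ vecs
    return MorphospaceModel(
        mean_shape=mean,
        eigenvectors=vecs,
        eigenvalues=eigenvalues,
        scores=scores,
        n_landmarks=alignment.mean_shape.shape[0],
    )


def reconstruct_shape(scores: Sequence[float], model: MorphospaceModel) -> LandmarkConfiguration:
    """Shape at a morphospace position: mean + sum_k score_k * eigenvector_k.

    Scores for components beyond ``len(scores)`` are taken as zero.
    """
    s = np.asarray(scores, dtype=float).reshape(-1)
    if s.size > model.n_components:
        raise ValueError(f"score vector length {s.size} exceeds {model.n_components} components")
    flat = model.mean_shape + model.eigenvectors[:, : s.size] @ s
    return LandmarkConfiguration(flat.reshape(model.n_landmarks, 3), species_id="reconstruction")


def theoretical_grid(
    model: MorphospaceModel | np.ndarray,
    n_per_axis: int = 8,
    extension: float = 0.10,
) -> np.ndarray:
    """Evenly spaced grid of (PC1, PC2) positions spanning the extended range.

    The empirical range of each of the first two axes is extended by
    ``extension`` in total, split equally between the two ends (the default
    0.10 adds 5% of the range on each side).  Returns an (n_per_axis**2, 2)
    array, PC1 varying fastest.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be >= 2")
    if not (0 <= extension < 1):
        raise ValueError("extension must be in [0, 1)")
    scores = model.scores if isinstance(model, MorphospaceModel) else np.asarray(model, float)
    if scores.shape[1] < 2:
        raise ValueError("need at least two morphospace axes")
    axes = []
    for j in (0, 1):
        lo, hi = scores[:, j].min(), scores[:, j].max()
        rng = hi - lo
        if rng <= 0:
            raise ValueError(f"degenerate (zero) empirical range on axis {j + 1}")
        pad = 0.5 * extension * rng
        axes.append(np.linspace(lo - pad, hi + pad, n_per_axis))
    g2, g1 = np.meshgrid(axes[1], axes[0], indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel()])
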