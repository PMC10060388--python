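"""Generalized Procrustes analysis (GPA) with optional sliding semilandmarks.

Alignment removes the similarity nuisances of landmark data — translation,
scale, and rotation — by centering every configuration, scaling it to unit
centroid size, and iteratively rotating it onto a running consensus (partial
Procrustes superimposition, the tpsRelw scheme).  Reflections are never
permitted: faces have a left/right identity, and a reflected alignment would
destroy asymmetry signal.

Semilandmarks — points on curves whose exact position along the curve is
arbitrary — may additionally slide along the chord between their flanking
landmarks, either minimizing the thin-plate-spline bending energy of the
residual from the consensus (the tpsRelw default) or the Procrustes distance
to the consensus (orthogonal projection of the residual onto the tangent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from facemorph.tps_io import LandmarkConfiguration, LandmarkDataset, SliderTable

logger = logging.getLogger(__name__)

SLIDING_MODES = ("none", "bending_energy", "procrustes_distance")


class DegenerateConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class ProcrustesFit:
    """Result of generalized Procrustes superimposition.

    Attributes
    ----------
    aligned : (n, k, 2) array
        Unit-centroid-size, centered, rotated configurations in shape space.
    consensus : (k, 2) array
        Mean configuration, centered, unit centroid size.
    centroid_sizes : (n,) array
        Original-scale centroid sizes (size information removed from shape).
    objective_trace : list of float
        Sum over specimens of squared distance to the consensus after each
        GPA iteration; monotone non-increasing.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool
    sliding_mode: str = "none"
    specimen_ids: list[str] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances of points from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size <= 1e-300:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is zero")
    return size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F for centered configs.

    Standard orthogonal-Procrustes solution via SVD of the 2x2 cross-covariance,
    with the reflection branch forced off.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape:
        raise ValueError(f"shape mismatch {source.shape} vs {target.shape}")
    m = source.T @ target
    if not np.any(np.abs(m) > 1e-14 * max(1.0, np.abs(source).max() * np.abs(target).max())):
        raise AlignmentError("zero cross-covariance between configurations")
    u, _, vt = scipy.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _center_and_scale(coords: np.ndarray, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Center each configuration and scale to unit centroid size."""
    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    for i, s in enumerate(sizes):
        if s <= 1e-300:
            raise DegenerateConfigurationError(
                f"specimen {ids[i]!r}: all landmarks coincide (zero centroid size)"
            )
    return centered / sizes[:, None, None], sizes


def _canonical_gauge(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting the consensus into a canonical orientation.

    GPA fixes shapes only up to a joint rotation of the whole solution; the
    gauge is pinned by aligning the consensus' principal axes with the
    coordinate axes and resolving the residual 180-degree ambiguity with a
    third-moment sign rule.  This makes the fit invariant to arbitrary
    rotations of the input specimens and to specimen order.
    """
    _, vecs = np.linalg.eigh(consensus.T @ consensus)
    r = vecs  # minor axis on x, major axis on y (faces upright)
    if np.linalg.det(r) < 0:
        r[:, 1] = -r[:, 1]
    rotated = consensus @ r
    s = float(np.sum(rotated[:, 0] ** 3) + np.sum(rotated[:, 1] ** 3))
    if s < 0:
        r = -r  # rotate by pi
    return r


def generalized_procrustes(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Iterative partial-Procrustes superimposition to a unit-size consensus.

    Each configuration is centered, scaled to unit centroid size, and rotated
    to the running consensus; the consensus is the re-normalized mean of the
    aligned shapes.  Iteration stops when the root-sum-square change of the
    consensus drops below ``tol`` or after ``max_iter`` iterations (the latter
    sets ``converged=False`` with a logged warning, not an exception).
    """
    if isinstance(dataset, LandmarkDataset):
        coords = dataset.coords()
        ids = [c.specimen_id for c in dataset.configurations]
    else:
        coords = np.asarray(dataset, float)
        ids = [str(i + 1) for i in range(coords.shape[0])]
    if coords.shape[0] < 2:
        raise ValueError("GPA requires at least 2 configurations")

    aligned, sizes = _center_and_scale(coords, ids)
    consensus = aligned[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        trace.append(float(np.sum((aligned - new_consensus) ** 2)))
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if it > 1 and delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    gauge = _canonical_gauge(consensus)
    consensus = consensus @ gauge
    aligned = aligned @ gauge
    return ProcrustesFit(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        n_iterations=it,
        converged=converged,
        sliding_mode="none",
        specimen_ids=ids,
        objective_trace=trace,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations (unit-size, rotated)."""
    ids = ["a", "b"]
    (ac, bc), _ = _center_and_scale(np.stack([np.asarray(a, float), np.asarray(b, float)]), ids)
    ar = ac @ optimal_rotation(ac, bc)
    return float(np.sqrt(np.sum((ar - bc) ** 2)))


def _tangent_directions(points: np.ndarray, sliders: SliderTable) -> np.ndarray:
    """Unit tangent per semilandmark: chord from its before- to after-neighbour."""
    before, _, after = sliders.triplets.T
    chords = points[after] - points[before]
    norms = np.sqrt(np.sum(chords**2, axis=1))
    norms[norms < 1e-300] = 1.0
    return chords / norms[:, None]


def _slide_one(
    points: np.ndarray,
    consensus: np.ndarray,
    sliders: SliderTable,
    mode: str,
    be_matrix: np.ndarray | None,
    specimen_id: str,
) -> np.ndarray:
    """Return the specimen with its semilandmarks slid along their tangents."""
    sl = sliders.slider_indices
    t = _tangent_directions(points, sliders)
    resid = consensus - points  # displacement wanted at each landmark
    if mode == "bending_energy" and be_matrix is not None:
        v0 = points - consensus
        bss = be_matrix[np.ix_(sl, sl)]
        a = t[:, 0, None] * bss * t[None, :, 0] + t[:, 1, None] * bss * t[None, :, 1]
        bvx = (be_matrix @ v0[:, 0])[sl]
        bvy = (be_matrix @ v0[:, 1])[sl]
        rhs = -(t[:, 0] * bvx + t[:, 1] * bvy)
        try:
            lam = scipy.linalg.solve(a, rhs, assume_a="sym")
            if not np.all(np.isfinite(lam)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
            logger.warning(
                "singular bending-energy system for specimen %r; "
                "falling back to procrustes_distance sliding",
                specimen_id,
            )
            lam = np.sum(resid[sl] * t, axis=1)
    else:
        lam = np.sum(resid[sl] * t, axis=1)  # orthogonal projection onto tangent
    out = points.copy()
    out[sl] += lam[:, None] * t
    return out


def slide_semilandmarks(
    fit: ProcrustesFit,
    sliders: SliderTable,
    mode: str = "bending_energy",
    outer_iter: int = 5,
    tol: float = 1e-8,
) -> ProcrustesFit:
    """Relax semilandmarks along their tangents, alternating with GPA.

    Each outer cycle slides every specimen's semilandmarks against the current
    consensus — minimizing bending energy of the residual (``bending_energy``)
    or projecting the residual onto the tangent (``procrustes_distance``) —
    then re-runs GPA on the slid configurations.  Cycles stop early when the
    consensus change falls below ``tol``.  Non-semilandmark points never move.
    """
    if mode not in ("bending_energy", "procrustes_distance"):
        raise ValueError(f"unknown sliding mode {mode!r}")
    sliders.validate_for_k(fit.k)
    from facemorph.relwarps import bending_energy  # deferred: avoids import cycle

    current = fit
    for _ in range(outer_iter):
        be_matrix = None
        if mode == "bending_energy":
            be_matrix = bending_energy(current.consensus).energy_matrix
        slid = np.stack(
            [
                _slide_one(
                    current.aligned[i],
                    current.consensus,
                    sliders,
                    mode,
                    be_matrix,
                    current.specimen_ids[i] if current.specimen_ids else str(i),
                )
                for i in range(current.n)
            ]
        )
        new_fit = generalized_procrustes(slid, tol=tol)
        delta = float(np.sqrt(np.sum((new_fit.consensus - current.consensus) ** 2)))
        new_fit.centroid_sizes = fit.centroid_sizes
        new_fit.specimen_ids = fit.specimen_ids
        new_fit.sliding_mode = mode
        current = new_fit
        if delta < tol:
            break
    return current


def tangent_project(fit: ProcrustesFit) -> np.ndarray:
    """Project aligned shapes orthogonally into the tangent space at the consensus.

    Returns an (n, 2k) matrix of consensus-centered rows, flattened in
    (x1, y1, x2, y2, ...) order.  The projection removes each row's component
    along the consensus direction (the scale gauge), linearizing shape space
    so Euclidean multivariate methods apply; it is idempotent, and the
    consensus itself maps to the zero row.
    """
    c = fit.consensus.reshape(-1)
    c = c / np.sqrt(np.sum(c**2))
    rows = fit.aligned.reshape(fit.n, -1)
    return rows - np.outer(rows @ c, c)
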