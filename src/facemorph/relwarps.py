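"""Thin-plate-spline machinery and relative warps (shape PCA).

The thin-plate spline (TPS) is the standard interpolating deformation of 2-D
geometric morphometrics: with kernel ``U(r) = r^2 log r^2`` and an affine
term, it minimizes the integrated squared second derivatives ("bending
energy") among all interpolants.  Its quadratic form on landmark
displacements — the bending-energy matrix — is the upper-left k x k block of
the inverted bordered TPS system and annihilates affine displacement fields.

Relative warps are the principal components of Procrustes shape coordinates,
optionally re-weighted in the principal-warp basis by the bending-energy
eigenvalues raised to ``-alpha/2`` (the tpsRelw convention: ``alpha = 1``
emphasizes large-scale variation).  With ``alpha = 0`` — the default here —
relative warps are an ordinary PCA of the tangent-space coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.interpolate import RBFInterpolator

from facemorph.procrustes import ProcrustesFit
from facemorph.tps_io import LandmarkConfiguration

RANK_CUTOFF = 1e-12  # eigenvalues below cutoff x largest are reported trivial


class SingularSystemError(ValueError):
    pass


@dataclass
class BendingEnergyModel:
    """Bending-energy quadratic form of a reference configuration.

    ``energy_matrix`` is symmetric positive-semidefinite (k x k) and acts on
    per-axis landmark displacements: for a displacement field ``v`` (k x 2),
    the bending energy is ``v_x' B v_x + v_y' B v_y``.
    """

    reference: np.ndarray
    energy_matrix: np.ndarray

    def energy(self, displacement: np.ndarray) -> float:
        v = np.asarray(displacement, float)
        b = self.energy_matrix
        return float(v[:, 0] @ b @ v[:, 0] + v[:, 1] @ b @ v[:, 1])


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 evaluated from squared distances, with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _tps_system(reference: np.ndarray) -> np.ndarray:
    """Bordered TPS matrix L = [[K, Q], [Q', 0]] with Q = [1, x, y]."""
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=2)
    kmat = _tps_kernel(d2)
    q = np.column_stack([np.ones(k), ref])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kmat
    l[:k, k:] = q
    l[k:, :k] = q.T
    return l


def bending_energy(reference: LandmarkConfiguration | np.ndarray) -> BendingEnergyModel:
    """Build the bending-energy matrix for a reference configuration.

    Raises :class:`SingularSystemError` for collinear references, whose TPS
    system has no unique solution.
    """
    ref = reference.points if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    k = ref.shape[0]
    if k < 3:
        raise SingularSystemError("bending energy requires at least 3 landmarks")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max())) < 2:
        raise SingularSystemError("collinear reference configuration")
    l = _tps_system(ref)
    try:
        linv = scipy.linalg.inv(l)
    except scipy.linalg.LinAlgError as e:  # pragma: no cover - rank check above
        raise SingularSystemError(f"singular TPS system: {e}") from None
    be = linv[:k, :k]
    be = (be + be.T) / 2.0
    return BendingEnergyModel(reference=ref, energy_matrix=be)


@dataclass
class RelativeWarpModel:
    """Shape PCA of tangent-space coordinates.

    Attributes
    ----------
    eigenvectors : (m, 2k) array
        Orthonormal PC axes, one per row, in (x1, y1, x2, y2, ...) order.
    eigenvalues : (m,) array
        Score variances (sample variance, non-increasing).
    scores : (n, m) array
        Per-specimen PC scores; each column has mean zero.
    variance_fraction : (m,) array
        Eigenvalues normalized to sum to one over the non-trivial PCs.
    """

    consensus: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    alpha: float = 0.0
    mean_row: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]


def _orient_signs(
    eigenvectors: np.ndarray, scores: np.ndarray, age_labels: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Fix each PC's sign: infant-minus-adult mean score non-negative when age
    labels are available, else largest-magnitude loading positive."""
    for j in range(eigenvectors.shape[0]):
        flip = False
        if age_labels is not None:
            inf = scores[age_labels == "infant", j]
            adu = scores[age_labels == "adult", j]
            if inf.size and adu.size:
                diff = inf.mean() - adu.mean()
                if diff < 0:
                    flip = True
                elif diff == 0:
                    flip = eigenvectors[j, np.argmax(np.abs(eigenvectors[j]))] < 0
            else:
                flip = eigenvectors[j, np.argmax(np.abs(eigenvectors[j]))] < 0
        else:
            flip = eigenvectors[j, np.argmax(np.abs(eigenvectors[j]))] < 0
        if flip:
            eigenvectors[j] = -eigenvectors[j]
            scores[:, j] = -scores[:, j]
    return eigenvectors, scores


def relative_warps(
    rows: np.ndarray,
    alpha: float = 0.0,
    be: BendingEnergyModel | None = None,
    consensus: np.ndarray | None = None,
    age_labels: np.ndarray | None = None,
) -> RelativeWarpModel:
    """Relative-warp decomposition of tangent coordinates.

    Parameters
    ----------
    rows : (n, 2k) array
        Tangent-projected shape coordinates (``tangent_project`` output).
    alpha : float
        Bending-energy weighting exponent.  0 (default) gives ordinary PCA;
        nonzero values weight the principal-warp basis by the bending-energy
        eigenvalues to the power ``-alpha/2`` (affine subspace unweighted)
        before the decomposition, and require ``be``.
    consensus : (k, 2) array, optional
        Stored for shape reconstruction (``shape_at_score``).
    age_labels : array of "adult"/"infant", optional
        Fixes PC signs so infant mean scores are >= adult mean scores.

    PCs with eigenvalue below ``1e-12`` times the largest are trivial
    (numerical zero) and dropped.
    """
    rows = np.asarray(rows, float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("relative_warps requires at least 2 coordinate rows")
    n, two_k = rows.shape
    if alpha != 0.0 and be is None:
        raise ValueError("alpha != 0 requires a BendingEnergyModel")

    work = rows
    if alpha != 0.0:
        evals, evecs = np.linalg.eigh(be.energy_matrix)
        nonzero = evals > max(evals.max(), 1.0) * 1e-10
        weights = np.ones_like(evals)
        weights[nonzero] = evals[nonzero] ** (-alpha / 2.0)
        # weight operator acting identically on x and y coordinate blocks
        w_axis = evecs @ np.diag(weights) @ evecs.T
        xk = rows[:, 0::2] @ w_axis.T
        yk = rows[:, 1::2] @ w_axis.T
        work = np.empty_like(rows)
        work[:, 0::2] = xk
        work[:, 1::2] = yk

    mean_row = work.mean(axis=0)
    centered = work - mean_row
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    cutoff = RANK_CUTOFF * (eigenvalues[0] if eigenvalues.size else 0.0)
    m = int(np.sum(eigenvalues > cutoff))
    eigenvectors = vt[:m].copy()
    scores = (u[:, :m] * s[:m]).copy()
    eigenvalues = eigenvalues[:m]
    eigenvectors, scores = _orient_signs(eigenvectors, scores, age_labels)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else eigenvalues
    if consensus is None:
        consensus = np.zeros((two_k // 2, 2))
    return RelativeWarpModel(
        consensus=np.asarray(consensus, float),
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fraction=fractions,
        alpha=alpha,
        mean_row=mean_row,
    )


def variance_table(model: RelativeWarpModel):
    """Per-PC eigenvalue/variance-fraction table (pc column is 1-based)."""
    import pandas as pd

    cum = np.cumsum(model.variance_fraction)
    return pd.DataFrame(
        {
            "pc": np.arange(1, model.n_components + 1),
            "eigenvalue": model.eigenvalues,
            "fraction": model.variance_fraction,
            "cumulative_fraction": cum,
        }
    )


def shape_at_score(model: RelativeWarpModel, pc: int, score: float) -> LandmarkConfiguration:
    """Landmark configuration at ``score`` along PC ``pc`` (0-based index).

    Returns ``consensus + score * eigenvector``, unflattened to (k, 2).  Use
    ``score = +/- 1.5 * sqrt(eigenvalue)`` for figure-style shape extremes.
    """
    if not 0 <= pc < model.n_components:
        raise IndexError(f"pc {pc} out of range (0..{model.n_components - 1})")
    flat = model.consensus.reshape(-1) + score * model.eigenvectors[pc]
    return LandmarkConfiguration(
        specimen_id=f"pc{pc + 1}_score{score:+g}", points=flat.reshape(-1, 2)
    )


def mean_shape(
    fit: ProcrustesFit,
    subset: np.ndarray | None = None,
    name: str = "mean",
) -> LandmarkConfiguration:
    """Mean of aligned configurations over a subset, unit centroid size.

    ``subset`` is a boolean mask or index array over specimens (default all).
    """
    if subset is None:
        idx = np.arange(fit.n)
    else:
        subset = np.asarray(subset)
        idx = np.flatnonzero(subset) if subset.dtype == bool else subset
    if idx.size == 0:
        raise ValueError(f"empty specimen subset for mean shape {name!r}")
    m = fit.aligned[idx].mean(axis=0)
    m -= m.mean(axis=0)
    m /= np.sqrt(np.sum(m**2))
    return LandmarkConfiguration(specimen_id=name, points=m)


def tps_warp(reference: np.ndarray, target: np.ndarray):
    """Exact thin-plate-spline map sending reference landmarks onto target's.

    Returns a callable mapping (m, 2) query points to their warped positions.
    """
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.shape != target.shape:
        raise ValueError("reference/target landmark counts differ")
    try:
        interp_x = RBFInterpolator(reference, target[:, 0], kernel="thin_plate_spline")
        interp_y = RBFInterpolator(reference, target[:, 1], kernel="thin_plate_spline")
    except np.linalg.LinAlgError as e:
        raise SingularSystemError(f"singular TPS interpolation system: {e}") from None

    def warp(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return np.column_stack([interp_x(pts), interp_y(pts)])

    return warp


def deformation_grid(
    reference: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
    density: int = 20,
    margin: float = 0.05,
) -> np.ndarray:
    """TPS deformation grid from reference to target.

    Evaluates the interpolating thin-plate spline on a ``density x density``
    grid spanning the reference bounding box (expanded by ``margin``), the
    classic D'Arcy-Thompson transformation-grid rendering of a shape change.
    Returns a (density, density, 2) array of warped grid points; the map is
    exact at the landmarks.
    """
    ref = reference.points if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    tgt = target.points if isinstance(target, LandmarkConfiguration) else np.asarray(target, float)
    warp = tps_warp(ref, tgt)
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    pad = margin * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], density)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], density)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return warp(pts).reshape(density, density, 2)
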