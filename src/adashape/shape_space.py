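"""Kendall shape-space geometry for 3D landmark configurations.

A specimen is a k x 3 configuration matrix of landmark coordinates in mm.
Translation is removed by the (k-1) x k Helmert sub-matrix H, scale by
dividing by the centroid size ||HX|| (Frobenius), giving the *pre-shape*
Y = HX / ||HX||, a point on the unit sphere in R^{3(k-1)}.  Rotation is
quotiented out by aligning pre-shapes with the optimal SO(3) rotation from
the SVD of S^T Y.  The full Procrustes distance, the iteratively estimated
full Procrustes (Frechet) mean, Kent partial tangent coordinates at the
mean, the exponential map back to the sphere, and the reconstruction of a
configuration from a pre-shape complete the toolkit on which the shape
archetypoid pipeline is built.

Reflections are excluded throughout (SO(3), not O(3)): a left foot is not
the same shape as a right foot.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    DegenerateConfigurationError,
    InvalidDimensionError,
    InvalidInputError,
    OutOfDomainError,
)

__all__ = [
    "ConfigurationMatrix",
    "PreShape",
    "ProcrustesMean",
    "TangentVector",
    "helmert_submatrix",
    "to_preshape",
    "optimal_rotation",
    "full_procrustes_distance",
    "procrustes_mean",
    "tangent_coordinates",
    "exp_map",
    "reconstruct_configuration",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConfigurationMatrix:
    """A specimen's raw landmarks: k x 3 coordinates (mm), similarity-variant.

    Parameters
    ----------
    coords
        ``(k, 3)`` array of landmark coordinates; ``k >= 3``, all finite.
    specimen_id
        Free-text label (file stem, database id, ...).
    """

    coords: np.ndarray
    specimen_id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidDimensionError(
                f"configuration must be k x 3, got shape {coords.shape}"
            )
        if coords.shape[0] < 3:
            raise InvalidDimensionError(
                f"need at least 3 landmarks, got {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise InvalidInputError("configuration contains non-finite entries")
        self.coords = coords

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclasses.dataclass
class PreShape:
    """Helmert-centered, unit-norm shape representative: (k-1) x 3, ||.||_F = 1.

    ``centroid_size`` is the Frobenius norm of the centered configuration,
    i.e. the physical scale (mm) that was divided out.
    """

    matrix: np.ndarray
    centroid_size: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 3:
            raise InvalidDimensionError(f"pre-shape must be (k-1) x 3, got {m.shape}")
        nrm = float(np.linalg.norm(m))
        if abs(nrm - 1.0) > 1e-10:
            raise InvalidInputError(f"pre-shape norm {nrm!r} is not 1 within 1e-10")
        if not self.centroid_size > 0:
            raise InvalidInputError("centroid_size must be positive")
        self.matrix = m

    @property
    def k(self) -> int:
        return self.matrix.shape[0] + 1


@dataclasses.dataclass
class ProcrustesMean:
    """Result of generalized Procrustes averaging.

    ``pole`` is the mean's pre-shape (its ``centroid_size`` carries the mean
    centroid size of the ensemble, useful to rescale reconstructions to mm);
    ``objective_trace`` records sum of squared full Procrustes distances to
    the pole at each iteration and is non-increasing.
    """

    pole: PreShape
    n_iterations: int
    converged: bool
    objective_trace: list[float]


@dataclasses.dataclass
class TangentVector:
    """Kent partial tangent coordinates of a pre-shape at a mean pole.

    ``v`` has length 3(k-1), is orthogonal to vec(pole) and has norm
    sin(rho) <= 1 where rho is the Procrustes angle to the pole.
    """

    v: np.ndarray
    pole: ProcrustesMean

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.v))


# ---------------------------------------------------------------------------
# Helmert transform
# ---------------------------------------------------------------------------


def helmert_submatrix(k: int) -> np.ndarray:
    """The (k-1) x k Helmert sub-matrix.

    Row j (1-based) has its first j entries equal to -1/sqrt(j(j+1)), entry
    j+1 equal to j/sqrt(j(j+1)) and zeros after.  Rows are orthonormal and
    each sums to zero, so left-multiplication removes location.
    """
    if k < 2:
        raise InvalidDimensionError(f"Helmert sub-matrix needs k >= 2, got {k}")
    H = np.zeros((k - 1, k))
    for j in range(1, k):
        d = np.sqrt(j * (j + 1.0))
        H[j - 1, :j] = -1.0 / d
        H[j - 1, j] = j / d
    return H


def _helmert_apply(X: np.ndarray) -> np.ndarray:
    """Compute H @ X in O(k) per column without materializing H."""
    k = X.shape[0]
    j = np.arange(1, k, dtype=float)[:, None]
    csum = np.cumsum(X, axis=0)[:-1]
    return (j * X[1:] - csum) / np.sqrt(j * (j + 1.0))


def _helmert_transpose_apply(Y: np.ndarray) -> np.ndarray:
    """Compute H.T @ Y in O(k) per column (the centered configuration)."""
    km1 = Y.shape[0]
    j = np.arange(1, km1 + 1, dtype=float)[:, None]
    w = Y / np.sqrt(j * (j + 1.0))
    suffix = np.cumsum(w[::-1], axis=0)[::-1]
    X = np.empty((km1 + 1, Y.shape[1]))
    X[0] = -suffix[0]
    X[1:] = (j * w)
    X[1:-1] -= suffix[1:]
    return X


# ---------------------------------------------------------------------------
# Pre-shape and rotation alignment
# ---------------------------------------------------------------------------


def _as_coords(X) -> np.ndarray:
    if isinstance(X, ConfigurationMatrix):
        return X.coords
    return ConfigurationMatrix(np.asarray(X, dtype=float)).coords


def to_preshape(X) -> PreShape:
    """Remove location and scale: Y = HX / ||HX||, centroid size ||HX||."""
    if isinstance(X, PreShape):
        return X
    coords = _as_coords(X)
    XH = _helmert_apply(coords)
    size = float(np.linalg.norm(XH))
    scale = float(np.max(np.abs(coords))) + 1.0
    if size <= 1e-12 * scale:
        raise DegenerateConfigurationError(
            "all landmarks coincide: centroid size is zero"
        )
    return PreShape(XH / size, size)


def _opt_rot(S: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """SO(3) rotation G maximizing trace(S.T @ Y @ G)."""
    A = S.T @ Y
    U, _, Vt = np.linalg.svd(A)
    D = np.ones(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[-1] = -1.0  # flip the singular vector of the smallest singular value
    return (Vt.T * D) @ U.T


def optimal_rotation(S: PreShape, Y: PreShape) -> np.ndarray:
    """Optimal rotation aligning pre-shape ``Y`` onto pole ``S``.

    Returned ``G`` in SO(3) maximizes trace(S.T Y G); from the SVD of
    S.T Y with a sign flip on the smallest singular vector when the raw
    product would be a reflection.
    """
    Sm, Ym = to_preshape(S).matrix, to_preshape(Y).matrix
    if Sm.shape != Ym.shape:
        raise InvalidDimensionError("pre-shapes have different landmark counts")
    return _opt_rot(Sm, Ym)


def _cos_rho(Y1: np.ndarray, Y2: np.ndarray) -> float:
    """cos of the Procrustes angle: sum of singular values of Y1.T Y2 with
    the smallest negated when det(Y1.T Y2) < 0 (reflection exclusion)."""
    A = Y1.T @ Y2
    sv = np.linalg.svd(A, compute_uv=False)
    s = float(sv.sum())
    if np.linalg.det(A) < 0:
        s = float(sv[0] + sv[1] - sv[2])
    return s


def full_procrustes_distance(X1, X2) -> float:
    """Full Procrustes distance d_F in [0, 1] between two configurations.

    d_F = sqrt(1 - (sum lambda_i)^2) where lambda_i are the square roots of
    the eigenvalues of Y1.T Y2 Y2.T Y1 (computed as singular values of
    Y1.T Y2), the smallest taken negative iff det(Y1.T Y2) < 0.  Invariant
    to translation, rotation and positive scaling of either argument.
    """
    Y1, Y2 = to_preshape(X1).matrix, to_preshape(X2).matrix
    if Y1.shape != Y2.shape:
        raise InvalidDimensionError("configurations have different landmark counts")
    # Evaluate the minimized residual ||Y2 - cos(rho) Y1 G|| directly rather
    # than sqrt(1 - cos^2): algebraically identical, but well-conditioned
    # when the shapes (nearly) coincide.
    G = _opt_rot(Y2, Y1)
    aligned = Y1 @ G
    c = float(np.sum(Y2 * aligned))
    return float(min(1.0, np.linalg.norm(Y2 - c * aligned)))


# ---------------------------------------------------------------------------
# Full Procrustes mean (generalized Procrustes algorithm)
# ---------------------------------------------------------------------------


def procrustes_mean(
    ensemble: Sequence,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> ProcrustesMean:
    """Full Procrustes (Frechet) mean shape by iterative alignment.

    Starting from the first specimen's pre-shape, every pre-shape is rotated
    to the current pole, the rotated pre-shapes are averaged, the average is
    renormalized to the unit sphere and becomes the new pole; iteration
    stops when the pole moves less than ``tol`` in Frobenius norm.  The pole
    locally minimizes sum of squared full Procrustes distances.
    """
    if len(ensemble) == 0:
        raise InvalidInputError("cannot average an empty ensemble")
    pres = [to_preshape(X) for X in ensemble]
    k = pres[0].k
    if any(p.k != k for p in pres):
        raise InvalidDimensionError("ensemble has inconsistent landmark counts")
    mats = np.stack([p.matrix for p in pres])
    mean_size = float(np.mean([p.centroid_size for p in pres]))

    pole = mats[0].copy()
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rotated = np.empty_like(mats)
        obj = 0.0
        for i, Y in enumerate(mats):
            G = _opt_rot(pole, Y)
            rotated[i] = Y @ G
            c = float(np.trace(pole.T @ rotated[i]))
            obj += max(0.0, 1.0 - c * c)
        trace.append(obj)
        avg = rotated.mean(axis=0)
        nrm = float(np.linalg.norm(avg))
        if nrm <= 1e-15:
            raise DegenerateConfigurationError("mean of rotated pre-shapes is zero")
        new_pole = avg / nrm
        delta = float(np.linalg.norm(new_pole - pole))
        pole = new_pole
        if delta < tol:
            converged = True
            break
    # objective at the final pole
    trace.append(sum(max(0.0, 1.0 - _cos_rho(Y, pole) ** 2) for Y in mats))
    if not converged:
        warnings.warn(
            f"Procrustes mean did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return ProcrustesMean(
        pole=PreShape(pole / np.linalg.norm(pole), mean_size),
        n_iterations=n_iter,
        converged=converged,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Tangent space at the mean
# ---------------------------------------------------------------------------


def _vec(M: np.ndarray) -> np.ndarray:
    """Column-stacking vec operator."""
    return M.ravel(order="F")


def _unvec(v: np.ndarray, km1: int) -> np.ndarray:
    return v.reshape((km1, 3), order="F")


def tangent_coordinates(Y, mean: ProcrustesMean) -> TangentVector:
    """Kent partial tangent coordinates of ``Y`` at the mean pole.

    v = (I - vec(S)vec(S)^T) vec(Y G) with G the optimal rotation of Y onto
    the pole S; orthogonal to vec(S) with norm sin(rho) where
    cos(rho) = trace(S^T Y G).
    """
    S = mean.pole.matrix
    Ym = to_preshape(Y).matrix
    if Ym.shape != S.shape:
        raise InvalidDimensionError("pre-shape landmark count differs from the pole")
    G = _opt_rot(S, Ym)
    y = _vec(Ym @ G)
    s = _vec(S)
    v = y - s * float(s @ y)
    return TangentVector(v=v, pole=mean)


def exp_map(v, mean: ProcrustesMean) -> PreShape:
    """Exponential map: tangent vector -> pre-shape on the unit sphere.

    Y_v = unvec(sqrt(1 - v.T v) vec(S) + v).  Requires ||v|| <= 1.
    """
    vv = v.v if isinstance(v, TangentVector) else np.asarray(v, dtype=float)
    S = mean.pole.matrix
    if vv.shape != (S.size,):
        raise InvalidDimensionError(
            f"tangent vector length {vv.shape} does not match pole size {S.size}"
        )
    n2 = float(vv @ vv)
    if n2 > 1.0 + 1e-10:
        raise OutOfDomainError(f"tangent vector norm {np.sqrt(n2)} exceeds 1")
    y = np.sqrt(max(0.0, 1.0 - n2)) * _vec(S) + vv
    Y = _unvec(y, S.shape[0])
    nrm = float(np.linalg.norm(Y))
    return PreShape(Y / nrm, mean.pole.centroid_size)


def reconstruct_configuration(
    Y: PreShape,
    centroid_size: float | None = None,
    specimen_id: str = "",
) -> ConfigurationMatrix:
    """Configuration matrix X = H.T Y: centered, unit centroid size.

    Pass ``centroid_size`` (mm) to rescale to physical units.
    """
    Ym = to_preshape(Y).matrix
    X = _helmert_transpose_apply(Ym)
    if centroid_size is not None:
        if not centroid_size > 0:
            raise InvalidInputError("centroid_size must be positive")
        X = X * centroid_size
    return ConfigurationMatrix(X, specimen_id)
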