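"""Archetypoid analysis of landmark shapes: the end-to-end pipeline.

Landmark ensembles are reduced to pre-shapes, a full Procrustes mean is
estimated, every specimen is mapped to Kent partial tangent coordinates at
the mean, and multivariate archetypoid analysis runs on the n x 3(k-1)
tangent matrix.  Because archetypoids are actual specimens, mapping them
back to configuration space is a lookup, not an inverse problem.

Tangent coordinates are used at full dimension, unreduced and
unstandardized: the coordinates are commensurate and archetypes are not in
general recoverable from principal-component subspaces.  Strata (e.g. the
two sexes) are analyzed by running the pipeline separately per stratum,
each with its own Procrustes mean.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .archetypes import ADAModel, DataMatrix, archetypoid_analysis
from .exceptions import InvalidInputError, InvalidSubsampleError
from .shape_space import (
    ConfigurationMatrix,
    ProcrustesMean,
    full_procrustes_distance,
    procrustes_mean,
    tangent_coordinates,
    to_preshape,
)

__all__ = ["ShapeADAResult", "StabilityReport", "subsample_landmarks", "fit_shape_ada", "stability_check"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ShapeADAResult:
    """Archetypal shapes of a landmark ensemble.

    ``archetypoid_shapes`` are the untouched input specimens selected by the
    optimizer; ``tangent`` holds the n x 3(k-1) Kent coordinates the
    multivariate engine actually saw; ``max_tangent_norm`` is the
    concentration diagnostic (sin of the largest Procrustes angle to the
    mean — the tangent approximation assumes it is small).
    """

    model: ADAModel
    mean: ProcrustesMean
    tangent: DataMatrix
    archetypoid_shapes: list[ConfigurationMatrix]
    max_tangent_norm: float
    kept_indices: np.ndarray | None = None  # set when outlier filtering ran

    @property
    def archetypoid_indices(self) -> np.ndarray:
        """Indices into the *original* ensemble (0-based)."""
        if self.kept_indices is None:
            return self.model.archetypoid_indices
        return self.kept_indices[self.model.archetypoid_indices]


@dataclasses.dataclass
class StabilityReport:
    """Agreement between full-landmark and subsampled-landmark fits."""

    indices_full: np.ndarray
    indices_subsampled: np.ndarray
    index_sets_match: bool
    max_alpha_difference: float


def subsample_landmarks(ensemble: Sequence[ConfigurationMatrix], every_m: int) -> list[ConfigurationMatrix]:
    """Systematic landmark subsample: keep landmarks 1, 1+m, 1+2m, ...

    Applied identically across specimens so correspondence is preserved.
    """
    if every_m < 1:
        raise InvalidInputError(f"every_m must be >= 1, got {every_m}")
    if not ensemble:
        raise InvalidInputError("empty ensemble")
    k = ensemble[0].coords.shape[0]
    kept = np.arange(0, k, every_m)
    if kept.size < 3:
        raise InvalidSubsampleError(
            f"subsampling every {every_m} of {k} landmarks leaves {kept.size} < 3"
        )
    return [
        ConfigurationMatrix(X.coords[kept], X.specimen_id) for X in ensemble
    ]


def fit_shape_ada(
    ensemble: Sequence[ConfigurationMatrix],
    p: int,
    n_restarts: int = 10,
    *,
    seed: int | None,
    outlier_quantile: float | None = None,
) -> ShapeADAResult:
    """Fit p archetypal shapes to a landmark ensemble.

    Parameters
    ----------
    ensemble
        Landmark configurations with a common landmark count.
    p
        Number of archetypoids.
    n_restarts
        Random restarts of the archetypoid search (on top of the
        AA-derived candidates).
    seed
        Seed for every stochastic step; required.
    outlier_quantile
        Off by default.  If set (e.g. 0.99), specimens whose full
        Procrustes distance to a provisional mean exceeds that sample
        quantile are dropped before the final fit; returned indices still
        refer to the original ensemble.
    """
    n = len(ensemble)
    if not 1 <= p <= n:
        raise InvalidInputError(f"need 1 <= p <= n, got p={p}, n={n}")
    pres = [to_preshape(X) for X in ensemble]

    kept = None
    if outlier_quantile is not None:
        if not 0.0 < outlier_quantile <= 1.0:
            raise InvalidInputError("outlier_quantile must be in (0, 1]")
        mean0 = procrustes_mean(pres)
        d = np.array([full_procrustes_distance(mean0.pole, Y) for Y in pres])
        kept = np.flatnonzero(d <= np.quantile(d, outlier_quantile))
        pres = [pres[i] for i in kept]
        if len(pres) < p:
            raise InvalidInputError("outlier filtering left fewer specimens than p")

    mean = procrustes_mean(pres)
    V = np.stack([tangent_coordinates(Y, mean).v for Y in pres])
    ids = [ensemble[i].specimen_id for i in (kept if kept is not None else range(len(ensemble)))]
    tangent = DataMatrix(V, list(ids))
    max_norm = float(np.max(np.linalg.norm(V, axis=1)))

    model = archetypoid_analysis(V, p, n_restarts, seed=seed)
    orig_idx = (kept[model.archetypoid_indices] if kept is not None else model.archetypoid_indices)
    shapes = [ensemble[int(i)] for i in orig_idx]
    logger.info(
        "shape ADA: n=%d k=%d p=%d restarts=%d gpa_iter=%d max|v|=%.4g rss=%.6g",
        len(pres), ensemble[0].coords.shape[0], p, model.restarts_used,
        mean.n_iterations, max_norm, model.rss,
    )
    return ShapeADAResult(
        model=model,
        mean=mean,
        tangent=tangent,
        archetypoid_shapes=shapes,
        max_tangent_norm=max_norm,
        kept_indices=kept,
    )


def stability_check(
    ensemble: Sequence[ConfigurationMatrix],
    p: int,
    every_m: int,
    n_restarts: int = 10,
    *,
    seed: int | None,
) -> StabilityReport:
    """Compare archetypoids from full and systematically subsampled landmarks.

    Runs the pipeline twice with the same seed and reports whether the two
    archetypoid index sets coincide and the maximum absolute difference of
    the alpha matrices after optimally matching their columns.
    """
    full = fit_shape_ada(ensemble, p, n_restarts, seed=seed)
    sub = fit_shape_ada(subsample_landmarks(ensemble, every_m), p, n_restarts, seed=seed)
    a, b = full.model.alphas, sub.model.alphas
    cost = np.array(
        [[float(np.mean(np.abs(a[:, i] - b[:, j]))) for j in range(p)] for i in range(p)]
    )
    ri, ci = linear_sum_assignment(cost)
    max_diff = float(np.max(np.abs(a[:, ri] - b[:, ci])))
    return StabilityReport(
        indices_full=full.archetypoid_indices,
        indices_subsampled=sub.archetypoid_indices,
        index_sets_match=set(full.archetypoid_indices.tolist())
        == set(sub.archetypoid_indices.tolist()),
        max_alpha_difference=max_diff,
    )
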