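"""Synthetic landmark ensembles with planted archetypal structure.

The generator builds K template shapes by deforming a common foot-box
landmark cloud (240 x 90 x 60 mm) along distinct smooth modes —
elongation, widening, arch-height change and, for larger K, further
low-order fields — then simulates n specimens as convex mixtures of the
templates.  Mixing happens in the tangent space at the templates'
Procrustes mean, matching the model class that tangent-space archetypoid
analysis assumes, so parameter recovery tests the estimator rather than
model misspecification; a raw-coordinate mixing mode is available to probe
robustness to that assumption.  The first K specimens are the pure
templates themselves, so the planted archetypoids exist as actual cases.
Each specimen finally receives a random similarity transform (uniform
SO(3) rotation, log-uniform scale, uniform translation) and iid Gaussian
landmark noise in mm.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy.stats import special_ortho_group

from .exceptions import InvalidComparisonError, InvalidInputError
from .shape_space import (
    ConfigurationMatrix,
    exp_map,
    full_procrustes_distance,
    procrustes_mean,
    reconstruct_configuration,
    tangent_coordinates,
    to_preshape,
)

__all__ = [
    "TransformRanges",
    "SyntheticShapeSet",
    "RecoveryScore",
    "make_archetypal_shapes",
    "simulate_ensemble",
    "recovery_score",
]

_BOX = np.array([240.0, 90.0, 60.0])  # foot-box proportions, mm


@dataclasses.dataclass(frozen=True)
class TransformRanges:
    """Similarity-transform nuisance ranges applied per specimen."""

    scale: tuple[float, float] = (0.8, 1.25)
    translation: float = 100.0  # mm, uniform in [-t, t] per axis


@dataclasses.dataclass
class SyntheticShapeSet:
    """A generated ensemble together with its ground truth."""

    ensemble: list[ConfigurationMatrix]
    true_alphas: np.ndarray  # n x K, rows on the simplex
    pure_case_indices: np.ndarray  # K indices of the planted pure cases
    generator_params: dict


@dataclasses.dataclass
class RecoveryScore:
    """How well a fitted model recovered the planted structure."""

    index_match: bool
    alpha_rmse: float
    alpha_correlation: float


def _deformation(base: np.ndarray, mode: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth displacement field for deformation mode ``mode`` (unit amplitude)."""
    u = base / _BOX  # normalized coords in [0, 1]^3
    d = np.zeros_like(base)
    if mode == 0:  # elongation
        d[:, 0] = (u[:, 0] - 0.5) * _BOX[0]
    elif mode == 1:  # widening
        d[:, 1] = (u[:, 1] - 0.5) * _BOX[1]
    elif mode == 2:  # arch-height change
        d[:, 2] = np.sin(np.pi * u[:, 0]) * _BOX[2] * 0.8
    elif mode == 3:  # taper: width varying along the length
        d[:, 1] = (u[:, 0] - 0.5) * (u[:, 1] - 0.5) * 2.0 * _BOX[1]
    elif mode == 4:  # toe lift
        d[:, 2] = u[:, 0] ** 2 * _BOX[2] * 0.8
    else:  # seeded random smooth quadratic field
        coeffs = rng.normal(size=(3, 9)) / 3.0
        feats = np.column_stack(
            [u, u**2, u[:, [0]] * u[:, [1]], u[:, [1]] * u[:, [2]], u[:, [0]] * u[:, [2]]]
        )
        d = feats @ coeffs.T * _BOX
    return d


def make_archetypal_shapes(
    K: int,
    k: int,
    *,
    seed: int | None,
    amplitude: float = 4.0,
) -> list[ConfigurationMatrix]:
    """K mutually distinct template shapes on a common k-landmark cloud.

    Templates share the same base landmarks (so correspondence is exact)
    and differ by one deformation mode each, scaled until every template
    pair is at full Procrustes distance > 0.05.
    """
    if K < 2:
        raise InvalidInputError(f"need K >= 2 templates, got {K}")
    if k < 3:
        raise InvalidInputError(f"need k >= 3 landmarks, got {k}")
    rng = np.random.default_rng(seed)
    base = rng.uniform(np.zeros(3), _BOX, size=(k, 3))
    fields = [_deformation(base, m, rng) for m in range(K)]
    amp = amplitude
    for _ in range(20):
        templates = [
            ConfigurationMatrix(base + amp * f, f"template-{j}")
            for j, f in enumerate(fields)
        ]
        dmin = min(
            full_procrustes_distance(a, b)
            for a, b in itertools.combinations(templates, 2)
        )
        if dmin > 0.05:
            return templates
        amp *= 1.4
    raise InvalidInputError("could not separate templates; increase k or amplitude")


def simulate_ensemble(
    templates: Sequence[ConfigurationMatrix],
    n: int = 100,
    concentration: float = 1.0,
    noise_sd: float = 0.5,
    transform_ranges: TransformRanges | None = TransformRanges(),
    *,
    seed: int | None,
    mixing: str = "tangent",
) -> SyntheticShapeSet:
    """Simulate n specimens as convex mixtures of the template shapes.

    The first K specimens are the pure templates; the rest draw mixture
    weights from Dirichlet(``concentration``).  ``mixing='tangent'``
    (default) mixes Kent tangent coordinates at the templates' Procrustes
    mean and maps back through the exponential map; ``mixing='raw'`` mixes
    raw template coordinates directly.  ``transform_ranges=None`` applies
    identity transforms (useful for exact-recovery tests); ``noise_sd`` is
    the per-coordinate Gaussian landmark noise in mm.
    """
    K = len(templates)
    if n < K:
        raise InvalidInputError(f"need n >= K, got n={n}, K={K}")
    if mixing not in ("tangent", "raw"):
        raise InvalidInputError(f"unknown mixing mode {mixing!r}")
    rng = np.random.default_rng(seed)

    mean = procrustes_mean(templates)
    T = np.stack([tangent_coordinates(to_preshape(t), mean).v for t in templates])
    size = mean.pole.centroid_size
    centered_raw = np.stack(
        [t.coords - t.coords.mean(axis=0) for t in templates]
    )

    alphas = np.vstack(
        [np.eye(K), rng.dirichlet(concentration * np.ones(K), size=n - K)]
    )

    ensemble = []
    for i in range(n):
        if mixing == "tangent":
            v = alphas[i] @ T
            X = reconstruct_configuration(exp_map(v, mean), centroid_size=size).coords
        else:
            X = np.einsum("j,jkl->kl", alphas[i], centered_raw)
        if transform_ranges is not None:
            beta = float(
                np.exp(
                    rng.uniform(
                        np.log(transform_ranges.scale[0]),
                        np.log(transform_ranges.scale[1]),
                    )
                )
            )
            R = special_ortho_group.rvs(3, random_state=rng)
            t = rng.uniform(-transform_ranges.translation, transform_ranges.translation, 3)
            X = beta * X @ R + t
        if noise_sd > 0:
            X = X + rng.normal(0.0, noise_sd, X.shape)
        ensemble.append(ConfigurationMatrix(X, f"spec-{i:04d}"))

    return SyntheticShapeSet(
        ensemble=ensemble,
        true_alphas=alphas,
        pure_case_indices=np.arange(K),
        generator_params={
            "K": K,
            "k": templates[0].coords.shape[0],
            "n": n,
            "dirichlet_concentration": concentration,
            "noise_sd": noise_sd,
            "transform_ranges": None
            if transform_ranges is None
            else dataclasses.asdict(transform_ranges),
            "seed": seed,
            "mixing": mixing,
        },
    )


def recovery_score(result, truth: SyntheticShapeSet) -> RecoveryScore:
    """Score a fitted shape-ADA model against the planted ground truth.

    Estimated archetypoids are matched to the planted pure cases by the
    permutation minimizing total full Procrustes distance; alpha columns
    are permuted accordingly before computing RMSE and correlation, so the
    score is invariant to column order.
    """
    K = len(truth.pure_case_indices)
    est_idx = np.asarray(result.archetypoid_indices)
    if len(est_idx) != K:
        raise InvalidComparisonError(
            f"model has p={len(est_idx)} archetypoids but truth has K={K}"
        )
    pure = [truth.ensemble[int(i)] for i in truth.pure_case_indices]
    D = np.array(
        [
            [full_procrustes_distance(s, t) for t in pure]
            for s in result.archetypoid_shapes
        ]
    )
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        cost = sum(D[j, perm[j]] for j in range(K))
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    # column j of the estimate corresponds to planted column best_perm[j]
    est_alphas = result.model.alphas
    aligned = np.empty_like(est_alphas)
    for j, l in enumerate(best_perm):
        aligned[:, l] = est_alphas[:, j]
    true_alphas = truth.true_alphas
    if aligned.shape != true_alphas.shape:
        raise InvalidComparisonError("alpha matrices have different shapes")
    diff = aligned - true_alphas
    rmse = float(np.sqrt(np.mean(diff**2)))
    corr = float(np.corrcoef(aligned.ravel(), true_alphas.ravel())[0, 1])
    return RecoveryScore(
        index_match=set(est_idx.tolist()) == set(truth.pure_case_indices.tolist()),
        alpha_rmse=rmse,
        alpha_correlation=corr,
    )
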