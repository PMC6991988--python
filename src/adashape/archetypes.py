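"""Archetype (AA) and archetypoid (ADA) analysis for multivariate data.

Given an n x d data matrix, AA finds p archetypes — extreme profiles on the
boundary of the convex hull, themselves convex combinations of cases — such
that every case is well approximated by a convex combination of archetypes.
ADA additionally constrains each archetype to BE a case of the sample
(beta weights become one-hot), turning the problem into a mixed-integer
least-squares minimization of

    RSS = sum_i || x_i - sum_j alpha_ij z_j ||^2,
    sum_j alpha_ij = 1, alpha_ij >= 0,  z_j = x_{l(j)}.

ADA is solved by a BUILD phase (candidate index sets derived from a fitted
AA model, plus seeded random sets) followed by a steepest-descent SWAP
phase that exchanges one archetypoid for one non-archetypoid case while any
exchange lowers the RSS — the same search pattern as PAM k-medoids, with
simplex-constrained least squares replacing the nearest-medoid assignment.

This module is purely multivariate; the shape pipeline feeds it tangent
coordinates (see :mod:`adashape.shape_ada`).
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import warnings
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import nnls

from .exceptions import InvalidInputError

__all__ = [
    "DataMatrix",
    "AAModel",
    "ADAModel",
    "ScreeplotData",
    "fit_alphas",
    "archetype_analysis",
    "archetypoid_analysis",
    "rss_profile",
    "max_alpha_assignment",
]

# enumeration of simplex faces is exact and vectorized for small p;
# beyond this, per-point NNLS in the reduced (Cholesky) space is used
_ENUM_MAX_P = 10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DataMatrix:
    """An n x d matrix of observations with row labels."""

    values: np.ndarray
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise InvalidInputError("empty data matrix")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("data matrix contains non-finite entries")
        self.values = v
        if self.row_ids is None:
            self.row_ids = [str(i) for i in range(v.shape[0])]
        elif len(self.row_ids) != v.shape[0]:
            raise InvalidInputError("row_ids length does not match data")


@dataclasses.dataclass
class AAModel:
    """Fitted archetype analysis: archetypes are convex mixtures of cases."""

    archetypes: np.ndarray  # p x d
    alphas: np.ndarray  # n x p, rows on the simplex
    betas: np.ndarray  # p x n, rows on the simplex
    rss: float
    rss_trace: list[float]


@dataclasses.dataclass
class ADAModel:
    """Fitted archetypoid analysis: archetypes constrained to actual cases."""

    archetypoid_indices: np.ndarray  # p distinct 0-based case indices
    alphas: np.ndarray  # n x p
    rss: float
    restarts_used: int
    seed: int | None


@dataclasses.dataclass
class ScreeplotData:
    """RSS versus number of archetypoids, for elbow reading.

    ``elbow_p`` is a diagnostic only (largest second difference of RSS);
    the choice of p remains the analyst's.
    """

    entries: list[tuple[int, float]]
    elbow_p: int | None = None

    def __post_init__(self) -> None:
        ps = [p for p, _ in self.entries]
        if any(b <= a for a, b in zip(ps, ps[1:])):
            raise InvalidInputError("screeplot p values must be strictly increasing")
        rss = [r for _, r in self.entries]
        for a, b in zip(rss, rss[1:]):
            if b > a + 1e-8 * max(1.0, abs(a)):
                raise InvalidInputError("screeplot RSS must be non-increasing")
        if self.elbow_p is None and len(rss) >= 3:
            second = [rss[i - 1] - 2 * rss[i] + rss[i + 1] for i in range(1, len(rss) - 1)]
            self.elbow_p = ps[1 + int(np.argmax(second))]


# ---------------------------------------------------------------------------
# Simplex-constrained least squares
# ---------------------------------------------------------------------------


def fit_alphas(data, archetypes, penalty: float = 200.0):
    """Best simplex weights of each case on a set of archetypes.

    Per row ``x_i``, minimizes ``||x_i - Z^T alpha||`` over the probability
    simplex via the classical penalty device: a row of ones weighted by a
    large constant M (``penalty`` times the data scale) is appended and the
    problem solved by non-negative least squares, then each alpha row is
    renormalized to sum exactly to one.

    Returns
    -------
    (alphas, rss)
        ``alphas``: n x p, rows non-negative summing to 1; ``rss``: summed
        squared residual of the returned weights.
    """
    X = np.atleast_2d(np.asarray(data.values if isinstance(data, DataMatrix) else data, dtype=float))
    Z = np.atleast_2d(np.asarray(archetypes, dtype=float))
    if Z.shape[0] < 1:
        raise InvalidInputError("need at least one archetype")
    if Z.shape[1] != X.shape[1]:
        raise InvalidInputError("archetype dimension does not match data")
    n, p = X.shape[0], Z.shape[0]
    scale = max(float(np.max(np.abs(X), initial=0.0)), float(np.max(np.abs(Z), initial=0.0)), 1e-8)
    M = penalty * scale
    design = np.vstack([Z.T, M * np.ones((1, p))])
    alphas = np.empty((n, p))
    for i in range(n):
        b = np.concatenate([X[i], [M]])
        sol, _ = nnls(design, b)
        s = sol.sum()
        alphas[i] = sol / s if s > 0 else np.full(p, 1.0 / p)
    resid = X - alphas @ Z
    return alphas, float(np.sum(resid * resid))


@functools.lru_cache(maxsize=None)
def _combos(p: int, t: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(p), t)), dtype=int)


def _alphas_qp(Q: np.ndarray, C: np.ndarray, want_alphas: bool = False):
    """Exact simplex QP min_a a^T Q a - 2 c^T a for every column c of C.

    The global simplex minimizer lies in the relative interior of some face,
    where it coincides with that face's equality-constrained KKT solution
    [[Q_T, 1], [1^T, 0]] [a; lam] = [c_T; 1]; so the minimum over all
    primal-feasible face solutions is the optimum.  Faces of equal size are
    solved in one batched call, vectorized over the n columns of C.
    """
    p, n = C.shape
    jit = 1e-12 * max(1.0, float(np.max(np.diag(Q))))
    best = np.full(n, np.inf)
    best_face = np.zeros(n, dtype=int) if want_alphas else None
    best_size = np.zeros(n, dtype=int) if want_alphas else None
    sols: dict[int, np.ndarray] = {}
    for t in range(1, p + 1):
        combos = _combos(p, t)
        m = combos.shape[0]
        Qf = Q[combos[:, :, None], combos[:, None, :]] + jit * np.eye(t)
        K = np.zeros((m, t + 1, t + 1))
        K[:, :t, :t] = Qf
        K[:, :t, t] = 1.0
        K[:, t, :t] = 1.0
        rhs = np.concatenate([C[combos], np.broadcast_to(1.0, (m, 1, n))], axis=1)
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(K) @ rhs
        A = sol[:, :t, :]  # (m, t, n)
        feas = np.all(A >= -1e-9, axis=1)
        obj = np.einsum("mtn,mtn->mn", A, Qf @ A) - 2.0 * np.einsum(
            "mtn,mtn->mn", A, C[combos]
        )
        obj = np.where(feas, obj, np.inf)
        face = obj.argmin(axis=0)
        vals = obj[face, np.arange(n)]
        upd = vals < best
        best = np.where(upd, vals, best)
        if want_alphas:
            sols[t] = A
            best_face[upd] = face[upd]
            best_size[upd] = t
    if want_alphas:
        alphas = np.zeros((n, p))
        for i in range(n):
            t = int(best_size[i])
            idx = _combos(p, t)[best_face[i]]
            alphas[i, idx] = sols[t][best_face[i], :, i]
        return best, alphas
    return best


def _alphas_qp_nnls(Q: np.ndarray, C: np.ndarray, want_alphas: bool = False):
    """Penalty-NNLS fallback for the simplex QP when p is large."""
    p, n = C.shape
    jit = 1e-10 * max(1.0, float(np.max(np.diag(Q))))
    R = cholesky(Q + jit * np.eye(p), lower=False)  # upper factor, Q = R^T R
    T = solve_triangular(R, C, trans="T", lower=False)  # R^T t = c
    M = 200.0 * max(1.0, float(np.sqrt(np.max(np.diag(Q)))))
    design = np.vstack([R, M * np.ones((1, p))])
    best = np.empty(n)
    alphas = np.zeros((n, p)) if want_alphas else None
    for i in range(n):
        b = np.concatenate([T[:, i], [M]])
        sol, _ = nnls(design, b)
        s = sol.sum()
        a = sol / s if s > 0 else np.full(p, 1.0 / p)
        best[i] = float(a @ Q @ a - 2.0 * a @ C[:, i])
        if want_alphas:
            alphas[i] = a
    if want_alphas:
        return best, alphas
    return best


def _set_rss(G: np.ndarray, sq: np.ndarray, idx: Sequence[int]) -> float:
    """RSS of the archetypoid index set ``idx`` on Gram matrix G."""
    idx = np.asarray(idx)
    Q = G[np.ix_(idx, idx)]
    C = G[idx, :]
    solver = _alphas_qp if len(idx) <= _ENUM_MAX_P else _alphas_qp_nnls
    obj = solver(Q, C)
    return float(np.sum(np.clip(sq + obj, 0.0, None)))


def _set_alphas_rss(G: np.ndarray, sq: np.ndarray, idx: Sequence[int]):
    idx = np.asarray(idx)
    Q = G[np.ix_(idx, idx)]
    C = G[idx, :]
    solver = _alphas_qp if len(idx) <= _ENUM_MAX_P else _alphas_qp_nnls
    _, alphas = solver(Q, C, want_alphas=True)
    alphas = np.clip(alphas, 0.0, None)
    alphas /= alphas.sum(axis=1, keepdims=True)
    obj = np.einsum("ip,pq,iq->i", alphas, Q, alphas) - 2.0 * np.einsum(
        "ip,pi->i", alphas, C
    )
    rss = float(np.sum(np.clip(sq + obj, 0.0, None)))
    return alphas, rss


# ---------------------------------------------------------------------------
# Archetype analysis (AA)
# ---------------------------------------------------------------------------


def archetype_analysis(
    data,
    p: int,
    *,
    seed: int | None,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> AAModel:
    """Alternating-minimization archetype analysis.

    Archetypes are initialized at ``p`` distinct cases drawn with the seeded
    generator; each outer iteration refits alphas (simplex least squares),
    solves the unconstrained optimal archetypes given alphas, and projects
    them back to convex combinations of cases by the analogous simplex
    least-squares (the beta step).  The RSS trace is non-increasing: an
    iteration that would raise the RSS is rolled back and the restart ends.
    """
    X = np.atleast_2d(np.asarray(data.values if isinstance(data, DataMatrix) else data, dtype=float))
    n = X.shape[0]
    if not 1 <= p <= n:
        raise InvalidInputError(f"need 1 <= p <= n, got p={p}, n={n}")
    rng = np.random.default_rng(seed)
    best: AAModel | None = None
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(n, size=p, replace=False)
        betas = np.zeros((p, n))
        betas[np.arange(p), idx] = 1.0
        Z = betas @ X
        alphas, rss = fit_alphas(X, Z)
        trace = [rss]
        for _ in range(max_iter):
            Zu = np.linalg.lstsq(alphas, X, rcond=None)[0]
            betas_new, _ = fit_alphas(Zu, X)
            Z_new = betas_new @ X
            alphas_new, rss_new = fit_alphas(X, Z_new)
            if rss_new > rss * (1 + 1e-12):
                break  # roll back: alternating step failed to improve
            improved = rss - rss_new
            Z, betas, alphas, rss = Z_new, betas_new, alphas_new, rss_new
            trace.append(rss)
            if improved < tol * max(rss, 1e-30):
                break
        if best is None or rss < best.rss:
            best = AAModel(archetypes=Z, alphas=alphas, betas=betas, rss=rss, rss_trace=trace)
    return best


# ---------------------------------------------------------------------------
# Archetypoid analysis (ADA)
# ---------------------------------------------------------------------------


def _build_candidates(X: np.ndarray, G: np.ndarray, sq: np.ndarray, p: int, rng) -> list[tuple[int, ...]]:
    """BUILD-phase candidate index sets derived from a fitted AA model:
    (a) the nearest case to each archetype, (b) the case with maximal alpha
    on each archetype, (c) the case with maximal beta per archetype."""
    n = X.shape[0]
    aa = archetype_analysis(X, p, seed=int(rng.integers(2**31)), n_restarts=2, max_iter=60)
    cands = []
    # (a) nearest case to each archetype, kept distinct greedily
    d2 = sq[None, :] - 2.0 * aa.archetypes @ X.T + np.einsum(
        "pd,pd->p", aa.archetypes, aa.archetypes
    )[:, None]
    cands.append(_distinct_argbest(d2, minimize=True))
    # (b) maximal alpha per archetype
    cands.append(_distinct_argbest(aa.alphas.T, minimize=False))
    # (c) maximal beta per archetype
    cands.append(_distinct_argbest(aa.betas, minimize=False))
    return [tuple(sorted(c)) for c in cands]


def _distinct_argbest(score: np.ndarray, minimize: bool) -> list[int]:
    """Per row of ``score`` pick the best column, forcing distinct picks
    (ties and collisions resolved toward the lowest index)."""
    s = score.copy() if minimize else -score.copy()
    chosen: list[int] = []
    for j in range(s.shape[0]):
        order = np.argsort(s[j], kind="stable")
        pick = next(int(c) for c in order if int(c) not in chosen)
        chosen.append(pick)
    return chosen


def _swap_descent(G, sq, idx, rng, sample_limit=2000, max_passes=200):
    """Steepest-descent SWAP: accept the single best improving exchange of
    one archetypoid for one outside case until none improves.  Evaluates
    all p*(n-p) exchanges per pass when n <= sample_limit, else a seeded
    random subsample of ``sample_limit`` exchanges."""
    idx = list(idx)
    n = G.shape[0]
    p = len(idx)
    cur = _set_rss(G, sq, idx)
    for _ in range(max_passes):
        members = set(idx)
        outside = [c for c in range(n) if c not in members]
        pairs = [(j, c) for j in range(p) for c in outside]
        if n > sample_limit and len(pairs) > sample_limit:
            sel = rng.choice(len(pairs), size=sample_limit, replace=False)
            pairs = [pairs[int(s)] for s in sel]
        best_rss, best_pair = cur, None
        for j, c in pairs:
            trial = idx.copy()
            trial[j] = c
            r = _set_rss(G, sq, trial)
            if r < best_rss - 1e-12 * max(1.0, cur):
                best_rss, best_pair = r, (j, c)
        if best_pair is None:
            break
        idx[best_pair[0]] = best_pair[1]
        cur = best_rss
    return idx, cur


def archetypoid_analysis(
    data,
    p: int,
    n_restarts: int = 10,
    *,
    seed: int | None,
    extra_candidates: Sequence[Sequence[int]] | None = None,
) -> ADAModel:
    """Mixed-integer archetypoid analysis by BUILD + SWAP search.

    Candidate initial sets come from three AA-derived heuristics plus
    ``n_restarts`` seeded random index sets (and any ``extra_candidates``,
    used by :func:`rss_profile` for its nested-restart protocol); each is
    refined by steepest-descent swaps and the best final set is returned.
    Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(data.values if isinstance(data, DataMatrix) else data, dtype=float))
    n = X.shape[0]
    if not 1 <= p <= n:
        raise InvalidInputError(f"need 1 <= p <= n, got p={p}, n={n}")
    rng = np.random.default_rng(seed)

    # degenerate data: every row identical
    if np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("all data rows identical; archetypoids are arbitrary", stacklevel=2)
        alphas = np.zeros((n, p))
        alphas[:, 0] = 1.0
        return ADAModel(np.arange(p), alphas, 0.0, 0, seed)

    if p == n:
        return ADAModel(np.arange(n), np.eye(n), 0.0, 0, seed)

    G = X @ X.T
    sq = np.diag(G).copy()

    candidates = _build_candidates(X, G, sq, p, rng)
    for _ in range(n_restarts):
        candidates.append(tuple(sorted(int(i) for i in rng.choice(n, size=p, replace=False))))
    if extra_candidates:
        for c in extra_candidates:
            candidates.append(tuple(sorted(int(i) for i in c)))
    seen = set()
    unique = []
    for c in candidates:
        if c not in seen:
            seen.add(c)
            unique.append(c)

    best_idx, best_rss = None, np.inf
    for cand in unique:
        idx, rss = _swap_descent(G, sq, list(cand), rng)
        key = tuple(sorted(idx))
        if (
            best_idx is None
            or rss < best_rss - 1e-12 * max(1.0, best_rss)
            or (abs(rss - best_rss) <= 1e-12 * max(1.0, best_rss) and key < tuple(best_idx))
        ):
            best_idx, best_rss = list(key), rss

    alphas, rss = _set_alphas_rss(G, sq, best_idx)
    return ADAModel(
        archetypoid_indices=np.asarray(best_idx, dtype=int),
        alphas=alphas,
        rss=rss,
        restarts_used=len(unique),
        seed=seed,
    )


def rss_profile(
    data,
    p_values: Sequence[int],
    n_restarts: int = 10,
    *,
    seed: int | None,
) -> ScreeplotData:
    """RSS screeplot over a series of p values (nested-restart protocol).

    The best index set at one p, greedily padded with the case whose
    addition most reduces the RSS, is offered as an extra starting
    candidate at the next p — which guarantees a non-increasing profile.
    """
    X = np.atleast_2d(np.asarray(data.values if isinstance(data, DataMatrix) else data, dtype=float))
    n = X.shape[0]
    ps = sorted(set(int(p) for p in p_values))
    if not ps or ps[0] < 1 or ps[-1] > n:
        raise InvalidInputError("p_values must lie in [1, n]")
    G = X @ X.T
    sq = np.diag(G).copy()
    rng = np.random.default_rng(seed)
    entries = []
    prev: list[int] | None = None
    for p in ps:
        extra = []
        if prev is not None:
            pad = list(prev)
            while len(pad) < p:
                outside = [c for c in range(n) if c not in set(pad)]
                rs = [_set_rss(G, sq, pad + [c]) for c in outside]
                pad.append(outside[int(np.argmin(rs))])
            extra.append(pad)
        model = archetypoid_analysis(
            X, p, n_restarts, seed=int(rng.integers(2**31)), extra_candidates=extra
        )
        entries.append((p, model.rss))
        prev = list(model.archetypoid_indices)
    return ScreeplotData(entries=entries)


def max_alpha_assignment(alphas: np.ndarray) -> np.ndarray:
    """Assign each case to the archetypoid with the largest alpha.

    Ties break toward the lowest index.  Labels are 0-based.
    """
    a = np.atleast_2d(np.asarray(alphas, dtype=float))
    if np.any(a < -1e-10):
        raise InvalidInputError("alpha matrix has negative entries")
    if np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-8):
        raise InvalidInputError("alpha rows must sum to 1")
    return np.argmax(a, axis=1)
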