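"""Synergy extraction: NMF seeding and semi-nonnegative refinement.

The observation model is

    Y  ~=  W @ C,      C >= 0,  W free sign,

i.e. an N-channel envelope at each time point is a linear combination of M
muscle synergies (columns of W) driven by rectified (nonnegative)
activation coefficients.  Because the bias is removed and the output
nonlinearity is the identity, maximum-likelihood estimation under Gaussian
noise reduces to alternating minimization of the Frobenius reconstruction
error: a nonnegative update for C and an unconstrained least-squares update
for W.  Negative entries in W are the "inhibitory components" that plain
NMF cannot represent.

Protocol (per envelope and candidate dimensionality M):

1. ``nmf_fit`` is run ``n_nmf_reps`` times (default 100) from random
   nonnegative initializations (multiplicative Frobenius updates).
2. The ``n_keep`` (default 10) repetitions with the highest R^2 seed
   ``rlvm_fit``, which lifts the nonnegativity constraint on W.
3. ``select_dimensionality`` picks the smallest M for which all refined
   solutions reach ``R^2 >= 0.8``.
4. ``average_synergy_sets`` matches the solutions column-wise, averages
   them, normalizes each synergy by the standard deviation of its weights,
   and refits C by nonnegative least squares.

Fit quality is the classical coefficient of determination
``R^2 = 1 - SSres/SStot`` with SStot centered per channel (an uncentered
variant is available via ``centered=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .seeding import derive_seed

__all__ = [
    "FactorizationConfig",
    "FitQuality",
    "SynergySet",
    "nmf_fit",
    "rlvm_fit",
    "r_squared",
    "extract_synergies",
    "select_dimensionality",
    "average_synergy_sets",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FactorizationConfig:
    n_nmf_reps: int = 100
    n_keep: int = 10
    r2_threshold: float = 0.8
    max_M: int | None = None
    max_iter: int = 500
    tol: float = 1e-8
    centered_r2: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_keep > self.n_nmf_reps:
            raise ValueError("n_keep must not exceed n_nmf_reps")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")


@dataclass
class FitQuality:
    R2: float
    SSres: float
    SStot: float


@dataclass
class SynergySet:
    """One factorization: free-sign W, nonnegative C, and its fit."""

    W: np.ndarray
    C: np.ndarray
    fit: FitQuality | None = None
    init_id: int | None = None
    meta: dict = field(default_factory=dict)
    objective_trace: np.ndarray | None = None

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]


def _as_matrix(env) -> np.ndarray:
    return np.asarray(getattr(env, "data", env), dtype=float)


# ---------------------------------------------------------------------------
# fit quality
# ---------------------------------------------------------------------------

def r_squared(env, W: np.ndarray, C: np.ndarray, centered: bool = True) -> FitQuality:
    """Coefficient of determination of the reconstruction ``W @ C``.

    ``SStot`` is computed around the per-channel mean (``centered=True``,
    the classical definition) or around zero.
    """
    Y = _as_matrix(env)
    resid = Y - W @ C
    ss_res = float(np.sum(resid * resid))
    if centered:
        Yc = Y - Y.mean(axis=1, keepdims=True)
    else:
        Yc = Y
    ss_tot = float(np.sum(Yc * Yc))
    if ss_tot == 0.0:
        raise ValueError("SStot is zero (all channels constant); R^2 undefined")
    return FitQuality(R2=1.0 - ss_res / ss_tot, SSres=ss_res, SStot=ss_tot)


# ---------------------------------------------------------------------------
# NMF (multiplicative updates, Frobenius loss)
# ---------------------------------------------------------------------------

def nmf_fit(
    env,
    M: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    centered_r2: bool = True,
) -> SynergySet:
    """Nonnegative factorization ``Y ~= W C`` with W, C >= 0.

    Multiplicative Frobenius updates from a random nonnegative
    initialization scaled to the data; iterations stop when the relative
    objective change falls below ``tol``.  The objective is non-increasing
    at every iteration.
    """
    Y = _as_matrix(env)
    if np.any(Y < -_EPS):
        raise ValueError(
            "input envelope has negative entries; NMF requires nonnegative "
            "data -- rectify/floor the envelope in preprocessing first"
        )
    Y = np.maximum(Y, 0.0)
    n_ch, n_s = Y.shape
    if not (1 <= M <= n_ch):
        raise ValueError(f"M must be in 1..{n_ch}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(Y.mean(), _EPS) / M)
    W = scale * rng.random((n_ch, M)) + _EPS
    C = scale * rng.random((M, n_s)) + _EPS
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        # C update
        WtY = W.T @ Y
        WtWC = (W.T @ W) @ C
        C *= WtY / np.maximum(WtWC, _EPS)
        # W update
        YCt = Y @ C.T
        WCCt = W @ (C @ C.T)
        W *= YCt / np.maximum(WCCt, _EPS)
        resid = Y - W @ C
        obj = float(np.sum(resid * resid))
        trace.append(obj)
        if prev < np.inf and abs(prev - obj) <= tol * max(prev, _EPS):
            break
        prev = obj
    fit = r_squared(Y, W, C, centered=centered_r2)
    return SynergySet(W, C, fit=fit, meta={"method": "nmf", "seed": seed},
                      objective_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# semi-nonnegative refinement (free-sign W, C >= 0)
# ---------------------------------------------------------------------------

def _hals_update_C(Y, W, C, n_sweeps: int = 2) -> np.ndarray:
    """Nonnegative coordinate-descent sweeps on the rows of C (W fixed).

    Each row update is the exact minimizer of the quadratic objective in
    that row subject to nonnegativity, so the objective never increases.
    """
    G = W.T @ W  # M x M
    F = W.T @ Y  # M x n
    diag = np.maximum(np.diag(G), _EPS)
    M = C.shape[0]
    for _ in range(n_sweeps):
        for j in range(M):
            grad = F[j] - G[j] @ C
            C[j] = np.maximum(C[j] + grad / diag[j], 0.0)
    return C


def _solve_W(Y, C, ridge: float = 0.0) -> np.ndarray:
    G = C @ C.T
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return np.linalg.solve(G, C @ Y.T).T


def rlvm_fit(
    env,
    init: SynergySet,
    config: FactorizationConfig | None = None,
) -> SynergySet:
    """Refine an NMF solution with the nonnegativity constraint on W lifted.

    Alternating minimization of ``||Y - W C||_F^2``: nonnegative
    coordinate-descent updates for C, unconstrained least squares for W
    (ridge fallback ``lambda=1e-8`` if the coefficient Gram matrix is
    singular).  The objective is non-increasing and the final R^2 is never
    below the initialization's.
    """
    cfg = config or FactorizationConfig()
    Y = _as_matrix(env)
    if init.W.shape[0] != Y.shape[0] or init.C.shape[1] != Y.shape[1]:
        raise ValueError("init dimensions do not match the envelope")
    W = init.W.astype(float, copy=True)
    C = np.maximum(init.C.astype(float, copy=True), 0.0)
    trace = []
    prev = np.inf
    for _ in range(cfg.max_iter):
        C = _hals_update_C(Y, W, C)
        try:
            Wn = _solve_W(Y, C)
            if not np.all(np.isfinite(Wn)):
                raise np.linalg.LinAlgError
            W = Wn
        except np.linalg.LinAlgError:
            logger.warning(
                "rank-deficient coefficients in W update; using ridge fallback"
            )
            W = _solve_W(Y, C, ridge=1e-8)
        resid = Y - W @ C
        obj = float(np.sum(resid * resid))
        trace.append(obj)
        if prev < np.inf and abs(prev - obj) <= cfg.tol * max(prev, _EPS):
            break
        prev = obj
    fit = r_squared(Y, W, C, centered=cfg.centered_r2)
    return SynergySet(
        W, C, fit=fit, init_id=init.init_id,
        meta={**init.meta, "method": "rlvm"},
        objective_trace=np.asarray(trace),
    )


def nnls_coefficients(Y: np.ndarray, W: np.ndarray, n_sweeps: int = 400,
                      tol: float = 1e-12) -> np.ndarray:
    """Nonnegative least-squares fit of C in ``Y ~= W C`` for fixed W."""
    Y = np.asarray(Y, dtype=float)
    G = W.T @ W
    F = W.T @ Y
    # start from the unconstrained ridge solution, clipped
    C = np.maximum(np.linalg.solve(G + 1e-10 * np.eye(G.shape[0]), F), 0.0)
    diag = np.maximum(np.diag(G), _EPS)
    prev = np.inf
    for _ in range(n_sweeps):
        for j in range(C.shape[0]):
            grad = F[j] - G[j] @ C
            C[j] = np.maximum(C[j] + grad / diag[j], 0.0)
        resid = Y - W @ C
        obj = float(np.sum(resid * resid))
        if prev < np.inf and abs(prev - obj) <= tol * max(prev, _EPS):
            break
        prev = obj
    return C


# ---------------------------------------------------------------------------
# repetition protocol
# ---------------------------------------------------------------------------

def extract_synergies(
    env,
    M: int,
    config: FactorizationConfig | None = None,
) -> list[SynergySet]:
    """Run the full repetition protocol at dimensionality M.

    ``n_nmf_reps`` NMF fits with distinct sub-seeds are ranked by R^2; the
    ``n_keep`` best initialize the free-sign refinement.  Returns the
    refined sets (each carrying the originating NMF repetition in
    ``init_id``).
    """
    cfg = config or FactorizationConfig()
    Y = _as_matrix(env)
    # The NMF seeding stage requires nonnegative data.  Measured envelopes
    # are nonnegative by construction; a synthetic free-sign forward model
    # may dip below zero, in which case the seeds are fit on the rectified
    # part while the refinement sees the full signal.
    Y_nmf = np.maximum(Y, 0.0) if Y.min() < 0 else Y
    nmf_sets = []
    for rep in range(cfg.n_nmf_reps):
        s = nmf_fit(Y_nmf, M, seed=derive_seed(cfg.seed, "nmf", M, rep),
                    max_iter=cfg.max_iter, tol=cfg.tol,
                    centered_r2=cfg.centered_r2)
        s.init_id = rep
        nmf_sets.append(s)
    order = sorted(range(len(nmf_sets)),
                   key=lambda i: (-nmf_sets[i].fit.R2, i))
    best = [nmf_sets[i] for i in order[: cfg.n_keep]]
    return [rlvm_fit(Y, s, cfg) for s in best]


def select_dimensionality(
    env,
    config: FactorizationConfig | None = None,
    return_sets: bool = False,
):
    """Smallest M for which all ``n_keep`` refined solutions reach the R^2
    threshold (default 0.8); ascends from M=1 and stops at first success."""
    cfg = config or FactorizationConfig()
    Y = _as_matrix(env)
    max_M = cfg.max_M or Y.shape[0]
    best_r2 = -np.inf
    for M in range(1, max_M + 1):
        sets = extract_synergies(env, M, cfg)
        worst = min(s.fit.R2 for s in sets)
        best_r2 = max(best_r2, worst)
        if worst >= cfg.r2_threshold:
            return (M, sets) if return_sets else M
    raise RuntimeError(
        f"no dimensionality up to {max_M} reaches R^2 >= {cfg.r2_threshold}; "
        f"best achieved min-R^2 was {best_r2:.4f}"
    )


# ---------------------------------------------------------------------------
# averaging across repetitions
# ---------------------------------------------------------------------------

def _unit_norm_columns(s: SynergySet) -> SynergySet:
    norms = np.linalg.norm(s.W, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return replace(s, W=s.W / norms, C=s.C * norms[:, None])


def average_synergy_sets(sets: Sequence[SynergySet], env=None) -> SynergySet:
    """Average matched synergies across repetitions.

    Columns are scale-normalized, matched to the highest-R^2 set by the
    optimal one-to-one assignment maximizing summed cosine similarity, and
    averaged.  Each averaged synergy is then divided by the standard
    deviation of its weights across channels ("normalized by variance"),
    and C is refit by nonnegative least squares against the averaged W
    (against ``env`` if given, else against the reference reconstruction).
    """
    if not sets:
        raise ValueError("no synergy sets to average")
    shapes = {s.W.shape for s in sets}
    if len(shapes) != 1:
        raise ValueError(f"synergy sets have mismatched shapes: {shapes}")
    ordered = sorted(sets, key=lambda s: (s.init_id if s.init_id is not None else 0))
    ref = max(ordered, key=lambda s: (s.fit.R2 if s.fit else -np.inf))
    ref_u = _unit_norm_columns(ref)
    acc = ref_u.W.copy()
    for s in ordered:
        if s is ref:
            continue
        su = _unit_norm_columns(s)
        sim = ref_u.W.T @ su.W  # cosine similarity matrix
        row, col = linear_sum_assignment(-sim)
        aligned = su.W[:, col[np.argsort(row)]]
        acc += aligned
    W_avg = acc / len(ordered)
    sd = W_avg.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    W_avg = W_avg / sd
    Y = _as_matrix(env) if env is not None else ref.W @ ref.C
    C = nnls_coefficients(Y, W_avg)
    fit = r_squared(Y, W_avg, C)
    return SynergySet(W_avg, C, fit=fit, init_id=ref.init_id,
                      meta={**ref.meta, "method": "rlvm_average",
                            "n_averaged": len(ordered)})
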