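"""Kernel ridge regression over atomic environments.

Prediction of a chemical shift is a weighted sum of kernel similarities
between the query atomic environment and the training environments,
y* = Σ_i α_i k(x*, x_i), with the dual coefficients α solving
(K + λI)α = y.  One-bond C–H couplings compare atom *pairs*: the kernel
between two pairs is the product of the separately computed carbon–carbon
and hydrogen–hydrogen kernel similarities, which keeps the similarity in
(0, 1] and self-similarity exactly 1.

Targets are centred (mean removed) before fitting and the mean restored at
prediction, so α stays well-scaled across the ppm (~0–200) and Hz
(~100–250) label ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial.distance import cdist

from .representations import AtomicRep, PairRep, RepParams, rep_for_label, represent_dataset
from .structures import Dataset

__all__ = [
    "KernelParams",
    "KRRModel",
    "kernel",
    "pair_kernel",
    "kernel_matrix",
    "krr_fit",
    "krr_predict",
    "fit_krr_model",
    "median_heuristic_sigma",
    "hyperparam_search",
    "assemble_targets",
    "structure_folds",
]

#: Default ridge per training point, relative to unit-diagonal kernels.
DEFAULT_LAM_PER_POINT = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Kernel family and length scale in representation space."""

    kind: str = "laplacian"
    sigma: float = 1.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "laplacian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def _check_compatible(x: AtomicRep, y: AtomicRep) -> None:
    if x.vector.shape != y.vector.shape:
        raise ValueError(
            f"representation length mismatch: {x.vector.shape} vs {y.vector.shape}"
        )


def kernel(x: AtomicRep, y: AtomicRep, kp: KernelParams) -> float:
    """Scalar kernel similarity in (0, 1]; k(x, x) = 1 exactly."""
    _check_compatible(x, y)
    d = x.vector - y.vector
    if kp.kind == "gaussian":
        return float(np.exp(-(d @ d) / (2.0 * kp.sigma**2)))
    return float(np.exp(-np.abs(d).sum() / kp.sigma))


def pair_kernel(a: PairRep, b: PairRep, kp: KernelParams) -> float:
    """Product kernel for C–H pairs: k(a_C, b_C)·k(a_H, b_H)."""
    if not isinstance(a, PairRep) or not isinstance(b, PairRep):
        raise TypeError("pair_kernel requires PairRep operands")
    return kernel(a.carbon, b.carbon, kp) * kernel(a.hydrogen, b.hydrogen, kp)


def _stack(reps: Sequence[AtomicRep]) -> np.ndarray:
    if not reps:
        return np.zeros((0, 0))
    return np.stack([r.vector for r in reps])


def _gram(X: np.ndarray, Y: np.ndarray, kp: KernelParams) -> np.ndarray:
    if X.shape[0] == 0 or Y.shape[0] == 0:
        return np.zeros((X.shape[0], Y.shape[0]))
    if kp.kind == "gaussian":
        return np.exp(-cdist(X, Y, "sqeuclidean") / (2.0 * kp.sigma**2))
    return np.exp(-cdist(X, Y, "cityblock") / kp.sigma)


def kernel_matrix(rows: Sequence, cols: Sequence, kp: KernelParams) -> np.ndarray:
    """Dense kernel matrix; entry (i, j) = kernel(rows[i], cols[j]).

    Accepts all-AtomicRep or all-PairRep inputs (the pair case multiplies
    the carbon and hydrogen Gram matrices elementwise).  When ``rows is
    cols`` the result is symmetric with unit diagonal.
    """
    rows, cols = list(rows), list(cols)
    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    row_pair = isinstance(rows[0], PairRep)
    col_pair = isinstance(cols[0], PairRep)
    if row_pair != col_pair:
        raise TypeError("cannot mix atomic and pair representations in one kernel matrix")
    if row_pair:
        kc = _gram(_stack([r.carbon for r in rows]), _stack([c.carbon for c in cols]), kp)
        kh = _gram(_stack([r.hydrogen for r in rows]), _stack([c.hydrogen for c in cols]), kp)
        return kc * kh
    return _gram(_stack(rows), _stack(cols), kp)


def krr_fit(K: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (K + λI)α = y by Cholesky factorisation.

    Raises a ``ValueError`` advising a larger λ when K + λI is not positive
    definite; verifies the residual ‖(K+λI)α − y‖∞ < 1e-8·max(1, ‖y‖∞).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got {K.shape}")
    if len(y) != K.shape[0]:
        raise ValueError(f"len(y)={len(y)} does not match dim(K)={K.shape[0]}")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    A = K + lam * np.eye(K.shape[0])
    try:
        alpha = cho_solve(cho_factor(A, lower=True), y)
    except LinAlgError as exc:
        raise ValueError(
            "K + lam*I is not positive definite; increase lam (regularization)"
        ) from exc
    resid = np.abs(A @ alpha - y).max(initial=0.0)
    if resid >= 1e-8 * max(1.0, np.abs(y).max(initial=0.0)):
        raise ValueError(
            f"ill-conditioned KRR solve (residual {resid:.3e}); increase lam"
        )
    return alpha


@dataclass
class KRRModel:
    """A trained kernel ridge machine for one NMR parameter."""

    param: str
    train_reps: list  # AtomicRep or PairRep
    alpha: np.ndarray
    kp: KernelParams
    lam: float
    rep_params: RepParams
    y_mean: float = 0.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.alpha) != len(self.train_reps):
            raise ValueError("one dual coefficient per training target required")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("non-finite dual coefficients")


def fit_krr_model(
    param: str,
    train_reps: Sequence,
    y: Sequence[float],
    kp: KernelParams,
    lam: float | None = None,
    rep_params: RepParams | None = None,
) -> KRRModel:
    """Centre targets, build the Gram matrix, and solve for α."""
    y = np.asarray(y, dtype=float)
    if rep_params is None:
        first = train_reps[0]
        rep_params = first.params
    if lam is None:
        lam = DEFAULT_LAM_PER_POINT * len(y)
    y_mean = float(y.mean())
    K = kernel_matrix(train_reps, train_reps, kp)
    alpha = krr_fit(K, y - y_mean, lam)
    return KRRModel(param, list(train_reps), alpha, kp, lam, rep_params, y_mean)


def krr_predict(m: KRRModel, targets: Sequence) -> np.ndarray:
    """One prediction per target: y* = Σ α_i k(x*, x_i) + mean."""
    if not len(targets):
        return np.zeros(0)
    K = kernel_matrix(targets, m.train_reps, m.kp)
    return K @ m.alpha + m.y_mean


def median_heuristic_sigma(reps: Sequence, kp_kind: str = "gaussian",
                           max_sample: int = 400, seed: int = 0) -> float:
    """Median pairwise distance among (a subsample of) the representations.

    The standard length-scale heuristic; for pair representations the two
    member distances are pooled.
    """
    rng = np.random.default_rng(seed)
    reps = list(reps)
    if len(reps) > max_sample:
        idx = rng.choice(len(reps), size=max_sample, replace=False)
        reps = [reps[i] for i in idx]
    if isinstance(reps[0], PairRep):
        X = np.concatenate([_stack([r.carbon for r in reps]),
                            _stack([r.hydrogen for r in reps])])
    else:
        X = _stack(reps)
    metric = "euclidean" if kp_kind == "gaussian" else "cityblock"
    d = cdist(X, X, metric)
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    return float(np.median(vals))


def assemble_targets(d: Dataset, param: str, cache: dict | None = None,
                     rep_params: RepParams | None = None,
                     structure_ids: Sequence[str] | None = None):
    """(reps, y, records) for every label of ``param`` in the chosen structures."""
    if cache is None:
        if rep_params is None:
            raise ValueError("need a representation cache or rep_params")
        cache = represent_dataset(d, rep_params)
    records = d.labels_for(param, structure_ids)
    reps = [rep_for_label(r, cache) for r in records]
    y = np.array([r.value for r in records])
    return reps, y, records


def structure_folds(structure_ids: Sequence[str], n_folds: int, seed: int) -> list[list[str]]:
    """Shuffle structures (seeded) into ``n_folds`` near-equal folds."""
    ids = list(structure_ids)
    if len(ids) < n_folds:
        raise ValueError(f"{len(ids)} structures is fewer than {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in part] for part in np.array_split(order, n_folds)]


def hyperparam_search(
    d: Dataset,
    param: str,
    grid: Sequence[tuple[KernelParams, float]],
    n_folds: int,
    seed: int,
    rep_params: RepParams,
) -> tuple[tuple[KernelParams, float], pd.DataFrame]:
    """Grid search by structure-level k-fold cross-validation.

    Folds are split by STRUCTURE so no molecule contributes to both train
    and validation.  Returns the grid point with the lowest mean CV MAE and
    the full score table; deterministic given ``seed``.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    sids = d.structure_ids_with(param)
    folds = structure_folds(sids, n_folds, seed)
    cache = represent_dataset(d, rep_params)

    rows = []
    means = []
    for gi, (kp, lam) in enumerate(grid):
        fold_maes = []
        for fi, fold in enumerate(folds):
            train_ids = [s for s in sids if s not in set(fold)]
            reps_tr, y_tr, _ = assemble_targets(d, param, cache, structure_ids=train_ids)
            reps_va, y_va, _ = assemble_targets(d, param, cache, structure_ids=fold)
            if not len(y_va):
                continue
            model = fit_krr_model(param, reps_tr, y_tr, kp, lam, rep_params)
            mae = float(np.abs(krr_predict(model, reps_va) - y_va).mean())
            fold_maes.append(mae)
            rows.append({"grid_index": gi, "kind": kp.kind, "sigma": kp.sigma,
                         "lam": lam, "fold": fi, "mae": mae})
        means.append(float(np.mean(fold_maes)))
    table = pd.DataFrame(rows)
    best = grid[int(np.argmin(means))]
    return best, table
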