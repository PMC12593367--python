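"""Lattice-energy prediction by Gaussian process regression on a
precomputed structure kernel.

The normalized similarity kernel acts directly as the GP prior covariance —
there are no kernel hyperparameters to optimize.  Targets are *relative*
lattice energies,

    E_rel(x) = E(x) - min{ E(i) | i in training pool },

recomputed whenever the training pool changes so the reference is always the
training-set global minimum.  Fitting solves (K_train + alpha I) w = y_rel by
Cholesky factorization; prediction is K_cross @ w with a zero prior mean on
the relative energies.

Two evaluation protocols: a block-wise learning curve (training grown in
fixed-size random blocks against a fixed held-out test set) and k-fold
cross-validation, each reporting RMSE and MAE in kJ/mol.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .kernels import KernelMatrix


@dataclass
class GPRModel:
    """Fitted precomputed-kernel GP regressor."""

    train_indices: np.ndarray
    alpha: float
    dual_weights: np.ndarray
    y_reference: float          # training-pool minimum absolute energy
    prior_mean: float = 0.0


@dataclass
class ErrorReport:
    rmse: float
    mae: float
    n_train: int
    n_test: int
    rmse_sd: float | None = None
    mae_sd: float | None = None


def relative_energies(energies: Sequence[float]) -> np.ndarray:
    """Energies relative to the pool minimum (min of output is 0)."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("energy pool must be nonempty")
    return e - e.min()


def fit(
    K_train: np.ndarray,
    y_rel: np.ndarray,
    alpha: float = 1e-6,
    train_indices: Sequence[int] | None = None,
    y_reference: float = 0.0,
    prior_mean: float = 0.0,
) -> GPRModel:
    """Solve (K_train + alpha I) w = y_rel - prior_mean.

    ``alpha`` is the observation-noise variance in (kJ/mol)^2, which also
    regularizes the factorization.  Raises with a minimum-eigenvalue
    diagnostic if the regularized kernel is not positive definite.
    """
    K_train = np.asarray(K_train, dtype=float)
    y = np.asarray(y_rel, dtype=float) - prior_mean
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    A = K_train + alpha * np.eye(len(K_train))
    try:
        factor = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        lam_min = float(np.linalg.eigvalsh(K_train)[0])
        raise np.linalg.LinAlgError(
            f"kernel + alpha*I not positive definite "
            f"(min eigenvalue of kernel: {lam_min:.3e})") from exc
    w = cho_solve(factor, y)
    idx = np.arange(len(K_train)) if train_indices is None \
        else np.asarray(train_indices)
    return GPRModel(train_indices=idx, alpha=alpha, dual_weights=w,
                    y_reference=y_reference, prior_mean=prior_mean)


def predict(model: GPRModel, K_cross: np.ndarray) -> np.ndarray:
    """Predicted relative energies: K_cross @ dual_weights (+ prior mean).

    ``K_cross`` is the (n_test, n_train) kernel block with columns aligned
    with the model's training order.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != len(model.dual_weights):
        raise ValueError(
            f"K_cross has {K_cross.shape[1]} columns, expected "
            f"{len(model.dual_weights)}")
    return K_cross @ model.dual_weights + model.prior_mean


def _errors(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    resid = np.asarray(y_true) - np.asarray(y_pred)
    return float(np.sqrt(np.mean(resid ** 2))), float(np.mean(np.abs(resid)))


def learning_curve(
    K: KernelMatrix | np.ndarray,
    energies: Sequence[float],
    block_size: int = 500,
    test_size: int = 2000,
    alpha: float = 1e-6,
    seed: int = 0,
    max_blocks: int | None = None,
) -> list[ErrorReport]:
    """Block-wise learning curve against a fixed random test set.

    A test set of ``test_size`` structures is drawn at random; the remainder
    is split into random disjoint blocks of ``block_size``.  For each
    cumulative block count the training targets are set relative to the
    current training pool's minimum, the model is fit, and RMSE/MAE are
    evaluated on the fixed test set (whose targets use the same reference).
    """
    vals = K.values if isinstance(K, KernelMatrix) else np.asarray(K)
    e = np.asarray(energies, dtype=float)
    n = len(e)
    if test_size + 1 > n:
        raise ValueError("not enough structures for a training pool plus the test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = order[:test_size]
    pool = order[test_size:]
    n_blocks = len(pool) // block_size
    if max_blocks is not None:
        n_blocks = min(n_blocks, max_blocks)
    if n_blocks == 0:
        # block larger than the pool: a single point using the whole pool
        n_blocks = 1
        block_size = len(pool)
    reports: list[ErrorReport] = []
    for b in range(1, n_blocks + 1):
        train_idx = pool[: b * block_size]
        ref = e[train_idx].min()
        y_train = e[train_idx] - ref
        model = fit(vals[np.ix_(train_idx, train_idx)], y_train, alpha=alpha,
                    train_indices=train_idx, y_reference=float(ref))
        preds = predict(model, vals[np.ix_(test_idx, train_idx)])
        rmse, mae = _errors(e[test_idx] - ref, preds)
        reports.append(ErrorReport(rmse=rmse, mae=mae,
                                   n_train=len(train_idx), n_test=len(test_idx)))
    return reports


def cross_validate(
    K: KernelMatrix | np.ndarray,
    energies: Sequence[float],
    folds: int = 5,
    alpha: float = 1e-6,
    seed: int = 0,
) -> ErrorReport:
    """K-fold cross-validation with per-fold energy referencing.

    Each fold's model is trained afresh with targets relative to that
    training fold's global minimum.  Reports mean and standard deviation of
    RMSE and MAE over folds; every structure is tested exactly once.
    """
    vals = K.values if isinstance(K, KernelMatrix) else np.asarray(K)
    e = np.asarray(energies, dtype=float)
    n = len(e)
    if n < folds:
        raise ValueError("need at least as many structures as folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    rmses, maes = [], []
    for f in range(folds):
        test_idx = fold_ids[f]
        train_idx = np.concatenate([fold_ids[g] for g in range(folds) if g != f])
        ref = e[train_idx].min()
        model = fit(vals[np.ix_(train_idx, train_idx)], e[train_idx] - ref,
                    alpha=alpha, train_indices=train_idx, y_reference=float(ref))
        preds = predict(model, vals[np.ix_(test_idx, train_idx)])
        rmse, mae = _errors(e[test_idx] - ref, preds)
        rmses.append(rmse)
        maes.append(mae)
    return ErrorReport(
        rmse=float(np.mean(rmses)), mae=float(np.mean(maes)),
        n_train=n - len(fold_ids[0]), n_test=len(fold_ids[0]),
        rmse_sd=float(np.std(rmses, ddof=1)), mae_sd=float(np.std(maes, ddof=1)))


def energy_window_subset(
    energies: Sequence[float],
    window: float,
) -> np.ndarray:
    """Indices of structures within ``window`` kJ/mol of the global minimum.

    Used both to focus evaluation on the low-energy region of a landscape
    and as a preprocessing cutoff against unphysical high-energy structures.
    """
    e = np.asarray(energies, dtype=float)
    idx = np.where(e - e.min() <= window + 1e-12)[0]
    if idx.size == 0:
        raise ValueError("energy window excludes every structure")
    return idx
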