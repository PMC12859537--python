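"""Tuning-parameter selection for penalized logistic regression.

Three selectors are provided, all minimizing cross-validated (or
out-of-sample) binomial deviance over a shared descending lambda grid:

``standard_tune``
    plain k-fold cross-validation on the development data; the cv-training
    sets are a factor (k-1)/k smaller than the data the final model is fit
    on, which biases the selected lambda upward (too much shrinkage).

``modified_tune``
    the same k-fold machinery applied to a bootstrap *pseudo-dataset* of
    inflated size n_pseudo = round(n*k/(k-1)), so each cv-training set has
    the original size n; repeated B times and the B deviance curves
    averaged pointwise before taking the argmin.

``bootstrap_tune``
    fit the path on bootstrap resamples of size n and score each lambda's
    deviance on the original data, averaged over B resamples.

The lambda grid is computed once from the original development data so
curves are pointwise comparable across folds and resamples. Argmin ties
break toward the larger lambda (more shrinkage); since grids descend, this
is the first index. Duplicated bootstrap rows may land in both cv-training
and cv-test folds of a pseudo-dataset; that is inherent to the method and
not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .models import MAX_ITER, lambda_grid

#: gradient/KKT tolerance for the many path fits inside cross-validation
#: and resampling loops; the resulting deviance curves agree with fully
#: tight (1e-8) fits to ~1e-8, far below any Monte-Carlo noise, while the
#: final model refit at the selected lambda keeps the 1e-8 contract.
PATH_TOL = 1e-7

__all__ = [
    "TuningResult",
    "pseudo_size",
    "cv_deviance",
    "standard_tune",
    "modified_tune",
    "bootstrap_tune",
]

_FOLD_RETRIES = 10


@dataclass
class TuningResult:
    """Selected lambda together with the evidence behind the choice."""

    selected_lambda: float
    grid: np.ndarray
    mean_deviance: np.ndarray
    method: str
    form: str
    k_folds: int | None = None
    B: int | None = None
    repeats: int | None = None
    seed: int | None = None
    n_failed: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean_deviance = np.asarray(self.mean_deviance, dtype=float)
        if self.mean_deviance.shape != self.grid.shape:
            raise ValueError("mean_deviance and grid lengths differ")
        if not np.any(np.isclose(self.grid, self.selected_lambda)):
            raise ValueError("selected_lambda not on the grid")

    def to_frame(self) -> pd.DataFrame:
        """Grid + curve table, e.g. for tuning-parameter distribution plots."""
        return pd.DataFrame({
            "lambda": self.grid,
            "mean_deviance": self.mean_deviance,
            "selected": np.isclose(self.grid, self.selected_lambda),
        })


def pseudo_size(n: int, k: int) -> int:
    """Pseudo-dataset size n*k/(k-1), rounded to the nearest integer, such
    that k-fold cv-training sets on the pseudo-dataset have size ~n."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return int(round(n * k / (k - 1)))


def _draw_folds(y: np.ndarray, k: int, rng) -> np.ndarray:
    """Uniform random fold labels (not outcome-stratified); re-drawn up to
    a bounded number of times if some cv-training set is single-class."""
    n = y.shape[0]
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    for _ in range(_FOLD_RETRIES):
        fold = base[rng.permutation(n)]
        ok = True
        for f in range(k):
            tr = y[fold != f]
            if tr.min() == tr.max():
                ok = False
                break
        if ok:
            return fold
    raise ValueError(
        f"could not draw {k} folds with both classes in every cv-training set")


def cv_deviance(dataset, form: str, grid: np.ndarray, k: int, seed,
                fold_id: np.ndarray | None = None) -> np.ndarray:
    """k-fold cross-validated total binomial deviance per lambda, divided
    by n (so values are per-observation and comparable across sizes).

    Supports k = n (leave-one-out). Held-out probabilities are clipped away
    from 0/1 so the deviance stays finite. ``fold_id`` overrides the random
    fold assignment (used by the hand-rolled test oracles).
    """
    y = dataset.y
    n = dataset.n
    if not 2 <= k <= n:
        raise ValueError("k must satisfy 2 <= k <= n")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    grid = np.ascontiguousarray(grid, dtype=float)
    if fold_id is None:
        rng = np.random.default_rng(seed)
        fold_id = _draw_folds(y, k, rng)
    return _core.cv_deviance_kernel(
        dataset.X, y, grid, fold_id.astype(np.int64), k,
        form == "lasso", PATH_TOL, MAX_ITER,
    )


def _argmin_largest_lambda(curve: np.ndarray) -> int:
    """Index of the minimum; ties break toward the larger lambda, which is
    the earliest index on a descending grid."""
    return int(np.argmin(curve))


def _snap_to_grid(value: float, grid: np.ndarray) -> float:
    """Nearest grid element (log scale); ties toward the larger lambda."""
    d = np.abs(np.log(grid) - np.log(value))
    return float(grid[int(np.argmin(d))])


def standard_tune(dataset, form: str, k: int = 10, seed=0,
                  repeats: int = 1, grid: np.ndarray | None = None,
                  n_lambda: int = 100, ratio: float = 1e-4) -> TuningResult:
    """Standard k-fold cross-validation choice of lambda (argmin of the
    cv deviance). With ``repeats > 1`` the median of per-repeat argmin
    lambdas is selected (snapped back to the grid) and the reported curve
    is the average over repeats."""
    if grid is None:
        grid = lambda_grid(dataset, form, n_lambda, ratio)
    rng = np.random.default_rng(seed)
    curves = []
    picks = []
    for _ in range(repeats):
        fold_id = _draw_folds(dataset.y, k, rng)
        curve = cv_deviance(dataset, form, grid, k, None, fold_id=fold_id)
        curves.append(curve)
        picks.append(grid[_argmin_largest_lambda(curve)])
    mean_curve = np.mean(curves, axis=0)
    if repeats == 1:
        lam = picks[0]
    else:
        lam = _snap_to_grid(float(np.median(picks)), grid)
    return TuningResult(float(lam), grid, mean_curve, "standard", form,
                        k_folds=k, repeats=repeats,
                        seed=seed if isinstance(seed, int) else None)


def modified_tune(dataset, form: str, k: int = 10, B: int = 100, seed=0,
                  grid: np.ndarray | None = None, n_lambda: int = 100,
                  ratio: float = 1e-4) -> TuningResult:
    """Modified tuning: B bootstrap pseudo-datasets of size
    ``pseudo_size(n, k)``, each cross-validated with k folds over the
    common grid; lambda is the argmin of the pointwise average of the B
    deviance curves. The caller fits the final model on the *original*
    data at the selected lambda.

    Iterations whose folds cannot be drawn (single-class cv-training sets)
    are dropped and counted in ``n_failed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if grid is None:
        grid = lambda_grid(dataset, form, n_lambda, ratio)
    rng = np.random.default_rng(seed)
    n = dataset.n
    m = pseudo_size(n, k)
    curves = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, m)
        pseudo = dataset.subsample(idx)
        try:
            fold_id = _draw_folds(pseudo.y, k, rng)
        except ValueError:
            failed += 1
            continue
        curves.append(cv_deviance(pseudo, form, grid, k, None, fold_id=fold_id))
    if not curves:
        raise ValueError("all modified-tuning iterations failed")
    mean_curve = np.mean(curves, axis=0)
    lam = grid[_argmin_largest_lambda(mean_curve)]
    return TuningResult(float(lam), grid, mean_curve, "modified", form,
                        k_folds=k, B=B, n_failed=failed,
                        seed=seed if isinstance(seed, int) else None)


def bootstrap_tune(dataset, form: str, B: int = 100, seed=0,
                   grid: np.ndarray | None = None, n_lambda: int = 100,
                   ratio: float = 1e-4) -> TuningResult:
    """Bootstrap tuning: fit the path on bootstrap resamples of size n and
    score each lambda's deviance on the original data; lambda is the
    argmin of the average curve over B resamples."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if grid is None:
        grid = lambda_grid(dataset, form, n_lambda, ratio)
    grid = np.ascontiguousarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = dataset.n
    curves = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = dataset.subsample(idx)
        if boot.y.min() == boot.y.max():
            failed += 1
            continue
        curves.append(_core.path_deviance_kernel(
            boot.X, boot.y, dataset.X, dataset.y, grid,
            form == "lasso", PATH_TOL, MAX_ITER,
        ))
    if not curves:
        raise ValueError("all bootstrap-tuning resamples failed")
    mean_curve = np.mean(curves, axis=0)
    lam = grid[_argmin_largest_lambda(mean_curve)]
    return TuningResult(float(lam), grid, mean_curve, "bootstrap", form,
                        B=B, n_failed=failed,
                        seed=seed if isinstance(seed, int) else None)
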