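"""Model fitting: MLE, penalized likelihood (ridge/lasso), Firth's
bias-reduced logistic regression, and bootstrap uniform shrinkage.

The penalized objective is, on the training data of size n,

    (1/n) * l(beta) - lambda * s(beta)

with s the squared L2 norm (ridge) or L1 norm (lasso) of the slopes; the
intercept is never penalized and covariates are standardized internally
(mean 0, SD 1 with denominator n) before penalization, with coefficients
back-transformed to the original scale. This matches the convention of the
standard penalized-GLM software in the field, so lambda values are
comparable across sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _core

__all__ = [
    "FittedModel",
    "PenaltySpec",
    "fit_mle",
    "fit_penalized",
    "fit_penalized_path",
    "lambda_grid",
    "fit_firth",
    "bootstrap_uniform_shrinkage",
]

GRAD_TOL = 1e-8
MAX_ITER = 200
#: ridge has no finite all-zero lambda; its grid anchor is the lasso
#: lambda_max scaled by this constant (the convention of the reference
#: penalized-GLM software for near-zero L1 mixing)
RIDGE_ANCHOR = 1000.0
#: |standardized coefficient| beyond which an unpenalized fit is treated
#: as (quasi-)separated
SEPARATION_BOUND = 40.0


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty form ('ridge' or 'lasso') and tuning parameter lambda >= 0."""

    form: str
    lam: float

    def __post_init__(self):
        if self.form not in ("ridge", "lasso"):
            raise ValueError(f"unknown penalty form {self.form!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class FittedModel:
    """A fitted logistic risk model: intercept, slopes and provenance."""

    intercept: float
    coefs: np.ndarray
    method: str
    lam: float | None = None
    shrinkage_factor: float | None = None
    converged: bool = True
    columns: list = field(default=None)

    def __post_init__(self):
        self.coefs = np.asarray(self.coefs, dtype=float).ravel()
        if self.columns is None:
            self.columns = [f"x{j + 1}" for j in range(self.coefs.shape[0])]
        in_penalized = self.method in ("ridge", "lasso")
        if (self.lam is not None) != in_penalized:
            raise ValueError("lam must be present iff method is ridge/lasso")
        if (self.shrinkage_factor is not None) != (self.method == "boot_unif"):
            raise ValueError(
                "shrinkage_factor must be present iff method is boot_unif")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))

    # --- structured-text serialization for audit and reuse ---

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "lambda": self.lam,
                "shrinkage_factor": self.shrinkage_factor,
                "converged": self.converged,
                "intercept": self.intercept,
                "coefficients": dict(zip(self.columns, self.coefs.tolist())),
            },
            indent=2,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        cols = list(d["coefficients"])
        return cls(
            intercept=d["intercept"],
            coefs=np.array([d["coefficients"][c] for c in cols]),
            method=d["method"],
            lam=d.get("lambda"),
            shrinkage_factor=d.get("shrinkage_factor"),
            converged=d.get("converged", True),
            columns=cols,
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")


def fit_mle(dataset) -> FittedModel:
    """Maximum-likelihood logistic regression.

    Flags (``converged=False``) non-convergence or coefficients diverging
    toward a separated configuration instead of raising, so simulation
    loops can count and exclude such replicates.
    """
    X, y = dataset.X, dataset.y
    _check_two_classes(y)
    Xs, mean, sd = _core.standardize(X)
    if np.any(sd == 0.0):
        raise ValueError("constant covariate column")
    n, p = Xs.shape
    A = np.hstack([np.ones((n, 1)), Xs])
    beta = np.zeros(p + 1)
    beta[0] = float(np.log(y.mean() / (1 - y.mean())))
    ok, _ = _core.newton_penalized(
        A, y, np.zeros(n), np.zeros(p + 1), beta, GRAD_TOL, MAX_ITER
    )
    if np.max(np.abs(beta[1:])) > SEPARATION_BOUND:
        ok = False
    coefs = beta[1:] / sd
    intercept = beta[0] - float(coefs @ mean)
    return FittedModel(intercept, coefs, "mle", converged=bool(ok),
                       columns=list(dataset.columns))


def fit_penalized(dataset, penalty: PenaltySpec) -> FittedModel:
    """Ridge or lasso logistic regression at a fixed lambda.

    At ``lam=0`` this reproduces the MLE. Lasso coefficients can be exactly
    zero (coordinate-descent soft thresholding).
    """
    X, y = dataset.X, dataset.y
    _check_two_classes(y)
    if np.any(X.std(axis=0) == 0.0):
        raise ValueError("constant covariate column")
    lams = np.array([penalty.lam], dtype=float)
    intercepts, coefs, conv = _core.fit_path(
        X, y, lams, penalty.form == "lasso", GRAD_TOL, MAX_ITER
    )
    ok = bool(conv[0])
    if penalty.lam == 0.0 and np.max(np.abs(coefs[0] * X.std(axis=0))) > SEPARATION_BOUND:
        ok = False
    return FittedModel(float(intercepts[0]), coefs[0], penalty.form,
                       lam=float(penalty.lam), converged=ok,
                       columns=list(dataset.columns))


def fit_penalized_path(dataset, form: str, grid: np.ndarray):
    """Fit the whole descending-lambda path on the dataset.

    Returns ``(intercepts, coefs, converged)`` arrays of shape (L,), (L,p),
    (L,). Used by the tuning module; ``fit_penalized`` is the single-lambda
    convenience wrapper.
    """
    _check_two_classes(dataset.y)
    grid = np.asarray(grid, dtype=float)
    return _core.fit_path(dataset.X, dataset.y, grid,
                          form == "lasso", GRAD_TOL, MAX_ITER)


def lambda_grid(dataset, form: str, n_lambda: int = 100,
                ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced lambda sequence anchored at lambda_max.

    For the lasso the first element is the smallest lambda at which all
    penalized coefficients are exactly zero (the max absolute score of the
    standardized covariates at the null model); for ridge the anchor is
    that value scaled by ``RIDGE_ANCHOR``.
    """
    if form not in ("ridge", "lasso"):
        raise ValueError(f"unknown penalty form {form!r}")
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    X, y = dataset.X, dataset.y
    _check_two_classes(y)
    if np.any(X.std(axis=0) == 0.0):
        raise ValueError("constant covariate column")
    lmax = float(_core.lasso_lambda_max(X, y))
    if lmax <= 0.0:
        raise ValueError("degenerate dataset: null-model score is zero")
    if form == "ridge":
        lmax *= RIDGE_ANCHOR
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * ratio), n_lambda))


def _firth_penalized_loglik(X1: np.ndarray, y: np.ndarray,
                            beta: np.ndarray) -> float:
    eta = X1 @ beta
    prob = expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    W = prob * (1.0 - prob)
    info = X1.T @ (X1 * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(dataset, tol: float = 1e-6, max_iter: int = 100) -> FittedModel:
    """Firth's bias-reduced logistic regression with intercept correction.

    Maximizes l(beta) + 0.5*log det I(beta) by modified-score iteration
    (Newton steps on the score adjusted by the hat diagonal, with
    step-halving on the penalized likelihood). Estimates stay finite under
    separation. Afterwards the intercept alone is re-estimated by ML with
    the slope part of the linear predictor as a fixed offset, so the mean
    predicted probability equals the observed event fraction.
    """
    X, y = dataset.X, dataset.y
    _check_two_classes(y)
    n, p = X.shape
    X1 = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    beta[0] = float(np.log(y.mean() / (1 - y.mean())))
    pll = _firth_penalized_loglik(X1, y, beta)
    ok = False
    for _ in range(max_iter):
        prob = expit(X1 @ beta)
        W = prob * (1.0 - prob)
        XW = X1 * W[:, None]
        info = X1.T @ XW
        # hat diagonal of W^(1/2) X (X'WX)^(-1) X' W^(1/2)
        h = np.einsum("ij,ij->i", X1 @ np.linalg.inv(info), XW)
        score = X1.T @ (y - prob + h * (0.5 - prob))
        if np.max(np.abs(score)) < tol:
            ok = True
            break
        step = np.linalg.solve(info, score)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            pll_c = _firth_penalized_loglik(X1, y, cand)
            if pll_c >= pll - 1e-12:
                beta, pll = cand, pll_c
                break
            t *= 0.5
        else:  # no ascent step found; treat as converged-to-tolerance
            break
    coefs = beta[1:]
    intercept = _reestimate_intercept(X @ coefs, y)
    return FittedModel(float(intercept), coefs, "firth", converged=bool(ok),
                       columns=list(dataset.columns))


def _reestimate_intercept(offset: np.ndarray, y: np.ndarray) -> float:
    """ML intercept with a fixed offset; makes mean predicted probability
    equal the event fraction (the intercept score equation)."""
    n = y.shape[0]
    A = np.ones((n, 1))
    beta = np.array([float(np.log(y.mean() / (1 - y.mean())))])
    ok, _ = _core.newton_penalized(
        A, np.asarray(y, float), np.asarray(offset, float),
        np.zeros(1), beta, 1e-10, 100
    )
    return float(beta[0])


def bootstrap_uniform_shrinkage(dataset, n_boot: int = 200,
                                seed=0) -> FittedModel:
    """Uniform (linear) shrinkage with a bootstrap shrinkage factor.

    For each bootstrap resample of the development data, the MLE model is
    refitted and its calibration slope on the *original* data computed; the
    average of those slopes is the shrinkage factor applied to the original
    MLE slopes. The intercept is then re-estimated so the mean predicted
    probability equals the outcome prevalence. Failed resample fits are
    skipped (aborts if more than half fail).
    """
    base = fit_mle(dataset)
    if not base.converged:
        raise ValueError("MLE failed on the original data; cannot apply "
                         "uniform shrinkage")
    rng = np.random.default_rng(seed)
    n = dataset.n
    slopes = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = dataset.subsample(idx)
        if boot.y.min() == boot.y.max():
            failed += 1
            continue
        m = fit_mle(boot)
        if not m.converged:
            failed += 1
            continue
        lp = m.linear_predictor(dataset.X)
        slope = _calibration_slope_fit(dataset.y, lp)
        if slope is None:
            failed += 1
            continue
        slopes.append(slope)
    if failed > n_boot / 2:
        raise ValueError(
            f"{failed}/{n_boot} bootstrap resamples failed to fit")
    factor = float(np.mean(slopes))
    coefs = base.coefs * factor
    intercept = _reestimate_intercept(dataset.X @ coefs, dataset.y)
    return FittedModel(intercept, coefs, "boot_unif",
                       shrinkage_factor=factor,
                       columns=list(dataset.columns))


def _calibration_slope_fit(y: np.ndarray, lp: np.ndarray) -> float | None:
    """Slope of the logistic recalibration fit of y on lp; None when lp is
    (numerically) constant or the fit diverges."""
    if np.ptp(lp) < 1e-12:
        return None
    n = lp.shape[0]
    lp = np.asarray(lp, dtype=float)
    m, s = lp.mean(), lp.std()
    A = np.column_stack([np.ones(n), (lp - m) / s])
    beta = np.array([float(np.log(y.mean() / (1 - y.mean()))), 0.0])
    ok, _ = _core.newton_penalized(
        A, np.asarray(y, float), np.zeros(n), np.zeros(2), beta, 1e-10, 100
    )
    if not ok or abs(beta[1]) > SEPARATION_BOUND:
        return None
    return float(beta[1] / s)
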