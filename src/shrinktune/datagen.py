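"""Synthetic development/validation data for risk-model simulation studies.

Covariates are multivariate normal with mean zero, unit variances and a
block correlation structure: a block of "true" predictors (non-zero
coefficients) with pairwise correlation ``r_true``, a block of noise
predictors with pairwise correlation ``r_noise``, and cross-block
correlation ``r_cross`` (0 by default). The binary outcome follows a
logistic model

    y_i ~ Bernoulli(pi_i),   pi_i = expit(beta0 + (k * base_coefs)' x_i)

where the intercept ``beta0`` sets the outcome prevalence and the scalar
multiplier ``k`` scales the slope vector to hit a target C-statistic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "Scenario",
    "Dataset",
    "build_correlation_matrix",
    "generate_dataset",
    "calibrate_dgm",
    "main_scenario",
]

#: slope pattern of the main simulation scenario (5 true + 7 noise predictors)
MAIN_BASE_COEFS = (0.5, 0.3, 0.3, 0.25, 0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def build_correlation_matrix(
    p_true: int,
    p_noise: int,
    r_true: float,
    r_noise: float,
    r_cross: float = 0.0,
) -> np.ndarray:
    """Assemble the block correlation matrix of the covariate distribution.

    Unit diagonal; ``r_true`` within the leading ``p_true`` block,
    ``r_noise`` within the trailing ``p_noise`` block, ``r_cross`` between
    blocks. Raises ``ValueError`` if the result is not positive definite.
    """
    if p_true < 0 or p_noise < 0 or p_true + p_noise == 0:
        raise ValueError("need at least one predictor")
    for name, r in (("r_true", r_true), ("r_noise", r_noise), ("r_cross", r_cross)):
        if not abs(r) < 1.0:
            raise ValueError(f"{name}={r} must satisfy |r| < 1")
    p = p_true + p_noise
    sigma = np.empty((p, p))
    sigma[:p_true, :p_true] = r_true
    sigma[p_true:, p_true:] = r_noise
    sigma[:p_true, p_true:] = r_cross
    sigma[p_true:, :p_true] = r_cross
    np.fill_diagonal(sigma, 1.0)
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] <= 1e-12:
        raise ValueError(
            "correlation structure is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.3e}); "
            f"r_true={r_true}, r_noise={r_noise}, r_cross={r_cross}"
        )
    return sigma


@dataclass(frozen=True)
class Scenario:
    """Full specification of a data-generating mechanism."""

    p_true: int = 5
    p_noise: int = 7
    base_coefs: tuple = MAIN_BASE_COEFS
    k: float = 1.0
    beta0: float = 0.0
    r_true: float = 0.1
    r_noise: float = 0.05
    r_cross: float = 0.0
    target_prevalence: float = 0.5
    target_c: float = 0.7

    def __post_init__(self):
        base = np.asarray(self.base_coefs, dtype=float)
        p = self.p_true + self.p_noise
        if base.shape != (p,):
            raise ValueError(
                f"base_coefs has length {base.shape[0]}, expected p_true+p_noise={p}"
            )
        if self.p_noise and not np.all(base[self.p_true:] == 0.0):
            raise ValueError("base_coefs must have exactly p_noise trailing zeros")
        if np.any(base[: self.p_true] == 0.0):
            raise ValueError("true-predictor base coefficients must be non-zero")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0,1)")
        if not 0.5 < self.target_c < 1.0:
            raise ValueError("target_c must lie in (0.5,1)")
        # validates positive definiteness eagerly
        build_correlation_matrix(
            self.p_true, self.p_noise, self.r_true, self.r_noise, self.r_cross
        )

    @property
    def p(self) -> int:
        return self.p_true + self.p_noise

    @property
    def coefs(self) -> np.ndarray:
        """Slope vector k * base_coefs."""
        return self.k * np.asarray(self.base_coefs, dtype=float)

    def correlation_matrix(self) -> np.ndarray:
        return build_correlation_matrix(
            self.p_true, self.p_noise, self.r_true, self.r_noise, self.r_cross
        )

    def replace(self, **kwargs) -> "Scenario":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_coefs"] = list(d["base_coefs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if "base_coefs" in d:
            d["base_coefs"] = tuple(d["base_coefs"])
        return cls(**d)


def main_scenario(k: float = 0.93, beta0: float = 0.0) -> Scenario:
    """The primary simulation scenario: C = 0.7, prevalence = 0.5,
    5 true + 7 noise predictors, correlations 0.1 / 0.05."""
    return Scenario(k=k, beta0=beta0)


@dataclass
class Dataset:
    """A development or validation sample with known truth."""

    X: np.ndarray
    y: np.ndarray
    true_prob: np.ndarray | None = None
    seed: int | None = None
    columns: list = field(default=None)

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("y must be binary 0/1")
        if self.true_prob is not None:
            self.true_prob = np.asarray(self.true_prob, dtype=float).ravel()
            if self.true_prob.shape[0] != self.y.shape[0]:
                raise ValueError("true_prob length differs from y")
        if self.columns is None:
            self.columns = [f"x{j + 1}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subsample(self, idx: np.ndarray, seed: int | None = None) -> "Dataset":
        """Row-indexed copy (used for bootstrap resampling)."""
        tp = None if self.true_prob is None else self.true_prob[idx]
        return Dataset(self.X[idx], self.y[idx], tp, seed, list(self.columns))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "y", self.y.astype(int))
        if self.true_prob is not None:
            df["true_prob"] = self.true_prob
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome: str = "y") -> "Dataset":
        if outcome not in df.columns:
            raise ValueError(f"outcome column {outcome!r} not found")
        tp = df["true_prob"].to_numpy() if "true_prob" in df.columns else None
        xcols = [c for c in df.columns if c not in (outcome, "true_prob")]
        return cls(df[xcols].to_numpy(float), df[outcome].to_numpy(float), tp,
                   columns=xcols)

    @classmethod
    def from_csv(cls, path, outcome: str = "y") -> "Dataset":
        return cls.from_frame(pd.read_csv(path), outcome=outcome)


def generate_dataset(scenario: Scenario, n: int, seed) -> Dataset:
    """Draw a dataset of size ``n`` from the scenario's mechanism.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; a given seed
    always reproduces the same dataset bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(scenario.correlation_matrix())
    X = rng.standard_normal((n, scenario.p)) @ chol.T
    eta = scenario.beta0 + X @ scenario.coefs
    prob = expit(eta)
    y = (rng.random(n) < prob).astype(float)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return Dataset(X, y, true_prob=prob, seed=seed_val)


def _c_statistic_fast(y: np.ndarray, score: np.ndarray) -> float:
    """Rank-based C-statistic (ties counted 1/2); local copy to avoid an
    import cycle with the validation module."""
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    ranks = rankdata(score)
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def calibrate_dgm(
    scenario: Scenario,
    n_calib: int = 500_000,
    seed=0,
    tol: float = 0.005,
    max_cycles: int = 8,
    k_bracket: tuple = (0.01, 10.0),
    beta0_bracket: tuple = (-10.0, 10.0),
) -> tuple:
    """Solve for (beta0, k) hitting the scenario's target prevalence and
    C-statistic.

    Uses one large Monte-Carlo sample with common random numbers: the
    covariate draw ``X`` and the uniform variates behind the Bernoulli
    outcomes are fixed, so prevalence is monotone increasing and smooth in
    beta0, and the C-statistic monotone increasing in k; each is solved by
    Brent's method, alternating until both targets are met within ``tol``.

    Returns ``(beta0, k)``.
    """
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(scenario.correlation_matrix())
    X = rng.standard_normal((n_calib, scenario.p)) @ chol.T
    u = rng.random(n_calib)
    base = np.asarray(scenario.base_coefs, dtype=float)
    lp_base = X @ base  # linear predictor at k=1, before scaling

    phi_t = scenario.target_prevalence
    c_t = scenario.target_c
    # the C-statistic only needs the ranks of the linear predictor, which
    # are invariant to (beta0, k) for k > 0 — compute once
    ranks = rankdata(lp_base)

    def prevalence(beta0, k):
        return float(expit(beta0 + k * lp_base).mean())

    def c_stat(beta0, k):
        prob = expit(beta0 + k * lp_base)
        y = u < prob
        n1 = int(y.sum())
        n0 = n_calib - n1
        if n1 == 0 or n0 == 0:
            return 0.5
        return (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    beta0, k = 0.0, 1.0
    for _ in range(max_cycles):
        # prevalence step (monotone increasing in beta0)
        f = lambda b0: prevalence(b0, k) - phi_t
        lo, hi = beta0_bracket
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError(
                "cannot bracket beta0: achievable prevalence range is "
                f"[{prevalence(lo, k):.4f}, {prevalence(hi, k):.4f}] "
                f"for target {phi_t}"
            )
        beta0 = brentq(f, lo, hi, xtol=1e-4)
        # C-statistic step (monotone increasing in k)
        g = lambda kk: c_stat(beta0, kk) - c_t
        klo, khi = k_bracket
        if g(klo) > 0 or g(khi) < 0:
            raise ValueError(
                "cannot bracket k: achievable C-statistic range is "
                f"[{c_stat(beta0, klo):.4f}, {c_stat(beta0, khi):.4f}] "
                f"for target {c_t}"
            )
        k = brentq(g, klo, khi, xtol=1e-4)
        if (abs(prevalence(beta0, k) - phi_t) < tol
                and abs(c_stat(beta0, k) - c_t) < tol):
            break
    return float(beta0), float(k)
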