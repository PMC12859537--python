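"""Validation metrics for risk models and across-replicate summaries.

Per-model metrics on a validation draw: calibration slope (CS; logistic
refit of the outcome on the model's linear predictor — 1 is perfect, <1
indicates overfitting), calibration in-the-large (intercept of the refit
with the linear predictor as a fixed offset), C-statistic, Brier score and
RMSPE against the known true event probabilities.

Across simulation replicates: RMSD(log-CS) (root mean square distance of
log CS from log target, combining bias and variability), the proportion of
replicates with CS in [0.9, 1.1] ("well-calibrated"), and paired
head-to-head win proportions against a reference method.

Degenerate models (constant linear predictor, e.g. a lasso fit shrunk to
intercept-only) have an undefined CS: it is reported missing, counted as
*not* well-calibrated, and excluded from RMSD(log-CS) with the count
reported, so no replicate disappears silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import _core
from .models import SEPARATION_BOUND

__all__ = [
    "ValidationMetrics",
    "calibration_slope",
    "calibration_in_the_large",
    "c_statistic",
    "brier",
    "rmspe",
    "rmsd_log_cs",
    "p_well_cal",
    "head_to_head",
    "validate_model",
    "summarize",
]


@dataclass
class ValidationMetrics:
    cal_slope: float | None
    cal_in_large: float | None
    c_statistic: float
    brier: float
    rmspe: float | None

    def as_dict(self) -> dict:
        return {
            "cs": np.nan if self.cal_slope is None else self.cal_slope,
            "citl": np.nan if self.cal_in_large is None else self.cal_in_large,
            "c": self.c_statistic,
            "brier": self.brier,
            "rmspe": np.nan if self.rmspe is None else self.rmspe,
        }


def _check_binary_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("both outcome classes required")
    return y


def calibration_slope(y, lp) -> float | None:
    """Slope of the logistic recalibration model of y on the linear
    predictor. ``None`` for a constant lp (range < 1e-12) or when the
    recalibration fit itself fails/separates."""
    y = _check_binary_two_class(y)
    lp = np.asarray(lp, dtype=float).ravel()
    if np.ptp(lp) < 1e-12:
        return None
    m, s = lp.mean(), lp.std()
    n = lp.shape[0]
    A = np.column_stack([np.ones(n), (lp - m) / s])
    beta = np.array([float(np.log(y.mean() / (1 - y.mean()))), 0.0])
    ok, _ = _core.newton_penalized(A, y, np.zeros(n), np.zeros(2), beta,
                                   1e-10, 100)
    if not ok or abs(beta[1]) > SEPARATION_BOUND:
        return None
    return float(beta[1] / s)


def calibration_in_the_large(y, lp) -> float:
    """Intercept of the logistic fit of y with lp as a fixed offset
    (slope pinned at one). Zero means mean predicted risk equals the
    observed event rate."""
    y = _check_binary_two_class(y)
    lp = np.asarray(lp, dtype=float).ravel()
    n = lp.shape[0]
    A = np.ones((n, 1))
    beta = np.zeros(1)
    ok, _ = _core.newton_penalized(A, y, lp, np.zeros(1), beta, 1e-10, 100)
    if not ok:
        raise RuntimeError("calibration-in-the-large fit did not converge")
    return float(beta[0])


def c_statistic(y, p) -> float:
    """Probability that an event carries a higher prediction than a
    non-event, ties counted 1/2; computed from ranks (equivalent to the
    all-pairs definition)."""
    y = _check_binary_two_class(y)
    p = np.asarray(p, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def brier(y, p) -> float:
    """Mean squared difference between outcome and predicted probability."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must lie in [0,1]")
    return float(np.mean((y - p) ** 2))


def rmspe(true_p, est_p) -> float:
    """Root mean square difference between true and estimated event
    probabilities."""
    true_p = np.asarray(true_p, dtype=float).ravel()
    est_p = np.asarray(est_p, dtype=float).ravel()
    if true_p.shape != est_p.shape:
        raise ValueError("probability vectors differ in length")
    return float(np.sqrt(np.mean((true_p - est_p) ** 2)))


def rmsd_log_cs(cs_values, target: float = 1.0) -> float:
    """Root mean square distance of log CS from log target across
    replicates. NaN entries (degenerate replicates) must be excluded by
    the caller; they raise here."""
    cs = np.asarray(cs_values, dtype=float).ravel()
    if cs.size == 0:
        raise ValueError("empty CS vector")
    if np.any(~np.isfinite(cs)) or np.any(cs <= 0):
        raise ValueError("CS values must be finite and positive; filter "
                         "degenerate replicates upstream")
    return float(np.sqrt(np.mean((np.log(cs) - np.log(target)) ** 2)))


def p_well_cal(cs_values, lo: float = 0.9, hi: float = 1.1) -> float:
    """Proportion of replicates with CS in [lo, hi] (inclusive). Missing
    (NaN) CS counts as not well-calibrated."""
    cs = np.asarray(cs_values, dtype=float).ravel()
    if cs.size == 0:
        raise ValueError("empty CS vector")
    with np.errstate(invalid="ignore"):
        inside = (cs >= lo) & (cs <= hi)
    return float(np.mean(np.where(np.isnan(cs), False, inside)))


def head_to_head(metric_a, metric_b, better: str = "smaller") -> float:
    """Proportion of paired replicates where method a beats method b.

    ``better`` is "smaller" or "larger"; ties count as no win. NaN in
    either member of a pair counts as no win for a.
    """
    a = np.asarray(metric_a, dtype=float).ravel()
    b = np.asarray(metric_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    if a.size == 0:
        raise ValueError("empty vectors")
    with np.errstate(invalid="ignore"):
        wins = a < b if better == "smaller" else a > b
    wins = np.where(np.isnan(a) | np.isnan(b), False, wins)
    return float(np.mean(wins))


def validate_model(model, dataset) -> ValidationMetrics:
    """All per-model metrics of ``model`` on a validation ``dataset``.

    RMSPE needs the dataset's true event probabilities and is ``None``
    when they are unknown.
    """
    lp = model.linear_predictor(dataset.X)
    p = model.predict_proba(dataset.X)
    cs = calibration_slope(dataset.y, lp)
    citl = calibration_in_the_large(dataset.y, lp)
    c = c_statistic(dataset.y, p)
    b = brier(dataset.y, p)
    r = None if dataset.true_prob is None else rmspe(dataset.true_prob, p)
    return ValidationMetrics(cs, citl, c, b, r)


_ABS_LOG_CS = "abs_log_cs"


def summarize(per_replicate: pd.DataFrame, reference: str = "mle",
              target_cs: float = 1.0) -> pd.DataFrame:
    """Across-replicate summary of a per-replicate metrics table.

    Expects columns: method, replicate, cs, citl, c, brier, rmspe. Returns
    one row per method with medians, RMSD(log-CS), p_well_cal,
    n_degenerate, and (where the reference method is present) paired win
    proportions: better-calibrated (|log CS| smaller), higher C-statistic,
    lower RMSPE.
    """
    rows = []
    ref = None
    if reference in set(per_replicate["method"]):
        ref = (per_replicate[per_replicate["method"] == reference]
               .set_index("replicate"))
    for method, g in per_replicate.groupby("method", sort=False):
        g = g.set_index("replicate")
        cs = g["cs"].to_numpy()
        ok = np.isfinite(cs) & (cs > 0)
        row = {
            "method": method,
            "n_replicates": len(g),
            "n_degenerate": int((~ok).sum()),
            "median_cs": float(np.nanmedian(cs)) if ok.any() else np.nan,
            "median_citl": float(np.nanmedian(g["citl"])),
            "median_c": float(np.nanmedian(g["c"])),
            "median_brier": float(np.nanmedian(g["brier"])),
            "median_rmspe": float(np.nanmedian(g["rmspe"])),
            "rmsd_log_cs": (rmsd_log_cs(cs[ok], target_cs)
                            if ok.any() else np.nan),
            "p_well_cal": p_well_cal(cs),
        }
        if ref is not None and method != reference:
            common = g.index.intersection(ref.index)
            gc, rc = g.loc[common], ref.loc[common]
            with np.errstate(invalid="ignore"):
                a = np.abs(np.log(gc["cs"].to_numpy()))
                b = np.abs(np.log(rc["cs"].to_numpy()))
            row["win_cal_vs_ref"] = head_to_head(a, b, "smaller")
            row["win_c_vs_ref"] = head_to_head(
                gc["c"].to_numpy(), rc["c"].to_numpy(), "larger")
            row["win_rmspe_vs_ref"] = head_to_head(
                gc["rmspe"].to_numpy(), rc["rmspe"].to_numpy(), "smaller")
        else:
            row["win_cal_vs_ref"] = np.nan
            row["win_c_vs_ref"] = np.nan
            row["win_rmspe_vs_ref"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
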