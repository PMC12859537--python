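"""Simulation-study orchestration: replicate loops over scenario x sample
size x method, the simulation-based recommended-sample-size search, and
the cross-validation folds sensitivity analysis.

Reproducibility: every replicate derives its seeds from
``SeedSequence([master_seed, replicate_index])`` — dev draw, validation
draw and one stream per method (in a fixed canonical order, so results do
not depend on which method subset is requested or on parallel worker
count).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .datagen import Scenario, generate_dataset
from .models import (
    PenaltySpec,
    bootstrap_uniform_shrinkage,
    fit_firth,
    fit_mle,
    fit_penalized,
)
from .tuning import bootstrap_tune, modified_tune, standard_tune
from .validation import summarize, validate_model

__all__ = [
    "RunConfig",
    "METHODS",
    "run_replicate",
    "run_scenario",
    "find_recommended_n",
    "folds_sensitivity",
]

#: canonical method order (fixes each method's seed stream)
METHODS = (
    "mle", "firth", "boot_unif", "ridge", "lasso",
    "mod_ridge", "mod_lasso", "boot_ridge", "boot_lasso",
)

#: CSV float formatting (10 significant digits) so re-runs with the same
#: master seed reproduce output files byte for byte
FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    scenario: Scenario = field(default_factory=Scenario)
    sample_sizes: tuple = (900,)
    methods: tuple = ("mle",)
    nsim: int = 1000
    nval: int = 50_000
    k_folds: int = 10
    B: int = 100
    repeats: int = 1
    n_boot: int = 200
    n_lambda: int = 100
    lambda_ratio: float = 1e-4
    master_seed: int = 0
    output_dir: str | None = None
    n_jobs: int = 1

    def __post_init__(self):
        if self.nsim < 1:
            raise ValueError("nsim must be >= 1")
        if self.nval < 1000:
            raise ValueError("nval must be >= 1000")
        if not self.methods:
            raise ValueError("methods must be nonempty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        from . import __version__

        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict()
        for key in ("sample_sizes", "methods"):
            d[key] = list(d[key])
        d["shrinktune_version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("shrinktune_version", None)
        if "scenario" in d and isinstance(d["scenario"], dict):
            d["scenario"] = Scenario.from_dict(d["scenario"])
        for key in ("sample_sizes", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _seed_int(ss: np.random.SeedSequence) -> int:
    """Collapse a SeedSequence to a plain int below 2**31."""
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _replicate_seeds(master_seed: int, replicate: int):
    """(dev_ss, val_ss, {method: int_seed}) for one replicate."""
    root = np.random.SeedSequence([int(master_seed), int(replicate)])
    children = root.spawn(2 + len(METHODS))
    dev_ss, val_ss = children[0], children[1]
    method_seeds = {m: _seed_int(children[2 + i])
                    for i, m in enumerate(METHODS)}
    return dev_ss, val_ss, method_seeds


def _fit_method(method: str, dev, cfg: RunConfig, seed: int):
    """Fit one method on a development dataset; returns (model, lam)."""
    if method == "mle":
        return fit_mle(dev), None
    if method == "firth":
        return fit_firth(dev), None
    if method == "boot_unif":
        return bootstrap_uniform_shrinkage(dev, cfg.n_boot, seed), None
    form = "ridge" if method.endswith("ridge") else "lasso"
    kwargs = dict(n_lambda=cfg.n_lambda, ratio=cfg.lambda_ratio)
    if method in ("ridge", "lasso"):
        tr = standard_tune(dev, form, k=cfg.k_folds, seed=seed,
                           repeats=cfg.repeats, **kwargs)
    elif method.startswith("mod_"):
        tr = modified_tune(dev, form, k=cfg.k_folds, B=cfg.B, seed=seed,
                           **kwargs)
    else:  # boot_ridge / boot_lasso
        tr = bootstrap_tune(dev, form, B=cfg.B, seed=seed, **kwargs)
    model = fit_penalized(dev, PenaltySpec(form, tr.selected_lambda))
    return model, tr.selected_lambda


def run_replicate(cfg: RunConfig, n: int, replicate: int) -> list:
    """All requested methods on one replicate; one metrics dict per method.

    Per-method failures (separation and the like) are recorded as rows
    with NaN metrics rather than raised, so a long run never aborts.
    """
    dev_ss, val_ss, method_seeds = _replicate_seeds(cfg.master_seed, replicate)
    dev = generate_dataset(cfg.scenario, n, dev_ss)
    val = generate_dataset(cfg.scenario, cfg.nval, val_ss)
    rows = []
    for method in METHODS:
        if method not in cfg.methods:
            continue
        row = {"method": method, "n": n, "replicate": replicate,
               "lambda": np.nan, "shrinkage_factor": np.nan,
               "converged": True, "cs": np.nan, "citl": np.nan,
               "c": np.nan, "brier": np.nan, "rmspe": np.nan}
        try:
            model, lam = _fit_method(method, dev, cfg, method_seeds[method])
            row["converged"] = bool(model.converged)
            if lam is not None:
                row["lambda"] = lam
            if model.shrinkage_factor is not None:
                row["shrinkage_factor"] = model.shrinkage_factor
            if model.converged:
                row.update(validate_model(model, val).as_dict())
        except ValueError:
            row["converged"] = False
        rows.append(row)
    return rows


def run_scenario(cfg: RunConfig):
    """Full simulation: nsim replicates per sample size, all methods.

    Returns ``(per_replicate, summary)`` DataFrames; when
    ``cfg.output_dir`` is set also writes ``replicates.csv``,
    ``summary.csv``, ``selected_lambda.csv`` and ``run.yaml`` there.
    """
    jobs = [(n, r) for n in cfg.sample_sizes for r in range(cfg.nsim)]
    if cfg.n_jobs == 1:
        results = [run_replicate(cfg, n, r) for n, r in jobs]
    else:
        results = Parallel(n_jobs=cfg.n_jobs)(
            delayed(run_replicate)(cfg, n, r) for n, r in jobs)
    per_replicate = pd.DataFrame([row for rows in results for row in rows])
    summaries = []
    for n in cfg.sample_sizes:
        s = summarize(per_replicate[per_replicate["n"] == n])
        s.insert(1, "n", n)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_replicate.to_csv(out / "replicates.csv", index=False,
                             float_format=FLOAT_FMT)
        summary.to_csv(out / "summary.csv", index=False,
                       float_format=FLOAT_FMT)
        lam = per_replicate.dropna(subset=["lambda"])
        lam[["method", "n", "replicate", "lambda"]].to_csv(
            out / "selected_lambda.csv", index=False, float_format=FLOAT_FMT)
        cfg.to_yaml(out / "run.yaml")
    return per_replicate, summary


def _median_cs_at_n(scenario: Scenario, n: int, nsim: int, nval: int,
                    master_seed: int) -> float:
    """Median validation calibration slope of MLE over nsim replicates.

    Replicate seeds depend only on (master_seed, replicate), so different
    candidate n values share random numbers — the search curve in n is
    smooth apart from the new observations."""
    cfg = RunConfig(scenario=scenario, sample_sizes=(n,), methods=("mle",),
                    nsim=nsim, nval=nval, master_seed=master_seed)
    per_rep, _ = run_scenario(cfg)
    return float(np.nanmedian(per_rep["cs"]))


def find_recommended_n(scenario: Scenario, target_cs: float = 0.9,
                       nsim: int = 300, seed: int = 0,
                       bracket: tuple = (200, 3200), step: int = 10,
                       nval: int = 10_000) -> int:
    """Smallest development size n (rounded to ``step``) at which the
    median validation calibration slope of MLE reaches ``target_cs``.

    Bisection over ``bracket``; the median CS is monotone increasing in n
    (larger samples overfit less). Raises with the achieved range when the
    bracket does not straddle the target.
    """
    if not 0.0 < target_cs < 1.0:
        raise ValueError("target_cs must lie in (0,1)")
    lo, hi = bracket
    med_lo = _median_cs_at_n(scenario, lo, nsim, nval, seed)
    med_hi = _median_cs_at_n(scenario, hi, nsim, nval, seed)
    if not med_lo < target_cs <= med_hi:
        raise ValueError(
            f"bracket {bracket} does not straddle target {target_cs}: "
            f"median CS range [{med_lo:.3f}, {med_hi:.3f}]")
    while hi - lo > step:
        mid = int(round((lo + hi) / 2 / step) * step)
        if mid in (lo, hi):
            break
        if _median_cs_at_n(scenario, mid, nsim, nval, seed) >= target_cs:
            hi = mid
        else:
            lo = mid
    return hi


def folds_sensitivity(cfg: RunConfig, fold_list,
                      forms=("ridge", "lasso")) -> pd.DataFrame:
    """Standard tuning at several cross-validation fold counts on shared
    replicates (paired comparison across fold counts).

    Uses the first sample size in ``cfg.sample_sizes``. ``k = n`` gives
    leave-one-out. Returns a per-replicate table with columns
    (form, k_folds, replicate, lambda, cs) suitable for distribution
    summaries of the selected tuning parameter and resulting calibration.
    """
    n = cfg.sample_sizes[0]
    for k in fold_list:
        if not 2 <= k <= n:
            raise ValueError(f"fold count {k} outside [2, n={n}]")
    rows = []
    for r in range(cfg.nsim):
        dev_ss, val_ss, method_seeds = _replicate_seeds(cfg.master_seed, r)
        dev = generate_dataset(cfg.scenario, n, dev_ss)
        val = generate_dataset(cfg.scenario, cfg.nval, val_ss)
        for form in forms:
            base_seed = method_seeds[form]
            for k in fold_list:
                tr = standard_tune(dev, form, k=int(k),
                                   seed=base_seed + int(k),
                                   repeats=cfg.repeats,
                                   n_lambda=cfg.n_lambda,
                                   ratio=cfg.lambda_ratio)
                model = fit_penalized(dev, PenaltySpec(form,
                                                       tr.selected_lambda))
                m = validate_model(model, val)
                rows.append({"form": form, "k_folds": int(k),
                             "replicate": r, "n": n,
                             "lambda": tr.selected_lambda,
                             "cs": np.nan if m.cal_slope is None
                             else m.cal_slope})
    return pd.DataFrame(rows)
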