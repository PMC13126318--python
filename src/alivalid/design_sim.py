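"""Design-selection simulation engine.

Simulates cohorts across data-quality scenarios (error rates x recovery
rates), applies each candidate validation design to the *same* cohorts
(common random numbers, to sharpen variance comparisons), fits the sieve
MLE, and summarizes bias and efficiency so the most informative design for
the next validation wave can be chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import validation_designs as vd
from .smle_inference import fit_naive, fit_smle
from .synthetic_cohort import GeneratorConfig, apply_validation, generate_cohort

__all__ = ["ScenarioGrid", "run_design_comparison", "recommend_design"]


@dataclass
class ScenarioGrid:
    """Cartesian grid of data-quality scenarios and candidate designs."""

    error_levels: Sequence[tuple[float, float]]     # (tpr, fpr) pairs
    recovery_levels: Sequence[float]
    n_reps: int
    base_config: GeneratorConfig
    designs: Sequence[vd.DesignSpec]
    seed: int = 0
    #: keyword options forwarded to the sieve-ML fitter (e.g. n_basis)
    smle_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be at least 2")
        if not self.error_levels or not self.recovery_levels or not self.designs:
            raise ValueError("error_levels, recovery_levels, and designs "
                             "must be non-empty")


def _design_key(spec: vd.DesignSpec) -> str:
    return spec.wave_label or spec.strategy


def run_design_comparison(grid: ScenarioGrid) -> pd.DataFrame:
    """One row per (scenario, design) with bias/efficiency summaries.

    Columns include the mean, Monte-Carlo standard error, empirical bias and
    SD of the fitted index coefficient, the variance ratio relative to
    simple random sampling in the same scenario (when present), the naive
    estimator's mean and bias, and the count of failed (non-converged or
    errored) fits, which are excluded from the summaries.
    """
    beta1_true = float(grid.base_config.beta[1])
    rows = []
    for tpr, fpr in grid.error_levels:
        for recovery in grid.recovery_levels:
            config = grid.base_config.with_rates(tpr=tpr, fpr=fpr,
                                                 recovery_rate=recovery)
            estimates: dict[str, list[float]] = {
                _design_key(s): [] for s in grid.designs}
            failures: dict[str, int] = {
                _design_key(s): 0 for s in grid.designs}
            naive_estimates: list[float] = []
            # Per-rep seeds derive deterministically from the master seed
            # and the scenario, so cells are independently reproducible.
            seed_root = np.random.SeedSequence(
                [grid.seed, int(round(tpr * 1e6)), int(round(fpr * 1e6)),
                 int(round(recovery * 1e6))])
            rep_seeds = seed_root.generate_state(grid.n_reps)
            for rep in range(grid.n_reps):
                rep_config = replace(config, seed=int(rep_seeds[rep]))
                cohort = generate_cohort(rep_config)
                try:
                    naive = fit_naive(cohort)
                    naive_estimates.append(float(naive.beta[1]))
                except Exception:
                    naive = None
                for spec in grid.designs:
                    key = _design_key(spec)
                    try:
                        wave = replace(
                            spec,
                            seed=(int(rep_seeds[rep]) + 1 if spec.seed is None
                                  else spec.seed),
                            beta_naive=(naive.beta if spec.strategy == "rs"
                                        and spec.beta_naive is None
                                        and naive is not None
                                        else spec.beta_naive),
                        )
                        result = vd._apply_spec(cohort, wave, None)
                        validated = apply_validation(
                            cohort, result.selected_ids, rep_config)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            fit = fit_smle(validated, **grid.smle_options)
                        if not fit.converged:
                            raise RuntimeError("EM did not converge")
                        estimates[key].append(float(fit.beta[1]))
                    except Exception:
                        failures[key] += 1
            srs_var = None
            for spec in grid.designs:
                if spec.strategy == "srs":
                    vals = estimates[_design_key(spec)]
                    if len(vals) >= 2:
                        srs_var = float(np.var(vals, ddof=1))
                    break
            for spec in grid.designs:
                key = _design_key(spec)
                vals = np.asarray(estimates[key])
                if vals.size == 0:
                    rows.append({
                        "tpr": tpr, "fpr": fpr, "recovery": recovery,
                        "design": key, "strategy": spec.strategy,
                        "n_ok": 0, "n_fail": failures[key],
                        "mean_beta1": np.nan, "mc_se": np.nan,
                        "bias": np.nan, "sd": np.nan,
                        "re_vs_srs": np.nan,
                        "mean_naive_beta1": np.nan, "naive_bias": np.nan,
                    })
                    continue
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
                naive_mean = (float(np.mean(naive_estimates))
                              if naive_estimates else np.nan)
                rows.append({
                    "tpr": tpr, "fpr": fpr, "recovery": recovery,
                    "design": key, "strategy": spec.strategy,
                    "n_ok": int(vals.size), "n_fail": failures[key],
                    "mean_beta1": float(np.mean(vals)),
                    "mc_se": sd / np.sqrt(vals.size),
                    "bias": float(np.mean(vals) - beta1_true),
                    "sd": sd,
                    "re_vs_srs": (sd**2 / srs_var
                                  if srs_var not in (None, 0.0) else np.nan),
                    "mean_naive_beta1": naive_mean,
                    "naive_bias": naive_mean - beta1_true,
                })
    return pd.DataFrame(rows)


def recommend_design(
    summary: pd.DataFrame,
    grid: ScenarioGrid,
    pilot_rates: dict | None = None,
    criterion: str = "variance",
) -> vd.DesignSpec:
    """Design minimizing the chosen criterion in the scenario closest to the
    observed pilot error rates (Euclidean distance on the probability
    scale).  Ties are broken toward the design requiring the fewest inputs
    (simple random sampling first, then stratified, then rank-based).
    """
    ok = summary[summary["n_ok"] > 0]
    if ok.empty:
        raise ValueError("summary contains no successful cells")
    if pilot_rates is None:
        scenario = ok.iloc[0][["tpr", "fpr", "recovery"]]
    else:
        target = np.array([pilot_rates.get("tpr", 1.0),
                           pilot_rates.get("fpr", 0.0),
                           pilot_rates.get("recovery", 1.0)])
        cells = ok[["tpr", "fpr", "recovery"]].drop_duplicates()
        dist = np.linalg.norm(cells.to_numpy() - target, axis=1)
        scenario = cells.iloc[int(np.argmin(dist))]
    cell = ok[(ok["tpr"] == scenario["tpr"]) & (ok["fpr"] == scenario["fpr"])
              & (ok["recovery"] == scenario["recovery"])]
    if criterion == "variance":
        scores = cell["sd"] ** 2
    elif criterion == "bias":
        scores = cell["bias"].abs()
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    simplicity = {"srs": 0, "cc": 1, "bcc": 2, "ets": 3, "rs": 4, "opt": 5}
    order = cell.assign(score=scores,
                        simple=cell["strategy"].map(simplicity))
    best = order.sort_values(["score", "simple"]).iloc[0]
    for spec in grid.designs:
        if _design_key(spec) == best["design"]:
            return spec
    raise ValueError("recommended design not found in the grid")
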