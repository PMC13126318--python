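"""Synthetic cohorts with the error structure the analysis assumes.

Each patient has ten true binary components, an index ``x_true`` computed
from all of them, and a binary outcome drawn from a logistic model in
``x_true`` and age.  The observed (EHR-like) components are corrupted copies:
a component can be missing, and a non-missing component is re-drawn from its
truth via per-component true/false-positive rates.  Validation (chart
review) corrects non-missing components to their true values and recovers a
missing *unhealthy* component with configurable probability, but only for
components that carry auxiliary anchors.

Age enters the model as ``z = (age - 18) / 10`` so the intercept is the
18-year-old baseline and the age coefficient is per decade of age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .ali_core import ComponentSpec, load_component_specs

__all__ = ["GeneratorConfig", "generate_cohort", "apply_validation", "true_column",
           "ehr_column", "validated_column"]

#: Defaults are chosen so the error-prone index is right-skewed with a median
#: near one-third; they are illustrative, not estimates from any cohort.
DEFAULT_PREVALENCE: dict[str, float] = {
    "systolic_bp": 0.35,
    "diastolic_bp": 0.20,
    "bmi": 0.45,
    "triglycerides": 0.35,
    "total_cholesterol": 0.40,
    "crp": 0.25,
    "hba1c": 0.20,
    "serum_albumin": 0.15,
    "creatinine_clearance": 0.50,
    "homocysteine": 0.10,
}

#: Vitals are essentially never missing; rare inflammation labs mostly are.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "systolic_bp": 0.0,
    "diastolic_bp": 0.0,
    "bmi": 0.05,
    "triglycerides": 0.20,
    "total_cholesterol": 0.20,
    "crp": 0.60,
    "hba1c": 0.20,
    "serum_albumin": 0.20,
    "creatinine_clearance": 0.10,
    "homocysteine": 0.60,
}


def true_column(name: str) -> str:
    return f"true_{name}"


def ehr_column(name: str) -> str:
    return f"ehr_{name}"


def validated_column(name: str) -> str:
    return f"val_{name}"


def _per_component(value: float | Mapping[str, float], names: Sequence[str],
                   what: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {n: float(value.get(n, 0.0)) for n in names}
    else:
        out = {n: float(value) for n in names}
    for n, p in out.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{what}[{n!r}] = {p} outside [0, 1]")
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic data-generating process.

    ``missingness`` is the per-component probability that a *healthy* value
    is missing (and of any value under the default missing-completely-at-
    random behaviour).  Setting ``missingness_unhealthy`` makes missingness
    depend on the true value (missing-not-at-random): unhealthy values are
    then missing with that probability instead.
    """

    n_patients: int = 1000
    beta: tuple[float, float, float] = (-1.47, 1.133, 0.104)
    age_range: tuple[float, float] = (18.0, 65.0)
    component_prevalence: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    prevalence_age_slope: float = 0.0
    tpr: float | Mapping[str, float] = 1.0
    fpr: float | Mapping[str, float] = 0.01
    missingness: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    missingness_unhealthy: float | Mapping[str, float] | None = None
    recovery_rate: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if len(self.beta) != 3:
            raise ValueError("beta must have three coefficients")
        if not 0.0 <= self.recovery_rate <= 1.0:
            raise ValueError("recovery_rate outside [0, 1]")

    def resolved(self, specs: Mapping[str, ComponentSpec]):
        names = list(specs)
        prev = _per_component(self.component_prevalence, names, "prevalence")
        tpr = _per_component(self.tpr, names, "tpr")
        fpr = _per_component(self.fpr, names, "fpr")
        miss0 = _per_component(self.missingness, names, "missingness")
        if self.missingness_unhealthy is None:
            miss1 = dict(miss0)
        else:
            miss1 = _per_component(self.missingness_unhealthy, names,
                                   "missingness_unhealthy")
        if any(tpr[n] < fpr[n] for n in names):
            warnings.warn("tpr < fpr for some component; the error-prone "
                          "indicator is anti-correlated with the truth",
                          stacklevel=3)
        return names, prev, tpr, fpr, miss0, miss1

    def with_rates(self, tpr: float | None = None, fpr: float | None = None,
                   recovery_rate: float | None = None) -> "GeneratorConfig":
        """Copy of this config with scenario-level rates swapped in."""
        kwargs: dict = {}
        if tpr is not None:
            kwargs["tpr"] = tpr
        if fpr is not None:
            kwargs["fpr"] = fpr
        if recovery_rate is not None:
            kwargs["recovery_rate"] = recovery_rate
        return replace(self, **kwargs)


def _nan_proportion(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise proportion of ones among non-NaN entries, with counts."""
    observed = ~np.isnan(values)
    counts = observed.sum(axis=1)
    sums = np.where(observed, values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        props = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return props, counts


def generate_cohort(
    config: GeneratorConfig,
    specs: Mapping[str, ComponentSpec] | None = None,
) -> pd.DataFrame:
    """Draw a cohort; bit-reproducible given ``config`` (incl. its seed)."""
    if specs is None:
        specs = load_component_specs()
    names, prev, tpr, fpr, miss0, miss1 = config.resolved(specs)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    z = (age - 18.0) / 10.0
    z_center = (np.mean(config.age_range) - 18.0) / 10.0

    true = np.empty((n, len(names)))
    ehr = np.empty((n, len(names)))
    for j, name in enumerate(names):
        p_j = prev[name]
        if config.prevalence_age_slope != 0.0:
            p_vec = expit(logit(p_j) + config.prevalence_age_slope * (z - z_center))
        else:
            p_vec = np.full(n, p_j)
        s = (rng.uniform(size=n) < p_vec).astype(float)
        true[:, j] = s
        p_miss = np.where(s == 1.0, miss1[name], miss0[name])
        missing = rng.uniform(size=n) < p_miss
        p_one = np.where(s == 1.0, tpr[name], fpr[name])
        s_star = (rng.uniform(size=n) < p_one).astype(float)
        ehr[:, j] = np.where(missing, np.nan, s_star)

    x_true = true.mean(axis=1)
    x_star, n_star = _nan_proportion(ehr)
    if np.any(n_star == 0):
        raise ValueError("some patients have all ten components missing; "
                         "the error-prone index is undefined — lower the "
                         "configured missingness")

    b0, b1, b2 = config.beta
    y = (rng.uniform(size=n) < expit(b0 + b1 * x_true + b2 * z)).astype(int)

    data: dict[str, np.ndarray] = {
        "patient_id": np.arange(n),
        "age": age,
        "z": z,
        "y": y,
    }
    for j, name in enumerate(names):
        data[true_column(name)] = true[:, j].astype(int)
    for j, name in enumerate(names):
        data[ehr_column(name)] = ehr[:, j]
    data["x_true"] = x_true
    data["x_star"] = x_star
    data["n_star"] = n_star.astype(int)
    cohort = pd.DataFrame(data)
    cohort["v"] = 0
    for name in names:
        cohort[validated_column(name)] = np.nan
    cohort["x_validated"] = np.nan
    cohort["n_validated"] = np.nan
    return cohort


def apply_validation(
    cohort: pd.DataFrame,
    selected_ids: Sequence[int],
    config: GeneratorConfig,
    specs: Mapping[str, ComponentSpec] | None = None,
) -> pd.DataFrame:
    """Simulate chart review for the selected patients.

    Non-missing error-prone components are corrected to their true values.
    Each missing, truly-unhealthy component with auxiliary anchors is
    revealed (as unhealthy) with probability ``config.recovery_rate``; all
    other missing components stay missing in the validated record.  Draws
    are keyed to ``(config.seed, patient_id)`` so validating a patient gives
    the same result regardless of which wave selected them.
    """
    if specs is None:
        specs = load_component_specs()
    names = list(specs)
    ids = np.asarray(selected_ids)
    if len(ids) != len(set(ids.tolist())):
        raise ValueError("selected_ids contains repeats")
    index = cohort.set_index("patient_id", drop=False)
    missing_ids = set(ids.tolist()) - set(index.index.tolist())
    if missing_ids:
        raise ValueError(f"unknown patient ids: {sorted(missing_ids)}")

    out = cohort.copy()
    pos = out["patient_id"].isin(ids)
    rows = out.index[pos]
    recoverable = np.array([specs[n].recoverable for n in names])

    for row in rows:
        pid = int(out.at[row, "patient_id"])
        rng = np.random.default_rng([int(config.seed), 0x5EED, pid])
        draws = rng.uniform(size=len(names))
        vals = np.empty(len(names))
        for j, name in enumerate(names):
            s_true = float(out.at[row, true_column(name)])
            s_ehr = out.at[row, ehr_column(name)]
            if not np.isnan(s_ehr):
                vals[j] = s_true  # review corrects errors
            elif s_true == 1.0 and recoverable[j] and draws[j] < config.recovery_rate:
                vals[j] = 1.0  # anchor found: recovered as unhealthy
            else:
                vals[j] = np.nan
        for j, name in enumerate(names):
            out.at[row, validated_column(name)] = vals[j]
        n_obs = int(np.sum(~np.isnan(vals)))
        if n_obs == 0:
            raise ValueError(f"patient {pid} has no validated components")
        out.at[row, "x_validated"] = np.nansum(vals) / n_obs
        out.at[row, "n_validated"] = n_obs
    out.loc[pos, "v"] = 1
    return out
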