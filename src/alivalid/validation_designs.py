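"""Sampling designs for choosing which patients to validate.

All strategies operate on the *eligible* pool (never-validated patients) and
depend only on fully observed quantities — the outcome, the error-prone
index, and age — never on the validated index, so validation selection is
missing-at-random by construction.

Strategies: simple random sampling (srs), case-control on the outcome (cc),
balanced case-control on outcome crossed with the dichotomized error-prone
index (bcc), variance-minimizing stratified allocation (opt), extreme-tail
sampling on a ranked column (ets), and residual sampling from the naive
logistic fit (rs).  A multi-wave driver guarantees each patient is selected
at most once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DesignSpec",
    "DesignResult",
    "eligible_pool",
    "sample_srs",
    "sample_stratified",
    "sample_cc",
    "sample_bcc",
    "sample_opt",
    "sample_ets",
    "compute_residuals",
    "sample_rs",
    "run_multiwave",
]

STRATEGIES = ("srs", "cc", "bcc", "opt", "ets", "rs")


@dataclass
class DesignSpec:
    """Declarative description of one selection wave."""

    strategy: str
    n_select: int
    cutpoint: float | None = None        # dichotomizes x_star (default median)
    rank_value: str = "x_star"           # ets ranking column
    seed: int | None = None
    beta_naive: Sequence[float] | None = None   # rs: naive coefficients
    pilot_beta: Sequence[float] | None = None   # opt
    pilot_error_rates: Mapping[str, float] | None = None  # opt: tpr/fpr
    wave_label: str = ""

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_select < 0:
            raise ValueError("n_select must be nonnegative")


@dataclass
class DesignResult:
    """Selected ids plus the strategy's bookkeeping for the audit trail."""

    selected_ids: np.ndarray
    strategy: str
    wave_label: str = ""
    per_stratum_counts: dict = field(default_factory=dict)
    residuals: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = np.asarray(self.selected_ids)
        if len(ids) != len(set(ids.tolist())):
            raise AssertionError("selected ids must be distinct")
        self.selected_ids = ids


def eligible_pool(cohort: pd.DataFrame) -> pd.DataFrame:
    """Never-validated patients."""
    return cohort[cohort["v"] == 0]


def _check_n(n: int, pool: pd.DataFrame) -> None:
    if n > len(pool):
        raise ValueError(f"cannot select {n} of {len(pool)} eligible patients")


def sample_srs(cohort: pd.DataFrame, n: int, seed: int | None = None,
               wave_label: str = "") -> DesignResult:
    """Uniform sampling without replacement from the eligible pool."""
    pool = eligible_pool(cohort)
    _check_n(n, pool)
    rng = np.random.default_rng(seed)
    ids = rng.choice(pool["patient_id"].to_numpy(), size=n, replace=False)
    return DesignResult(np.sort(ids), "srs", wave_label, params={"n": n, "seed": seed})


def _equal_allocation(sizes: Mapping[object, int], n: int) -> dict:
    """Equal split with deterministic remainder order (sorted labels)."""
    labels = sorted(sizes, key=str)
    base = n // len(labels)
    alloc = {lab: base for lab in labels}
    for lab in labels[: n % len(labels)]:
        alloc[lab] += 1
    return alloc


def _redistribute(alloc: dict, sizes: Mapping[object, int]) -> dict:
    """Cap allocations at stratum sizes, pushing the excess to strata with
    room (proportionally to remaining capacity)."""
    alloc = dict(alloc)
    while True:
        excess = sum(max(alloc[lab] - sizes[lab], 0) for lab in alloc)
        if excess == 0:
            return alloc
        for lab in alloc:
            alloc[lab] = min(alloc[lab], sizes[lab])
        room = {lab: sizes[lab] - alloc[lab] for lab in alloc}
        total_room = sum(room.values())
        if total_room < excess:
            raise ValueError("allocation exceeds the eligible pool")
        labels = sorted(room, key=str)
        for lab in labels:
            give = min(room[lab], math.ceil(excess * room[lab] / total_room))
            give = min(give, excess)
            alloc[lab] += give
            excess -= give
            if excess == 0:
                break


def sample_stratified(cohort: pd.DataFrame, strata: pd.Series,
                      allocation: Mapping[object, int], seed: int | None = None,
                      wave_label: str = "", strategy: str = "bcc") -> DesignResult:
    """Independent simple random samples within each stratum.

    ``strata`` must be indexed like ``cohort`` and label every eligible
    patient.  Allocations exceeding a stratum's size are redistributed
    proportionally to the remaining strata.
    """
    pool = eligible_pool(cohort)
    strata = strata.loc[pool.index]
    sizes = strata.value_counts().to_dict()
    for lab, k in allocation.items():
        if k > 0 and sizes.get(lab, 0) == 0:
            raise ValueError(f"stratum {lab!r} is empty but has allocation {k}")
    alloc = _redistribute(dict(allocation), sizes)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for lab in sorted(alloc, key=str):
        members = pool.loc[strata == lab, "patient_id"].to_numpy()
        chosen.append(rng.choice(members, size=alloc[lab], replace=False))
    ids = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return DesignResult(ids, strategy, wave_label,
                        per_stratum_counts=dict(alloc),
                        params={"seed": seed})


def outcome_strata(cohort: pd.DataFrame) -> pd.Series:
    return cohort["y"].map(lambda y: f"y={int(y)}")


def bcc_strata(cohort: pd.DataFrame, cutpoint: float | None = None
               ) -> tuple[pd.Series, float]:
    """Outcome crossed with the dichotomized error-prone index.

    The cutpoint defaults to the within-pool median of the error-prone index
    among eligible patients.
    """
    if cutpoint is None:
        cutpoint = float(eligible_pool(cohort)["x_star"].median())
    hi = (cohort["x_star"] > cutpoint).astype(int)
    labels = ("y=" + cohort["y"].astype(int).astype(str)
              + ",x*" + np.where(hi == 1, ">", "<=") + f"{cutpoint:g}")
    return pd.Series(labels, index=cohort.index), cutpoint


def sample_cc(cohort: pd.DataFrame, n: int, seed: int | None = None,
              wave_label: str = "") -> DesignResult:
    """Case-control: equal split across the two outcome strata."""
    pool = eligible_pool(cohort)
    _check_n(n, pool)
    strata = outcome_strata(cohort)
    sizes = strata.loc[pool.index].value_counts().to_dict()
    alloc = _equal_allocation(sizes, n)
    return sample_stratified(cohort, strata, alloc, seed, wave_label, "cc")


def sample_bcc(cohort: pd.DataFrame, n: int, cutpoint: float | None = None,
               seed: int | None = None, wave_label: str = "") -> DesignResult:
    """Balanced case-control: equal split across the four (Y, X*_D) strata."""
    pool = eligible_pool(cohort)
    _check_n(n, pool)
    strata, cutpoint = bcc_strata(cohort, cutpoint)
    sizes = strata.loc[pool.index].value_counts().to_dict()
    alloc = _equal_allocation(sizes, n)
    res = sample_stratified(cohort, strata, alloc, seed, wave_label, "bcc")
    res.params["cutpoint"] = cutpoint
    return res


def _stratum_info(pool: pd.DataFrame, strata: pd.Series,
                  pilot_beta: Sequence[float]) -> tuple[list, np.ndarray, dict]:
    """Mean per-patient complete-data information matrix per stratum."""
    b = np.asarray(pilot_beta, dtype=float)
    labels = sorted(strata.loc[pool.index].unique(), key=str)
    infos = []
    sizes = {}
    for lab in labels:
        sub = pool.loc[strata.loc[pool.index] == lab]
        D = np.column_stack([np.ones(len(sub)), sub["x_star"], sub["z"]])
        mu = expit(D @ b)
        w = mu * (1 - mu)
        infos.append((D * w[:, None]).T @ D / len(sub))
        sizes[lab] = len(sub)
    return labels, np.asarray(infos), sizes


def _enumerate_allocations(n: int, caps: Sequence[int]):
    """All integer allocations of ``n`` across strata respecting caps."""
    H = len(caps)
    ranges = [range(0, min(c, n) + 1) for c in caps[:-1]]
    for head in product(*ranges):
        rest = n - sum(head)
        if 0 <= rest <= caps[-1]:
            yield (*head, rest)


def opt_variance(alloc: Sequence[int], infos: np.ndarray, sizes: Sequence[int],
                 kappa: float) -> float:
    """Approximate variance of the index coefficient under an allocation.

    Validated patients contribute their full (complete-data) logistic
    information; unvalidated patients contribute a fraction ``kappa`` of it,
    reflecting how much information survives the classification error.  The
    criterion is the (1, 1) element (index coefficient) of the inverse total
    information.  This is a complete-data approximation, cross-checked only
    against brute-force enumeration of the same criterion.
    """
    total = np.zeros((3, 3))
    for n_h, I_h, N_h in zip(alloc, infos, sizes):
        total += (n_h + kappa * (N_h - n_h)) * I_h
    try:
        return float(np.linalg.inv(total)[1, 1])
    except np.linalg.LinAlgError:
        return float("inf")


def sample_opt(cohort: pd.DataFrame, n: int, pilot_beta: Sequence[float],
               pilot_error_rates: Mapping[str, float],
               strata: pd.Series | None = None, cutpoint: float | None = None,
               seed: int | None = None, wave_label: str = "") -> DesignResult:
    """Stratified design with allocation minimizing the approximate variance
    of the index coefficient, found by exhaustive search (steps of 1).

    Requires pilot estimates of the coefficients and the error rates
    (``{"tpr": ..., "fpr": ...}``); intended for at most four strata, where
    the exhaustive search is exact for the stated criterion.
    """
    if pilot_beta is None or pilot_error_rates is None:
        raise ValueError("opt requires pilot coefficient and error-rate "
                         "estimates")
    pool = eligible_pool(cohort)
    _check_n(n, pool)
    if strata is None:
        strata, cutpoint = bcc_strata(cohort, cutpoint)
    labels, infos, sizes = _stratum_info(pool, strata, pilot_beta)
    caps = [sizes[lab] for lab in labels]
    tpr = float(pilot_error_rates["tpr"])
    fpr = float(pilot_error_rates["fpr"])
    kappa = min(max(tpr - fpr, 0.0), 1.0) ** 2

    best: tuple[float, float, tuple[int, ...]] | None = None
    equal = n / len(labels)
    for alloc in _enumerate_allocations(n, caps):
        var = opt_variance(alloc, infos, caps, kappa)
        imbalance = max(abs(a - equal) for a in alloc)
        key = (round(var, 12), imbalance, alloc)
        if best is None or key < best:
            best = key
    assert best is not None
    allocation = dict(zip(labels, best[2]))
    res = sample_stratified(cohort, strata, allocation, seed, wave_label, "opt")
    res.params.update({"pilot_beta": list(pilot_beta),
                       "kappa": kappa, "variance": best[0]})
    return res


def _take_extremes(ids: np.ndarray, values: np.ndarray, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """n//2 smallest and the rest largest, ties at either boundary broken by
    a seeded uniform draw (odd n: the extra patient joins the side whose
    boundary value is more extreme in absolute value)."""
    n_low = n // 2
    n_high = n - n_low
    if n % 2 == 1:
        order = np.argsort(values, kind="stable")
        if abs(values[order[0]]) < abs(values[order[-1]]):
            n_low, n_high = n // 2, n - n // 2
        else:
            n_low, n_high = n - n // 2, n // 2
    jitter = rng.uniform(size=len(values))
    low_order = np.lexsort((jitter, values))
    high_order = np.lexsort((jitter, -values))
    low = set(ids[low_order[:n_low]].tolist())
    chosen_high: list = []
    for idx in high_order:
        if len(chosen_high) == n_high:
            break
        if ids[idx] not in low:
            chosen_high.append(ids[idx])
    return np.sort(np.concatenate([np.array(sorted(low)),
                                   np.array(chosen_high)]).astype(ids.dtype))


def sample_ets(cohort: pd.DataFrame, n: int, rank_value: str = "x_star",
               seed: int | None = None, wave_label: str = "") -> DesignResult:
    """Extreme-tail sampling on a ranked column (default: error-prone index).

    Deterministic given the data except at ties, which are broken by a
    seeded uniform draw.
    """
    pool = eligible_pool(cohort)
    _check_n(n, pool)
    rng = np.random.default_rng(seed)
    ids = _take_extremes(pool["patient_id"].to_numpy(),
                         pool[rank_value].to_numpy(dtype=float), n, rng)
    return DesignResult(ids, "ets", wave_label,
                        params={"rank_value": rank_value, "seed": seed})


def compute_residuals(cohort: pd.DataFrame,
                      beta_naive: Sequence[float]) -> pd.Series:
    """Raw residuals from the naive logistic model:
    ``r = y - expit(b0 + b1*x_star + b2*z)``."""
    b = np.asarray(beta_naive, dtype=float)
    if b.shape != (3,):
        raise ValueError("beta_naive must have three coefficients")
    cols = cohort[["x_star", "z"]]
    if cols.isna().any().any():
        raise ValueError("x_star and z must be non-missing for residuals")
    pred = expit(b[0] + b[1] * cohort["x_star"].to_numpy(dtype=float)
                 + b[2] * cohort["z"].to_numpy(dtype=float))
    return pd.Series(cohort["y"].to_numpy(dtype=float) - pred,
                     index=cohort["patient_id"].to_numpy(), name="residual")


def sample_rs(cohort: pd.DataFrame, n: int, beta_naive: Sequence[float],
              seed: int | None = None, wave_label: str = "") -> DesignResult:
    """Residual sampling: the n/2 most-negative and n/2 most-positive
    residuals from the naive model among eligible patients."""
    pool = eligible_pool(cohort)
    _check_n(n, pool)
    resid = compute_residuals(pool, beta_naive)
    rng = np.random.default_rng(seed)
    ids = _take_extremes(pool["patient_id"].to_numpy(),
                         resid.to_numpy(), n, rng)
    return DesignResult(ids, "rs", wave_label, residuals=resid,
                        params={"beta_naive": list(beta_naive), "seed": seed})


def _apply_spec(cohort: pd.DataFrame, spec: DesignSpec,
                naive_fitter: Callable[[pd.DataFrame], Sequence[float]] | None
                ) -> DesignResult:
    if spec.strategy == "srs":
        return sample_srs(cohort, spec.n_select, spec.seed, spec.wave_label)
    if spec.strategy == "cc":
        return sample_cc(cohort, spec.n_select, spec.seed, spec.wave_label)
    if spec.strategy == "bcc":
        return sample_bcc(cohort, spec.n_select, spec.cutpoint, spec.seed,
                          spec.wave_label)
    if spec.strategy == "opt":
        return sample_opt(cohort, spec.n_select, spec.pilot_beta,
                          spec.pilot_error_rates, cutpoint=spec.cutpoint,
                          seed=spec.seed, wave_label=spec.wave_label)
    if spec.strategy == "ets":
        return sample_ets(cohort, spec.n_select, spec.rank_value, spec.seed,
                          spec.wave_label)
    beta = spec.beta_naive
    if beta is None:
        if naive_fitter is None:
            from .smle_inference import fit_naive
            naive_fitter = lambda c: fit_naive(c).beta  # noqa: E731
        beta = naive_fitter(cohort)
    return sample_rs(cohort, spec.n_select, beta, spec.seed, spec.wave_label)


def run_multiwave(
    cohort: pd.DataFrame,
    wave_specs: Sequence[DesignSpec],
    naive_fitter: Callable[[pd.DataFrame], Sequence[float]] | None = None,
) -> list[DesignResult]:
    """Run waves in order, removing each wave's selections from the pool.

    Rank-based waves recompute their inputs from the current data: a
    residual-sampling wave without explicit coefficients refits the naive
    model just before selecting.  Patients are selected at most once
    (asserted).
    """
    total = sum(s.n_select for s in wave_specs)
    if total > (cohort["v"] == 0).sum():
        raise ValueError("cumulative selections exceed the eligible pool")
    work = cohort.copy()
    results: list[DesignResult] = []
    seen: set = set()
    for w, spec in enumerate(wave_specs):
        if not spec.wave_label:
            spec = DesignSpec(**{**spec.__dict__, "wave_label": f"wave-{w}"})
        res = _apply_spec(work, spec, naive_fitter)
        overlap = seen.intersection(res.selected_ids.tolist())
        assert not overlap, f"patients selected twice: {sorted(overlap)}"
        seen.update(res.selected_ids.tolist())
        work.loc[work["patient_id"].isin(res.selected_ids), "v"] = 1
        results.append(res)
    return results
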