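"""Sieve maximum-likelihood logistic regression with an error-prone exposure.

The outcome model ``logit Pr(Y=1 | X, Z) = b0 + b1*X + b2*Z`` is fit from a
cohort in which the exposure ``X`` (validated index) is observed only for a
validated subsample, while an error-prone surrogate ``X*`` is observed for
everyone.  The exposure error mechanism ``Pr(X = x_k | X*)`` is modelled
nonparametrically on a finite support grid through a B-spline sieve in
``X*``:

    Pr(X = x_k | X*) = sum_j p_kj B_j(X*),

with the basis a partition of unity and each column of ``p`` a probability
vector, so the mixture is a valid pmf at every ``X*``.  Validated patients
contribute the complete-data likelihood; unvalidated patients contribute the
mixture over the support grid.  The observed-data log-likelihood is
maximized by EM: posterior grid weights in the E-step, a weighted logistic
solve for the regression coefficients and closed-form column proportions for
the sieve coefficients in the M-step.

Standard errors come from the numerically differentiated profile
log-likelihood (the sieve coefficients re-maximized at each perturbed
coefficient vector).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.special import expit

from . import _logistic

__all__ = [
    "SupportGrid",
    "SieveBasis",
    "NaiveFit",
    "SmleFit",
    "default_grid",
    "make_basis",
    "fit_naive",
    "observed_loglik",
    "fit_smle",
    "profile_se",
    "predict_validated_ali",
]

_PROB_FLOOR = 1e-12


def default_grid() -> np.ndarray:
    """Tenths support {0, 0.1, ..., 1} for the validated index."""
    return np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass(frozen=True)
class SupportGrid:
    """Ordered distinct values the validated index may take."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def snap(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest grid point and its index, for each value."""
        idx = np.argmin(np.abs(x[:, None] - self.points[None, :]), axis=1)
        return self.points[idx], idx


@dataclass
class SieveBasis:
    """B-spline partition-of-unity basis in the error-prone index."""

    knots: np.ndarray          # full (clamped) knot vector
    degree: int
    lo: float
    hi: float
    conditioning: str = "x_star_only"

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x_star: np.ndarray, clamp: bool = True) -> np.ndarray:
        x = np.asarray(x_star, dtype=float)
        if x.size == 0:
            return np.zeros((0, self.n_basis))
        if clamp:
            out_of_range = (x < self.lo) | (x > self.hi)
            if np.any(out_of_range):
                warnings.warn("x_star outside the basis range; clamping",
                              stacklevel=2)
            x = np.clip(x, self.lo, self.hi)
        # Clamped B-splines sum to one everywhere on [lo, hi].
        B = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B


def make_basis(
    x_star: np.ndarray,
    n_basis: int | None = None,
    degree: int = 3,
    conditioning: str = "x_star_only",
    n_validated: int | None = None,
) -> SieveBasis:
    """Cubic B-spline basis with interior knots at quantiles of ``x_star``.

    The default dimension is ``ceil(2 * n_validated ** (1/3))``.  A basis of
    dimension one degenerates to the constant function (error mechanism
    independent of ``x_star``).
    """
    x = np.asarray(x_star, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no x_star values to build the basis from")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    if n_basis is None:
        n_val = n_validated if n_validated is not None else x.size
        n_basis = int(np.ceil(2.0 * max(n_val, 1) ** (1.0 / 3.0)))
    if n_basis <= 1:
        knots = np.array([lo, hi])
        return SieveBasis(knots=knots, degree=0, lo=lo, hi=hi,
                          conditioning=conditioning)
    degree = min(degree, n_basis - 1)
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = interior[(interior > lo) & (interior < hi)]
        interior = np.unique(interior)
    else:
        interior = np.array([])
    knots = np.concatenate([
        np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])
    basis = SieveBasis(knots=knots, degree=degree, lo=lo, hi=hi,
                       conditioning=conditioning)
    # Merge away basis functions with no support in the data.
    colsum = basis.design(x).sum(axis=0)
    if np.any(colsum <= 0):
        warnings.warn("basis functions without data support; reducing the "
                      "basis dimension", stacklevel=2)
        return make_basis(x, n_basis=n_basis - 1, degree=degree,
                          conditioning=conditioning, n_validated=n_validated)
    return basis


@dataclass
class NaiveFit:
    """Standard logistic fit of Y on (X*, Z), ignoring exposure error."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int

    @property
    def ci(self) -> np.ndarray:
        half = 1.96 * self.se
        return np.column_stack([self.beta - half, self.beta + half])


def fit_naive(cohort: pd.DataFrame, exposure: str = "x_star") -> NaiveFit:
    """Maximum-likelihood logistic regression of ``y`` on (exposure, z).

    Raises
    ------
    _logistic.SeparationError
        On (quasi-)separation; the fit is reported, never regularized away.
    """
    needed = ["y", exposure, "z"]
    if cohort[needed].isna().any().any():
        raise ValueError(f"columns {needed} must be complete")
    X = np.column_stack([np.ones(len(cohort)), cohort[exposure], cohort["z"]])
    y = cohort["y"].to_numpy(dtype=float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0)
        except np.linalg.LinAlgError as exc:
            raise _logistic.SeparationError(
                "singular information matrix (possible separation)") from exc
    if any("separation" in str(w.message).lower() for w in caught) or (
            not res.mle_retvals.get("converged", True)) or (
            np.max(np.abs(res.params)) > 40.0):
        raise _logistic.SeparationError(
            "logistic fit did not converge cleanly (possible separation)")
    return NaiveFit(beta=np.asarray(res.params), se=np.asarray(res.bse),
                    cov=np.asarray(res.cov_params()), loglik=float(res.llf),
                    n=len(cohort))


def _prob_y(beta: np.ndarray, y: np.ndarray, x: np.ndarray,
            z: np.ndarray) -> np.ndarray:
    """Pr(Y = y | X = x, Z = z) under the logistic model."""
    mu = expit(beta[0] + beta[1] * x + beta[2] * z)
    return np.where(y == 1, mu, 1.0 - mu)


@dataclass
class _Arrays:
    """Pre-extracted data arrays shared across the EM routines."""

    yv: np.ndarray
    zv: np.ndarray
    kv: np.ndarray          # grid index of each validated X
    Bv: np.ndarray          # basis at validated patients' X*
    yu: np.ndarray
    zu: np.ndarray
    Bu: np.ndarray          # basis at unvalidated patients' X*
    grid: np.ndarray

    @property
    def n(self) -> int:
        return len(self.yv) + len(self.yu)


def _extract_arrays(cohort: pd.DataFrame, grid: SupportGrid, basis: SieveBasis,
                    snap: str) -> _Arrays:
    val = cohort["v"].to_numpy() == 1
    if val.any():
        xval = cohort.loc[val, "x_validated"].to_numpy(dtype=float)
    else:
        xval = np.array([], dtype=float)
    if np.any(np.isnan(xval)):
        raise ValueError("validated patients must have x_validated")
    if snap == "tenths" or snap == "nearest":
        snapped, kv = grid.snap(xval)
        if np.max(np.abs(snapped - xval), initial=0.0) > 0.5 * np.min(
                np.diff(grid.points)):
            warnings.warn("validated index values far from the support grid",
                          stacklevel=3)
    elif snap == "exact":
        kv = np.searchsorted(grid.points, xval)
        kv = np.clip(kv, 0, len(grid.points) - 1)
        if not np.allclose(grid.points[kv], xval):
            raise ValueError("grid does not contain every validated value")
    else:
        raise ValueError(f"unknown snap mode {snap!r}")
    return _Arrays(
        yv=cohort.loc[val, "y"].to_numpy(dtype=float),
        zv=cohort.loc[val, "z"].to_numpy(dtype=float),
        kv=kv,
        Bv=basis.design(cohort.loc[val, "x_star"].to_numpy(dtype=float)),
        yu=cohort.loc[~val, "y"].to_numpy(dtype=float),
        zu=cohort.loc[~val, "z"].to_numpy(dtype=float),
        Bu=basis.design(cohort.loc[~val, "x_star"].to_numpy(dtype=float)),
        grid=grid.points,
    )


def _loglik_arrays(beta: np.ndarray, p: np.ndarray, arr: _Arrays) -> float:
    ll = 0.0
    if len(arr.yv):
        py = _prob_y(beta, arr.yv, arr.grid[arr.kv], arr.zv)
        perr = np.sum(arr.Bv * p[arr.kv, :], axis=1)
        ll += float(np.sum(np.log(np.maximum(py, _PROB_FLOOR))))
        ll += float(np.sum(np.log(np.maximum(perr, _PROB_FLOOR))))
    if len(arr.yu):
        mix = arr.Bu @ p.T                                   # (n_u, K)
        py = _prob_y(beta, arr.yu[:, None], arr.grid[None, :],
                     arr.zu[:, None])                        # (n_u, K)
        denom = np.sum(py * mix, axis=1)
        if np.any(denom <= 0):
            raise ValueError(
                "zero mixture probability for an unvalidated patient; the "
                "support grid or sieve basis does not cover the data")
        ll += float(np.sum(np.log(denom)))
    return ll


def observed_loglik(
    beta: np.ndarray,
    p: np.ndarray,
    cohort: pd.DataFrame,
    grid: SupportGrid,
    basis: SieveBasis,
    snap: str = "tenths",
) -> float:
    """Observed-data log-likelihood (sampling and marginal terms omitted).

    Validated patients contribute ``log Pr(Y|X,Z) + log Pr(X|X*)``;
    unvalidated patients contribute the log of the grid mixture
    ``sum_k Pr(Y|x_k,Z) Pr(x_k|X*)``.
    """
    p = np.asarray(p, dtype=float)
    K, J = len(grid.points), basis.n_basis
    if p.shape != (K, J):
        raise ValueError(f"p must have shape ({K}, {J})")
    if np.any(p < 0) or not np.allclose(p.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("columns of p must be probability vectors")
    arr = _extract_arrays(cohort, grid, basis, snap)
    return _loglik_arrays(np.asarray(beta, dtype=float), p, arr)


@dataclass
class SmleFit:
    """Converged sieve-ML fit with its error-mechanism estimate."""

    beta: np.ndarray
    p: np.ndarray
    grid: SupportGrid
    basis: SieveBasis
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n: int
    n_validated: int
    se: np.ndarray | None = None
    cov: np.ndarray | None = None
    beta_naive: np.ndarray | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def ci(self) -> np.ndarray | None:
        if self.se is None:
            return None
        half = 1.96 * self.se
        return np.column_stack([self.beta - half, self.beta + half])

    def error_mechanism(self, x_star: np.ndarray) -> np.ndarray:
        """Pr(X = x_k | X*) for each row of ``x_star`` (rows sum to one)."""
        B = self.basis.design(np.atleast_1d(np.asarray(x_star, dtype=float)))
        return B @ self.p.T

    def to_json(self) -> str:
        payload = {
            "beta": self.beta.tolist(),
            "se": None if self.se is None else self.se.tolist(),
            "p": self.p.tolist(),
            "grid": self.grid.points.tolist(),
            "basis": {
                "knots": self.basis.knots.tolist(),
                "degree": self.basis.degree,
                "lo": self.basis.lo,
                "hi": self.basis.hi,
                "conditioning": self.basis.conditioning,
            },
            "loglik_trace": self.loglik_trace.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n": self.n,
            "n_validated": self.n_validated,
            "beta_naive": None if self.beta_naive is None
            else self.beta_naive.tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SmleFit":
        d = json.loads(text)
        basis = SieveBasis(knots=np.asarray(d["basis"]["knots"]),
                           degree=int(d["basis"]["degree"]),
                           lo=float(d["basis"]["lo"]),
                           hi=float(d["basis"]["hi"]),
                           conditioning=d["basis"]["conditioning"])
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            p=np.asarray(d["p"], dtype=float),
            grid=SupportGrid(np.asarray(d["grid"], dtype=float)),
            basis=basis,
            loglik_trace=np.asarray(d["loglik_trace"], dtype=float),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            n=int(d["n"]),
            n_validated=int(d["n_validated"]),
            se=None if d["se"] is None else np.asarray(d["se"], dtype=float),
            beta_naive=None if d["beta_naive"] is None
            else np.asarray(d["beta_naive"], dtype=float),
        )


def _em_state(beta: np.ndarray, p: np.ndarray, arr: _Arrays):
    """Shared per-iteration quantities: posterior weights and log-likelihood.

    Returns ``(w_u, py_u, mu_u, ll)`` where ``py_u``/``mu_u`` are the
    outcome probabilities on the grid for unvalidated patients.
    """
    ll = 0.0
    if len(arr.yv):
        py_v = _prob_y(beta, arr.yv, arr.grid[arr.kv], arr.zv)
        perr_v = np.sum(arr.Bv * p[arr.kv, :], axis=1)
        ll += float(np.sum(np.log(np.maximum(py_v, _PROB_FLOOR))))
        ll += float(np.sum(np.log(np.maximum(perr_v, _PROB_FLOOR))))
    if len(arr.yu):
        mu = expit(beta[0] + beta[1] * arr.grid[None, :]
                   + beta[2] * arr.zu[:, None])              # (n_u, K)
        py = (1.0 - mu) + arr.yu[:, None] * (2.0 * mu - 1.0)
        mix = arr.Bu @ p.T
        num = py * mix
        denom = num.sum(axis=1)
        if np.any(denom <= 0):
            raise ValueError("zero mixture probability for an unvalidated "
                             "patient; support/basis misconfiguration")
        ll += float(np.sum(np.log(denom)))
        return num / denom[:, None], py, mu, ll
    K = len(arr.grid)
    return (np.zeros((0, K)), np.zeros((0, K)), np.zeros((0, K)), ll)


def _p_only_updates(beta: np.ndarray, p: np.ndarray, arr: _Arrays,
                    n_steps: int, py: np.ndarray | None = None) -> np.ndarray:
    """EM steps updating only the sieve coefficients (beta held fixed).

    The outcome-probability grid ``py`` does not depend on ``p`` and is
    reused across sub-steps.
    """
    if py is None and len(arr.yu):
        mu = expit(beta[0] + beta[1] * arr.grid[None, :]
                   + beta[2] * arr.zu[:, None])
        py = (1.0 - mu) + arr.yu[:, None] * (2.0 * mu - 1.0)
    has_val = len(arr.yv) > 0
    if has_val:
        onehotT = np.zeros((len(arr.grid), len(arr.kv)))
        onehotT[arr.kv, np.arange(len(arr.kv))] = 1.0
    for _ in range(n_steps):
        C = np.zeros_like(p)
        if has_val:
            perr_v = np.maximum(np.sum(arr.Bv * p[arr.kv, :], axis=1),
                                _PROB_FLOOR)
            C += p * (onehotT @ (arr.Bv / perr_v[:, None]))
        if len(arr.yu):
            mix = arr.Bu @ p.T
            denom = np.maximum(np.sum(py * mix, axis=1), _PROB_FLOOR)
            # w/mix simplifies to py/denom, avoiding 0/0 at empty cells
            C += p * ((py / denom[:, None]).T @ arr.Bu)
        tot = C.sum(axis=0)
        ok = tot > _PROB_FLOOR
        new_p = p.copy()
        new_p[:, ok] = C[:, ok] / tot[ok]
        if not np.all(ok):
            warnings.warn("empty sieve basis cell; keeping previous column",
                          stacklevel=3)
        p = new_p
    return p


def _init_p(arr: _Arrays, basis: SieveBasis) -> np.ndarray:
    """Initial sieve coefficients: validated empirical frequencies smoothed
    toward uniform, modulated by a kernel centred at each basis function."""
    K = len(arr.grid)
    J = basis.n_basis
    counts = np.bincount(arr.kv, minlength=K).astype(float) if len(arr.kv) \
        else np.zeros(K)
    emp = (counts + 1.0) / (counts.sum() + K)
    # Greville-style centre of each basis function, on the x_star axis.
    if basis.degree > 0:
        centres = np.array([
            np.mean(basis.knots[j + 1: j + basis.degree + 1])
            for j in range(J)])
    else:
        centres = np.array([(basis.lo + basis.hi) / 2.0] * J)
    sigma = 0.25
    kern = np.exp(-0.5 * ((arr.grid[:, None] - centres[None, :]) / sigma) ** 2)
    p = emp[:, None] * (0.5 + kern)
    return p / p.sum(axis=0, keepdims=True)


def fit_smle(
    cohort: pd.DataFrame,
    grid: SupportGrid | None = None,
    basis: SieveBasis | None = None,
    n_basis: int | None = None,
    snap: str = "tenths",
    tol: float = 1e-4,
    p_tol: float | None = None,
    max_iter: int = 1000,
    compute_se: bool = False,
    se_h: float = 1.0,
) -> SmleFit:
    """EM fit of the outcome model fusing validated and unvalidated data.

    Convergence requires the maximum coefficient change below ``tol`` and
    the maximum sieve-coefficient change below ``p_tol`` (default
    ``10 * tol``: weakly identified nuisance cells crawl along likelihood
    ridges without moving the coefficients).

    With every patient validated the estimate reduces (exactly, up to solver
    tolerance) to the complete-data logistic MLE on (Y, X, Z).
    """
    if p_tol is None:
        p_tol = 10.0 * tol
    cohort = cohort.reset_index(drop=True)
    n_val = int((cohort["v"] == 1).sum())
    if n_val == 0:
        raise ValueError("no validated patients; the error mechanism is "
                         "unidentifiable")
    if grid is None:
        if snap == "exact":
            pts = np.unique(cohort.loc[cohort["v"] == 1, "x_validated"]
                            .to_numpy(dtype=float))
            grid = SupportGrid(pts) if len(pts) > 1 else SupportGrid(
                np.array([pts[0] - 0.05, pts[0] + 0.05]))
        else:
            grid = SupportGrid(default_grid())
    if basis is None:
        basis = make_basis(cohort["x_star"].to_numpy(dtype=float),
                           n_basis=n_basis, n_validated=n_val)
    arr = _extract_arrays(cohort, grid, basis, snap)
    K = len(grid.points)

    try:
        naive = fit_naive(cohort)
        beta = naive.beta.copy()
        beta_naive = naive.beta
    except (np.linalg.LinAlgError, _logistic.SeparationError):
        # degenerate naive fit (tiny or separable data): start from zero
        beta = np.zeros(3)
        beta_naive = None
    p = _init_p(arr, basis)

    # Static expanded design matrix: validated rows then grid-expanded
    # unvalidated rows (row order (i, k)); only the weights change.
    n_u = len(arr.yu)
    Dv = np.column_stack([np.ones(len(arr.yv)), arr.grid[arr.kv], arr.zv])
    if n_u:
        Du = np.column_stack([
            np.ones(n_u * K),
            np.tile(arr.grid, n_u),
            np.repeat(arr.zu, K),
        ])
        D = np.vstack([Dv, Du])
        y_exp = np.concatenate([arr.yv, np.repeat(arr.yu, K)])
    else:
        D = Dv
        y_exp = arr.yv

    trace: list[float] = []
    converged = False
    it = 0
    prev = (beta.copy(), p.copy())
    for it in range(1, max_iter + 1):
        w_u, py_u, mu_u, ll = _em_state(beta, p, arr)
        if trace and ll < trace[-1] - 1e-9:
            # The single guarded Newton step overshot: redo the previous
            # beta update with a fully converged (step-halving) solve.
            beta, p = prev
            w_u, py_u, mu_u, _ = _em_state(beta, p, arr)
            weights = (np.concatenate([np.ones(len(arr.yv)), w_u.ravel()])
                       if n_u else np.ones(len(arr.yv)))
            beta, _, _, _ = _logistic.fit(D, y_exp, w=weights, beta0=beta)
            p = _p_only_updates(beta, p, arr, 1)
            w_u, py_u, mu_u, ll = _em_state(beta, p, arr)
        trace.append(ll)
        prev = (beta.copy(), p.copy())

        new_p = _p_only_updates(beta, p, arr, 8, py=py_u)
        weights = (np.concatenate([np.ones(len(arr.yv)), w_u.ravel()])
                   if n_u else np.ones(len(arr.yv)))
        mu_exp = (np.concatenate([expit(Dv @ beta), mu_u.ravel()])
                  if n_u else expit(Dv @ beta))
        grad = D.T @ (weights * (y_exp - mu_exp))
        wd = weights * mu_exp * (1.0 - mu_exp)
        H = D.T @ (D * wd[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # flat coefficient direction (tiny or degenerate data): ascend
            # within the identified subspace
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        new_beta = beta + step
        done = (float(np.max(np.abs(new_beta - beta))) < tol
                and float(np.max(np.abs(new_p - p))) < p_tol)
        beta, p = new_beta, new_p
        if done:
            w_u, py_u, mu_u, ll = _em_state(beta, p, arr)
            trace.append(ll)
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations",
                      stacklevel=2)

    fit = SmleFit(beta=beta, p=p, grid=grid, basis=basis,
                  loglik_trace=np.asarray(trace), converged=converged,
                  n_iter=it, n=arr.n, n_validated=n_val,
                  beta_naive=beta_naive)
    if compute_se:
        profile_se(fit, cohort, h=se_h, snap=snap)
    return fit


def _profile_loglik(beta: np.ndarray, p0: np.ndarray, arr: _Arrays,
                    tol: float = 1e-8, max_iter: int = 5000) -> float:
    """Log-likelihood maximized over the sieve coefficients at fixed beta."""
    p = p0.copy()
    py = None
    if len(arr.yu):
        mu = expit(beta[0] + beta[1] * arr.grid[None, :]
                   + beta[2] * arr.zu[:, None])
        py = (1.0 - mu) + arr.yu[:, None] * (2.0 * mu - 1.0)
    ll = _loglik_arrays(beta, p, arr)
    for _ in range(max_iter):
        p = _p_only_updates(beta, p, arr, 1, py=py)
        new_ll = _loglik_arrays(beta, p, arr)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return ll


def profile_se(fit: SmleFit, cohort: pd.DataFrame, h: float = 1.0,
               snap: str = "tenths") -> np.ndarray:
    """Profile-likelihood standard errors for the three coefficients.

    The step size is ``h / sqrt(N)``; the full 3x3 profile Hessian is built
    by central differences (including cross terms) and inverted.

    Raises
    ------
    RuntimeError
        If the profile curvature is not negative definite.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    cohort = cohort.reset_index(drop=True)
    arr = _extract_arrays(cohort, fit.grid, fit.basis, snap)
    step = h / np.sqrt(arr.n)
    beta_hat = fit.beta
    p_hat = fit.p

    cache: dict[tuple[int, ...], float] = {}

    def pl(offsets: tuple[int, int, int]) -> float:
        if offsets not in cache:
            beta = beta_hat + step * np.asarray(offsets, dtype=float)
            cache[offsets] = _profile_loglik(beta, p_hat, arr)
        return cache[offsets]

    H = np.empty((3, 3))
    centre = pl((0, 0, 0))
    for m in range(3):
        em = tuple(int(i == m) for i in range(3))
        neg = tuple(-v for v in em)
        H[m, m] = (pl(em) - 2.0 * centre + pl(neg)) / step**2
    for m in range(3):
        for l in range(m + 1, 3):
            pp = tuple(int(i == m) + int(i == l) for i in range(3))
            pm = tuple(int(i == m) - int(i == l) for i in range(3))
            mp = tuple(-int(i == m) + int(i == l) for i in range(3))
            mm = tuple(-int(i == m) - int(i == l) for i in range(3))
            H[m, l] = H[l, m] = (pl(pp) - pl(pm) - pl(mp) + pl(mm)) / (
                4.0 * step**2)
    cov = np.linalg.inv(-H)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise RuntimeError("profile log-likelihood curvature is not negative "
                           "definite; no standard errors available")
    fit.cov = cov
    fit.se = np.sqrt(diag)
    return fit.se


def predict_validated_ali(
    fit: SmleFit,
    x_star: np.ndarray | float,
    z: np.ndarray | float | None = None,
    y: np.ndarray | float | None = None,
    use_outcome: bool = True,
) -> np.ndarray:
    """Expected validated index given the error-prone index (and optionally
    the outcome), under the fitted model.

    With ``use_outcome`` the prediction is the posterior mean over the grid,
    ``sum_k x_k Pr(Y|x_k,Z) Pr(x_k|X*) / sum_k Pr(Y|x_k,Z) Pr(x_k|X*)``;
    without it, the error-mechanism mean ``sum_k x_k Pr(x_k|X*)``.
    Predictions are convex combinations of the grid points.
    """
    xs = np.atleast_1d(np.asarray(x_star, dtype=float))
    mech = fit.error_mechanism(xs)                           # (n, K)
    g = fit.grid.points
    if not use_outcome:
        return mech @ g
    if y is None or z is None:
        raise ValueError("use_outcome=True requires y and z")
    yv = np.broadcast_to(np.asarray(y, dtype=float), xs.shape)
    zv = np.broadcast_to(np.asarray(z, dtype=float), xs.shape)
    py = _prob_y(fit.beta, yv[:, None], g[None, :], zv[:, None])
    num = (py * mech) @ g
    den = np.sum(py * mech, axis=1)
    return num / np.maximum(den, _PROB_FLOOR)


def predict_cohort(fit: SmleFit, cohort: pd.DataFrame,
                   use_outcome: bool = True) -> pd.Series:
    """Per-patient predicted validated index; validated patients keep their
    observed value unchanged."""
    pred = predict_validated_ali(
        fit,
        cohort["x_star"].to_numpy(dtype=float),
        z=cohort["z"].to_numpy(dtype=float),
        y=cohort["y"].to_numpy(dtype=float),
        use_outcome=use_outcome,
    )
    out = pd.Series(pred, index=cohort.index, name="ali_predicted")
    validated = cohort["v"] == 1
    out[validated] = cohort.loc[validated, "x_validated"]
    return out
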