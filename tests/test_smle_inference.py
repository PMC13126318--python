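import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from alivalid import smle_inference as si
from alivalid._logistic import SeparationError
from alivalid.synthetic_cohort import GeneratorConfig, apply_validation, generate_cohort
from alivalid.validation_designs import sample_srs
from conftest import BETA_TRUE, low_error_config


def tiny_instance():
    """Bounded-likelihood instance: every covariate pattern carries both
    outcomes, grid of two points, constant (one-function) sieve basis."""
    cohort = pd.DataFrame({
        "patient_id": range(10),
        "y":      [1, 0, 1, 0, 1, 0, 0, 1, 0, 0],
        "z":      [0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.5, 1.0, 1.0, 0.2],
        "x_star": [0.3, 0.3, 0.7, 0.7, 0.3, 0.3, 0.5, 0.7, 0.7, 0.4],
        "v":      [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
        "x_validated": [0.2, 0.2, 0.8, 0.8] + [np.nan] * 6,
    })
    grid = si.SupportGrid(np.array([0.2, 0.8]))
    basis = si.SieveBasis(knots=np.array([0.0, 1.0]), degree=0, lo=0.0,
                          hi=1.0)
    return cohort, grid, basis


def brute_force_mle(cohort, grid, basis, n_starts=12):
    """Direct maximization of the observed-data log-likelihood over the
    coefficients and (logit-parametrized) sieve column."""
    K, J = len(grid.points), basis.n_basis
    assert J == 1 and K == 2, "oracle written for the 2-point, 1-basis case"

    def negll(theta):
        q = expit(theta[3])
        p = np.array([[q], [1.0 - q]])
        return -si.observed_loglik(theta[:3], p, cohort, grid, basis,
                                   snap="exact")

    best = None
    for s in range(n_starts):
        rng = np.random.default_rng(s)
        r = minimize(negll, rng.normal(0, 1, 4), method="Nelder-Mead",
                     options={"xatol": 1e-11, "fatol": 1e-13,
                              "maxiter": 40000, "maxfev": 40000})
        if best is None or r.fun < best.fun:
            best = r
    return best.x[:3], -best.fun


@pytest.fixture(scope="module")
def fitted():
    """One moderate fit shared by the structural tests."""
    cfg = low_error_config(seed=101, n=600)
    cohort = generate_cohort(cfg)
    sel = sample_srs(cohort, 80, seed=1)
    cohort = apply_validation(cohort, sel.selected_ids, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = si.fit_smle(cohort)
    return cohort, fit


class TestNaive:
    def test_null_slopes_near_zero(self):
        cfg = GeneratorConfig(n_patients=20_000, beta=(-0.5, 0.0, 0.0),
                              seed=2)
        fit = si.fit_naive(generate_cohort(cfg))
        assert abs(fit.beta[1]) < 2.5 * fit.se[1]
        assert abs(fit.beta[2]) < 2.5 * fit.se[2]

    def test_balanced_null_intercept_is_logit_event_rate(self):
        # perfectly balanced data: y = 1 equally often within every
        # covariate pattern, so the slopes vanish and the intercept is the
        # logit of the overall event rate
        n = 400
        cohort = pd.DataFrame({
            "y": [0, 1] * (n // 2),
            "x_star": np.tile([0.2, 0.2, 0.8, 0.8], n // 4),
            "z": np.tile([0.0, 1.0, 1.0, 0.0], n // 4),
        })
        fit = si.fit_naive(cohort)
        rate = cohort["y"].mean()
        assert fit.beta[0] == pytest.approx(np.log(rate / (1 - rate)),
                                            abs=1e-6)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-6)
        assert fit.beta[2] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_no_error(self):
        cfg = GeneratorConfig(n_patients=10_000, beta=BETA_TRUE, tpr=1.0,
                              fpr=0.0, missingness=0.0, seed=3)
        fit = si.fit_naive(generate_cohort(cfg))
        for est, se, truth in zip(fit.beta, fit.se, BETA_TRUE):
            assert abs(est - truth) < 2.5 * se

    def test_separation_reported(self):
        cohort = pd.DataFrame({
            "y": [0, 0, 0, 1, 1, 1],
            "x_star": [0.0, 0.1, 0.2, 0.8, 0.9, 1.0],
            "z": [0.0] * 6,
        })
        with pytest.raises(SeparationError):
            si.fit_naive(cohort)


class TestObservedLoglik:
    def test_hand_enumerated_tiny_sum(self):
        # 3 patients, grid of 2 points, constant basis: enumerate by hand
        cohort = pd.DataFrame({
            "patient_id": [0, 1, 2],
            "y": [1, 0, 1],
            "z": [0.0, 1.0, 2.0],
            "x_star": [0.3, 0.5, 0.7],
            "v": [1, 0, 0],
            "x_validated": [0.2, np.nan, np.nan],
        })
        grid = si.SupportGrid(np.array([0.2, 0.8]))
        basis = si.SieveBasis(knots=np.array([0.0, 1.0]), degree=0,
                              lo=0.0, hi=1.0)
        beta = np.array([-1.0, 2.0, 0.5])
        p = np.array([[0.7], [0.3]])

        def pr_y(y, x, z):
            mu = expit(beta[0] + beta[1] * x + beta[2] * z)
            return mu if y == 1 else 1 - mu

        expected = (np.log(pr_y(1, 0.2, 0.0)) + np.log(0.7)          # validated
                    + np.log(pr_y(0, 0.2, 1.0) * 0.7
                             + pr_y(0, 0.8, 1.0) * 0.3)              # unval 1
                    + np.log(pr_y(1, 0.2, 2.0) * 0.7
                             + pr_y(1, 0.8, 2.0) * 0.3))             # unval 2
        got = si.observed_loglik(beta, p, cohort, grid, basis, snap="exact")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_all_validated_reduces_to_complete_data(self):
        cohort = pd.DataFrame({
            "patient_id": [0, 1],
            "y": [1, 0],
            "z": [0.0, 1.0],
            "x_star": [0.3, 0.7],
            "v": [1, 1],
            "x_validated": [0.2, 0.8],
        })
        grid = si.SupportGrid(np.array([0.2, 0.8]))
        basis = si.SieveBasis(knots=np.array([0.0, 1.0]), degree=0,
                              lo=0.0, hi=1.0)
        beta = np.array([0.5, -1.0, 0.3])
        p = np.array([[0.5], [0.5]])
        mu0 = expit(beta[0] + beta[1] * 0.2)
        mu1 = expit(beta[0] + beta[1] * 0.8 + beta[2])
        expected = (np.log(mu0) + np.log(1 - mu1) + 2 * np.log(0.5))
        got = si.observed_loglik(beta, p, cohort, grid, basis, snap="exact")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_degenerate_p_matches_naive_loglik_at_x_star(self):
        # histogram basis separating the two x_star values; p maps each
        # basis cell to its own x_star with probability one
        cohort = pd.DataFrame({
            "patient_id": range(4),
            "y": [1, 0, 0, 1],
            "z": [0.0, 0.5, 1.0, 1.5],
            "x_star": [0.2, 0.2, 0.8, 0.8],
            "v": [0, 0, 0, 0],
        })
        grid = si.SupportGrid(np.array([0.2, 0.8]))
        # histogram (degree-0) basis with cells [0, 0.5) and [0.5, 1]
        basis = si.SieveBasis(knots=np.array([0.0, 0.5, 1.0]), degree=0,
                              lo=0.0, hi=1.0)
        # identity error model: cell at low x_star -> point 0.2, high -> 0.8
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        beta = np.array([-0.3, 1.2, 0.4])
        mu = expit(beta[0] + beta[1] * cohort["x_star"]
                   + beta[2] * cohort["z"])
        naive_ll = float(np.sum(np.log(np.where(cohort["y"] == 1,
                                                mu, 1 - mu))))
        got = si.observed_loglik(beta, p, cohort, grid, basis, snap="exact")
        assert got == pytest.approx(naive_ll, abs=1e-9)

    def test_invalid_p_rejected(self):
        cohort, grid, basis = tiny_instance()
        with pytest.raises(ValueError, match="probability"):
            si.observed_loglik(np.zeros(3), np.array([[0.7], [0.7]]),
                               cohort, grid, basis, snap="exact")


class TestFitSmle:
    def test_all_validated_equals_complete_data_mle(self, clean_cohort):
        cfg = GeneratorConfig(n_patients=800, beta=BETA_TRUE, tpr=1.0,
                              fpr=0.0, missingness=0.0, seed=7)
        cohort = apply_validation(clean_cohort,
                                  clean_cohort["patient_id"], cfg)
        assert (cohort["v"] == 1).all()
        fit = si.fit_smle(cohort, tol=1e-8)
        complete = cohort.copy()
        complete["x_star"] = complete["x_validated"]
        naive = si.fit_naive(complete)
        np.testing.assert_allclose(fit.beta, naive.beta, atol=5e-5)

    def test_tiny_instance_matches_brute_force(self):
        cohort, grid, basis = tiny_instance()
        beta_bf, ll_bf = brute_force_mle(cohort, grid, basis)
        fit = si.fit_smle(cohort, grid=grid, basis=basis, snap="exact",
                          tol=1e-11, max_iter=50_000)
        np.testing.assert_allclose(fit.beta, beta_bf, atol=1e-4)
        assert fit.loglik == pytest.approx(ll_bf, abs=1e-8)

    def test_em_monotone_loglik(self, fitted):
        _, fit = fitted
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_error_model_columns_normalized(self, fitted):
        _, fit = fitted
        np.testing.assert_allclose(fit.p.sum(axis=0), 1.0, atol=1e-8)
        assert (fit.p >= 0).all()

    def test_error_mechanism_rows_normalized(self, fitted):
        cohort, fit = fitted
        mech = fit.error_mechanism(cohort["x_star"].to_numpy())
        np.testing.assert_allclose(mech.sum(axis=1), 1.0, atol=1e-8)

    def test_no_validated_patients_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="validated"):
            si.fit_smle(small_cohort)

    def test_convergence_flag_and_trace(self, fitted):
        _, fit = fitted
        assert fit.converged
        assert fit.n_iter <= 1000
        assert len(fit.loglik_trace) >= fit.n_iter

    def test_json_round_trip(self, fitted):
        _, fit = fitted
        back = si.SmleFit.from_json(fit.to_json())
        np.testing.assert_allclose(back.beta, fit.beta)
        np.testing.assert_allclose(back.p, fit.p)
        x = np.array([0.1, 0.4, 0.7])
        np.testing.assert_allclose(back.error_mechanism(x),
                                   fit.error_mechanism(x))


class TestProfileSe:
    def test_complete_validation_matches_logistic_se(self, clean_cohort):
        cfg = GeneratorConfig(n_patients=800, beta=BETA_TRUE, tpr=1.0,
                              fpr=0.0, missingness=0.0, seed=7)
        cohort = apply_validation(clean_cohort,
                                  clean_cohort["patient_id"], cfg)
        fit = si.fit_smle(cohort, tol=1e-8)
        se = si.profile_se(fit, cohort)
        complete = cohort.copy()
        complete["x_star"] = complete["x_validated"]
        naive = si.fit_naive(complete)
        np.testing.assert_allclose(se, naive.se, rtol=0.05)

    def test_h_insensitive(self, fitted):
        cohort, fit = fitted
        ses = [si.profile_se(fit, cohort, h=h) for h in (0.5, 1.0, 2.0)]
        for se in ses[1:]:
            np.testing.assert_allclose(se, ses[0], rtol=0.01)

    def test_root_n_consistency(self):
        # quadrupling the sample size roughly halves the standard errors
        ses = {}
        for n, seed in ((400, 41), (1600, 42)):
            cfg = GeneratorConfig(n_patients=n, beta=BETA_TRUE, tpr=1.0,
                                  fpr=0.0, missingness=0.0, seed=seed)
            cohort = generate_cohort(cfg)
            cohort = apply_validation(cohort, cohort["patient_id"], cfg)
            fit = si.fit_smle(cohort, tol=1e-8)
            ses[n] = si.profile_se(fit, cohort)
        ratio = ses[400] / ses[1600]
        assert np.all(ratio > 1.4) and np.all(ratio < 2.9)

    def test_requires_converged_fit(self, fitted):
        cohort, fit = fitted
        broken = si.SmleFit(**{**fit.__dict__, "converged": False})
        with pytest.raises(ValueError, match="converged"):
            si.profile_se(broken, cohort)


class TestPredict:
    def test_identity_error_model_returns_x_star(self):
        grid = si.SupportGrid(np.array([0.2, 0.8]))
        basis = si.SieveBasis(knots=np.array([0.0, 0.5, 1.0]), degree=0,
                              lo=0.0, hi=1.0)
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        fit = si.SmleFit(beta=np.array([0.0, 1.0, 0.0]), p=p, grid=grid,
                         basis=basis, loglik_trace=np.array([0.0]),
                         converged=True, n_iter=1, n=4, n_validated=2)
        pred = si.predict_validated_ali(fit, np.array([0.2, 0.8]),
                                        use_outcome=False)
        np.testing.assert_allclose(pred, [0.2, 0.8])

    def test_two_point_posterior_mean_by_hand(self):
        grid = si.SupportGrid(np.array([0.0, 1.0]))
        basis = si.SieveBasis(knots=np.array([0.0, 1.0]), degree=0,
                              lo=0.0, hi=1.0)
        p = np.array([[0.4], [0.6]])
        beta = np.array([0.0, 2.0, 0.0])
        fit = si.SmleFit(beta=beta, p=p, grid=grid, basis=basis,
                         loglik_trace=np.array([0.0]), converged=True,
                         n_iter=1, n=1, n_validated=1)
        # prior mean ignores y
        prior = si.predict_validated_ali(fit, 0.5, use_outcome=False)
        assert prior[0] == pytest.approx(0.6)
        # posterior with y = 1: weights prop to expit(0)*0.4, expit(2)*0.6
        w0 = expit(0.0) * 0.4
        w1 = expit(2.0) * 0.6
        post = si.predict_validated_ali(fit, 0.5, z=0.0, y=1.0,
                                        use_outcome=True)
        assert post[0] == pytest.approx(w1 / (w0 + w1))

    def test_predictions_within_grid_range(self, fitted):
        cohort, fit = fitted
        pred = si.predict_validated_ali(
            fit, cohort["x_star"].to_numpy(),
            z=cohort["z"].to_numpy(), y=cohort["y"].to_numpy())
        assert (pred >= fit.grid.points.min() - 1e-12).all()
        assert (pred <= fit.grid.points.max() + 1e-12).all()

    def test_validated_patients_keep_observed_value(self, fitted):
        cohort, fit = fitted
        pred = si.predict_cohort(fit, cohort)
        mask = cohort["v"] == 1
        np.testing.assert_allclose(pred[mask],
                                   cohort.loc[mask, "x_validated"])

    def test_x_star_outside_range_clamped_with_warning(self, fitted):
        _, fit = fitted
        with pytest.warns(UserWarning, match="clamp"):
            pred = si.predict_validated_ali(fit, np.array([5.0]),
                                            use_outcome=False)
        assert fit.grid.points.min() <= pred[0] <= fit.grid.points.max()


class TestBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 500)
        basis = si.make_basis(x, n_basis=8)
        B = basis.design(x)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)
        assert (B >= 0).all()

    def test_default_dimension_rule(self):
        x = np.random.default_rng(1).uniform(0, 1, 1000)
        basis = si.make_basis(x, n_validated=100)
        assert basis.n_basis == int(np.ceil(2 * 100 ** (1 / 3)))

    def test_degenerate_single_basis(self):
        x = np.array([0.1, 0.5, 0.9])
        basis = si.make_basis(x, n_basis=1)
        B = basis.design(x)
        np.testing.assert_allclose(B, 1.0)
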