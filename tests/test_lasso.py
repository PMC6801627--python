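"""Standardization, the L1 logistic path (vs R glmnet oracle) and marker ranking."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from uropanel import CohortTable, rank_by_lasso, standardize
from uropanel._fast import logistic_lasso_path
from uropanel.lasso import fit_l1_logistic_cv, lambda_grid, log_transform

from test_screen import _two_group_cohort


def _logistic_data(n=120, p=6, beta=None, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
    eta = X @ beta
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    X = (X - X.mean(0)) / X.std(0)
    return np.ascontiguousarray(X), y


class TestStandardize:
    def test_columns_have_unit_sd_zero_mean(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.lognormal(1, 2, (50, 5)), columns=list("abcde"))
        Z, params = standardize(x)
        assert np.allclose(Z.mean(0), 0.0, atol=1e-10)
        assert np.allclose(Z.std(0), 1.0, atol=1e-10)

    def test_params_reproduce_training_matrix(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.lognormal(0, 1, (40, 3)), columns=list("abc"))
        Z, params = standardize(x)
        assert np.allclose(params.apply(x), Z, atol=1e-12)

    def test_constant_column_dropped_and_recorded(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame({"a": rng.lognormal(0, 1, 30), "c": np.full(30, 7.0)})
        with pytest.warns(UserWarning, match="constant"):
            Z, params = standardize(x)
        assert params.dropped == ["c"]
        assert params.markers == ["a"]
        assert Z.shape[1] == 1

    def test_held_out_data_not_unit_sd_under_training_params(self):
        rng = np.random.default_rng(3)
        train = pd.DataFrame(rng.lognormal(0, 1, (60, 2)), columns=["a", "b"])
        held = pd.DataFrame(rng.lognormal(0.5, 2, (60, 2)), columns=["a", "b"])
        _, params = standardize(train)
        Zh = params.apply(held)
        assert not np.allclose(Zh.std(0), 1.0, atol=0.05)


class TestL1Path:
    def test_huge_lambda_gives_intercept_only_model(self):
        X, y = _logistic_data(seed=4)
        lams = np.array([10.0, 5.0])
        icpt, coefs, conv = logistic_lasso_path(X, y, lams)
        assert np.all(coefs == 0.0)
        ybar = y.mean()
        assert icpt[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_matches_r_glmnet_oracle(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH in this environment"
        X, y = _logistic_data(n=80, p=6, beta=np.array([1.2, -0.8, 0, 0, 0, 0]), seed=7)
        lams = np.array([0.2, 0.1, 0.05, 0.02, 0.01, 0.005])
        icpt, coefs, conv = logistic_lasso_path(X, y, lams)
        assert conv.all()
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "lam.csv", lams, delimiter=",")
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("X.csv", header=FALSE))
            y <- scan("y.csv", quiet=TRUE)
            lam <- scan("lam.csv", quiet=TRUE)
            fit <- glmnet(X, y, family="binomial", lambda=lam,
                          standardize=FALSE, thresh=1e-12)
            co <- as.matrix(coef(fit, s=lam, exact=TRUE, x=X, y=y))
            write.table(t(co), "glmnet.csv", sep=",",
                        row.names=FALSE, col.names=FALSE)
        """))
        subprocess.run([rscript, "fit.R"], cwd=tmp_path, check=True,
                       capture_output=True, timeout=300)
        theirs = np.loadtxt(tmp_path / "glmnet.csv", delimiter=",")
        ours = np.column_stack([icpt, coefs])
        assert np.abs(ours - theirs).max() < 1e-4

    def test_duplicated_column_grouped_shrinkage(self):
        X, y = _logistic_data(n=150, p=4, beta=np.array([1.5, 0, 0, 0]), seed=8)
        lams = lambda_grid(X, y, size=30)
        _, coefs_single, _ = logistic_lasso_path(X, y, lams)
        Xd = np.ascontiguousarray(np.column_stack([X, X[:, 0]]))
        icpt_d, coefs_dup, _ = logistic_lasso_path(Xd, y, lams)
        # the two copies together carry the single column's coefficient
        combined = coefs_dup[:, 0] + coefs_dup[:, 4]
        assert np.abs(combined - coefs_single[:, 0]).max() < 1e-3
        assert np.abs(coefs_dup[:, 1:4] - coefs_single[:, 1:4]).max() < 1e-3

    def test_cv_fit_sparsity_recovery(self):
        # 1 informative (d=2 on the logit scale) + 5 null markers, n=200:
        # the informative coefficient is always kept, nulls are mostly zeroed
        null_zero = []
        inf_nonzero = 0
        for seed in range(10):
            X, y = _logistic_data(n=200, p=6, beta=np.array([2.0, 0, 0, 0, 0, 0]), seed=100 + seed)
            lam, icpt, beta = fit_l1_logistic_cv(X, y, n_folds=10, seed=seed)
            inf_nonzero += beta[0] != 0.0
            null_zero.append((beta[1:] == 0.0).mean())
        assert inf_nonzero == 10
        assert np.mean(null_zero) >= 0.5


class TestRankByLasso:
    def test_single_iteration_equals_single_fit_order(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        imp = rank_by_lasso(cohort, n_iter=1, seed=5)
        X, params = standardize(cohort)
        y = cohort.labels().astype(float)
        fold_seed = int(np.random.default_rng(np.random.SeedSequence(5)).integers(0, 2**31 - 1, size=1)[0])
        _, _, beta = fit_l1_logistic_cv(X, y, seed=fold_seed)
        expected = np.abs(beta)
        got = imp.table.set_index("marker").loc[params.markers, "mean_abs_coef"].to_numpy()
        assert np.allclose(got, expected)

    def test_bit_reproducible_with_fixed_seed(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        a = rank_by_lasso(cohort, n_iter=3, seed=9)
        b = rank_by_lasso(cohort, n_iter=3, seed=9)
        assert np.array_equal(a.coefs, b.coefs)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_column_order_invariance(self, analyzed_cohort):
        cohort, _ = analyzed_cohort
        imp = rank_by_lasso(cohort, n_iter=2, seed=13)
        shuffled = CohortTable(cohort.meta.copy(), cohort.x[list(reversed(cohort.markers))].copy())
        imp2 = rank_by_lasso(shuffled, n_iter=2, seed=13)
        a = imp.table.set_index("marker")["mean_abs_coef"]
        b = imp2.table.set_index("marker")["mean_abs_coef"]
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-5)

    def test_null_only_cohort_has_tiny_coefficients_typically(self):
        # With a flat cross-validated deviance curve the arg-min lambda is
        # noisy, so the bound is a typical-case (median over cohorts)
        # calibration rather than a per-cohort guarantee.
        maxima = []
        for seed in (17, 23, 31, 47, 59):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(0, 1, (300, 8))
            cohort = _two_group_cohort(x, [f"m{j}" for j in range(8)])
            imp = rank_by_lasso(cohort, n_iter=10, seed=seed)
            maxima.append(imp.table["mean_abs_coef"].max())
        assert np.median(maxima) < 0.05

    def test_selection_frequency_of_null_decreases_with_n(self):
        # On null-only cohorts the cross-validated penalty keeps (or
        # strengthens) its hold as n grows, so null markers enter less often.
        freqs = {}
        for n in (100, 400):
            accum = []
            for seed in range(5):
                rng = np.random.default_rng(7000 * n + seed)
                x = rng.lognormal(0, 1, (n, 6))
                cohort = _two_group_cohort(x, [f"m{j}" for j in range(6)])
                imp = rank_by_lasso(cohort, n_iter=8, seed=seed)
                accum.append(imp.table["selection_freq"].mean())
            freqs[n] = np.mean(accum)
        assert freqs[400] <= freqs[100] + 0.02
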