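"""REML engine checks against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.optimize
from scipy import stats as sps

from mvcs.mixedlm import (
    KroneckerCS,
    Unstructured,
    reml_fit,
    satterthwaite_df,
    satterthwaite_nu,
    wald_f_test,
)
from mvcs.stats import SI_FACTORS, SI_TERMS, _build_design, fit_lmm_si, fit_repeated

CONDS = [("cTBS", "SEQ"), ("cTBS", "RND"), ("iTBS", "SEQ"), ("iTBS", "RND")]


def _paired_df(rng, n):
    y1 = rng.normal(0.3, 1.0, n)
    y2 = 0.5 * y1 + rng.normal(0.0, 0.8, n)
    return pd.DataFrame(
        {
            "subject": np.repeat([f"s{i:02d}" for i in range(n)], 2),
            "condition": ["A", "B"] * n,
            "y": np.column_stack([y1, y2]).ravel(),
        }
    ), y1, y2


def _si_df(rng, n=10, effect=0.0):
    A = rng.normal(size=(4, 4))
    V = A @ A.T / 4 + np.eye(4) * 0.3
    rows = []
    for s in range(n):
        e = rng.multivariate_normal(np.zeros(4), V)
        for j, (stim, task) in enumerate(CONDS):
            mu = 0.2 + effect * (task == "SEQ")
            rows.append((f"s{s:02d}", (s + j) % 4 + 1, stim, task, mu + e[j]))
    return pd.DataFrame(
        rows, columns=["subject", "visit", "stimulation", "task", "si"]
    )


class TestPairedTEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_f_equals_squared_t_and_df_n_minus_1(self, seed):
        rng = np.random.default_rng(seed)
        n = 8 + seed
        df, y1, y2 = _paired_df(rng, n)
        res = fit_repeated(
            df, response="y", factors={"condition": ("A", "B")},
            terms=(("condition",),), repeated=("condition",),
        )
        t2 = sps.ttest_rel(y1, y2).statistic ** 2
        row = res.anova.iloc[0]
        assert row["F"] == pytest.approx(t2, abs=1e-6, rel=1e-6)
        assert row["df_den"] == pytest.approx(n - 1, abs=1e-6)


class TestRemlCorrectness:
    def test_loglik_matches_dense_oracle(self, rng):
        df = _si_df(rng, n=8)
        res = fit_lmm_si(df)
        # independent dense-matrix evaluation of the REML criterion
        cell = {c: i for i, c in enumerate(CONDS)}
        df = df.assign(
            u=[cell[(a, b)] for a, b in zip(df.stimulation, df.task)]
        ).sort_values(["subject", "u"]).reset_index(drop=True)
        X, _, _ = _build_design(df, SI_FACTORS, SI_TERMS)
        y = df["si"].to_numpy()
        n_sub = df["subject"].nunique()
        omega = np.kron(np.eye(n_sub), res.V)
        oi = np.linalg.inv(omega)
        xtox = X.T @ oi @ X
        beta = np.linalg.solve(xtox, X.T @ oi @ y)
        r = y - X @ beta
        ll = -0.5 * (
            np.linalg.slogdet(omega)[1]
            + np.linalg.slogdet(xtox)[1]
            + r @ oi @ r
        )
        assert res.loglik == pytest.approx(ll, abs=1e-8)
        assert np.allclose(res.fit.beta, beta, atol=1e-8)

    def test_matches_nlme_gls_fitted_covariance(self):
        # Frozen oracle: the same dataset fitted with R nlme::gls
        # (corSymm + varIdent, REML) yields this covariance matrix; the
        # dataset is regenerated deterministically below.
        rng = np.random.default_rng(42)
        n = 8
        A = rng.normal(size=(4, 4))
        Vt = A @ A.T / 4 + np.eye(4) * 0.3
        rows = []
        for s in range(n):
            e = rng.multivariate_normal(np.zeros(4), Vt)
            for j, (stim, task) in enumerate(CONDS):
                rows.append(
                    (f"s{s:02d}", (s + j) % 4 + 1, stim, task,
                     0.2 + 0.1 * (task == "SEQ") + e[j])
                )
        df = pd.DataFrame(
            rows, columns=["subject", "visit", "stimulation", "task", "si"]
        )
        res = fit_lmm_si(df)
        v_gls = np.array(
            [
                [0.25816554, -0.040833, 0.07742895, 0.11786512],
                [-0.040833, 0.94771301, -0.01316814, -0.01905689],
                [0.07742895, -0.01316814, 0.02822907, 0.07461325],
                [0.11786512, -0.01905689, 0.07461325, 0.39994984],
            ]
        )
        assert np.max(np.abs(res.V - v_gls)) < 5e-4

    def test_loglik_never_decreases_over_iterations(self, rng):
        df = _si_df(rng, n=12, effect=0.3)
        res = fit_lmm_si(df)
        hist = np.array(res.fit.history)
        assert np.all(np.diff(hist) >= -1e-10)
        assert res.converged

    def test_gls_identity_saturated_design(self, rng):
        # complete balanced saturated design: fixed effects equal
        # cell-mean contrasts regardless of the covariance estimate
        df = _si_df(rng, n=9)
        res = fit_repeated(
            df, response="si",
            factors={k: v for k, v in SI_FACTORS.items() if k != "visit"},
            terms=(("stimulation",), ("task",), ("stimulation", "task")),
            repeated=("stimulation", "task"),
        )
        cell_means = df.groupby(["stimulation", "task"])["si"].mean()
        for label, row in res.cell_rows.items():
            stim = "cTBS" if label.startswith("c") else "iTBS"
            task = "SEQ" if label.endswith("SEQ") else "RND"
            assert float(row @ res.fit.beta) == pytest.approx(
                cell_means.loc[(stim, task)], abs=1e-8
            )

    def test_constant_response_degenerate_flagged(self):
        df = _si_df(np.random.default_rng(0), n=5)
        df["si"] = 1.25
        res = fit_lmm_si(df)
        assert res.fit.degenerate
        assert (res.anova["F"] == 0).all()
        assert (res.anova["p"] == 1.0).all()

    def test_kronecker_matches_dense_scipy_optimizer(self):
        # independent route: optimize the dense REML criterion with
        # scipy over the same parameterization and compare the optimum
        rng = np.random.default_rng(10)
        n_sub, b = 8, 3
        U_t = np.array([[1.0, 0.4], [0.4, 0.8]])
        r_t = 0.3
        R_t = np.full((b, b), r_t)
        np.fill_diagonal(R_t, 1.0)
        V_t = np.kron(U_t, R_t)
        X_rows, y_rows, subj, units = [], [], [], []
        for s in range(n_sub):
            e = rng.multivariate_normal(np.zeros(2 * b), V_t)
            for c in range(2):
                for blk in range(b):
                    X_rows.append([1.0, 1.0 if c == 0 else -1.0])
                    y_rows.append(0.5 + 0.4 * (c == 0) + e[c * b + blk])
                    subj.append(s)
                    units.append(c * b + blk)
        X = np.array(X_rows)
        y = np.array(y_rows)
        cov = KroneckerCS(2, b)
        fit = reml_fit(y, X, np.array(subj), np.array(units), cov)
        assert fit.converged

        def neg_reml(theta):
            V = cov.build(theta)
            if np.tanh(theta[-1]) <= -1 / (b - 1) + 1e-9:
                return 1e10
            omega = np.kron(np.eye(n_sub), np.zeros((2 * b, 2 * b)))
            # subjects are complete: same pattern for everyone
            blocks = [V[np.ix_(np.arange(2 * b), np.arange(2 * b))]] * n_sub
            omega = scipy.linalg.block_diag(*blocks)
            try:
                oi = np.linalg.inv(omega)
            except np.linalg.LinAlgError:
                return 1e10
            xtox = X.T @ oi @ X
            sign, ld = np.linalg.slogdet(xtox)
            if sign <= 0:
                return 1e10
            beta = np.linalg.solve(xtox, X.T @ oi @ y)
            r = y - X @ beta
            return 0.5 * (np.linalg.slogdet(omega)[1] + ld + r @ oi @ r)

        res = scipy.optimize.minimize(
            neg_reml, cov.initial(np.eye(2), 0.1), method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-5)
        assert np.tanh(fit.theta[-1]) == pytest.approx(
            np.tanh(res.x[-1]), abs=1e-3
        )


class TestSatterthwaite:
    def test_one_sample_mean_df_is_n_minus_1(self, rng):
        n = 14
        y = rng.normal(2.0, 1.0, n)
        fit = reml_fit(
            y, np.ones((n, 1)), np.arange(n), np.zeros(n, dtype=int),
            Unstructured(1),
        )
        assert satterthwaite_df(fit, np.array([1.0])) == pytest.approx(
            n - 1, abs=1e-6
        )

    def test_nu_decreases_when_theta_uncertainty_inflates(self):
        v = 0.5
        g = np.array([0.2, -0.1])
        A = np.array([[0.05, 0.01], [0.01, 0.08]])
        assert satterthwaite_nu(v, g, 4.0 * A) == pytest.approx(
            satterthwaite_nu(v, g, A) / 4.0
        )
        assert satterthwaite_nu(v, g, 4.0 * A) < satterthwaite_nu(v, g, A)

    def test_single_df_contrast_equals_omnibus(self, rng):
        # in a 2-condition sub-design the cell-difference contrast and
        # the omnibus condition effect are the same test
        df, _, _ = _paired_df(rng, 10)
        res = fit_repeated(
            df, response="y", factors={"condition": ("A", "B")},
            terms=(("condition",),), repeated=("condition",),
        )
        omnibus = res.anova.iloc[0]
        c = np.array([0.0, 2.0])  # A-minus-B difference in effects coding
        manual = wald_f_test(res.fit, c[None, :], "diff")
        assert manual.f == pytest.approx(omnibus["F"], rel=1e-10)
        assert manual.df_den == pytest.approx(omnibus["df_den"], rel=1e-10)
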