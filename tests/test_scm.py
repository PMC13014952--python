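"""Inner weight solve, nested importance optimization, series and RMSPE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from erposcm.panel import StateMonthPanel, month_range
from erposcm.scm import (
    PredictorMatrices,
    PredictorSpec,
    SyntheticControl,
    build_predictors,
    fit_state,
    gap_and_rmspe,
    optimize_importance,
    solve_inner_weights,
    synthetic_series,
)


def simplex_grid(J: int, step: float = 0.005) -> np.ndarray:
    """All weight vectors on the J-simplex with coordinates in multiples of step."""
    n = int(round(1.0 / step))
    if J == 1:
        return np.ones((1, 1))
    if J == 2:
        i = np.arange(n + 1)
        W = np.stack([i, n - i], axis=1)
    elif J == 3:
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        m = i + j <= n
        W = np.stack([i[m], j[m], n - i[m] - j[m]], axis=1)
    elif J == 4:
        i, j, k = np.meshgrid(
            np.arange(n + 1, dtype=np.int32),
            np.arange(n + 1, dtype=np.int32),
            np.arange(n + 1, dtype=np.int32),
            indexing="ij",
        )
        m = (i + j + k) <= n
        W = np.stack([i[m], j[m], k[m], n - i[m] - j[m] - k[m]], axis=1)
    else:
        raise ValueError("grid oracle supports J <= 4")
    return W.astype(float) / n


def weighted_objective(X1, X0, v, w):
    r = X1 - X0 @ w
    return float(r @ (np.asarray(v) * r))


class TestInnerSolve:
    def test_perfect_match_identity(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal(size=(4, 6))
        w = solve_inner_weights(X0[:, 3], X0)
        assert w[3] == pytest.approx(1.0, abs=1e-9)
        assert weighted_objective(X0[:, 3], X0, np.full(4, 0.25), w) < 1e-18

    def test_symmetric_midpoint(self):
        X0 = np.array([[1.0, -1.0], [2.0, -2.0]])
        X1 = np.zeros(2)
        w = solve_inner_weights(X1, X0)
        assert w == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_matches_grid_oracle_small(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            J = int(rng.integers(2, 4))
            k = int(rng.integers(1, 4))
            X0 = rng.normal(size=(k, J))
            X1 = rng.normal(size=k)
            v = rng.dirichlet(np.ones(k))
            w = solve_inner_weights(X1, X0, v)
            grid = simplex_grid(J, 0.005)
            objs = np.einsum("k,nk->n", v, (X1[:, None] - X0 @ grid.T).T ** 2)
            assert weighted_objective(X1, X0, v, w) <= objs.min() + 1e-12

    def test_exact_and_slsqp_agree(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X0 = rng.normal(size=(3, 8))
            X1 = rng.normal(size=3)
            w_a = solve_inner_weights(X1, X0, solver="exact")
            w_b = solve_inner_weights(X1, X0, solver="slsqp")
            o_a = weighted_objective(X1, X0, np.ones(3) / 3, w_a)
            o_b = weighted_objective(X1, X0, np.ones(3) / 3, w_b)
            assert o_a <= o_b + 1e-8

    @given(st.integers(0, 10_000))
    def test_simplex_feasibility(self, seed):
        """Every returned W is non-negative and sums to one within 1e-8."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        J = int(rng.integers(1, 12))
        X0 = rng.normal(scale=rng.uniform(0.1, 10), size=(k, J))
        X1 = rng.normal(scale=rng.uniform(0.1, 10), size=k)
        w = solve_inner_weights(X1, X0)
        assert w.min() >= -1e-8
        assert abs(w.sum() - 1.0) <= 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_inner_weights([1.0], np.ones((2, 3)))
        with pytest.raises(ValueError):
            solve_inner_weights([np.nan, 1.0], np.ones((2, 3)))
        with pytest.raises(ValueError):
            solve_inner_weights([1.0, 1.0], np.ones((2, 3)), v=[-1.0, 2.0])


class TestOptimizeImportance:
    @staticmethod
    def _mats(rng, k=2, J=3, T0=12):
        X0 = rng.normal(size=(k, J))
        X1 = rng.normal(size=k)
        Z0 = rng.normal(size=(T0, J))
        Z1 = rng.normal(size=T0)
        return PredictorMatrices(
            X1=X1, X0=X0, Z1=Z1, Z0=Z0,
            names=[f"p{i}" for i in range(k)], donors=[f"d{j}" for j in range(J)],
        )

    def test_single_predictor_forces_v(self):
        rng = np.random.default_rng(1)
        mats = self._mats(rng, k=1)
        v, w, mspe, conv = optimize_importance(mats)
        assert v == pytest.approx([1.0])
        w_inner = solve_inner_weights(mats.X1, mats.X0, np.ones(1))
        assert w == pytest.approx(w_inner)

    def test_replicating_donor_gives_zero_mspe(self):
        rng = np.random.default_rng(2)
        mats = self._mats(rng, k=2, J=4)
        mats.X0[:, 1] = mats.X1
        mats.Z0[:, 1] = mats.Z1
        v, w, mspe, conv = optimize_importance(mats)
        assert mspe < 1e-12
        assert w[1] == pytest.approx(1.0, abs=1e-6)

    def test_monotone_nesting_and_v_grid_oracle(self):
        """Nested V never fits the pre-period worse than uniform V, and comes
        within 1e-3 of a step-0.01 grid over the 2-predictor simplex."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            mats = self._mats(rng, k=2, J=3, T0=10)
            v, w, mspe, conv = optimize_importance(mats, n_starts=5, random_state=0)

            def premspe(vv):
                ww = solve_inner_weights(mats.X1, mats.X0, vv)
                r = mats.Z1 - mats.Z0 @ ww
                return float(r @ r) / r.size

            assert mspe <= premspe(np.array([0.5, 0.5])) + 1e-12
            grid_best = min(premspe(np.array([a, 1 - a])) for a in np.arange(0.0, 1.0001, 0.01))
            assert mspe <= grid_best + 1e-3


class TestEstimator:
    def test_sklearn_protocol(self):
        est = SyntheticControl(v_mode="equal", n_starts=3)
        params = est.get_params()
        assert params["v_mode"] == "equal"
        est2 = clone(est).set_params(random_state=5)
        assert est2.random_state == 5

    def test_fit_predict_and_determinism(self):
        rng = np.random.default_rng(4)
        Z0 = rng.normal(size=(20, 5)) + 10
        Z1 = Z0 @ rng.dirichlet(np.ones(5)) + rng.normal(scale=0.01, size=20)
        fits = [
            SyntheticControl(v_mode="nested", n_starts=4, random_state=9).fit(Z0, Z1)
            for _ in range(2)
        ]
        assert (fits[0].w_ == fits[1].w_).all()  # bitwise reproducible
        assert (fits[0].v_ == fits[1].v_).all()
        pred = fits[0].predict(Z0)
        assert pred.shape == (20,)
        assert fits[0].rmspe_pre_ < 0.2

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            SyntheticControl().predict(np.ones((3, 2)))


def _toy_panel(rng, units, n_months=24, start="2014-01"):
    months = month_range(start, str(pd.Period(start, freq="M") + n_months - 1))
    rates = rng.uniform(2, 8, size=(len(units), len(months)))
    pop = pd.DataFrame(1e6, index=units, columns=months)
    counts = pd.DataFrame(rates, index=units, columns=months) * pop / 1e6
    return StateMonthPanel(counts=counts, population=pop)


class TestPredictors:
    def test_mean_rule_arithmetic_and_standardization(self):
        rng = np.random.default_rng(5)
        panel = _toy_panel(rng, ["T", "D1", "D2"])
        cov = pd.DataFrame(
            [(u, y, v) for u, v in [("T", 1.0), ("D1", 3.0), ("D2", 5.0)] for y in (2014, 2015)],
            columns=["state", "year", "c1"],
        )
        pre = panel.months[:12]
        mats = build_predictors(
            panel, "T", ["D1", "D2"], pre, covariates=cov,
            spec=PredictorSpec(covariates={"c1": "mean"}, outcome_lags=None),
        )
        raw = np.array([1.0, 3.0, 5.0])
        z = (raw - raw.mean()) / raw.std()
        assert mats.X1[0] == pytest.approx(z[0])
        assert mats.X0[0] == pytest.approx(z[1:])

    def test_identical_units_share_predictor_columns(self):
        rng = np.random.default_rng(6)
        panel = _toy_panel(rng, ["T", "D1", "D2"])
        panel.counts.loc["D1"] = panel.counts.loc["T"]
        pre = panel.months[:12]
        mats = build_predictors(panel, "T", ["D1", "D2"], pre)
        assert mats.X0[:, 0] == pytest.approx(mats.X1)

    def test_matches_naive_loop_oracle(self):
        """Outcome-third predictors agree with an explicit per-unit loop."""
        rng = np.random.default_rng(7)
        units = ["T"] + [f"D{i}" for i in range(4)]
        panel = _toy_panel(rng, units)
        pre = panel.months[:15]
        mats = build_predictors(panel, "T", units[1:], pre)
        rates = panel.rates
        thirds = np.array_split(np.arange(15), 3)
        naive = np.array(
            [[rates.loc[u, pre].to_numpy()[part].mean() for u in units] for part in thirds]
        )
        z = (naive - naive.mean(axis=1, keepdims=True)) / naive.std(axis=1, keepdims=True)
        assert mats.X1 == pytest.approx(z[:, 0])
        assert mats.X0 == pytest.approx(z[:, 1:])

    def test_zero_variance_covariate_dropped(self):
        rng = np.random.default_rng(8)
        panel = _toy_panel(rng, ["T", "D1", "D2"])
        cov = pd.DataFrame(
            [(u, y, 7.0) for u in ["T", "D1", "D2"] for y in (2014, 2015)],
            columns=["state", "year", "flat"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            mats = build_predictors(
                panel, "T", ["D1", "D2"], panel.months[:12], covariates=cov,
                spec=PredictorSpec(covariates={"flat": "mean"}, outcome_lags="thirds"),
            )
        assert "flat" not in mats.names


class TestSeriesAndRmspe:
    def test_identity_weight(self):
        rng = np.random.default_rng(9)
        panel = _toy_panel(rng, ["D1", "D2", "D3"])
        s = synthetic_series(np.array([0.0, 0.0, 1.0]), panel.rates)
        assert s.to_numpy() == pytest.approx(panel.rates.loc["D3"].to_numpy())

    def test_average_of_constants(self):
        months = month_range("2014-01", "2014-06")
        rates = pd.DataFrame([[2.0] * 6, [4.0] * 6], index=["a", "b"], columns=months)
        s = synthetic_series(np.array([0.5, 0.5]), rates)
        assert (s == 3.0).all()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(10)
        panel = _toy_panel(rng, ["D1", "D2", "D3", "D4"])
        w = rng.dirichlet(np.ones(4))
        s = synthetic_series(w, panel.rates)
        for t, month in enumerate(panel.months):
            naive = sum(w[j] * panel.rates.iloc[j, t] for j in range(4))
            assert s.loc[month] == pytest.approx(naive)

    def test_convex_hull_bound(self):
        rng = np.random.default_rng(11)
        panel = _toy_panel(rng, ["D1", "D2", "D3"])
        w = rng.dirichlet(np.ones(3))
        s = synthetic_series(w, panel.rates).to_numpy()
        lo = panel.rates.min(axis=0).to_numpy()
        hi = panel.rates.max(axis=0).to_numpy()
        assert (s >= lo - 1e-12).all() and (s <= hi + 1e-12).all()

    def test_zero_gap_case(self):
        months = month_range("2014-01", "2014-12")
        obs = pd.Series(np.arange(12.0), index=months)
        gap, pre, post = gap_and_rmspe(obs, obs.copy(), "2014-07")
        assert (gap == 0).all() and pre == 0.0 and post == 0.0

    def test_rmspe_arithmetic(self):
        months = month_range("2014-01", "2014-04")
        obs = pd.Series([1.0, 1.0, 4.0, 5.0], index=months)
        syn = pd.Series([1.0, 1.0, 1.0, 1.0], index=months)
        gap, pre, post = gap_and_rmspe(obs, syn, "2014-03")
        assert pre == 0.0
        assert post == pytest.approx(np.sqrt(12.5))  # gaps (3, 4)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(12)
        months = month_range("2014-01", "2015-12")
        obs = pd.Series(rng.normal(size=24), index=months)
        syn = pd.Series(rng.normal(size=24), index=months)
        gap, pre, post = gap_and_rmspe(obs, syn, "2015-01")
        g = (obs - syn).to_numpy()
        assert pre == pytest.approx(np.sqrt((g[:12] ** 2).mean()))
        assert post == pytest.approx(np.sqrt((g[12:] ** 2).mean()))

    def test_empty_window_raises(self):
        months = month_range("2014-01", "2014-04")
        obs = pd.Series(np.ones(4), index=months)
        with pytest.raises(ValueError):
            gap_and_rmspe(obs, obs, "2014-01")


class TestFitState:
    def test_duplicate_donor_recovered(self):
        rng = np.random.default_rng(13)
        panel = _toy_panel(rng, ["T", "D1", "D2", "D3"], n_months=36)
        panel.counts.loc["D2"] = panel.counts.loc["T"]
        fit = fit_state(panel, "T", ["D1", "D2", "D3"], "2016-01", v_mode="nested", n_starts=4)
        assert fit.weights["D2"] >= 0.999
        assert fit.rmspe_pre <= 1e-8

    def test_treated_in_donors_rejected(self):
        rng = np.random.default_rng(14)
        panel = _toy_panel(rng, ["T", "D1"])
        with pytest.raises(ValueError):
            fit_state(panel, "T", ["T", "D1"], "2014-06")
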