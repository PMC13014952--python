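"""Abadie–Diamond–Hainmueller synthetic control for one treated unit.

The counterfactual for a treated state is a convex combination of donor
states: weights ``W`` live on the probability simplex (non-negative, summing
to one) and are chosen so the weighted donor predictors match the treated
unit's predictors under a predictor-importance metric ``V``.  ``V`` itself is
either uniform or chosen by a nested optimization that minimizes the
pre-period mean squared prediction error of the resulting outcome fit.

The estimator :class:`SyntheticControl` follows the scikit-learn protocol:
``fit(X, y)`` takes the donors' pre-period outcome series as columns of ``X``
and the treated unit's series as ``y``; ``predict`` extends the fitted weights
to any window of donor outcomes, yielding the synthetic series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .panel import StateMonthPanel

__all__ = [
    "PredictorSpec",
    "PredictorMatrices",
    "SyntheticControl",
    "SCMFit",
    "build_predictors",
    "solve_inner_weights",
    "optimize_importance",
    "synthetic_series",
    "gap_and_rmspe",
    "fit_state",
]

_SIMPLEX_TOL = 1e-8


# ---------------------------------------------------------------------------
# Inner problem: simplex-constrained least squares
# ---------------------------------------------------------------------------

def _objective(A: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    r = A @ w - b
    return float(r @ r)


def _simplex_lsq(A: np.ndarray, b: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Minimize ``||A w - b||^2`` over the probability simplex.

    A non-negative least squares solve with a sum-to-one penalty row proposes
    the active set; an exact KKT active-set refinement then polishes it to the
    constrained optimum.  Deterministic; degenerate optima (duplicate donor
    columns) resolve to the minimum-norm KKT solution, which splits weight
    evenly among duplicates.
    """
    k, J = A.shape
    if J == 1:
        return np.ones(1)
    scale = max(float(np.abs(A).max()), float(np.abs(b).max()), 1.0)
    rho = 1e4 * scale
    A_aug = np.vstack([A, rho * np.ones((1, J))])
    b_aug = np.append(b, rho)
    w_prop, _ = optimize.nnls(A_aug, b_aug)
    total = w_prop.sum()
    w_prop = w_prop / total if total > 0 else np.full(J, 1.0 / J)

    support = set(np.flatnonzero(w_prop > 1e-9))
    if not support:
        support = {int(np.argmax(w_prop))}

    G = A.T @ A
    c = A.T @ b
    best_w = w_prop
    kkt_tol = max(tol, 1e-10 * scale * scale)
    for _ in range(3 * J + 10):
        S = sorted(support)
        m = len(S)
        K = np.zeros((m + 1, m + 1))
        K[:m, :m] = 2.0 * G[np.ix_(S, S)]
        K[:m, m] = 1.0
        K[m, :m] = 1.0
        rhs = np.append(2.0 * c[S], 1.0)
        try:
            sol = np.linalg.solve(K, rhs)
            if not np.all(np.isfinite(sol)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        w_S, lam = sol[:m], sol[m]
        if w_S.min() < -1e-11:
            support.discard(S[int(np.argmin(w_S))])
            if not support:
                break
            continue
        w = np.zeros(J)
        w[S] = np.clip(w_S, 0.0, None)
        w /= w.sum()
        best_w = w
        # dual feasibility for excluded donors: grad_j + lambda >= 0
        mu = 2.0 * (G @ w - c) + lam
        outside = [j for j in range(J) if j not in support]
        if outside:
            j_min = min(outside, key=lambda j: mu[j])
            if mu[j_min] < -kkt_tol:
                support.add(j_min)
                continue
        break

    # keep whichever feasible point is better (guards rare active-set stalls)
    if _objective(A, b, w_prop) < _objective(A, b, best_w):
        best_w = w_prop
    best_w = np.clip(best_w, 0.0, None)
    return best_w / best_w.sum()


def _simplex_lsq_slsqp(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same problem via SLSQP from a uniform start (cross-check path)."""
    J = A.shape[1]
    if J == 1:
        return np.ones(1)
    w0 = np.full(J, 1.0 / J)
    res = optimize.minimize(
        lambda w: _objective(A, b, w),
        w0,
        jac=lambda w: 2.0 * A.T @ (A @ w - b),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * J,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(J)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def solve_inner_weights(
    X1: np.ndarray,
    X0: np.ndarray,
    v: np.ndarray | None = None,
    solver: str = "exact",
) -> np.ndarray:
    """Donor weights ``W`` minimizing ``(X1 - X0 W)' diag(V) (X1 - X0 W)`` on
    the simplex.

    Parameters
    ----------
    X1 : (k,) treated predictor vector.
    X0 : (k, J) donor predictor matrix, columns in donor order.
    v : (k,) non-negative predictor importances; uniform when omitted.
    solver : "exact" (NNLS + KKT polish, default) or "slsqp".
    """
    X1 = np.asarray(X1, dtype=float).ravel()
    X0 = np.asarray(X0, dtype=float)
    if X0.ndim != 2 or X0.shape[0] != X1.size:
        raise ValueError(f"X0 shape {X0.shape} does not conform to X1 length {X1.size}")
    if not (np.isfinite(X1).all() and np.isfinite(X0).all()):
        raise ValueError("non-finite predictor entries")
    k = X1.size
    if v is None:
        v = np.full(k, 1.0 / k)
    v = np.asarray(v, dtype=float).ravel()
    if v.size != k or (v < 0).any() or not np.isfinite(v).all():
        raise ValueError("invalid importance vector")
    total = v.sum()
    if total <= 0:
        raise ValueError("importance vector sums to zero")
    sq = np.sqrt(v / total)
    A = X0 * sq[:, None]
    b = X1 * sq
    if solver == "exact":
        w = _simplex_lsq(A, b)
    elif solver == "slsqp":
        w = _simplex_lsq_slsqp(A, b)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    assert w.min() >= -_SIMPLEX_TOL and abs(w.sum() - 1.0) <= _SIMPLEX_TOL
    return w


# ---------------------------------------------------------------------------
# Predictor construction
# ---------------------------------------------------------------------------

@dataclass
class PredictorSpec:
    """Which predictors enter the weight-matching problem.

    ``covariates`` maps covariate name -> aggregation rule over the
    pre-period: "mean", "last", or a list of 'YYYY-MM' months to average.
    ``None`` uses every numeric column of the covariate table with rule
    "mean".  ``outcome_lags``: "thirds" (pre-period split into three
    contiguous blocks, mean of each — the default), "mean" (single pre-period
    mean), a list of 'YYYY-MM' months (each month's outcome is its own
    predictor), or None.
    """

    covariates: dict[str, object] | None = None
    outcome_lags: object = "thirds"


@dataclass
class PredictorMatrices:
    X1: np.ndarray  # (k,)
    X0: np.ndarray  # (k, J)
    Z1: np.ndarray  # (T0,)
    Z0: np.ndarray  # (T0, J)
    names: list[str]
    donors: list[str]

    def __post_init__(self) -> None:
        if self.X0.shape != (self.X1.size, len(self.donors)):
            raise ValueError("X0 shape mismatch")
        if self.Z0.shape != (self.Z1.size, len(self.donors)):
            raise ValueError("Z0 shape mismatch")
        if self.X1.size < 1 or len(self.donors) < 1 or self.Z1.size < 2:
            raise ValueError("need k >= 1 predictors, J >= 1 donors, T0 >= 2 pre months")


def _standardize_rows(X1: np.ndarray, X0: np.ndarray, names: list[str]):
    """Z-score each predictor across all units; drop zero-variance rows."""
    all_vals = np.column_stack([X1.reshape(-1, 1), X0])
    mean = all_vals.mean(axis=1)
    sd = all_vals.std(axis=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance predictor(s): {dropped}", stacklevel=3)
    if not keep.any():
        raise ValueError("all predictors have zero variance across units")
    X1s = (X1[keep] - mean[keep]) / sd[keep]
    X0s = (X0[keep] - mean[keep, None]) / sd[keep, None]
    return X1s, X0s, [n for n, k in zip(names, keep) if k]


def _outcome_lag_rows(Z1: np.ndarray, Z0: np.ndarray, outcome_lags, months_pre: pd.PeriodIndex | None):
    rows1, rows0, names = [], [], []
    if outcome_lags is None:
        return rows1, rows0, names
    if outcome_lags == "mean":
        rows1.append(Z1.mean())
        rows0.append(Z0.mean(axis=0))
        names.append("outcome_mean")
    elif outcome_lags == "thirds":
        idx = np.arange(Z1.size)
        for part, label in zip(np.array_split(idx, 3), ("early", "mid", "late")):
            if part.size == 0:
                continue
            rows1.append(Z1[part].mean())
            rows0.append(Z0[part].mean(axis=0))
            names.append(f"outcome_{label}_third")
    elif isinstance(outcome_lags, (list, tuple)):
        if months_pre is None:
            raise ValueError("month-specific outcome lags need the pre-period month index")
        for m in outcome_lags:
            pos = months_pre.get_loc(pd.Period(m, freq="M"))
            rows1.append(Z1[pos])
            rows0.append(Z0[pos])
            names.append(f"outcome_{m}")
    else:
        raise ValueError(f"unknown outcome_lags {outcome_lags!r}")
    return rows1, rows0, names


def build_predictors(
    panel: StateMonthPanel,
    treated: str,
    donors: list[str],
    pre_period: pd.PeriodIndex,
    covariates: pd.DataFrame | None = None,
    spec: PredictorSpec | None = None,
) -> PredictorMatrices:
    """Assemble standardized predictor matrices and raw pre-period outcomes.

    Covariates are observed at state-year resolution; each year's value is
    repeated across that year's months before pre-period aggregation.
    Predictor rows are z-scored across treated + donors so no covariate
    dominates the ``V``-weighted metric through its units.
    """
    spec = spec or PredictorSpec()
    rates = panel.rates
    missing = [u for u in [treated] + donors if u not in rates.index]
    if missing:
        raise ValueError(f"unit(s) not in panel: {missing}")
    if len(pre_period) < 2:
        raise ValueError("pre-period must contain at least 2 months")
    Z1 = rates.loc[treated, pre_period].to_numpy(dtype=float)
    Z0 = rates.loc[donors, pre_period].to_numpy(dtype=float).T

    rows1: list = []
    rows0: list = []
    names: list[str] = []
    if covariates is not None:
        cov_spec = spec.covariates
        if cov_spec is None:
            value_cols = [
                c for c in covariates.columns
                if c not in ("state", "year") and pd.api.types.is_numeric_dtype(covariates[c])
            ]
            cov_spec = {c: "mean" for c in value_cols}
        years_pre = pre_period.year
        table = covariates.set_index(["state", "year"])
        for name, rule in cov_spec.items():
            if name not in table.columns:
                raise ValueError(f"covariate {name!r} not in table")
            per_unit = []
            for unit in [treated] + donors:
                try:
                    monthly = np.array([table.loc[(unit, y), name] for y in years_pre], dtype=float)
                except KeyError:
                    raise ValueError(f"covariate {name!r} missing for unit {unit!r}") from None
                if rule == "mean":
                    per_unit.append(monthly.mean())
                elif rule == "last":
                    per_unit.append(monthly[-1])
                elif isinstance(rule, (list, tuple)):
                    sel = [pre_period.get_loc(pd.Period(m, freq="M")) for m in rule]
                    per_unit.append(monthly[sel].mean())
                else:
                    raise ValueError(f"unknown aggregation rule {rule!r} for {name!r}")
            vals = np.asarray(per_unit)
            rows1.append(vals[0])
            rows0.append(vals[1:])
            names.append(name)

    lag1, lag0, lag_names = _outcome_lag_rows(Z1, Z0, spec.outcome_lags, pre_period)
    rows1 += lag1
    rows0 += lag0
    names += lag_names
    if not names:
        raise ValueError("predictor spec yields no predictors")

    X1 = np.asarray(rows1, dtype=float)
    X0 = np.vstack([np.asarray(r, dtype=float) for r in rows0])
    X1, X0, names = _standardize_rows(X1, X0, names)
    return PredictorMatrices(X1=X1, X0=X0, Z1=Z1, Z0=Z0, names=names, donors=list(donors))


def _solve_weights_refined(
    X1: np.ndarray,
    X0: np.ndarray,
    v: np.ndarray,
    Z1: np.ndarray,
    Z0: np.ndarray,
    solver: str = "exact",
) -> np.ndarray:
    """Inner solve with a degeneracy tie-break.

    When fewer predictors than donors leave the predictor-matching problem
    underdetermined (many exact matches, e.g. a donor duplicating the treated
    unit), re-solve preferring the best pre-period *outcome* fit among the
    exact predictor matches.  Leaves non-degenerate solutions untouched.
    """
    w = solve_inner_weights(X1, X0, v, solver=solver)
    v_n = np.asarray(v, dtype=float)
    v_n = v_n / v_n.sum()
    r = X1 - X0 @ w
    xobj = float(r @ (v_n * r))
    degeneracy_floor = 1e-12 * max(1.0, float(v_n @ X1**2))
    if xobj > degeneracy_floor:
        return w
    sq = np.sqrt(v_n)
    z_scale = max(float(np.abs(Z1).max()), 1.0)
    x_scale = max(float(np.abs(X1 * sq).max()), 1e-12)
    kappa = 1e4 * z_scale / x_scale
    A = np.vstack([X0 * (kappa * sq)[:, None], Z0])
    b = np.concatenate([X1 * (kappa * sq), Z1])
    w2 = _simplex_lsq(A, b)
    r2 = X1 - X0 @ w2
    if float(r2 @ (v_n * r2)) <= max(xobj, degeneracy_floor):
        rz, rz2 = Z1 - Z0 @ w, Z1 - Z0 @ w2
        if float(rz2 @ rz2) < float(rz @ rz):
            return w2
    return w


# ---------------------------------------------------------------------------
# Outer problem: predictor importance V
# ---------------------------------------------------------------------------

def optimize_importance(
    matrices: PredictorMatrices,
    n_starts: int = 10,
    random_state: int | None = 0,
    tol: float = 1e-8,
    maxiter: int = 200,
    solver: str = "exact",
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Nested choice of ``V``: minimize the pre-period outcome MSPE of the
    inner weight solve over the predictor simplex.

    Multi-start (uniform start plus Dirichlet draws from a seeded generator)
    bounded SLSQP; the incumbent with the lowest pre-MSPE wins, so the result
    is never worse than the uniform-``V`` baseline.

    Returns ``(v, w, pre_mspe, converged)``.
    """
    X1, X0, Z1, Z0 = matrices.X1, matrices.X0, matrices.Z1, matrices.Z0
    k = X1.size
    T0 = Z1.size

    def pre_mspe_for(v: np.ndarray) -> tuple[float, np.ndarray]:
        w = _solve_weights_refined(X1, X0, v, Z1, Z0, solver=solver)
        r = Z1 - Z0 @ w
        return float(r @ r) / T0, w

    if k == 1:
        v = np.ones(1)
        mspe, w = pre_mspe_for(v)
        return v, w, mspe, True

    def objective(v_free: np.ndarray) -> float:
        v = np.clip(v_free, 0.0, None)
        s = v.sum()
        if s <= 0:
            return np.inf
        return pre_mspe_for(v / s)[0]

    rng = np.random.default_rng(random_state)
    # direct pre-sampling: the objective is only piecewise smooth in V (the
    # inner active set changes), so scatter candidates before local polish
    candidates = [np.full(k, 1.0 / k)]
    candidates += [np.eye(k)[i] for i in range(k)] if k <= 12 else []
    candidates += [rng.dirichlet(np.ones(k)) for _ in range(max(16, 8 * k))]
    scored = sorted(candidates, key=objective)
    starts = scored[: max(1, n_starts)]

    best_v = starts[0]
    best_mspe = objective(best_v)
    converged = False
    constraints = [{"type": "eq", "fun": lambda v: v.sum() - 1.0, "jac": lambda v: np.ones(k)}]
    for v0 in starts:
        res = optimize.minimize(
            objective,
            v0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=constraints,
            options={"maxiter": maxiter, "ftol": tol},
        )
        converged = converged or bool(res.success)
        polish = optimize.minimize(
            objective,
            np.clip(res.x, 0.0, None) if np.clip(res.x, 0.0, None).sum() > 0 else v0,
            method="Nelder-Mead",
            options={"maxiter": 200 * k, "xatol": 1e-6, "fatol": tol},
        )
        for raw in (res.x, polish.x):
            cand = np.clip(raw, 0.0, None)
            if cand.sum() <= 0:
                continue
            cand /= cand.sum()
            cand_mspe = objective(cand)
            if cand_mspe < best_mspe:
                best_v, best_mspe = cand, cand_mspe
    best_mspe, best_w = pre_mspe_for(best_v)
    return best_v, best_w, best_mspe, converged


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class SyntheticControl(BaseEstimator, RegressorMixin):
    """Simplex-weighted donor combination fit to a treated unit's pre-period.

    Parameters
    ----------
    v_mode : "nested" or "equal"
        Nested optimizes predictor importance ``V`` to minimize the pre-period
        outcome MSPE; "equal" uses uniform importances.
    outcome_lags : predictor construction rule when no explicit predictor
        matrices are supplied at fit time (see :class:`PredictorSpec`).
    n_starts : multi-start count for the nested ``V`` search.
    random_state : seed for the multi-start draws; fits are reproducible
        bit-for-bit given identical inputs and seed.
    solver : inner-solve backend, "exact" or "slsqp".

    Attributes
    ----------
    w_ : (J,) donor weights on the simplex.
    v_ : (k,) predictor importances (sums to one).
    pre_mspe_ : pre-period outcome mean squared prediction error.
    rmspe_pre_ : its square root.
    converged_ : whether the nested search reported convergence.
    """

    def __init__(
        self,
        v_mode: str = "nested",
        outcome_lags: object = "thirds",
        n_starts: int = 10,
        random_state: int | None = 0,
        tol: float = 1e-8,
        solver: str = "exact",
    ):
        self.v_mode = v_mode
        self.outcome_lags = outcome_lags
        self.n_starts = n_starts
        self.random_state = random_state
        self.tol = tol
        self.solver = solver

    def fit(self, X, y, predictors: tuple[np.ndarray, np.ndarray] | None = None):
        """Fit donor weights.

        Parameters
        ----------
        X : (T0, J) donor pre-period outcomes, one donor per column.
        y : (T0,) treated pre-period outcomes.
        predictors : optional ``(X1, X0)`` standardized predictor matrices;
            when omitted, outcome-lag predictors are built from ``X, y``.
        """
        Z0 = np.asarray(X, dtype=float)
        Z1 = np.asarray(y, dtype=float).ravel()
        if Z0.ndim != 2 or Z0.shape[0] != Z1.size:
            raise ValueError("X must be (T0, J) with T0 matching y")
        if Z1.size < 2 or Z0.shape[1] < 1:
            raise ValueError("need T0 >= 2 and at least one donor")
        if not (np.isfinite(Z0).all() and np.isfinite(Z1).all()):
            raise ValueError("non-finite outcome entries")

        if predictors is not None:
            X1, X0 = (np.asarray(a, dtype=float) for a in predictors)
            names = [f"p{i}" for i in range(X1.size)]
        else:
            r1, r0, names = _outcome_lag_rows(Z1, Z0, self.outcome_lags, None)
            X1 = np.asarray(r1, dtype=float)
            X0 = np.vstack([np.asarray(r, dtype=float) for r in r0])
            X1, X0, names = _standardize_rows(X1, X0, names)

        mats = PredictorMatrices(X1=X1, X0=X0, Z1=Z1, Z0=Z0,
                                 names=names, donors=[f"d{j}" for j in range(Z0.shape[1])])
        if self.v_mode == "nested":
            v, w, mspe, conv = optimize_importance(
                mats, n_starts=self.n_starts, random_state=self.random_state,
                tol=self.tol, solver=self.solver,
            )
        elif self.v_mode == "equal":
            v = np.full(X1.size, 1.0 / X1.size)
            w = _solve_weights_refined(X1, X0, v, Z1, Z0, solver=self.solver)
            r = Z1 - Z0 @ w
            mspe, conv = float(r @ r) / Z1.size, True
        else:
            raise ValueError(f"unknown v_mode {self.v_mode!r}")

        self.w_ = w
        self.v_ = v
        self.pre_mspe_ = mspe
        self.rmspe_pre_ = float(np.sqrt(mspe))
        self.converged_ = conv
        self.predictor_names_ = names
        self.n_features_in_ = Z0.shape[1]
        return self

    def predict(self, X):
        """Synthetic series for any donor outcome window (T, J) -> (T,)."""
        if not hasattr(self, "w_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.w_.size:
            raise ValueError("X must be (T, J) with J matching the fitted donors")
        return X @ self.w_


# ---------------------------------------------------------------------------
# Series-level outputs
# ---------------------------------------------------------------------------

def synthetic_series(w: np.ndarray, donor_rates: pd.DataFrame) -> pd.Series:
    """Weighted donor combination, month by month: ``y_hat_t = sum_j W_j y_jt``."""
    w = np.asarray(w, dtype=float)
    if w.size != donor_rates.shape[0]:
        raise ValueError("weight length does not match donor count")
    return pd.Series(w @ donor_rates.to_numpy(dtype=float), index=donor_rates.columns)


def gap_and_rmspe(
    observed: pd.Series,
    synthetic: pd.Series,
    treatment_month: str | pd.Period,
) -> tuple[pd.Series, float, float]:
    """Gap series (observed − synthetic) and pre/post RMSPE.

    The calendar month containing the effective date is the first *post*
    month: pre covers months strictly before it.
    """
    if not observed.index.equals(synthetic.index):
        raise ValueError("observed and synthetic month indices differ")
    tp = pd.Period(treatment_month, freq="M")
    months = pd.PeriodIndex(observed.index, freq="M")
    pre = months < tp
    post = ~pre
    if not pre.any() or not post.any():
        raise ValueError("treatment month leaves an empty pre or post window")
    gap = observed - synthetic
    g = gap.to_numpy(dtype=float)
    rmspe_pre = float(np.sqrt(np.mean(g[pre] ** 2)))
    rmspe_post = float(np.sqrt(np.mean(g[post] ** 2)))
    return gap, rmspe_pre, rmspe_post


@dataclass
class SCMFit:
    """Complete synthetic-control fit for one (pseudo-)treated unit."""

    unit: str
    donors: list[str]
    weights: pd.Series
    importance: pd.Series
    observed: pd.Series
    synthetic: pd.Series
    gap: pd.Series
    treatment_month: pd.Period
    rmspe_pre: float
    rmspe_post: float
    converged: bool

    @property
    def ratio(self) -> float:
        """Post/pre RMSPE ratio; infinite when the pre-period fit is exact
        but the post-period diverges."""
        if self.rmspe_pre == 0.0:
            return np.inf if self.rmspe_post > 0 else 0.0
        return self.rmspe_post / self.rmspe_pre

    def to_frames(self) -> dict[str, pd.DataFrame]:
        gaps = pd.DataFrame(
            {
                "month": self.gap.index.astype(str),
                "observed": self.observed.to_numpy(),
                "synthetic": self.synthetic.to_numpy(),
                "gap": self.gap.to_numpy(),
            }
        )
        weights = pd.DataFrame({"donor": self.weights.index, "weight": self.weights.to_numpy()})
        v = pd.DataFrame({"predictor": self.importance.index, "importance": self.importance.to_numpy()})
        return {"gaps": gaps, "weights": weights, "importance": v}


def fit_state(
    panel: StateMonthPanel,
    treated: str,
    donors: list[str],
    treatment_month: str | pd.Period,
    covariates: pd.DataFrame | None = None,
    spec: PredictorSpec | None = None,
    v_mode: str = "nested",
    n_starts: int = 10,
    random_state: int | None = 0,
    solver: str = "exact",
) -> SCMFit:
    """Fit the synthetic control for ``treated`` against ``donors`` on a panel.

    ``treatment_month`` is the first post month (the calendar month containing
    the law's effective date).
    """
    if len(donors) < 1:
        raise ValueError("need at least one donor")
    if treated in donors:
        raise ValueError("treated unit cannot be its own donor")
    tp = pd.Period(treatment_month, freq="M")
    months = panel.months
    pre_period = months[months < tp]
    if len(pre_period) < 2 or tp > months[-1]:
        raise ValueError("treatment month leaves no usable pre/post window")

    mats = build_predictors(panel, treated, donors, pre_period, covariates=covariates, spec=spec)
    est = SyntheticControl(
        v_mode=v_mode, n_starts=n_starts, random_state=random_state, solver=solver
    ).fit(mats.Z0, mats.Z1, predictors=(mats.X1, mats.X0))

    rates = panel.rates
    synth = synthetic_series(est.w_, rates.loc[donors])
    observed = rates.loc[treated]
    gap, rmspe_pre, rmspe_post = gap_and_rmspe(observed, synth, tp)
    return SCMFit(
        unit=treated,
        donors=list(donors),
        weights=pd.Series(est.w_, index=donors, name="weight"),
        importance=pd.Series(est.v_, index=est.predictor_names_, name="importance"),
        observed=observed,
        synthetic=synth,
        gap=gap,
        treatment_month=tp,
        rmspe_pre=rmspe_pre,
        rmspe_post=rmspe_post,
        converged=est.converged_,
    )
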