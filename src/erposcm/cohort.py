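"""Treated-cohort selection and donor-pool construction for the ERPO study.

A state enters the treated cohort when (1) its ERPO effective date falls late
enough after the panel start to leave a usable pre-period, (2) early enough to
leave a usable post-period, and (3) petition filings show a statistically
significant increase after enactment — petition volume before an ERPO exists
is structurally zero, so the test is one-sample against zero.  Donor states
never enacted an ERPO during the panel window and have complete covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import month_range

__all__ = [
    "load_policy_catalog",
    "apply_window_filters",
    "petition_increase_test",
    "build_donor_pool",
    "select_cohort",
    "CohortDecision",
    "PetitionTestResult",
    "DEFAULT_WINDOW_BOUNDS",
]

#: Inclusive effective-date bounds for the treated cohort.  Both ends are
#: inclusive: a law effective exactly on the upper bound still leaves the
#: required three post-years within a panel ending 2021-12.
DEFAULT_WINDOW_BOUNDS = ("2015-01-01", "2019-01-01")


def load_policy_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """Load a policy catalog CSV (state, effective_date, covariate_complete).

    With no ``path``, the packaged catalog of state ERPO effective dates for
    the 2014–2021 window is returned.  Colorado is carried with a nominal
    in-window date so that the petition-increase test, not the date filter, is
    what decides it (its petition uptake, not its statute timing, is the
    reason it leaves the cohort).
    """
    if path is None:
        ref = resources.files("erposcm.data").joinpath("policy_catalog.csv")
        with resources.as_file(ref) as p:
            catalog = pd.read_csv(p)
    else:
        catalog = pd.read_csv(path)
    for col in ("state", "effective_date", "covariate_complete"):
        if col not in catalog.columns:
            raise ValueError(f"policy catalog missing column {col!r}")
    if catalog["state"].duplicated().any():
        raise ValueError("duplicate state in policy catalog")
    catalog = catalog.copy()
    catalog["effective_date"] = pd.to_datetime(catalog["effective_date"], errors="raise")
    catalog["covariate_complete"] = catalog["covariate_complete"].astype(bool)
    return catalog


def apply_window_filters(
    catalog: pd.DataFrame,
    lower: str = DEFAULT_WINDOW_BOUNDS[0],
    upper: str = DEFAULT_WINDOW_BOUNDS[1],
) -> pd.DataFrame:
    """Per-state effective-date window outcomes.

    Returns a DataFrame indexed by state with boolean columns ``has_erpo``,
    ``passes_pre_window`` (effective date >= lower: enough pre-period),
    ``passes_post_window`` (effective date <= upper: enough post-period) and
    ``passes_windows``.  States without an ERPO pass neither window — they are
    donor candidates, not treated candidates.
    """
    lower_ts, upper_ts = pd.Timestamp(lower), pd.Timestamp(upper)
    if lower_ts >= upper_ts:
        raise ValueError("window lower bound must precede upper bound")
    eff = catalog.set_index("state")["effective_date"]
    has = eff.notna()
    pre = has & (eff >= lower_ts)
    post = has & (eff <= upper_ts)
    return pd.DataFrame(
        {
            "has_erpo": has,
            "passes_pre_window": pre,
            "passes_post_window": post,
            "passes_windows": pre & post,
        }
    )


@dataclass
class PetitionTestResult:
    t_statistic: float
    p_value: float
    passed: bool
    status: str  # "ok" | "inconclusive" | "degenerate"
    n_post_months: int


def petition_increase_test(
    post_counts: np.ndarray | pd.Series | list,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> PetitionTestResult:
    """One-sample t-test of post-enactment monthly petition counts against zero.

    Pre-enactment petition volume is identically zero (the order type did not
    exist), so an increase is a post-period mean above zero.  One-sided by
    default; ``alternative="two-sided"`` is available.

    Fewer than two post months yields an inconclusive (non-passing) result.
    All-equal positive counts have zero sample variance: the increase is then
    exact and the p-value is reported at the smallest positive float.
    """
    x = np.asarray(post_counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("post_counts must be one-dimensional")
    if (x < 0).any():
        raise ValueError("petition counts must be non-negative")
    n = x.size
    if n < 2:
        return PetitionTestResult(np.nan, np.nan, False, "inconclusive", n)
    if np.ptp(x) == 0.0:
        if x[0] > 0:
            return PetitionTestResult(np.inf, np.finfo(float).tiny, True, "degenerate", n)
        return PetitionTestResult(0.0, 1.0, False, "degenerate", n)
    res = stats.ttest_1samp(x, popmean=0.0, alternative=alternative)
    passed = bool(res.pvalue < alpha)
    return PetitionTestResult(float(res.statistic), float(res.pvalue), passed, "ok", n)


def build_donor_pool(catalog: pd.DataFrame, window: tuple[str, str] = ("2014-01", "2021-12")) -> list[str]:
    """Donor states: no ERPO effective date inside the panel window and no
    missing covariate years.

    A state whose ERPO predates the panel window is not "treated during the
    study period" and may serve as a donor if its covariates are complete.
    """
    months = month_range(*window)
    start = months[0].to_timestamp(how="start")
    end = months[-1].to_timestamp(how="end")
    eff = catalog["effective_date"]
    in_window = eff.notna() & (eff >= start) & (eff <= end)
    donors = catalog.loc[~in_window & catalog["covariate_complete"], "state"]
    pool = sorted(donors)
    if not pool:
        raise ValueError("empty donor pool")
    return pool


@dataclass
class CohortDecision:
    """Inclusion decision for one candidate treated state."""

    state: str
    included: bool
    failed_filters: list[str] = field(default_factory=list)
    t_statistic: float = np.nan
    p_value: float = np.nan
    effective_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        assert self.included == (not self.failed_filters)


def _post_petition_counts(petitions: pd.DataFrame, state: str, effective: pd.Timestamp, months: pd.PeriodIndex) -> np.ndarray:
    sub = petitions.loc[petitions["state"] == state]
    if sub.empty:
        return np.array([])
    series = pd.Series(
        sub["petitions"].to_numpy(dtype=float),
        index=pd.PeriodIndex(sub["month"], freq="M"),
    ).reindex(months)
    post = series.loc[series.index >= effective.to_period("M")]
    return post.dropna().to_numpy()


def select_cohort(
    catalog: pd.DataFrame,
    petitions: pd.DataFrame | None = None,
    window: tuple[str, str] = ("2014-01", "2021-12"),
    bounds: tuple[str, str] = DEFAULT_WINDOW_BOUNDS,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> tuple[list[str], list[str], dict[str, CohortDecision]]:
    """Apply all three treated-state filters and build the donor pool.

    ``petitions`` is a long table (state, month, petitions); if ``None`` the
    petition test is skipped (every window-passing state passes filter 3).

    Returns ``(treated, donors, decisions)``; treated, donors and the
    remaining excluded states partition the catalog's states.
    """
    months = month_range(*window)
    windows = apply_window_filters(catalog, *bounds)
    eff = catalog.set_index("state")["effective_date"]
    decisions: dict[str, CohortDecision] = {}
    treated: list[str] = []
    for state in catalog["state"]:
        row = windows.loc[state]
        failed: list[str] = []
        if not row["has_erpo"]:
            continue  # donor candidate, not a treated candidate
        if not row["passes_pre_window"]:
            failed.append("pre_window")
        if not row["passes_post_window"]:
            failed.append("post_window")
        t_stat, p_val = np.nan, np.nan
        if not failed and petitions is not None:
            res = petition_increase_test(
                _post_petition_counts(petitions, state, eff.loc[state], months),
                alpha=alpha,
                alternative=alternative,
            )
            t_stat, p_val = res.t_statistic, res.p_value
            if not res.passed:
                failed.append("petition_test")
        decisions[state] = CohortDecision(
            state=state,
            included=not failed,
            failed_filters=failed,
            t_statistic=t_stat,
            p_value=p_val,
            effective_date=eff.loc[state],
        )
        if not failed:
            treated.append(state)

    donors = [s for s in build_donor_pool(catalog, window) if s not in treated]
    return treated, donors, decisions
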