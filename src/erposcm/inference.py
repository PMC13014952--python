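"""Placebo-permutation inference for synthetic-control fits.

Every donor is refit as if it, not the actual treated state, had adopted the
policy on the same date; the treated state's post/pre RMSPE ratio is then
ranked against the placebo ratios.  Under the sharp null the treated unit is
exchangeable with the placebos, so the rank-based p-value is uniform on the
grid {1/n, ..., 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import StateMonthPanel
from .scm import PredictorSpec, SCMFit, fit_state

__all__ = [
    "PlaceboEnsemble",
    "RatioRanking",
    "GateResult",
    "YearlyEffect",
    "run_placebos",
    "rank_p_value",
    "fit_gate",
    "yearly_effects",
]


@dataclass
class PlaceboEnsemble:
    """SCM fits for the treated unit and every donor treated-as-placebo."""

    treated: str
    fits: dict[str, SCMFit]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.fits)

    @property
    def ratios(self) -> pd.Series:
        return pd.Series({u: f.ratio for u, f in self.fits.items()}, name="ratio")

    def table(self) -> pd.DataFrame:
        """Per-unit RMSPE diagnostics, sorted most-extreme first."""
        df = pd.DataFrame(
            {
                "unit": list(self.fits),
                "rmspe_pre": [f.rmspe_pre for f in self.fits.values()],
                "rmspe_post": [f.rmspe_post for f in self.fits.values()],
                "ratio": [f.ratio for f in self.fits.values()],
                "is_treated": [u == self.treated for u in self.fits],
            }
        ).sort_values("ratio", ascending=False, kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True)


def run_placebos(
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
    rmspe_filter: float | None = None,
) -> PlaceboEnsemble:
    """Fit the treated unit and each donor as pseudo-treated.

    Each placebo keeps the same treatment month and predictor spec and is fit
    against the remaining donors; the actual treated unit never enters any
    placebo's donor pool.  Individual fit failures are recorded and the
    ensemble proceeds without them.

    ``rmspe_filter``: optionally drop placebos whose pre-period RMSPE exceeds
    this multiple of the treated unit's (off by default — the ratio statistic
    already normalizes by pre-period fit).
    """
    if len(donors) < 2:
        raise ValueError("placebo inference needs at least 2 donors")
    fits: dict[str, SCMFit] = {}
    failures: dict[str, str] = {}
    for unit in [treated] + list(donors):
        pool = [d for d in donors if d != unit]
        try:
            fits[unit] = fit_state(
                panel, unit, pool, treatment_month,
                covariates=covariates, spec=spec, v_mode=v_mode,
                n_starts=n_starts, random_state=random_state, solver=solver,
            )
        except Exception as exc:  # noqa: BLE001 - quarantine per-unit failures
            failures[unit] = f"{type(exc).__name__}: {exc}"
    if treated not in fits:
        raise RuntimeError(f"treated unit fit failed: {failures.get(treated)}")
    if rmspe_filter is not None:
        cut = rmspe_filter * fits[treated].rmspe_pre
        fits = {
            u: f for u, f in fits.items()
            if u == treated or f.rmspe_pre <= cut
        }
    return PlaceboEnsemble(treated=treated, fits=fits, failures=failures)


@dataclass
class RatioRanking:
    rank: int
    n_units: int
    p_value: float


def rank_p_value(ensemble: PlaceboEnsemble) -> RatioRanking:
    """Rank the treated unit's RMSPE ratio among all units; p = rank / n.

    Extremity is one-sided on the ratio (larger = stronger post-period
    divergence relative to fit).  Ties count as at least as extreme, so the
    treated rank is the number of units with ratio >= its own — conservative.
    """
    ratios = ensemble.ratios
    if ensemble.treated not in ratios.index:
        raise ValueError("treated ratio missing from ensemble")
    r_treated = ratios.loc[ensemble.treated]
    n = ensemble.n_units
    if np.isnan(r_treated):
        raise ValueError("treated ratio is undefined")
    rank = int((ratios >= r_treated).sum())
    return RatioRanking(rank=rank, n_units=n, p_value=rank / n)


@dataclass
class GateResult:
    interpretable: bool
    reasons: list[str]
    relative_rmspe: float
    placebo_median_rmspe: float


def fit_gate(
    fit: SCMFit,
    ensemble: PlaceboEnsemble | None = None,
    tau_relative: float = 0.10,
    tau_placebo: float = 2.0,
) -> GateResult:
    """Declare a fit interpretable or not from its pre-period quality.

    Two checks: pre-period RMSPE must not exceed ``tau_relative`` of the
    treated unit's mean pre-period rate (poor absolute fit), and must not
    exceed ``tau_placebo`` times the median placebo pre-period RMSPE (poor
    fit relative to what the donor pool supports).  A zero pre-period mean
    rate disables the relative check.
    """
    reasons: list[str] = []
    pre_mask = pd.PeriodIndex(fit.observed.index, freq="M") < fit.treatment_month
    mean_rate = float(fit.observed.to_numpy()[np.asarray(pre_mask)].mean())
    rel = fit.rmspe_pre / mean_rate if mean_rate > 0 else np.nan
    if mean_rate > 0 and rel > tau_relative:
        reasons.append(
            f"pre-period RMSPE is {rel:.1%} of the mean pre-period rate "
            f"(threshold tau_relative={tau_relative:.0%})"
        )
    med = np.nan
    if ensemble is not None:
        placebo_pre = [f.rmspe_pre for u, f in ensemble.fits.items() if u != fit.unit]
        if placebo_pre:
            med = float(np.median(placebo_pre))
            if med > 0 and fit.rmspe_pre > tau_placebo * med:
                reasons.append(
                    f"pre-period RMSPE exceeds {tau_placebo:g}x the median placebo "
                    f"pre-period RMSPE ({med:.4g})"
                )
    return GateResult(
        interpretable=not reasons,
        reasons=reasons,
        relative_rmspe=rel,
        placebo_median_rmspe=med,
    )


@dataclass
class YearlyEffect:
    """Policy effect over one 12-month implementation year.

    ``effect`` is the sum of monthly gaps in the block: incidents per
    1,000,000 residents per year, negative meaning a reduction relative to
    the synthetic counterfactual.  ``percent_change`` scales it by the
    synthetic (counterfactual) annual rate.
    """

    year: int
    effect: float
    ci_low: float
    ci_high: float
    percent_change: float
    n_months: int


def yearly_effects(
    fit: SCMFit,
    method: str = "monthly",
    ensemble: PlaceboEnsemble | None = None,
) -> list[YearlyEffect]:
    """Summarize post-period gaps in consecutive 12-month implementation years.

    ``method="monthly"`` builds a normal interval from the within-year spread
    of monthly gaps: effect ± 1.96·√n·sd(monthly gaps).  ``method="placebo"``
    takes the 2.5/97.5 percentiles of the placebo units' matching yearly
    effects.  A truncated final year is reported with its ``n_months``.
    """
    months = pd.PeriodIndex(fit.gap.index, freq="M")
    post = months >= fit.treatment_month
    gaps = fit.gap.to_numpy(dtype=float)[post]
    synth = fit.synthetic.to_numpy(dtype=float)[post]
    if gaps.size == 0:
        raise ValueError("no post-period months")

    placebo_blocks: dict[int, np.ndarray] = {}
    if method == "placebo":
        if ensemble is None:
            raise ValueError("placebo CI method needs an ensemble")
        others = [f for u, f in ensemble.fits.items() if u != fit.unit]
        for yr in range(1 + (gaps.size - 1) // 12):
            vals = []
            for f in others:
                g = f.gap.to_numpy(dtype=float)[np.asarray(pd.PeriodIndex(f.gap.index, freq="M") >= f.treatment_month)]
                block = g[yr * 12:(yr + 1) * 12]
                if block.size:
                    vals.append(block.sum())
            placebo_blocks[yr] = np.asarray(vals)
    elif method != "monthly":
        raise ValueError(f"unknown CI method {method!r}")

    out: list[YearlyEffect] = []
    for yr in range(1 + (gaps.size - 1) // 12):
        block = gaps[yr * 12:(yr + 1) * 12]
        sblock = synth[yr * 12:(yr + 1) * 12]
        effect = float(block.sum())
        baseline = float(sblock.sum())
        percent = 100.0 * effect / baseline if baseline != 0 else np.nan
        if method == "monthly":
            sd = float(block.std(ddof=1)) if block.size > 1 else 0.0
            half = 1.96 * np.sqrt(block.size) * sd
            lo, hi = effect - half, effect + half
        else:
            vals = placebo_blocks.get(yr, np.array([]))
            if vals.size:
                lo, hi = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
            else:
                lo = hi = np.nan
        out.append(
            YearlyEffect(
                year=yr + 1,
                effect=effect,
                ci_low=lo,
                ci_high=hi,
                percent_change=percent,
                n_months=int(block.size),
            )
        )
    return out
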