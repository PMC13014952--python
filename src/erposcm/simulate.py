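"""Ground-truth-annotated study generator.

Emits every input the pipeline consumes — incident records, state-year
populations and covariates, a policy catalog, petition series — from a linear
factor model of latent state-month rates, the data-generating process under
which the synthetic-control counterfactual is well-motivated:

    lambda_it = max(0, [delta_t + f_t' mu_i + eps_it] * covid_t + effect_it)

with a common seasonal/trended component ``delta_t``, smooth latent factors
``f_t`` with unit loadings ``mu_i``, Gaussian rate jitter ``eps``, a
multiplicative pandemic shock from 2020-03, and an injected treatment effect
expressed as a fraction of the baseline monthly rate.  Counts are Poisson
draws at ``lambda_it * pop_i / 1e6``, so small states are realistically noisy.

Treated loadings are drawn inside the donor convex hull by default (a good
synthetic control exists); ``overlap=False`` places them outside it to
exercise the pre-period fit gate.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import StateMonthPanel, month_range

__all__ = [
    "FactorModelConfig",
    "EffectProfile",
    "SimulatedStudy",
    "generate_panel",
    "generate_incidents",
    "generate_petitions",
    "DEFAULT_EFFECTIVE_DATES",
    "DEFAULT_INTENT_MIXTURE",
    "DEFAULT_FATALITY",
]

#: Default treated effective dates: the spread of real state ERPO effective
#: dates across 2016–2019, cycled over however many treated units are asked for.
DEFAULT_EFFECTIVE_DATES = (
    "2016-01-01", "2016-12-08", "2018-01-01", "2018-03-09", "2018-04-11",
    "2018-06-01", "2018-08-17", "2018-10-01", "2018-12-27", "2019-01-01",
)

#: Media-sourced incident compilations over-represent interpersonal violence;
#: self-harm is rarely reported unless fatal.
DEFAULT_INTENT_MIXTURE = {"assault": 0.85, "self_harm": 0.05, "unintentional": 0.10}
DEFAULT_FATALITY = {"assault": 0.25, "self_harm": 0.90, "unintentional": 0.05}


@dataclass
class FactorModelConfig:
    """Panel-generator settings.

    Defaults mirror the study geometry: 10 treated states, 25 donors, 96
    months (2014-01..2021-12), a baseline of 60 incidents per 1M residents
    per year, and a +20% rate shock from 2020-03.
    """

    n_treated: int = 10
    n_donors: int = 25
    start: str = "2014-01"
    end: str = "2021-12"
    n_factors: int = 2
    baseline_annual_rate: float = 60.0   # incidents per 1M residents per year
    trend_amplitude: float = 0.10        # relative linear drift over the window
    seasonal_amplitude: float = 0.05     # relative seasonal swing
    factor_scale: float = 0.30           # factor contribution, relative to baseline
    noise_sd: float = 0.20               # additive rate jitter, per 1M per month
    covid_start: str = "2020-03"
    covid_magnitude: float = 0.20        # relative rate increase from covid_start
    overlap: bool = True
    observation: str = "poisson"         # "poisson" counts or "exact" expected counts
    pop_log_mean: float = float(np.log(4.0e6))
    pop_log_sd: float = 0.9
    pop_min: float = 6.0e5
    pop_max: float = 3.9e7
    effective_dates: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_annual_rate <= 0:
            raise ValueError("baseline rate must be positive")


@dataclass
class EffectProfile:
    """Injected treatment-effect shape for one treated unit.

    ``delta`` is a fraction of the baseline *monthly* rate: a step of
    ``delta=-0.10`` removes 10% of the baseline monthly rate from every post
    month, i.e. a true yearly effect of ``-0.10 * 12 * baseline_monthly`` per
    1M residents.  A ramp scales linearly with the implementation year,
    reaching ``delta`` in the final year.  ``delta`` may also be a per-year
    sequence.
    """

    shape: str = "none"  # none | step | ramp
    delta: float | tuple[float, ...] = 0.0
    start: str | None = None  # effective date; defaults to the catalog's

    def monthly_fractions(self, n_post: int) -> np.ndarray:
        if self.shape == "none":
            return np.zeros(n_post)
        n_years = max(1, int(np.ceil(n_post / 12)))
        if isinstance(self.delta, (tuple, list)):
            per_year = np.asarray(self.delta, dtype=float)
            per_year = np.resize(per_year, n_years)
        elif self.shape == "step":
            per_year = np.full(n_years, float(self.delta))
        elif self.shape == "ramp":
            per_year = float(self.delta) * np.arange(1, n_years + 1) / n_years
        else:
            raise ValueError(f"unknown effect shape {self.shape!r}")
        return np.repeat(per_year, 12)[:n_post]


@dataclass
class SimulatedStudy:
    """Generated study inputs plus the ground truth behind them."""

    config: FactorModelConfig
    panel: StateMonthPanel
    catalog: pd.DataFrame
    populations: pd.DataFrame       # (state, year, population)
    covariates: pd.DataFrame        # (state, year, cov_*)
    petitions: pd.DataFrame | None  # (state, month, petitions)
    loadings: pd.DataFrame          # units x factors
    true_effects: pd.DataFrame      # treated units x months, rate per 1M
    latent_rates: pd.DataFrame      # units x months, lambda per 1M
    effects: dict[str, EffectProfile]

    @property
    def treated(self) -> list[str]:
        return list(self.true_effects.index)

    @property
    def donors(self) -> list[str]:
        return [u for u in self.panel.units if u not in set(self.true_effects.index)]

    def true_yearly_effects(self, unit: str) -> np.ndarray:
        """Ground-truth yearly effect sums (per 1M per year) for one treated unit."""
        eff = self.true_effects.loc[unit].to_numpy(dtype=float)
        start = pd.Period(self.catalog.set_index("state").loc[unit, "effective_date"], freq="M")
        months = self.panel.months
        post = eff[np.asarray(months >= start)]
        n_years = int(np.ceil(post.size / 12))
        return np.array([post[y * 12:(y + 1) * 12].sum() for y in range(n_years)])

    def write(self, outdir: str | Path, incidents: pd.DataFrame | None = None) -> dict[str, Path]:
        """Emit the CSV dialects the pipeline reads, plus a manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        cat = self.catalog.copy()
        cat["effective_date"] = cat["effective_date"].dt.strftime("%Y-%m-%d")
        for name, df in (
            ("policy_catalog", cat),
            ("populations", self.populations),
            ("covariates", self.covariates),
            ("petitions", self.petitions),
            ("incidents", incidents),
        ):
            if df is None:
                continue
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p

        p = outdir / "panel_counts.csv"
        counts = self.panel.counts.copy()
        counts.columns = counts.columns.astype(str)
        counts.to_csv(p, index_label="state")
        paths["panel_counts"] = p

        manifest = {
            "config": asdict(self.config),
            "effects": {u: asdict(e) for u, e in self.effects.items()},
            "treated": self.treated,
            "donors": self.donors,
            "true_yearly_effects": {
                u: self.true_yearly_effects(u).tolist() for u in self.treated
            },
        }
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, default=str))
        paths["manifest"] = p
        return paths


def _smooth_factors(rng: np.random.Generator, n_factors: int, n_months: int) -> np.ndarray:
    """Standardized AR(1) factor paths (phi=0.95)."""
    phi = 0.95
    innov = rng.normal(size=(n_factors, n_months))
    f = np.empty_like(innov)
    f[:, 0] = innov[:, 0]
    for t in range(1, n_months):
        f[:, t] = phi * f[:, t - 1] + np.sqrt(1 - phi**2) * innov[:, t]
    f -= f.mean(axis=1, keepdims=True)
    sd = f.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return f / sd


def generate_panel(
    config: FactorModelConfig | None = None,
    effects: dict[str, EffectProfile] | EffectProfile | None = None,
) -> SimulatedStudy:
    """Draw a complete study: panel, catalog, populations, covariates, petitions.

    ``effects`` may be a single profile (applied to every treated unit) or a
    map from treated unit name to profile.  Fully reproducible from
    ``config.seed``.
    """
    config = config or FactorModelConfig()
    rng = np.random.default_rng(config.seed)
    months = month_range(config.start, config.end)
    n_months = len(months)
    treated_units = [f"T{i + 1:02d}" for i in range(config.n_treated)]
    donor_units = [f"D{j + 1:02d}" for j in range(config.n_donors)]
    units = treated_units + donor_units
    n_units = len(units)

    base_m = config.baseline_annual_rate / 12.0

    # loadings: donors uniform on [0,1]^K; treated inside (or outside) their hull
    mu_donor = rng.uniform(0.0, 1.0, size=(config.n_donors, config.n_factors))
    if config.overlap:
        combos = rng.dirichlet(np.ones(config.n_donors), size=config.n_treated)
        mu_treated = combos @ mu_donor
    else:
        margin = rng.uniform(0.5, 1.0, size=(config.n_treated, config.n_factors))
        mu_treated = mu_donor.max(axis=0)[None, :] + margin
    mu = np.vstack([mu_treated, mu_donor])

    # common component: trend + seasonality, relative to baseline
    t_frac = np.arange(n_months) / max(1, n_months - 1)
    season = np.sin(2 * np.pi * (months.month.to_numpy() - 1) / 12.0)
    delta_t = base_m * (
        1.0
        + config.trend_amplitude * (2.0 * t_frac - 1.0)
        + config.seasonal_amplitude * season
    )

    factors = _smooth_factors(rng, config.n_factors, n_months)
    factor_part = base_m * config.factor_scale * ((mu - 0.5) @ factors)

    eps = rng.normal(0.0, config.noise_sd, size=(n_units, n_months)) if config.noise_sd > 0 else 0.0
    covid_mult = np.where(
        months >= pd.Period(config.covid_start, freq="M"), 1.0 + config.covid_magnitude, 1.0
    )
    lam_null = np.clip((delta_t[None, :] + factor_part + eps) * covid_mult[None, :], 0.0, None)

    # effective dates and injected effects
    date_cycle = config.effective_dates or DEFAULT_EFFECTIVE_DATES
    eff_dates = {
        u: pd.Timestamp(date_cycle[i % len(date_cycle)]) for i, u in enumerate(treated_units)
    }
    if effects is None:
        effect_map = {u: EffectProfile() for u in treated_units}
    elif isinstance(effects, EffectProfile):
        effect_map = {u: effects for u in treated_units}
    else:
        effect_map = {u: effects.get(u, EffectProfile()) for u in treated_units}
    for u, prof in effect_map.items():
        if prof.start is not None:
            eff_dates[u] = pd.Timestamp(prof.start)

    effect_rate = np.zeros((config.n_treated, n_months))
    for i, u in enumerate(treated_units):
        start_p = eff_dates[u].to_period("M")
        post = np.asarray(months >= start_p)
        fracs = effect_map[u].monthly_fractions(int(post.sum()))
        effect_rate[i, post] = fracs * base_m

    lam = lam_null.copy()
    lam[: config.n_treated] = np.clip(lam_null[: config.n_treated] + effect_rate, 0.0, None)
    true_effect = lam[: config.n_treated] - lam_null[: config.n_treated]

    # populations (constant across years) and counts
    pops = np.round(
        np.clip(
            rng.lognormal(config.pop_log_mean, config.pop_log_sd, size=n_units),
            config.pop_min,
            config.pop_max,
        )
    )
    expected = lam * pops[:, None] / 1e6
    if config.observation == "poisson":
        counts = rng.poisson(expected).astype(float)
    elif config.observation == "exact":
        counts = expected
    else:
        raise ValueError(f"unknown observation mode {config.observation!r}")

    years = sorted(set(months.year))
    pop_df = pd.DataFrame(
        [(u, y, int(round(p))) for u, p in zip(units, pops) for y in years],
        columns=["state", "year", "population"],
    )
    pop_month = pd.DataFrame(
        np.repeat(np.round(pops)[:, None], n_months, axis=1), index=units, columns=months
    )
    panel = StateMonthPanel(
        counts=pd.DataFrame(counts, index=units, columns=months), population=pop_month
    )

    catalog = pd.DataFrame(
        {
            "state": units,
            "effective_date": [eff_dates.get(u, pd.NaT) for u in units],
            "covariate_complete": True,
        }
    )

    # covariates: noisy linear functions of the loadings, so genuinely informative
    n_cov = 4
    beta = rng.normal(1.0, 0.5, size=(n_cov, config.n_factors))
    alpha = rng.normal(0.0, 1.0, size=n_cov)
    cov_vals = mu @ beta.T + alpha[None, :] + rng.normal(0.0, 0.1, size=(n_units, n_cov))
    cov_rows = []
    for i, u in enumerate(units):
        for y in years:
            cov_rows.append([u, y] + list(cov_vals[i]))
    cov_df = pd.DataFrame(cov_rows, columns=["state", "year"] + [f"cov{c + 1}" for c in range(n_cov)])

    petitions = generate_petitions(
        units, {u: str(d.date()) for u, d in eff_dates.items()}, (config.start, config.end),
        seed=int(rng.integers(2**31)),
    )

    return SimulatedStudy(
        config=config,
        panel=panel,
        catalog=catalog,
        populations=pop_df,
        covariates=cov_df,
        petitions=petitions,
        loadings=pd.DataFrame(mu, index=units, columns=[f"f{k + 1}" for k in range(config.n_factors)]),
        true_effects=pd.DataFrame(true_effect, index=treated_units, columns=months),
        latent_rates=pd.DataFrame(lam, index=units, columns=months),
        effects=effect_map,
    )


def generate_incidents(
    study: SimulatedStudy,
    intent_mixture: dict[str, float] | None = None,
    fatality: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Disaggregate panel counts into incident records.

    Each state-month count becomes that many records with iid intent draws
    (multinomial) and intent-specific fatality Bernoullis.  Every record has
    at least one casualty, so filtering + classifying + aggregating the
    records reproduces the panel's all-violence counts cell for cell.
    """
    mixture = intent_mixture or DEFAULT_INTENT_MIXTURE
    fat = fatality or DEFAULT_FATALITY
    intents = list(mixture)
    probs = np.array([mixture[i] for i in intents], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("intent mixture must be a probability vector")
    counts = study.panel.counts.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError(
            "panel counts are not integers (generate the panel with observation='poisson')"
        )
    counts = counts.astype(int)
    if counts.sum() == 0:
        raise ValueError("empty panel: no incidents to disaggregate")
    rng = np.random.default_rng(seed)
    units = study.panel.units
    months = study.panel.months

    unit_idx = np.repeat(np.arange(len(units)), counts.sum(axis=1))
    month_idx = np.concatenate([np.repeat(np.arange(len(months)), row) for row in counts])
    n = unit_idx.size
    intent_draw = rng.choice(len(intents), size=n, p=probs)
    intent_arr = np.array(intents, dtype=object)[intent_draw]
    p_fatal = np.array([fat[i] for i in intents])[intent_draw]
    fatal = rng.random(n) < p_fatal
    n_killed = fatal.astype(int)
    n_injured = np.where(fatal, rng.poisson(0.3, size=n), 1 + rng.poisson(0.3, size=n))

    month_objs = months[month_idx]
    days_in_month = np.array([calendar.monthrange(p.year, p.month)[1] for p in month_objs])
    day = rng.integers(1, days_in_month + 1)
    dates = [f"{p.year:04d}-{p.month:02d}-{d:02d}" for p, d in zip(month_objs, day)]

    return pd.DataFrame(
        {
            "state": np.array(units, dtype=object)[unit_idx],
            "date": dates,
            "n_injured": n_injured,
            "n_killed": n_killed,
            "intent": intent_arr,
            "mass_shooting": (n_injured + n_killed) >= 4,
        }
    )


def generate_petitions(
    states: list[str],
    effective_dates: dict[str, str | None],
    window: tuple[str, str],
    mean_rate: float = 5.0,
    growth: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Monthly petition counts: structurally zero before enactment, Poisson
    with mean ``mean_rate`` after, optionally growing ``growth`` per year of
    implementation (uptake improving over time)."""
    if mean_rate < 0:
        raise ValueError("mean_rate must be non-negative")
    months = month_range(*window)
    rng = np.random.default_rng(seed)
    rows = []
    for state in states:
        eff = effective_dates.get(state)
        counts = np.zeros(len(months), dtype=int)
        if eff is not None and not pd.isna(eff):
            eff_p = pd.Timestamp(eff).to_period("M")
            post = np.asarray(months >= eff_p)
            if post.any():
                yrs = np.arange(int(post.sum())) // 12
                lam = mean_rate * (1.0 + growth) ** yrs
                counts[post] = rng.poisson(lam)
        rows.append(pd.DataFrame({"state": state, "month": months.astype(str), "petitions": counts}))
    return pd.concat(rows, ignore_index=True)
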