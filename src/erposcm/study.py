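"""End-to-end study orchestration: cohort selection, per-state synthetic
controls, placebo inference, fit gating, and intent-stratified re-analysis.

Each treated state is analyzed independently (its own treatment month, its
own placebo ensemble) because the policies being compared differ in design
and uptake; pooling them would equate laws that are not equivalent.  Each
outcome stratum is a full re-analysis on the stratum's own panel, not a
decomposition of the overall estimate.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortDecision, load_policy_catalog, select_cohort, DEFAULT_WINDOW_BOUNDS
from .inference import (
    GateResult,
    fit_gate,
    rank_p_value,
    run_placebos,
    yearly_effects,
)
from .panel import OutcomeCategory, aggregate_rates, read_incidents
from .scm import PredictorSpec

__all__ = ["StudyConfig", "StudyReport", "StateResult", "CategoryResult", "run_study", "export_report"]

ALL_CATEGORIES = [c.value for c in OutcomeCategory]


@dataclass
class StudyConfig:
    """Declarative description of one full study run."""

    incidents: str
    populations: str
    policy_catalog: str | None = None  # None -> packaged ERPO catalog
    petitions: str | None = None
    covariates: str | None = None
    window: tuple[str, str] = ("2014-01", "2021-12")
    cohort_bounds: tuple[str, str] = DEFAULT_WINDOW_BOUNDS
    alpha: float = 0.05
    categories: list[str] = field(default_factory=lambda: list(ALL_CATEGORIES))
    outcome_lags: object = "thirds"
    v_mode: str = "nested"
    n_starts: int = 10
    solver: str = "exact"
    ci_method: str = "monthly"
    tau_relative: float = 0.10
    tau_placebo: float = 2.0
    rmspe_filter: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.window = tuple(self.window)
        self.cohort_bounds = tuple(self.cohort_bounds)
        bad = [c for c in self.categories if c not in ALL_CATEGORIES]
        if bad:
            raise ValueError(f"unknown outcome categories: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CategoryResult:
    """Placebo inference for one (state, outcome category) pair."""

    category: str
    p_value: float
    rank: int
    n_units: int
    ratios: pd.DataFrame
    weights: pd.Series
    importance: pd.Series
    effects: list
    gap_data: pd.DataFrame


@dataclass
class StateResult:
    state: str
    status: str  # excluded | uninterpretable | estimated
    decision: CohortDecision | None = None
    gate: GateResult | None = None
    categories: dict[str, CategoryResult] = field(default_factory=dict)
    error: str | None = None


@dataclass
class StudyReport:
    config: StudyConfig
    states: dict[str, StateResult]
    treated: list[str]
    donors: list[str]
    provenance: dict

    def status_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(self.states),
                "status": [r.status for r in self.states.values()],
            }
        )


def _gap_data(ensemble) -> pd.DataFrame:
    frames = []
    for unit, fit in ensemble.fits.items():
        frames.append(
            pd.DataFrame(
                {
                    "month": fit.gap.index.astype(str),
                    "unit": unit,
                    "gap": fit.gap.to_numpy(),
                    "is_treated": unit == ensemble.treated,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full pipeline described by ``config``.

    Per treated state: cohort filters first (excluded states get no fits),
    then the overall-violence synthetic control and its placebo ensemble,
    the pre-period fit gate (uninterpretable states carry no effect
    estimates), and finally one independent placebo-inference run per
    requested outcome stratum.  Deterministic given the config and seed.
    """
    records = read_incidents(config.incidents)
    populations = pd.read_csv(config.populations)
    catalog = load_policy_catalog(config.policy_catalog)
    petitions = pd.read_csv(config.petitions) if config.petitions else None
    covariates = pd.read_csv(config.covariates) if config.covariates else None

    treated, donors, decisions = select_cohort(
        catalog, petitions, window=config.window, bounds=config.cohort_bounds, alpha=config.alpha
    )
    # restrict to units actually present in the outcome data
    present = set(records["state"].unique()) & set(populations["state"].unique())
    treated = [s for s in treated if s in present]
    donors = [s for s in donors if s in present]
    units = treated + donors
    spec = PredictorSpec(outcome_lags=config.outcome_lags)

    panels = {
        cat: aggregate_rates(records, populations, cat, window=config.window, states=units)
        for cat in dict.fromkeys([OutcomeCategory.ALL_VIOLENCE.value] + list(config.categories))
    }

    eff_dates = catalog.set_index("state")["effective_date"]
    states: dict[str, StateResult] = {}
    for state, decision in decisions.items():
        if state not in present and decision.included:
            continue
        if not decision.included:
            states[state] = StateResult(state=state, status="excluded", decision=decision)
            continue
        treatment_month = eff_dates.loc[state].to_period("M")
        pool = [d for d in donors if d != state]
        common = dict(
            covariates=covariates, spec=spec, v_mode=config.v_mode,
            n_starts=config.n_starts, random_state=config.seed, solver=config.solver,
            rmspe_filter=config.rmspe_filter,
        )
        try:
            main = run_placebos(
                panels[OutcomeCategory.ALL_VIOLENCE.value], state, pool, treatment_month, **common
            )
        except Exception as exc:  # noqa: BLE001 - quarantine, keep the run going
            states[state] = StateResult(
                state=state, status="uninterpretable", decision=decision,
                error=f"{type(exc).__name__}: {exc}",
            )
            continue
        gate = fit_gate(
            main.fits[state], main,
            tau_relative=config.tau_relative, tau_placebo=config.tau_placebo,
        )
        if not gate.interpretable:
            states[state] = StateResult(
                state=state, status="uninterpretable", decision=decision, gate=gate
            )
            continue

        result = StateResult(state=state, status="estimated", decision=decision, gate=gate)
        for cat in config.categories:
            ensemble = (
                main if cat == OutcomeCategory.ALL_VIOLENCE.value
                else run_placebos(panels[cat], state, pool, treatment_month, **common)
            )
            fit = ensemble.fits[state]
            ranking = rank_p_value(ensemble)
            effects = yearly_effects(
                fit, method=config.ci_method,
                ensemble=ensemble if config.ci_method == "placebo" else None,
            )
            result.categories[cat] = CategoryResult(
                category=cat,
                p_value=ranking.p_value,
                rank=ranking.rank,
                n_units=ranking.n_units,
                ratios=ensemble.table(),
                weights=fit.weights,
                importance=fit.importance,
                effects=effects,
                gap_data=_gap_data(ensemble),
            )
        states[state] = result

    provenance = {
        "config_digest": StudyConfig.digest(config),
        "seed": config.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_treated": len(treated),
        "n_donors": len(donors),
    }
    return StudyReport(config=config, states=states, treated=treated, donors=donors, provenance=provenance)


def export_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write the report's tables: cohort decisions, per-state per-category
    ratio rankings, yearly effects with CIs, weights, importances, gap-plot
    data, and a gate/provenance manifest.  Re-running is idempotent."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    dec_rows = []
    for state, res in report.states.items():
        d = res.decision
        dec_rows.append(
            {
                "state": state,
                "status": res.status,
                "included": d.included if d else None,
                "failed_filters": ";".join(d.failed_filters) if d else "",
                "t_statistic": d.t_statistic if d else None,
                "p_value": d.p_value if d else None,
            }
        )
    p = outdir / "cohort_decisions.csv"
    pd.DataFrame(dec_rows).to_csv(p, index=False)
    paths["cohort_decisions"] = p

    effect_rows = []
    for state, res in report.states.items():
        for cat, cr in res.categories.items():
            stem = f"{state}_{cat}"
            cr.ratios.to_csv(outdir / f"{stem}_ratios.csv", index=False)
            cr.weights.rename_axis("donor").to_csv(outdir / f"{stem}_weights.csv")
            cr.importance.rename_axis("predictor").to_csv(outdir / f"{stem}_importance.csv")
            cr.gap_data.to_csv(outdir / f"{stem}_gaps.csv", index=False)
            for eff in cr.effects:
                effect_rows.append(
                    {
                        "state": state,
                        "category": cat,
                        "year": eff.year,
                        "effect_per_1m": eff.effect,
                        "ci_low": eff.ci_low,
                        "ci_high": eff.ci_high,
                        "percent_change": eff.percent_change,
                        "n_months": eff.n_months,
                        "p_value": cr.p_value,
                    }
                )
    p = outdir / "yearly_effects.csv"
    pd.DataFrame(
        effect_rows,
        columns=[
            "state", "category", "year", "effect_per_1m", "ci_low", "ci_high",
            "percent_change", "n_months", "p_value",
        ],
    ).to_csv(p, index=False)
    paths["yearly_effects"] = p

    gate = {
        state: {
            "status": res.status,
            "reasons": res.gate.reasons if res.gate else [],
            "relative_rmspe": res.gate.relative_rmspe if res.gate else None,
            "error": res.error,
        }
        for state, res in report.states.items()
    }
    p = outdir / "gate_report.json"
    p.write_text(json.dumps(gate, indent=2, default=str))
    paths["gate_report"] = p

    p = outdir / "manifest.json"
    p.write_text(
        json.dumps(
            {"provenance": report.provenance, "config": asdict(report.config),
             "treated": report.treated, "donors": report.donors},
            indent=2,
            default=str,
        )
    )
    paths["manifest"] = p
    return paths
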