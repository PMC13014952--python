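"""State-month firearm-violence outcome panels built from incident-level records.

The outcome unit is the *incident* (an event in which at least one person was
injured or killed by gunfire), not the victim: victim counts are retained only
to classify each incident by intent and lethality.  Rates are expressed per
1,000,000 residents per month, with annual population denominators held
constant within each calendar year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeCategory",
    "StateMonthPanel",
    "read_incidents",
    "filter_injurious",
    "classify_incident",
    "category_mask",
    "aggregate_rates",
    "month_range",
    "VALID_INTENTS",
    "DEFAULT_WINDOW",
]

VALID_INTENTS = frozenset({"assault", "self_harm", "unintentional", "undetermined"})

#: Default study window.  The end is pinned at 2021-12 because incident
#: compilations changed how self-directed violence is captured from 2022 on;
#: extending past it is allowed but triggers a warning.
DEFAULT_WINDOW = ("2014-01", "2021-12")

_REQUIRED_COLUMNS = ("state", "date", "n_injured", "n_killed", "intent")


class OutcomeCategory(str, Enum):
    """Outcome stratifications: overall firearm violence plus six intent strata."""

    ALL_VIOLENCE = "all_violence"
    NONFATAL_ASSAULT = "nonfatal_assault"
    HOMICIDE = "homicide"
    OTHER_DIRECTED = "other_directed"
    NONFATAL_SELF_HARM = "nonfatal_self_harm"
    SUICIDE = "suicide"
    SELF_DIRECTED = "self_directed"


def month_range(start: str, end: str) -> pd.PeriodIndex:
    """Contiguous monthly PeriodIndex from ``start`` to ``end`` inclusive."""
    idx = pd.period_range(start, end, freq="M")
    if len(idx) == 0:
        raise ValueError(f"empty month window {start}..{end}")
    return idx


@dataclass
class StateMonthPanel:
    """Rectangular units x months panel of incident counts, rates and populations.

    Attributes
    ----------
    counts : DataFrame, units x months (PeriodIndex columns)
        Incident counts per state-month.  Float-valued so that noiseless
        simulated panels (expected counts) are representable.
    population : DataFrame, units x months
        Resident population, constant within each calendar year.
    """

    counts: pd.DataFrame
    population: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.population.index):
            raise ValueError("counts and population unit indices differ")
        if not self.counts.columns.equals(self.population.columns):
            raise ValueError("counts and population month columns differ")
        if self.counts.isna().any().any():
            raise ValueError("panel has missing cells")
        months = self.months
        if len(months) > 1 and (np.diff(months.asi8) != 1).any():
            raise ValueError("months are not contiguous")

    @property
    def units(self) -> list[str]:
        return list(self.counts.index)

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(self.counts.columns, freq="M")

    @property
    def rates(self) -> pd.DataFrame:
        """Incidents per 1,000,000 residents per month."""
        return self.counts * 1e6 / self.population

    def to_long(self, category: str = OutcomeCategory.ALL_VIOLENCE.value) -> pd.DataFrame:
        """Long table (state, month, category, count, rate)."""
        rates = self.rates
        rows = []
        for unit in self.units:
            rows.append(
                pd.DataFrame(
                    {
                        "state": unit,
                        "month": self.months.astype(str),
                        "category": category,
                        "count": self.counts.loc[unit].to_numpy(),
                        "rate": rates.loc[unit].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_wide_csv(self, path: str | Path) -> None:
        out = self.rates.copy()
        out.columns = out.columns.astype(str)
        out.to_csv(path, index_label="state")


def read_incidents(path: str | Path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an incident-record CSV into a validated DataFrame.

    Parameters
    ----------
    schema
        Optional map from canonical column names (``state``, ``date``,
        ``n_injured``, ``n_killed``, ``intent``, ``mass_shooting``) to the
        column names used in the file.

    Returns
    -------
    DataFrame with canonical columns.  Rows with unparseable dates or negative
    victim counts are dropped; a warning lists each rejected row index and the
    offending field, and the diagnostics are kept in ``df.attrs["rejected"]``.

    Raises
    ------
    FileNotFoundError, ValueError (missing required column, or every row rejected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if "mass_shooting" not in raw.columns:
        raw["mass_shooting"] = False

    df = raw.loc[:, list(_REQUIRED_COLUMNS) + ["mass_shooting"]].copy()
    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    injured = pd.to_numeric(df["n_injured"], errors="coerce")
    killed = pd.to_numeric(df["n_killed"], errors="coerce")

    diagnostics: list[tuple[int, str, str]] = []
    bad = pd.Series(False, index=df.index)
    for idx in df.index[dates.isna()]:
        diagnostics.append((int(idx), "date", f"unparseable date {df.at[idx, 'date']!r}"))
    bad |= dates.isna()
    for field, series in (("n_injured", injured), ("n_killed", killed)):
        invalid = series.isna() | (series < 0)
        for idx in df.index[invalid]:
            diagnostics.append((int(idx), field, f"invalid count {df.at[idx, field]!r}"))
        bad |= invalid

    if diagnostics:
        warnings.warn(
            "rejected rows: " + "; ".join(f"row {i}: {f} ({m})" for i, f, m in diagnostics),
            stacklevel=2,
        )
    df = df.loc[~bad].copy()
    if df.empty:
        raise ValueError("all rows rejected during validation")
    df["date"] = dates.loc[df.index]
    df["n_injured"] = injured.loc[df.index].astype(int)
    df["n_killed"] = killed.loc[df.index].astype(int)
    df["state"] = df["state"].astype(str)
    df["intent"] = df["intent"].astype(str)
    df["mass_shooting"] = df["mass_shooting"].astype(bool)
    df = df.reset_index(drop=True)
    df.attrs["rejected"] = diagnostics
    return df


def filter_injurious(records: pd.DataFrame) -> pd.DataFrame:
    """Retain only incidents in which at least one person was injured or killed.

    Events without casualties (warning shots, gun-involved robberies with no
    one hit, firearm recoveries) are not firearm-violence outcomes here.
    Order is preserved; the operation is idempotent.
    """
    keep = (records["n_injured"] + records["n_killed"]) >= 1
    return records.loc[keep]


def classify_incident(
    intent: str, n_injured: int, n_killed: int, strict: bool = True
) -> frozenset[OutcomeCategory]:
    """Map one incident to the set of outcome categories it counts toward.

    Every injurious incident counts toward ``all_violence``.  Assaults split
    into homicide (any death) vs nonfatal assault, self-harm into suicide vs
    nonfatal self-harm — fatal dominance, so an incident with both a death and
    a nonfatal injury of the same intent counts once, in the fatal category,
    keeping the composite strata additive.  Unintentional and undetermined
    incidents contribute to ``all_violence`` only.

    ``strict=False`` maps unknown intent labels to ``undetermined`` instead of
    raising.
    """
    if intent not in VALID_INTENTS:
        if strict:
            raise ValueError(f"unknown intent label {intent!r}")
        intent = "undetermined"
    cats = {OutcomeCategory.ALL_VIOLENCE}
    fatal = n_killed >= 1
    if intent == "assault":
        cats.add(OutcomeCategory.OTHER_DIRECTED)
        cats.add(OutcomeCategory.HOMICIDE if fatal else OutcomeCategory.NONFATAL_ASSAULT)
    elif intent == "self_harm":
        cats.add(OutcomeCategory.SELF_DIRECTED)
        cats.add(OutcomeCategory.SUICIDE if fatal else OutcomeCategory.NONFATAL_SELF_HARM)
    return frozenset(cats)


def category_mask(records: pd.DataFrame, category: OutcomeCategory | str) -> pd.Series:
    """Vectorized membership of each record in ``category`` (same rules as
    :func:`classify_incident`)."""
    category = OutcomeCategory(category)
    intent = records["intent"]
    fatal = records["n_killed"] >= 1
    if category is OutcomeCategory.ALL_VIOLENCE:
        return pd.Series(True, index=records.index)
    if category is OutcomeCategory.OTHER_DIRECTED:
        return intent == "assault"
    if category is OutcomeCategory.NONFATAL_ASSAULT:
        return (intent == "assault") & ~fatal
    if category is OutcomeCategory.HOMICIDE:
        return (intent == "assault") & fatal
    if category is OutcomeCategory.SELF_DIRECTED:
        return intent == "self_harm"
    if category is OutcomeCategory.NONFATAL_SELF_HARM:
        return (intent == "self_harm") & ~fatal
    if category is OutcomeCategory.SUICIDE:
        return (intent == "self_harm") & fatal
    raise ValueError(category)  # pragma: no cover


def monthly_population(populations: pd.DataFrame, units: list[str], months: pd.PeriodIndex) -> pd.DataFrame:
    """Expand a (state, year, population) table to a units x months matrix.

    Populations are treated as constant within each calendar year.
    """
    for col in ("state", "year", "population"):
        if col not in populations.columns:
            raise ValueError(f"population table missing column {col!r}")
    table = populations.set_index(["state", "year"])["population"]
    if table.index.duplicated().any():
        raise ValueError("duplicate (state, year) rows in population table")
    out = np.empty((len(units), len(months)), dtype=float)
    years = months.year
    for i, unit in enumerate(units):
        for j, yr in enumerate(years):
            try:
                out[i, j] = table.loc[(unit, yr)]
            except KeyError:
                raise ValueError(f"population missing for state {unit!r}, year {yr}") from None
    if (out <= 0).any():
        raise ValueError("non-positive population")
    return pd.DataFrame(out, index=units, columns=months)


def aggregate_rates(
    records: pd.DataFrame,
    populations: pd.DataFrame,
    category: OutcomeCategory | str = OutcomeCategory.ALL_VIOLENCE,
    window: tuple[str, str] = DEFAULT_WINDOW,
    states: list[str] | None = None,
    strict_intent: bool = True,
) -> StateMonthPanel:
    """Aggregate injurious incidents into a complete state-month panel.

    Cells count incidents (not victims) matching ``category``; state-months
    with no matching incident are present with count zero.  ``states``
    defaults to every state in the population table, which therefore defines
    the panel's unit universe.
    """
    if window[1] > DEFAULT_WINDOW[1]:
        warnings.warn(
            "window extends past 2021-12; post-2021 self-directed incident capture "
            "is not comparable to earlier years",
            stacklevel=2,
        )
    months = month_range(*window)
    if states is None:
        states = sorted(populations["state"].unique())
    if strict_intent:
        unknown = set(records["intent"].unique()) - VALID_INTENTS
        if unknown:
            raise ValueError(f"unknown intent label(s) {sorted(unknown)}")

    rec_states = set(records["state"].unique())
    missing_states = rec_states - set(populations["state"].unique())
    if missing_states:
        raise ValueError(f"state(s) absent from population table: {sorted(missing_states)}")

    kept = filter_injurious(records)
    kept = kept.loc[category_mask(kept, category)]
    period = pd.PeriodIndex(kept["date"], freq="M")
    in_window = (period >= months[0]) & (period <= months[-1])
    kept = kept.loc[in_window]
    period = period[in_window]

    tally = (
        pd.DataFrame({"state": kept["state"].to_numpy(), "month": period})
        .groupby(["state", "month"], observed=True)
        .size()
    )
    counts = tally.unstack(fill_value=0).reindex(index=states, columns=months, fill_value=0)
    counts = counts.astype(float)
    pop = monthly_population(populations, states, months)
    return StateMonthPanel(counts=counts, population=pop)
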