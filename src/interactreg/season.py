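"""In-season weekly yield forecasting with historical scenario ensembles.

At week w of the target season, weather and management are observed only
through week w.  Each historical donor year supplies one completion scenario:
columns for weeks ≤ w come from the target season, later weekly columns from
the donor year, and static columns (soil, non-weekly management) from the
target.  The model predicts every scenario; the weekly forecast is the median
with a first/third-quartile band.  Once the season is fully observed
(week 52) every scenario equals the observed row and the band collapses to
the point prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InteractRegError
from .kernels import KernelRegistry
from .model import FittedModel, predict
from .panel import WEEK_MAX, WEEK_MIN, SamplePanel


@dataclass
class ScenarioEnsemble:
    """Completed scenarios for one (county, year) target at one week."""

    as_of_week: int
    county_id: str
    year: int
    scenarios: SamplePanel          # one row per donor year
    donor_years: list[int]

    def __post_init__(self) -> None:
        if not (WEEK_MIN <= self.as_of_week <= WEEK_MAX):
            raise InteractRegError(
                f"as_of_week {self.as_of_week} outside [{WEEK_MIN}, {WEEK_MAX}]"
            )
        if self.scenarios.n == 0:
            raise InteractRegError("scenario ensemble is empty")
        if self.scenarios.n != len(self.donor_years):
            raise InteractRegError("one scenario per donor year required")


def build_scenarios(
    target_partial: SamplePanel,
    history: SamplePanel,
    as_of_week: int,
    management_splice: str = "monotone",
) -> ScenarioEnsemble:
    """Splice the target's observed prefix with each donor year's completion.

    ``target_partial`` is a single-row panel for the target county-year whose
    weekly columns are trusted through ``as_of_week`` (later weekly values are
    ignored).  ``history`` holds complete past rows for the same county; each
    of its years becomes one scenario.

    Management progress columns are cumulative, so with the default
    ``monotone`` splice an unobserved progress value is the donor's value
    floored at the last observed target value (the curve continues
    monotonically from where observation stopped); ``copy`` takes the donor
    value as-is.
    """
    if history.n == 0:
        raise InteractRegError("donor history is empty")
    if target_partial.n != 1:
        raise InteractRegError("target must be a single-row panel")
    if target_partial.catalogue != history.catalogue:
        raise InteractRegError("target and history catalogues differ")
    if management_splice not in ("monotone", "copy"):
        raise InteractRegError(f"unknown management splice {management_splice!r}")

    catalogue = target_partial.catalogue
    county, year = target_partial.rows[0]
    target_x = target_partial.X[0]

    # last observed cumulative value per management stem, for the monotone splice
    last_observed: dict[str, float] = {}
    if management_splice == "monotone":
        for j, v in enumerate(catalogue):
            if (v.category == "management" and v.week_index is not None
                    and v.week_index <= as_of_week):
                stem = v.name.rsplit("_wk", 1)[0]
                prev_week, _ = last_observed.get(stem, (-1, 0.0))
                if v.week_index > prev_week:
                    last_observed[stem] = (v.week_index, float(target_x[j]))

    X = np.empty((history.n, len(catalogue)))
    for j, v in enumerate(catalogue):
        if v.week_index is None or v.week_index <= as_of_week:
            X[:, j] = target_x[j]
        else:
            donor = history.X[:, j]
            if v.category == "management" and management_splice == "monotone":
                stem = v.name.rsplit("_wk", 1)[0]
                floor = last_observed.get(stem, (None, None))[1]
                X[:, j] = donor if floor is None else np.maximum(donor, floor)
            else:
                X[:, j] = donor

    donor_years = [t for _, t in history.rows]
    scenarios = SamplePanel(
        rows=[(f"{county}|scenario{y}", year) for y in donor_years],
        X=X,
        catalogue=catalogue,
    )
    return ScenarioEnsemble(
        as_of_week=as_of_week, county_id=county, year=year,
        scenarios=scenarios, donor_years=donor_years,
    )


@dataclass
class WeeklyForecast:
    """Median and interquartile forecast band per week."""

    frame: pd.DataFrame  # week, median, q1, q3, n_scenarios

    def __post_init__(self) -> None:
        bad = (self.frame["q1"] > self.frame["median"]) | (
            self.frame["median"] > self.frame["q3"]
        )
        if bad.any():
            raise InteractRegError("quartile ordering violated")

    def at_week(self, week: int) -> pd.Series:
        rows = self.frame[self.frame["week"] == week]
        if rows.empty:
            raise InteractRegError(f"no forecast for week {week}")
        return rows.iloc[0]


def weekly_forecast(
    model: FittedModel,
    ensembles: Iterable[ScenarioEnsemble] | Mapping[int, ScenarioEnsemble],
    registry: KernelRegistry | None = None,
) -> WeeklyForecast:
    """Predict every scenario and summarize per week.

    Quartiles use linear interpolation between order statistics (numpy's
    default percentile rule), so predictions (8, 9, 10) give a (8.5, 9, 9.5)
    band.
    """
    if isinstance(ensembles, Mapping):
        ensembles = [ensembles[k] for k in sorted(ensembles)]
    records = []
    for ens in ensembles:
        preds = predict(model, ens.scenarios, registry)
        q1, med, q3 = np.percentile(preds, [25, 50, 75])
        records.append(
            {"week": ens.as_of_week, "median": float(med), "q1": float(q1),
             "q3": float(q3), "n_scenarios": len(preds)}
        )
    if not records:
        raise InteractRegError("no scenario ensembles supplied")
    frame = pd.DataFrame.from_records(records).sort_values("week").reset_index(drop=True)
    return WeeklyForecast(frame=frame)


def season_forecast(
    model: FittedModel,
    target_partial: SamplePanel,
    history: SamplePanel,
    weeks: Sequence[int],
    registry: KernelRegistry | None = None,
    management_splice: str = "monotone",
) -> WeeklyForecast:
    """Convenience: build one ensemble per requested week and forecast."""
    ensembles = [
        build_scenarios(target_partial, history, int(w), management_splice)
        for w in weeks
    ]
    return weekly_forecast(model, ensembles, registry)
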