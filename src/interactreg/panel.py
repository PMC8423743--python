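"""County-year panel data model.

A panel holds one row per (county, year) with explanatory variables in three
categories — weekly weather (weeks 13–52), soil by depth layer, and
management — plus an optional observed yield in t/ha.  The module reads and
writes the CSV representation, aggregates sub-county grid cells to county
level, derives standard agronomic features (growing degree days, rainy days,
heat units, a historical yield-trend covariate), min-max normalizes on
designated fit rows, and builds blocked train/validation fold schemes along
the temporal and spatial axes.

CSV convention: header ``county_id,year[,yield],<vars...>`` with variable
columns prefixed ``W_`` (weather), ``S_`` (soil) or ``M_`` (management);
weekly variables carry a ``_wk<13..52>`` suffix and soil depths a
``_d<label>`` suffix.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRowError,
    FoldError,
    PanelSchemaError,
    UnknownVariableError,
)

WEEK_MIN = 13
WEEK_MAX = 52

CATEGORIES = ("weather", "soil", "management")
_PREFIX_TO_CATEGORY = {"W_": "weather", "S_": "soil", "M_": "management"}
_WEEK_RE = re.compile(r"_wk(\d+)$")
_DEPTH_RE = re.compile(r"_d([A-Za-z0-9]+)$")

RESERVED_COLUMNS = ("county_id", "year", "yield")


@dataclass(frozen=True)
class Variable:
    """One catalogue entry: a named explanatory variable with a category."""

    name: str
    category: str
    week_index: int | None = None
    depth_label: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PanelSchemaError(
                f"variable {self.name!r}: unknown category {self.category!r}"
            )
        if self.week_index is not None and not (
            WEEK_MIN <= self.week_index <= WEEK_MAX
        ):
            raise PanelSchemaError(
                f"variable {self.name!r}: week index {self.week_index} "
                f"outside [{WEEK_MIN}, {WEEK_MAX}]"
            )

    @staticmethod
    def from_column(column: str) -> "Variable":
        """Infer category/week/depth from a prefixed CSV column name."""
        prefix = column[:2]
        category = _PREFIX_TO_CATEGORY.get(prefix)
        if category is None:
            raise PanelSchemaError(
                f"column {column!r}: unknown category prefix "
                f"(expected one of {sorted(_PREFIX_TO_CATEGORY)})"
            )
        week = None
        m = _WEEK_RE.search(column)
        if m:
            week = int(m.group(1))
        depth = None
        if category == "soil":
            d = _DEPTH_RE.search(column)
            if d:
                depth = d.group(1)
        return Variable(name=column, category=category, week_index=week, depth_label=depth)


class VariableCatalogue:
    """Ordered, name-unique collection of Variable entries."""

    def __init__(self, entries: Iterable[Variable]):
        self.entries: tuple[Variable, ...] = tuple(entries)
        names = [v.name for v in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelSchemaError(f"duplicate variable names: {dupes}")
        self._index = {v.name: i for i, v in enumerate(self.entries)}

    @classmethod
    def from_columns(cls, columns: Sequence[str]) -> "VariableCatalogue":
        return cls(Variable.from_column(c) for c in columns)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, VariableCatalogue) and self.entries == other.entries

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.entries]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownVariableError(f"variable {name!r} not in catalogue") from None

    def get(self, name: str) -> Variable:
        return self.entries[self.index(name)]

    def category_of(self, name: str) -> str:
        return self.get(name).category

    def by_category(self, category: str) -> list[str]:
        return [v.name for v in self.entries if v.category == category]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for v in self.entries:
            counts[v.category] += 1
        return counts

    def content_hash(self) -> str:
        """Stable hash of names+categories, used to guard schema mismatches."""
        import hashlib

        payload = json.dumps(
            [(v.name, v.category, v.week_index, v.depth_label) for v in self.entries]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SamplePanel:
    """The county-year design: rows, X matrix aligned to a catalogue, optional y."""

    rows: list[tuple[str, int]]
    X: np.ndarray
    catalogue: VariableCatalogue
    y: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.rows = [(str(c), int(t)) for c, t in self.rows]
        if len(set(self.rows)) != len(self.rows):
            seen: set[tuple[str, int]] = set()
            for r in self.rows:
                if r in seen:
                    raise DuplicateRowError(f"duplicate (county_id, year) pair: {r}")
                seen.add(r)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.rows), len(self.catalogue)):
            raise PanelSchemaError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.rows)} rows x {len(self.catalogue)} variables"
            )
        if self.X.size and not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise PanelSchemaError(
                f"non-finite value at row {bad[0]}, column "
                f"{self.catalogue.names[bad[1]]!r}"
            )
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (len(self.rows),):
                raise PanelSchemaError("y length does not match number of rows")
            if self.y.size and not np.all(np.isfinite(self.y)):
                raise PanelSchemaError("non-finite value in yield column")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def p(self) -> int:
        return len(self.catalogue)

    @property
    def years(self) -> np.ndarray:
        return np.array([t for _, t in self.rows], dtype=int)

    @property
    def counties(self) -> np.ndarray:
        return np.array([c for c, _ in self.rows], dtype=object)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.catalogue.index(name)]

    def subset(self, row_ids: Sequence[int]) -> "SamplePanel":
        idx = np.asarray(row_ids, dtype=int)
        return SamplePanel(
            rows=[self.rows[i] for i in idx],
            X=self.X[idx],
            catalogue=self.catalogue,
            y=None if self.y is None else self.y[idx],
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "county_id": [c for c, _ in self.rows],
            "year": [t for _, t in self.rows],
        }
        if self.y is not None:
            data["yield"] = self.y
        frame = pd.DataFrame(data)
        for j, name in enumerate(self.catalogue.names):
            frame[name] = self.X[:, j]
        return frame


def load_panel(path) -> SamplePanel:
    """Read a panel CSV; the catalogue is inferred from header prefixes.

    Raises structured errors for duplicate (county, year) pairs, unknown
    column prefixes, non-numeric cells, and empty files.
    """
    try:
        frame = pd.read_csv(path, dtype={"county_id": str},
                            float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise PanelSchemaError(f"{path}: no data rows") from None
    if frame.empty:
        raise PanelSchemaError(f"{path}: no data rows")
    for required in ("county_id", "year"):
        if required not in frame.columns:
            raise PanelSchemaError(f"{path}: missing required column {required!r}")
    var_columns = [c for c in frame.columns if c not in RESERVED_COLUMNS]
    catalogue = VariableCatalogue.from_columns(var_columns)

    numeric_cols = var_columns + (["yield"] if "yield" in frame.columns else [])
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelSchemaError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise PanelSchemaError(f"{path}: missing value at row {row}, column {col!r}")
        frame[col] = coerced

    rows = list(zip(frame["county_id"].astype(str), frame["year"].astype(int)))
    X = frame[var_columns].to_numpy(dtype=float) if var_columns else np.empty((len(rows), 0))
    y = frame["yield"].to_numpy(dtype=float) if "yield" in frame.columns else None
    return SamplePanel(rows=rows, X=X, catalogue=catalogue, y=y)


def write_panel(panel: SamplePanel, path) -> None:
    """Write the panel back to the CSV convention (round-trips load_panel)."""
    panel.to_frame().to_csv(path, index=False)


def panel_csv_bytes(panel: SamplePanel) -> bytes:
    """Serialize the panel CSV to bytes (used for determinism checks)."""
    buf = io.StringIO()
    write_panel(panel, buf)
    return buf.getvalue().encode()


def aggregate_to_county(grid_values: Sequence[float], category: str) -> float:
    """Aggregate sub-county grid-cell values to one county value.

    Soil uses the arithmetic mean; weather uses the median (robust to single
    bad cells).  Management variables are reported at county level already,
    so aggregation is refused.
    """
    values = np.asarray(grid_values, dtype=float)
    if values.size == 0:
        raise PanelSchemaError(f"cannot aggregate empty grid for category {category!r}")
    if not np.all(np.isfinite(values)):
        raise PanelSchemaError("grid values contain NaN/inf")
    if category == "soil":
        return float(np.mean(values))
    if category == "weather":
        return float(np.median(values))
    if category == "management":
        raise PanelSchemaError("management variables are already county-level")
    raise PanelSchemaError(f"unknown category {category!r}")


# --- derived agronomic features -------------------------------------------------

def daily_gdd(tmax: float, tmin: float, base: float = 10.0, cap: float = 30.0) -> float:
    """Growing-degree-day contribution of one day.

    Uses the capped-average convention: Tmax is capped at ``cap`` and Tmin
    floored at ``base`` before averaging, then ``base`` is subtracted and the
    result floored at zero.  Defaults are the corn conventions (10/30 °C).
    """
    return max(0.0, (min(tmax, cap) + max(tmin, base)) / 2.0 - base)


def count_rainy_days(daily_prcp: Sequence[float], threshold: float = 1.0) -> int:
    """Number of days with precipitation strictly above ``threshold`` mm."""
    return int(np.sum(np.asarray(daily_prcp, dtype=float) > threshold))


def count_heat_days(daily_tmax: Sequence[float], threshold: float = 30.0) -> int:
    """Number of days with maximum temperature strictly above ``threshold`` °C."""
    return int(np.sum(np.asarray(daily_tmax, dtype=float) > threshold))


@dataclass
class FeatureRecipes:
    """Which derived features to append, and their thresholds.

    The weekly panel stores weekly summaries, so weekly GDD is 7 × the daily
    formula applied to the week's Tmax/Tmin, and rainy-day / heat-unit counts
    per week are the indicator approximation 7·1[weekly value > threshold].
    Exact daily-resolution counters are available as module functions when
    daily data exist upstream of the panel.
    """

    gdd: bool = False
    gdd_base: float = 10.0
    gdd_cap: float = 30.0
    rainy_days: bool = False
    rain_threshold_mm: float = 1.0
    heat_units: bool = False
    heat_threshold_c: float = 30.0
    yield_trend: bool = False
    tmax_stem: str = "W_tmax"
    tmin_stem: str = "W_tmin"
    prcp_stem: str = "W_prcp"


def _weekly_columns(catalogue: VariableCatalogue, stem: str) -> dict[int, str]:
    out = {}
    for v in catalogue:
        if v.week_index is not None and v.name == f"{stem}_wk{v.week_index}":
            out[v.week_index] = v.name
    return out


def fit_yield_trend(history_years: Sequence[int], history_yields: Sequence[float],
                    at_year: int) -> float:
    """Least-squares line of yield vs year over prior years, evaluated at ``at_year``."""
    t = np.asarray(history_years, dtype=float)
    z = np.asarray(history_yields, dtype=float)
    slope, intercept = np.polyfit(t, z, 1)
    return float(slope * at_year + intercept)


def derive_features(
    panel: SamplePanel,
    recipes: FeatureRecipes,
    history: pd.DataFrame | None = None,
) -> SamplePanel:
    """Append derived feature columns; existing columns are untouched.

    ``history`` (county_id, year, yield) feeds the per-county yield-trend
    covariate: a least-squares line of historical yield against year, fit on
    years strictly before each row's year (so test years never leak into
    their own trend) and evaluated at the row's year.
    """
    new_vars: list[Variable] = []
    new_cols: list[np.ndarray] = []

    tmax = _weekly_columns(panel.catalogue, recipes.tmax_stem)
    tmin = _weekly_columns(panel.catalogue, recipes.tmin_stem)
    prcp = _weekly_columns(panel.catalogue, recipes.prcp_stem)

    if recipes.gdd:
        for wk in sorted(set(tmax) & set(tmin)):
            tx, tn = panel.column(tmax[wk]), panel.column(tmin[wk])
            daily = np.maximum(
                0.0,
                (np.minimum(tx, recipes.gdd_cap) + np.maximum(tn, recipes.gdd_base)) / 2.0
                - recipes.gdd_base,
            )
            new_vars.append(Variable(f"W_gdd_wk{wk}", "weather", week_index=wk))
            new_cols.append(7.0 * daily)

    if recipes.rainy_days:
        for wk in sorted(prcp):
            new_vars.append(Variable(f"W_rainydays_wk{wk}", "weather", week_index=wk))
            new_cols.append(7.0 * (panel.column(prcp[wk]) > recipes.rain_threshold_mm))

    if recipes.heat_units:
        for wk in sorted(tmax):
            new_vars.append(Variable(f"W_heatunits_wk{wk}", "weather", week_index=wk))
            new_cols.append(7.0 * (panel.column(tmax[wk]) > recipes.heat_threshold_c))

    if recipes.yield_trend:
        if history is None:
            raise PanelSchemaError("yield_trend recipe requires a yield history table")
        hist = history.sort_values("year")
        by_county = {c: g for c, g in hist.groupby("county_id")}
        trend = np.empty(panel.n)
        for i, (county, year) in enumerate(panel.rows):
            g = by_county.get(county)
            if g is not None:
                prior = g[g["year"] < year]
            else:
                prior = None
            if prior is None or len(prior) < 2:
                raise PanelSchemaError(
                    f"yield trend for county {county!r} needs >=2 years before {year}"
                )
            trend[i] = fit_yield_trend(
                prior["year"].to_numpy(), prior["yield"].to_numpy(), year
            )
        new_vars.append(Variable("M_yield_trend", "management"))
        new_cols.append(trend)

    if not new_vars:
        return panel
    catalogue = VariableCatalogue(list(panel.catalogue.entries) + new_vars)
    X = np.column_stack([panel.X] + new_cols) if panel.p else np.column_stack(new_cols)
    return SamplePanel(rows=list(panel.rows), X=X, catalogue=catalogue,
                       y=None if panel.y is None else panel.y.copy())


# --- normalization --------------------------------------------------------------

@dataclass
class Scaler:
    """Per-variable min-max scaler learned from designated fit rows.

    Maps x → (x − min)/(max − min); constant variables map to 0 everywhere
    (kept so catalogue indices stay stable; selection never picks them).
    Rows outside the fit set may map outside [0, 1] — no clipping.
    """

    names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise PanelSchemaError("scaler has max < min for some variable")
        self._idx = {n: i for i, n in enumerate(self.names)}

    def _params(self, name: str) -> tuple[float, float]:
        try:
            i = self._idx[name]
        except KeyError:
            raise UnknownVariableError(f"scaler has no variable {name!r}") from None
        return float(self.mins[i]), float(self.maxs[i])

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self._params(name)
        span = hi - lo
        if span == 0.0:
            return np.zeros_like(np.asarray(values, dtype=float))
        return (np.asarray(values, dtype=float) - lo) / span

    def inverse_column(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self._params(name)
        return np.asarray(values, dtype=float) * (hi - lo) + lo

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scaler":
        return cls(names=list(d["names"]), mins=np.array(d["mins"]), maxs=np.array(d["maxs"]))


def fit_scaler(panel: SamplePanel, fit_rows: Sequence[int] | None = None) -> Scaler:
    """Learn per-variable min/max from ``fit_rows`` (default: all rows)."""
    idx = np.arange(panel.n) if fit_rows is None else np.asarray(fit_rows, dtype=int)
    if idx.size == 0:
        raise PanelSchemaError("fit_rows must be nonempty")
    sub = panel.X[idx]
    return Scaler(
        names=panel.catalogue.names,
        mins=sub.min(axis=0) if panel.p else np.empty(0),
        maxs=sub.max(axis=0) if panel.p else np.empty(0),
    )


def apply_scaler(panel: SamplePanel, scaler: Scaler) -> SamplePanel:
    """Return a normalized copy of the panel (X mapped through the scaler)."""
    if scaler.names != panel.catalogue.names:
        missing = [n for n in panel.catalogue.names if n not in scaler._idx]
        if missing:
            raise UnknownVariableError(f"scaler missing variables: {missing[:5]}")
    X = np.empty_like(panel.X)
    for j, name in enumerate(panel.catalogue.names):
        X[:, j] = scaler.transform_column(name, panel.X[:, j])
    return SamplePanel(rows=list(panel.rows), X=X, catalogue=panel.catalogue,
                       y=None if panel.y is None else panel.y.copy(), normalized=True)


# --- fold schemes ---------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    train_rows: tuple[int, ...]
    validation_rows: tuple[int, ...]
    axis: str  # "temporal" | "spatial"
    label: str = ""


@dataclass
class FoldScheme:
    """Blocked train/validation splits used by the robustness score."""

    folds: list[Fold]

    def validate(self, panel: SamplePanel) -> None:
        years = panel.years
        counties = panel.counties
        for f in self.folds:
            train, val = set(f.train_rows), set(f.validation_rows)
            if not val:
                raise FoldError(f"fold {f.label!r}: empty validation set")
            if train & val:
                raise FoldError(f"fold {f.label!r}: train/validation overlap")
            if f.axis == "temporal":
                if train and years[list(train)].max() >= years[list(val)].min():
                    raise FoldError(
                        f"fold {f.label!r}: training years do not strictly "
                        "precede validation years"
                    )
            elif f.axis == "spatial":
                if set(counties[list(train)]) & set(counties[list(val)]):
                    raise FoldError(f"fold {f.label!r}: county appears on both sides")
            else:
                raise FoldError(f"fold {f.label!r}: unknown axis {f.axis!r}")

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "axis": f.axis,
                    "label": f.label,
                    "train_row_ids": [int(i) for i in f.train_rows],
                    "validation_row_ids": [int(i) for i in f.validation_rows],
                }
                for f in self.folds
            ],
            indent=2,
        )

    @property
    def axes(self) -> list[str]:
        return [f.axis for f in self.folds]


def _year_blocks(years: np.ndarray, n_blocks: int) -> list[np.ndarray]:
    distinct = np.unique(years)
    if n_blocks > len(distinct):
        raise FoldError(
            f"requested {n_blocks} year blocks but only {len(distinct)} distinct years"
        )
    return [np.asarray(b) for b in np.array_split(distinct, n_blocks)]


def temporal_block_folds(panel: SamplePanel, n_blocks: int) -> FoldScheme:
    """Contiguous year blocks; each fold validates one block and trains on all
    strictly earlier years.  The earliest block has no earlier years and is
    used only for training, so n_blocks blocks yield n_blocks−1 folds."""
    years = panel.years
    if len(np.unique(years)) < 2:
        raise FoldError("temporal folds need >=2 distinct years")
    blocks = _year_blocks(years, n_blocks)
    folds = []
    for i in range(1, len(blocks)):
        cutoff = blocks[i].min()
        train = tuple(np.flatnonzero(years < cutoff))
        val = tuple(np.flatnonzero(np.isin(years, blocks[i])))
        folds.append(
            Fold(train, val, axis="temporal",
                 label=f"years<{cutoff}|{blocks[i].min()}-{blocks[i].max()}")
        )
    return FoldScheme(folds)


def leave_year_block_out_folds(panel: SamplePanel) -> FoldScheme:
    """One fold per year except the earliest: train on all earlier years."""
    return temporal_block_folds(panel, n_blocks=len(np.unique(panel.years)))


def spatial_holdout_folds(
    panel: SamplePanel,
    groups: Mapping[str, str],
    holdout: str | None = None,
) -> FoldScheme:
    """Leave-one-group-out over county group labels (e.g. states).

    With ``holdout`` given, a single fold validating that group; otherwise one
    fold per distinct group.
    """
    labels = np.array([groups.get(c) for c in panel.counties], dtype=object)
    if any(l is None for l in labels):
        missing = sorted({c for c, l in zip(panel.counties, labels) if l is None})
        raise FoldError(f"counties without a group label: {missing[:5]}")
    distinct = sorted(set(labels))
    if holdout is not None:
        if holdout not in distinct:
            raise FoldError(f"holdout group {holdout!r} not present")
        distinct = [holdout]
    elif len(distinct) < 2:
        raise FoldError("spatial folds need >=2 groups")
    folds = []
    for g in distinct:
        val = tuple(np.flatnonzero(labels == g))
        train = tuple(np.flatnonzero(labels != g))
        folds.append(Fold(train, val, axis="spatial", label=str(g)))
    return FoldScheme(folds)


def make_folds(panel: SamplePanel, scheme: str, **params) -> FoldScheme:
    """Build a FoldScheme: ``temporal_blocks`` (n_blocks), ``leave_year_block_out``,
    or ``spatial_holdout`` (groups, optional holdout)."""
    if scheme == "temporal_blocks":
        out = temporal_block_folds(panel, n_blocks=int(params["n_blocks"]))
    elif scheme == "leave_year_block_out":
        out = leave_year_block_out_folds(panel)
    elif scheme == "spatial_holdout":
        out = spatial_holdout_folds(panel, params["groups"], params.get("holdout"))
    else:
        raise FoldError(f"unknown fold scheme {scheme!r}")
    out.validate(panel)
    return out


def combine_folds(*schemes: FoldScheme) -> FoldScheme:
    """Pool folds from several schemes (e.g. temporal + spatial axes)."""
    return FoldScheme([f for s in schemes for f in s.folds])
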