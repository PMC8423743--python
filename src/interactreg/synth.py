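"""Synthetic county-year panel generator with planted ground truth.

Emulates the statistical structure the method assumes — weekly weather as an
AR(1) process around a seasonal mean, static per-county soil profiles,
logistic planting/harvest progress curves, a per-county yield-trend
covariate — and composes yields from known additive effects, planted kernel
interactions and Gaussian noise.  The ground truth (coefficients, interaction
list, noise level) is returned alongside the panel so selection and fitting
can be scored for recovery.

What it does not emulate: spatial correlation between counties, weather
persistence across years, heteroscedastic yield noise, and any real crop
physiology — passing recovery tests shows the search finds planted structure
under the model's own assumptions, not that it finds true agronomy in real
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InteractRegError
from .kernels import InteractionTerm, KernelRegistry, default_registry
from .panel import SamplePanel, Variable, VariableCatalogue, apply_scaler, fit_scaler

WEATHER_STEMS = ("tmax", "tmin", "prcp", "srad")


@dataclass
class WeatherProcess:
    """AR(1) around a seasonal sinusoid, one independent process per stem."""

    mean: float
    seasonal_amplitude: float
    peak_week: float
    rho: float
    sd: float
    nonnegative: bool = False


def default_weather_processes() -> dict[str, WeatherProcess]:
    return {
        "tmax": WeatherProcess(mean=24.0, seasonal_amplitude=8.0, peak_week=28.0,
                               rho=0.5, sd=2.5),
        "tmin": WeatherProcess(mean=12.0, seasonal_amplitude=7.0, peak_week=28.0,
                               rho=0.5, sd=2.2),
        "prcp": WeatherProcess(mean=22.0, seasonal_amplitude=6.0, peak_week=24.0,
                               rho=0.3, sd=12.0, nonnegative=True),
        "srad": WeatherProcess(mean=18.0, seasonal_amplitude=6.0, peak_week=26.0,
                               rho=0.4, sd=3.0),
    }


@dataclass
class SynthConfig:
    """Generation conditions for one synthetic panel.

    Defaults are the reference scenario used throughout the test suite:
    50 counties × 20 years (n = 1000), 40 weekly weather variables (four
    stems over weeks 20–29), 10 static soil variables (five properties at
    two depths), 5 management variables, two planted product interactions
    whose effect sizes are at least three yield-noise standard deviations.
    """

    n_counties: int = 50
    year_start: int = 1998
    year_end: int = 2017
    weather_weeks: tuple[int, int] = (20, 29)
    weather: dict = field(default_factory=default_weather_processes)
    soil_properties: tuple[str, ...] = ("om", "clay", "sand", "ph", "bddry")
    soil_depths: tuple[str, ...] = ("5", "30")
    progress_weeks: tuple[int, ...] = (20, 22)
    harvest_week: int = 44
    beta0: float = 6.0
    true_effects: dict = field(default_factory=lambda: {
        "W_tmax_wk24": -1.2,
        "W_prcp_wk22": 1.0,
        "W_srad_wk25": 0.8,
        "S_om_d5": 2.0,
        "M_planted_wk20": 0.6,
        "M_yield_trend": 3.0,
    })
    # Product-kernel interactions whose per-county contributions span a few
    # t/ha, the magnitude county-level E×M interaction effects reach; far
    # above the |b|/noise_sd >= 3 identifiability floor.
    true_interactions: list = field(default_factory=lambda: [
        ("W_prcp_wk24", "W_tmax_wk26", "product", 10.0),
        ("W_srad_wk27", "M_planted_wk22", "product", -8.0),
    ])
    noise_sd: float = 0.45
    county_trend_sd: float = 0.0   # per-county extra linear drift (t/ha per year)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.county_trend_sd < 0:
            raise InteractRegError("standard deviations must be >= 0")
        if self.year_end < self.year_start:
            raise InteractRegError("year_end before year_start")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to recompute noiseless yields and score recovery."""

    beta0: float
    effects: dict[str, float]          # additive effects on the normalized scale
    interactions: list[tuple[InteractionTerm, float]]
    noise_sd: float
    county_trends: dict[str, float]    # county -> extra slope (t/ha per year)
    trend_origin_year: int
    seed: int

    @property
    def terms(self) -> list[InteractionTerm]:
        return [t for t, _ in self.interactions]

    def noiseless_yield(self, panel: SamplePanel,
                        registry: KernelRegistry | None = None) -> np.ndarray:
        """Recompute the deterministic part of the yield from the panel."""
        registry = registry or default_registry()
        norm = apply_scaler(panel, fit_scaler(panel))
        y = np.full(panel.n, self.beta0)
        for name, beta in self.effects.items():
            y += beta * norm.column(name)
        for term, b in self.interactions:
            k = registry.get(term.kernel_id)
            y += b * k.func(norm.column(term.var_a), norm.column(term.var_b))
        years = panel.years
        for i, (county, _) in enumerate(panel.rows):
            y[i] += self.county_trends.get(county, 0.0) * (
                years[i] - self.trend_origin_year
            )
        return y

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta0": self.beta0,
                "effects": self.effects,
                "interactions": [
                    {**t.to_dict(), "coefficient": b} for t, b in self.interactions
                ],
                "noise_sd": self.noise_sd,
                "county_trends": self.county_trends,
                "trend_origin_year": self.trend_origin_year,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGroundTruth":
        d = json.loads(text)
        return cls(
            beta0=d["beta0"],
            effects=dict(d["effects"]),
            interactions=[
                (InteractionTerm.from_dict(t), t["coefficient"])
                for t in d["interactions"]
            ],
            noise_sd=d["noise_sd"],
            county_trends=dict(d["county_trends"]),
            trend_origin_year=d["trend_origin_year"],
            seed=d["seed"],
        )


def _build_catalogue(config: SynthConfig) -> VariableCatalogue:
    entries: list[Variable] = []
    w0, w1 = config.weather_weeks
    for stem in WEATHER_STEMS:
        for wk in range(w0, w1 + 1):
            entries.append(Variable(f"W_{stem}_wk{wk}", "weather", week_index=wk))
    for prop in config.soil_properties:
        for d in config.soil_depths:
            entries.append(Variable(f"S_{prop}_d{d}", "soil", depth_label=d))
    for wk in config.progress_weeks:
        entries.append(Variable(f"M_planted_wk{wk}", "management", week_index=wk))
    entries.append(Variable(f"M_harvested_wk{config.harvest_week}", "management",
                            week_index=config.harvest_week))
    entries.append(Variable("M_acres", "management"))
    entries.append(Variable("M_yield_trend", "management"))
    return VariableCatalogue(entries)


_SOIL_BASE = {"om": 3.0, "clay": 25.0, "sand": 35.0, "ph": 6.5, "bddry": 1.35}
_SOIL_SD = {"om": 0.8, "clay": 6.0, "sand": 9.0, "ph": 0.4, "bddry": 0.12}


def generate_panel(config: SynthConfig | None = None,
                   registry: KernelRegistry | None = None
                   ) -> tuple[SamplePanel, SyntheticGroundTruth]:
    """Draw one panel and its ground truth; fully reproducible from the seed.

    yield_i = β₀ + Σ β_j X̃_ij + Σ b_m K_m(X̃_i) + trend_c·(year − year₀) + ε,
    with X̃ the min-max normalization of the generated panel and
    ε ~ N(0, noise_sd²).
    """
    config = config or SynthConfig()
    registry = registry or default_registry()
    catalogue = _build_catalogue(config)
    for name in config.true_effects:
        if name not in catalogue:
            raise InteractRegError(f"true effect references unknown variable {name!r}")
    terms: list[tuple[InteractionTerm, float]] = []
    for var_a, var_b, kernel_id, b in config.true_interactions:
        term = InteractionTerm(var_a, var_b, kernel_id)
        term.validate(catalogue, registry)
        terms.append((term.canonical(catalogue, registry), float(b)))

    rng = np.random.default_rng(config.seed)
    counties = [f"county{c:03d}" for c in range(config.n_counties)]
    years = list(range(config.year_start, config.year_end + 1))
    rows = [(c, t) for c in counties for t in years]
    n = len(rows)
    w0, w1 = config.weather_weeks
    weeks = np.arange(w0, w1 + 1)

    X = np.empty((n, len(catalogue)))
    col = {name: j for j, name in enumerate(catalogue.names)}

    # soil: static per county
    soil_values = {
        c: {
            f"S_{prop}_d{d}": _SOIL_BASE[prop]
            + rng.normal(0.0, _SOIL_SD[prop])
            + 0.1 * _SOIL_SD[prop] * rng.normal()   # depth-layer wobble
            for prop in config.soil_properties
            for d in config.soil_depths
        }
        for c in counties
    }
    acres = {c: float(rng.lognormal(mean=11.0, sigma=0.35)) for c in counties}
    trend_base = {c: float(rng.normal(9.0, 0.5)) for c in counties}
    trend_slope = {c: float(rng.normal(0.08, 0.02)) for c in counties}
    county_trends = {
        c: float(rng.normal(0.0, config.county_trend_sd)) if config.county_trend_sd
        else 0.0
        for c in counties
    }

    for i, (c, t) in enumerate(rows):
        # weekly weather: independent AR(1) per stem
        for stem in WEATHER_STEMS:
            proc: WeatherProcess = config.weather[stem]
            seasonal = proc.mean + proc.seasonal_amplitude * np.cos(
                2.0 * np.pi * (weeks - proc.peak_week) / 52.0
            )
            e = np.empty(len(weeks))
            e[0] = rng.normal(0.0, proc.sd)
            innov_sd = proc.sd * np.sqrt(max(0.0, 1.0 - proc.rho**2))
            for k in range(1, len(weeks)):
                e[k] = proc.rho * e[k - 1] + rng.normal(0.0, innov_sd)
            series = seasonal + e
            if proc.nonnegative:
                series = np.maximum(series, 0.0)
            for wk, val in zip(weeks, series):
                X[i, col[f"W_{stem}_wk{wk}"]] = val
        for name, val in soil_values[c].items():
            X[i, col[name]] = val
        # management: logistic cumulative progress, acreage, trend covariate
        plant_mid = rng.normal(21.0, 1.2)
        for wk in config.progress_weeks:
            X[i, col[f"M_planted_wk{wk}"]] = 100.0 / (
                1.0 + np.exp(-(wk - plant_mid) / 0.8)
            )
        harvest_mid = rng.normal(43.0, 1.0)
        X[i, col[f"M_harvested_wk{config.harvest_week}"]] = 100.0 / (
            1.0 + np.exp(-(config.harvest_week - harvest_mid) / 1.2)
        )
        X[i, col["M_acres"]] = acres[c] * float(rng.normal(1.0, 0.03))
        X[i, col["M_yield_trend"]] = trend_base[c] + trend_slope[c] * (
            t - config.year_start
        )

    panel = SamplePanel(rows=rows, X=X, catalogue=catalogue)
    truth = SyntheticGroundTruth(
        beta0=config.beta0,
        effects={k: float(v) for k, v in config.true_effects.items()},
        interactions=terms,
        noise_sd=config.noise_sd,
        county_trends=county_trends,
        trend_origin_year=config.year_start,
        seed=config.seed,
    )
    y = truth.noiseless_yield(panel, registry)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=n)
    panel.y = np.asarray(y, dtype=float)
    return panel, truth


@dataclass
class RecoveryScore:
    recall: float
    false_discovery_rate: float
    coefficient_rmse: float | None = None


def _canonical_key(term: InteractionTerm, registry: KernelRegistry):
    if registry.get(term.kernel_id).symmetric:
        return (frozenset((term.var_a, term.var_b)), term.kernel_id)
    return (term.var_a, term.var_b, term.kernel_id)


def score_recovery(
    truth: SyntheticGroundTruth,
    result,
    model=None,
    registry: KernelRegistry | None = None,
) -> RecoveryScore:
    """Recall / false-discovery of the selected interaction set against the
    planted one (pair + kernel, unordered for symmetric kernels); coefficient
    RMSE on matched terms when a fitted model is supplied."""
    registry = registry or default_registry()
    true_keys = {_canonical_key(t, registry): b for t, b in truth.interactions}
    found = list(getattr(result, "terms", result))
    found_keys = {_canonical_key(t, registry) for t in found}
    hits = found_keys & set(true_keys)
    recall = len(hits) / len(true_keys) if true_keys else (1.0 if not found_keys else 0.0)
    fdr = (len(found_keys - set(true_keys)) / len(found_keys)) if found_keys else 0.0

    coef_rmse = None
    if model is not None and hits:
        fitted = {
            _canonical_key(t, registry): b for t, b in model.interaction_coefficients
        }
        errs = [fitted[k] - true_keys[k] for k in hits if k in fitted]
        if errs:
            coef_rmse = float(np.sqrt(np.mean(np.square(errs))))
    return RecoveryScore(recall=float(recall), false_discovery_rate=float(fdr),
                         coefficient_rmse=coef_rmse)


def reference_config(seed: int = 0) -> SynthConfig:
    """The shipped reference scenario (defaults) with a chosen seed."""
    return SynthConfig(seed=seed)
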