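"""The interaction regression model: final OLS fit, prediction, metrics,
yield dissection, and partial dependence.

Prediction is the linear form

    ŷ_i = β₀ + Σ_j β_j X̃_{ij} + Σ_m b_m Z_{im}

where X̃ are the selected features on the normalized scale and Z the
kernel-encoded interaction columns.  Because the form is linear, each
prediction decomposes exactly into weather, soil, management and interaction
contributions plus the intercept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, InteractRegError, UnknownVariableError
from .kernels import (
    InteractionTerm,
    KernelRegistry,
    build_interaction_matrix,
    default_registry,
)
from .panel import SamplePanel, Scaler, apply_scaler, fit_scaler

METRIC_NAMES = ("RMSE", "RRMSE", "RSE", "MAE", "RAE", "R2")


def evaluate(observed, predicted, metrics: Sequence[str] = METRIC_NAMES) -> dict[str, float]:
    """Prediction-error metrics.

    RMSE = √(Σe²/n); RRMSE = 100·RMSE/mean(observed) (percent of mean
    observed yield); RSE = Σe²/Σ(y−ȳ)²; MAE = Σ|e|/n; RAE = Σ|e|/Σ|y−ȳ|;
    R² = 1 − RSE.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise InteractRegError("observed and predicted must be 1-d of equal length")
    if y.size == 0:
        raise InteractRegError("cannot evaluate on zero samples")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise InteractRegError(f"unknown metrics: {sorted(unknown)}")
    e = y - yhat
    out: dict[str, float] = {}
    sq_dev = float(np.sum((y - y.mean()) ** 2))
    abs_dev = float(np.sum(np.abs(y - y.mean())))
    for m in metrics:
        if m == "RMSE":
            out[m] = float(np.sqrt(np.mean(e**2)))
        elif m == "RRMSE":
            if y.mean() == 0:
                raise InteractRegError("RRMSE undefined: mean(observed) is zero")
            out[m] = float(100.0 * np.sqrt(np.mean(e**2)) / y.mean())
        elif m == "MAE":
            out[m] = float(np.mean(np.abs(e)))
        elif m in ("RSE", "R2"):
            if sq_dev == 0:
                raise InteractRegError(f"{m} undefined: observed has zero variance")
            rse = float(np.sum(e**2) / sq_dev)
            out[m] = rse if m == "RSE" else 1.0 - rse
        elif m == "RAE":
            if abs_dev == 0:
                raise InteractRegError("RAE undefined: observed has zero variance")
            out[m] = float(np.sum(np.abs(e)) / abs_dev)
    return out


@dataclass
class FittedModel:
    """Fitted interaction regression: coefficients keyed by name/term, with the
    training scaler and catalogue hash embedded so prediction refuses panels
    with a mismatched schema."""

    intercept: float
    coefficients: dict[str, float]           # additive effects, by feature name
    interaction_coefficients: list[tuple[InteractionTerm, float]]
    scaler: Scaler
    catalogue_hash: str
    feature_categories: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [self.intercept, *self.coefficients.values()]
        values += [b for _, b in self.interaction_coefficients]
        if not np.all(np.isfinite(values)):
            raise FitError("non-finite coefficient in fitted model")

    @property
    def features(self) -> list[str]:
        return list(self.coefficients)

    @property
    def terms(self) -> list[InteractionTerm]:
        return [t for t, _ in self.interaction_coefficients]

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "interactions": [
                    {**t.to_dict(), "coefficient": b}
                    for t, b in self.interaction_coefficients
                ],
                "scaler": self.scaler.to_dict(),
                "catalogue_hash": self.catalogue_hash,
                "feature_categories": self.feature_categories,
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            interaction_coefficients=[
                (InteractionTerm.from_dict(t), t["coefficient"])
                for t in d["interactions"]
            ],
            scaler=Scaler.from_dict(d["scaler"]),
            catalogue_hash=d["catalogue_hash"],
            feature_categories=dict(d["feature_categories"]),
            metadata=d.get("metadata", {}),
        )


def design_matrix(
    panel_norm: SamplePanel,
    features: Sequence[str],
    terms: Sequence[InteractionTerm],
    registry: KernelRegistry,
) -> np.ndarray:
    """[1 | X_selected | Z] on an already-normalized panel."""
    cols = [np.ones(panel_norm.n)]
    cols += [panel_norm.column(f) for f in features]
    if terms:
        cols.append(build_interaction_matrix(panel_norm, list(terms), registry).Z)
    return np.column_stack(cols)


def ols_minimum_norm(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Least-squares fit returning (coefficients, rank); minimum-norm on
    rank-deficient designs, with a warning."""
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"design matrix rank {rank} < {A.shape[1]} columns; "
            "minimum-norm solution used (collinear features/terms)",
            stacklevel=2,
        )
    return coef, rank


def fit_model(
    panel: SamplePanel,
    features: Sequence[str],
    terms: Sequence[InteractionTerm] = (),
    registry: KernelRegistry | None = None,
    scaler: Scaler | None = None,
    metadata: Mapping | None = None,
) -> FittedModel:
    """Ordinary-least-squares fit of the interaction regression.

    The panel is raw (unnormalized); the scaler defaults to min-max fit on
    the panel's own rows and is embedded in the returned model.
    """
    if panel.y is None:
        raise FitError("panel has no yield column to fit against")
    registry = registry or default_registry()
    if panel.normalized:
        if scaler is None:
            raise FitError("normalized panel supplied without its scaler")
        panel_norm = panel
    else:
        scaler = scaler or fit_scaler(panel)
        panel_norm = apply_scaler(panel, scaler)
    features = list(features)
    terms = [t for t in terms]
    for t in terms:
        t.validate(panel.catalogue, registry)
    A = design_matrix(panel_norm, features, terms, registry)
    if panel.n <= A.shape[1]:
        raise FitError(
            f"{panel.n} samples cannot identify {A.shape[1]} coefficients"
        )
    coef, _ = ols_minimum_norm(A, panel.y)
    n_feat = len(features)
    meta = dict(metadata or {})
    meta.setdefault("n_train", panel.n)
    meta.setdefault("train_years", [int(panel.years.min()), int(panel.years.max())])
    return FittedModel(
        intercept=float(coef[0]),
        coefficients={f: float(c) for f, c in zip(features, coef[1 : 1 + n_feat])},
        interaction_coefficients=list(zip(terms, map(float, coef[1 + n_feat :]))),
        scaler=scaler,
        catalogue_hash=panel.catalogue.content_hash(),
        feature_categories={f: panel.catalogue.category_of(f) for f in features},
        metadata=meta,
    )


def _normalized_columns(model: FittedModel, panel: SamplePanel) -> dict[str, np.ndarray]:
    """Normalized columns for every variable the model touches, by name."""
    needed = set(model.features)
    for t in model.terms:
        needed.update((t.var_a, t.var_b))
    missing = sorted(n for n in needed if n not in panel.catalogue)
    if missing:
        raise UnknownVariableError(f"panel is missing model variables: {missing}")
    if panel.normalized:
        return {n: panel.column(n) for n in needed}
    return {n: model.scaler.transform_column(n, panel.column(n)) for n in needed}


def predict(
    model: FittedModel,
    panel: SamplePanel,
    registry: KernelRegistry | None = None,
) -> np.ndarray:
    """ŷ = β₀ + Σβ_j X̃_j + Σ b_m Z_m, scaler applied first."""
    registry = registry or default_registry()
    cols = _normalized_columns(model, panel)
    yhat = np.full(panel.n, model.intercept)
    for f, beta in model.coefficients.items():
        yhat += beta * cols[f]
    for term, b in model.interaction_coefficients:
        k = registry.get(term.kernel_id)
        yhat += b * k.func(cols[term.var_a], cols[term.var_b])
    return yhat


@dataclass
class ContributionBreakdown:
    """Per-sample additive contributions; components + intercept sum to ŷ."""

    frame: pd.DataFrame  # county_id, year, intercept, weather, soil, management, interaction, total

    def conservation_gap(self) -> float:
        parts = self.frame[
            ["intercept", "weather", "soil", "management", "interaction"]
        ].sum(axis=1)
        return float(np.max(np.abs(parts - self.frame["total"])))


def decompose_contributions(
    model: FittedModel,
    panel: SamplePanel,
    registry: KernelRegistry | None = None,
) -> ContributionBreakdown:
    """Dissect each predicted yield into weather, soil, management and
    interaction contributions plus the intercept."""
    registry = registry or default_registry()
    cols = _normalized_columns(model, panel)
    parts = {c: np.zeros(panel.n) for c in ("weather", "soil", "management")}
    for f, beta in model.coefficients.items():
        parts[model.feature_categories[f]] += beta * cols[f]
    interaction = np.zeros(panel.n)
    for term, b in model.interaction_coefficients:
        k = registry.get(term.kernel_id)
        interaction += b * k.func(cols[term.var_a], cols[term.var_b])
    total = model.intercept + parts["weather"] + parts["soil"] + parts["management"] + interaction
    frame = pd.DataFrame(
        {
            "county_id": [c for c, _ in panel.rows],
            "year": [t for _, t in panel.rows],
            "intercept": model.intercept,
            "weather": parts["weather"],
            "soil": parts["soil"],
            "management": parts["management"],
            "interaction": interaction,
            "total": total,
        }
    )
    return ContributionBreakdown(frame=frame)


def partial_dependence(
    model: FittedModel,
    panel: SamplePanel,
    variables: Sequence[str],
    grid: Sequence[float] | Mapping[str, Sequence[float]],
    registry: KernelRegistry | None = None,
) -> pd.DataFrame:
    """Marginal effect of one or two variables on the predicted yield.

    PD(v) = mean over panel rows of the prediction with the variable(s)
    clamped to each grid point.  Grids are on the normalized [0,1] scale; the
    output also carries the back-transformed original units.
    """
    registry = registry or default_registry()
    variables = list(variables)
    if not 1 <= len(variables) <= 2:
        raise InteractRegError("partial dependence supports one or two variables")
    for v in variables:
        if v not in panel.catalogue:
            raise UnknownVariableError(f"unknown variable {v!r}")
    if isinstance(grid, Mapping):
        grids = {v: np.asarray(grid[v], dtype=float) for v in variables}
    else:
        grids = {v: np.asarray(grid, dtype=float) for v in variables}
    for v, g in grids.items():
        if g.size == 0:
            raise InteractRegError(f"empty grid for {v!r}")

    if panel.normalized:
        raise InteractRegError("partial dependence expects a raw panel")
    panel_norm = apply_scaler(panel, model.scaler)

    def pd_at(point: dict[str, float]) -> float:
        work = SamplePanel(
            rows=list(panel_norm.rows),
            X=panel_norm.X.copy(),
            catalogue=panel_norm.catalogue,
            normalized=True,
        )
        for v, val in point.items():
            work.X[:, work.catalogue.index(v)] = val
        return float(np.mean(predict(model, work, registry)))

    records = []
    if len(variables) == 1:
        v = variables[0]
        for g in grids[v]:
            records.append(
                {
                    v: g,
                    f"{v}_orig": float(model.scaler.inverse_column(v, np.array([g]))[0]),
                    "partial_dependence": pd_at({v: float(g)}),
                }
            )
    else:
        v1, v2 = variables
        for g1 in grids[v1]:
            for g2 in grids[v2]:
                records.append(
                    {
                        v1: g1,
                        v2: g2,
                        f"{v1}_orig": float(model.scaler.inverse_column(v1, np.array([g1]))[0]),
                        f"{v2}_orig": float(model.scaler.inverse_column(v2, np.array([g2]))[0]),
                        "partial_dependence": pd_at({v1: float(g1), v2: float(g2)}),
                    }
                )
    return pd.DataFrame.from_records(records)
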