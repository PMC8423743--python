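"""Spatio-temporally robust feature and interaction selection.

The robustness score of a candidate model is its mean validation error over
blocked folds that span different year ranges (temporal axis) and different
county groups (spatial axis); a feature or interaction only survives if it
keeps predicting well across all of them.  Selection proceeds in three
stages: an elastic-net pre-screen shortlists variables within each category
(weather, soil, management); forward/backward stepwise search adds and prunes
candidates by robustness improvement; and an outer loop alternates between
screening new kernel-interaction candidates against the current model's
residuals and cross-validating them, until a full cycle changes nothing.

All tie-breaks use canonical order (catalogue index, then kernel order), so a
given panel + seed + config always yields the same result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import FitError, InteractRegError
from .kernels import (
    InteractionTerm,
    KernelRegistry,
    default_registry,
    enumerate_candidates,
)
from .model import METRIC_NAMES, evaluate, ols_minimum_norm
from .panel import FoldScheme, SamplePanel, apply_scaler, fit_scaler

Candidate = Union[str, InteractionTerm]

DEFAULT_METRIC = "RRMSE"

# Scores within this margin are ties, resolved by canonical candidate order.
# Needed because some kernels span identical model spaces once main effects
# are present (e.g. 1-(1-x)(1-y) = x + y - xy), differing only by float noise.
TIE_EPS = 1e-6


@dataclass
class RobustnessReport:
    """Per-fold validation error and its mean; lower is better."""

    per_fold: list[float]
    metric: str
    axes: list[str]

    @property
    def aggregate(self) -> float:
        return float(np.mean(self.per_fold))


@dataclass
class SelectionResult:
    """Selected features and interaction terms with the accepted-step trajectory."""

    features: list[str] = field(default_factory=list)
    terms: list[InteractionTerm] = field(default_factory=list)
    trajectory: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int | None = None
    feature_categories: dict[str, str] = field(default_factory=dict)

    def features_by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for f in self.features:
            out.setdefault(self.feature_categories.get(f, "unknown"), []).append(f)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "features_by_category": self.features_by_category(),
                "interactions": [t.to_dict() for t in self.terms],
                "trajectory": self.trajectory,
                "config": self.config,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


class _FoldWorkspace:
    """Normalized view of one fold: scaler fit on the training rows only."""

    def __init__(self, panel: SamplePanel, train_rows, val_rows, axis: str,
                 registry: KernelRegistry):
        self.train = np.asarray(train_rows, dtype=int)
        self.val = np.asarray(val_rows, dtype=int)
        self.axis = axis
        self.registry = registry
        scaler = fit_scaler(panel, self.train)
        self._norm = apply_scaler(panel, scaler)
        self.y = panel.y
        self._zcache: dict[InteractionTerm, np.ndarray] = {}

    def column(self, name: str) -> np.ndarray:
        return self._norm.column(name)

    def zcolumn(self, term: InteractionTerm) -> np.ndarray:
        z = self._zcache.get(term)
        if z is None:
            k = self.registry.get(term.kernel_id)
            z = k.func(self.column(term.var_a), self.column(term.var_b))
            self._zcache[term] = z
        return z

    def design(self, features: Sequence[str], terms: Sequence[InteractionTerm]
               ) -> np.ndarray:
        cols = [np.ones(len(self.y))]
        cols += [self.column(f) for f in features]
        cols += [self.zcolumn(t) for t in terms]
        return np.column_stack(cols)


def _make_workspaces(panel: SamplePanel, folds: FoldScheme,
                     registry: KernelRegistry) -> list[_FoldWorkspace]:
    if not folds.folds:
        raise InteractRegError("fold scheme is empty")
    if panel.y is None:
        raise FitError("panel has no yield column")
    folds.validate(panel)
    return [
        _FoldWorkspace(panel, f.train_rows, f.validation_rows, f.axis, registry)
        for f in folds.folds
    ]


def _score_workspaces(
    workspaces: list[_FoldWorkspace],
    features: Sequence[str],
    terms: Sequence[InteractionTerm],
    metric: str,
    return_details: bool = False,
):
    per_fold: list[float] = []
    details: list[dict] = []
    for ws in workspaces:
        A = ws.design(features, terms)
        n_coef = A.shape[1]
        if len(ws.train) <= n_coef:
            raise FitError(
                f"fold training set ({len(ws.train)} rows) cannot identify "
                f"{n_coef} coefficients; use fewer features/terms"
            )
        coef, _ = ols_minimum_norm(A[ws.train], ws.y[ws.train])
        pred = A[ws.val] @ coef
        per_fold.append(evaluate(ws.y[ws.val], pred, [metric])[metric])
        if return_details:
            details.append(
                {"train_rows": ws.train.copy(), "validation_rows": ws.val.copy(),
                 "coefficients": coef}
            )
    report = RobustnessReport(per_fold=per_fold, metric=metric,
                              axes=[ws.axis for ws in workspaces])
    return (report, details) if return_details else report


def robustness_score(
    features: Sequence[str],
    terms: Sequence[InteractionTerm],
    panel: SamplePanel,
    folds: FoldScheme,
    registry: KernelRegistry | None = None,
    metric: str = DEFAULT_METRIC,
    return_details: bool = False,
):
    """Mean validation error of the model over the blocked folds.

    Each fold re-fits the normalization and the OLS coefficients on its
    training rows only, then evaluates the metric on its validation rows.
    """
    if metric not in METRIC_NAMES:
        raise InteractRegError(f"unknown metric {metric!r}")
    registry = registry or default_registry()
    workspaces = _make_workspaces(panel, folds, registry)
    return _score_workspaces(workspaces, features, terms, metric,
                             return_details=return_details)


def elastic_net_prescreen(
    panel: SamplePanel,
    category: str,
    grid: dict | None = None,
    cap: int | None = None,
    cv: int = 10,
    seed: int = 0,
) -> list[str]:
    """Shortlist one category's variables by elastic net with CV-tuned penalty.

    Hyperparameters (mixing ratios × an automatic penalty path) are tuned by
    a seeded shuffled k-fold grid search; variables with nonzero coefficients
    at the optimum are returned (catalogue order), truncated to ``cap`` by
    descending |coefficient|.
    """
    if panel.y is None:
        raise FitError("prescreen requires a panel with yields")
    names = panel.catalogue.by_category(category)
    if not names:
        raise InteractRegError(f"category {category!r} has no variables")
    grid = grid or {}
    scaler = fit_scaler(panel)
    norm = apply_scaler(panel, scaler)
    X = np.column_stack([norm.column(n) for n in names])
    y = panel.y
    if np.ptp(y) == 0:
        return []
    splitter = KFold(n_splits=min(cv, panel.n), shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=list(grid.get("l1_ratio", (0.2, 0.5, 0.8))),
        alphas=int(grid.get("n_alphas", 30)),
        eps=float(grid.get("eps", 1e-3)),
        cv=splitter,
        max_iter=int(grid.get("max_iter", 5000)),
        random_state=seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # convergence chatter on tiny penalties
        enet.fit(X, y)
    coefs = enet.coef_
    nonzero = [(abs(c), i) for i, c in enumerate(coefs) if abs(c) > 1e-12]
    if cap is not None and len(nonzero) > cap:
        nonzero = sorted(nonzero, key=lambda t: (-t[0], t[1]))[:cap]
    keep = sorted(i for _, i in nonzero)
    return [names[i] for i in keep]


def _with_candidate(features: list[str], terms: list[InteractionTerm],
                    cand: Candidate) -> tuple[list[str], list[InteractionTerm]]:
    if isinstance(cand, InteractionTerm):
        return features, terms + [cand]
    return features + [cand], terms


def _without_element(features: list[str], terms: list[InteractionTerm],
                     elem: Candidate) -> tuple[list[str], list[InteractionTerm]]:
    if isinstance(elem, InteractionTerm):
        return features, [t for t in terms if t != elem]
    return [f for f in features if f != elem], terms


def _candidate_order_key(cand: Candidate, panel: SamplePanel,
                         registry: KernelRegistry):
    if isinstance(cand, InteractionTerm):
        return (1, *cand.sort_key(panel.catalogue, registry))
    return (0, panel.catalogue.index(cand), -1, -1)


def forward_stepwise(
    candidates: Iterable[Candidate],
    current: SelectionResult | None,
    panel: SamplePanel,
    folds: FoldScheme,
    registry: KernelRegistry | None = None,
    tol: float = 0.0,
    max_added: int | None = None,
    metric: str = DEFAULT_METRIC,
    _workspaces: list[_FoldWorkspace] | None = None,
) -> SelectionResult:
    """Greedy forward search: repeatedly add the candidate with the largest
    robustness improvement while the improvement is at least ``tol``.

    Candidates may be feature names or interaction terms; ties break by
    canonical candidate order.  ``max_added`` caps the number of additions.
    """
    if tol < 0:
        raise InteractRegError("tol must be >= 0")
    registry = registry or default_registry()
    ws = _workspaces or _make_workspaces(panel, folds, registry)
    result = current or SelectionResult()
    features = list(result.features)
    terms = list(result.terms)
    trajectory = list(result.trajectory)

    pool = [
        c for c in candidates
        if not (c in features if isinstance(c, str) else c in terms)
    ]
    pool.sort(key=lambda c: _candidate_order_key(c, panel, registry))

    score = _score_workspaces(ws, features, terms, metric).aggregate
    added = 0
    while pool and (max_added is None or added < max_added):
        best_cand, best_score = None, None
        for cand in pool:
            f2, t2 = _with_candidate(features, terms, cand)
            try:
                s = _score_workspaces(ws, f2, t2, metric).aggregate
            except FitError:
                continue  # too many coefficients for a fold; skip candidate
            if best_score is None or s < best_score - TIE_EPS:
                best_cand, best_score = cand, s
        if best_cand is None or score - best_score < tol or (
            tol == 0.0 and best_score >= score
        ):
            break
        features, terms = _with_candidate(features, terms, best_cand)
        pool.remove(best_cand)
        trajectory.append(
            {
                "action": "add",
                "candidate": best_cand.to_dict()
                if isinstance(best_cand, InteractionTerm) else best_cand,
                "score": best_score,
                "metric": metric,
            }
        )
        score = best_score
        added += 1
    return replace(result, features=features, terms=terms, trajectory=trajectory,
                   feature_categories={f: panel.catalogue.category_of(f)
                                       for f in features})


def backward_eliminate(
    current: SelectionResult,
    panel: SamplePanel,
    folds: FoldScheme,
    registry: KernelRegistry | None = None,
    tol: float = 0.0,
    metric: str = DEFAULT_METRIC,
    heredity: bool = True,
    _workspaces: list[_FoldWorkspace] | None = None,
) -> SelectionResult:
    """Prune the selection: repeatedly drop the element whose removal most
    improves (or least degrades, within ``tol``) the robustness score.

    With ``heredity`` (default) a feature that appears in a selected
    interaction term cannot be dropped while the term remains: keeping the
    parent main effects makes a product term's fit invariant to the affine
    rescaling each fold's normalization applies, so pruning a parent would
    silently change what the term means across folds.
    """
    if tol < 0:
        raise InteractRegError("tol must be >= 0")
    registry = registry or default_registry()
    ws = _workspaces or _make_workspaces(panel, folds, registry)
    features = list(current.features)
    terms = list(current.terms)
    trajectory = list(current.trajectory)

    score = _score_workspaces(ws, features, terms, metric).aggregate
    while features or terms:
        protected = (
            {v for t in terms for v in (t.var_a, t.var_b)} if heredity else set()
        )
        elements: list[Candidate] = [
            f for f in features if f not in protected
        ] + list(terms)
        elements.sort(key=lambda c: _candidate_order_key(c, panel, registry))
        best_elem, best_score = None, None
        for elem in elements:
            f2, t2 = _without_element(features, terms, elem)
            s = _score_workspaces(ws, f2, t2, metric).aggregate
            if best_score is None or s < best_score - TIE_EPS:
                best_elem, best_score = elem, s
        if best_elem is None or best_score > score + tol:
            break
        features, terms = _without_element(features, terms, best_elem)
        trajectory.append(
            {
                "action": "remove",
                "candidate": best_elem.to_dict()
                if isinstance(best_elem, InteractionTerm) else best_elem,
                "score": best_score,
                "metric": metric,
            }
        )
        score = min(score, best_score)
    return replace(current, features=features, terms=terms, trajectory=trajectory,
                   feature_categories={f: panel.catalogue.category_of(f)
                                       for f in features})


@dataclass
class SearchConfig:
    """Knobs of the robust-selection search.

    Tolerances are in units of the metric (RRMSE points by default); the
    caps bound the per-category elastic-net shortlist sizes.
    """

    caps: dict = field(default_factory=lambda: {"weather": 25, "soil": 10,
                                                "management": 5})
    enet_grid: dict = field(default_factory=dict)
    enet_cv: int = 10
    metric: str = DEFAULT_METRIC
    tol_forward: float = 0.15
    tol_backward: float = 0.15
    top_screen: int = 25
    max_added_per_cycle: int = 8
    max_cycles: int = 4
    allow_self: bool = True
    heredity: bool = True
    feature_stepwise: bool = True
    max_features: int | None = None
    seed: int = 0

    def echo(self) -> dict:
        return {
            "caps": dict(self.caps),
            "enet_grid": dict(self.enet_grid),
            "enet_cv": self.enet_cv,
            "metric": self.metric,
            "tol_forward": self.tol_forward,
            "tol_backward": self.tol_backward,
            "top_screen": self.top_screen,
            "max_added_per_cycle": self.max_added_per_cycle,
            "max_cycles": self.max_cycles,
            "allow_self": self.allow_self,
            "heredity": self.heredity,
            "feature_stepwise": self.feature_stepwise,
            "max_features": self.max_features,
            "seed": self.seed,
        }


def _residual_screen(
    workspaces: list[_FoldWorkspace],
    panel: SamplePanel,
    features: Sequence[str],
    terms: Sequence[InteractionTerm],
    registry: KernelRegistry,
    config: SearchConfig,
) -> list[InteractionTerm]:
    """Rank candidate terms by partial correlation with training residuals.

    Each candidate column is first projected onto the orthogonal complement
    of the current design (intercept + features + terms) on the pooled
    training rows, so the ranking reflects only what the candidate adds
    beyond the model — without this, kernels that embed main-effect content
    (e.g. min(x,y) = (x+y-|x-y|)/2) crowd out the genuinely novel direction.
    Candidates collinear with the current design are dropped.
    """
    pool_rows = sorted({i for ws in workspaces for i in ws.train})
    pool = panel.subset(pool_rows)
    scaler = fit_scaler(pool)
    norm = apply_scaler(pool, scaler)
    # residuals of the current model refit on the pooled training rows
    cols = [np.ones(norm.n)] + [norm.column(f) for f in features]
    for t in terms:
        k = registry.get(t.kernel_id)
        cols.append(k.func(norm.column(t.var_a), norm.column(t.var_b)))
    A = np.column_stack(cols)
    Q, _ = np.linalg.qr(A, mode="reduced")
    resid = pool.y - Q @ (Q.T @ pool.y)
    rnorm = np.linalg.norm(resid)
    if rnorm < 1e-12 * max(1.0, float(np.linalg.norm(pool.y))):
        return []

    cache = {n: norm.column(n) for n in panel.catalogue.names}
    existing = set(terms)
    scored: list[tuple[float, InteractionTerm]] = []
    for term in enumerate_candidates(panel.catalogue, registry,
                                     allow_self=config.allow_self,
                                     dedupe_symmetric=True):
        if term in existing:
            continue
        k = registry.get(term.kernel_id)
        z = k.func(cache[term.var_a], cache[term.var_b])
        z_perp = z - Q @ (Q.T @ z)
        znorm = np.linalg.norm(z_perp)
        if znorm < 1e-8 * max(1.0, float(np.linalg.norm(z))):
            continue  # adds no new direction
        scored.append((abs(float(z_perp @ resid)) / (znorm * rnorm), term))
    scored.sort(key=lambda t: (-t[0], t[1].sort_key(panel.catalogue, registry)))
    return [term for _, term in scored[: config.top_screen]]


def search_robust_interactions(
    panel: SamplePanel,
    folds: FoldScheme,
    registry: KernelRegistry | None = None,
    config: SearchConfig | None = None,
) -> SelectionResult:
    """Full robust selection: elastic-net pre-screen per category, stepwise
    main-effect selection, then cycles of residual screening / forward
    addition / backward elimination over kernel-interaction candidates,
    until a full cycle changes nothing or ``max_cycles`` is reached."""
    registry = registry or default_registry()
    config = config or SearchConfig()
    workspaces = _make_workspaces(panel, folds, registry)

    prescreened: list[str] = []
    for category in ("weather", "soil", "management"):
        if not panel.catalogue.by_category(category):
            continue
        prescreened += elastic_net_prescreen(
            panel, category, grid=config.enet_grid,
            cap=config.caps.get(category), cv=config.enet_cv, seed=config.seed,
        )
    prescreened.sort(key=panel.catalogue.index)

    base = SelectionResult(config=config.echo(), seed=config.seed,
                           feature_categories={f: panel.catalogue.category_of(f)
                                               for f in prescreened})
    if config.max_cycles == 0:
        return replace(base, features=prescreened)

    if config.feature_stepwise:
        result = forward_stepwise(
            prescreened, base, panel, folds, registry,
            tol=config.tol_forward, max_added=config.max_features,
            metric=config.metric, _workspaces=workspaces,
        )
        result = backward_eliminate(result, panel, folds, registry,
                                    tol=config.tol_backward, metric=config.metric,
                                    heredity=config.heredity,
                                    _workspaces=workspaces)
    else:
        result = replace(base, features=prescreened)

    for _ in range(config.max_cycles):
        before = (tuple(result.features), tuple(result.terms))
        shortlist = _residual_screen(workspaces, panel, result.features,
                                     result.terms, registry, config)
        result = forward_stepwise(
            shortlist, result, panel, folds, registry,
            tol=config.tol_forward, max_added=config.max_added_per_cycle,
            metric=config.metric, _workspaces=workspaces,
        )
        if config.heredity:
            # strong heredity: selected terms keep their parent main effects
            parents = [
                v
                for t in result.terms
                for v in (t.var_a, t.var_b)
                if v not in result.features
            ]
            if parents:
                parents = sorted(set(parents), key=panel.catalogue.index)
                result = replace(
                    result,
                    features=sorted(result.features + parents,
                                    key=panel.catalogue.index),
                    feature_categories={
                        f: panel.catalogue.category_of(f)
                        for f in result.features + parents
                    },
                )
        result = backward_eliminate(result, panel, folds, registry,
                                    tol=config.tol_backward, metric=config.metric,
                                    heredity=config.heredity,
                                    _workspaces=workspaces)
        if (tuple(result.features), tuple(result.terms)) == before:
            break
    return result
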