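"""Kernel registry and interaction-column materialization.

An interaction term pairs two catalogue variables (a self-interaction when
they coincide) with exactly one kernel from the registry; its column
Z[i] = K(x_a[i], x_b[i]) on the normalized features becomes an extra
regression column.  With the product kernel a self-interaction is the
quadratic effect x².

The default registry holds six bounded bivariate kernels on [0,1]² spanning
synergy, limiting-factor and antagonism shapes; it is user-extensible so a
different kernel set can be dropped in via :meth:`KernelRegistry.register`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np

from .errors import UnknownKernelError, UnknownVariableError, InteractRegError
from .panel import SamplePanel, VariableCatalogue


@dataclass(frozen=True)
class Kernel:
    """A named bivariate map on normalized features.

    ``output_range`` documents the image of [0,1]² (asserted by tests);
    ``self_admissible`` is False for kernels that are degenerate on the
    diagonal (e.g. |x−y| ≡ 0).
    """

    kernel_id: str
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    symmetric: bool = True
    self_admissible: bool = True
    output_range: tuple[float, float] = (0.0, 1.0)


class KernelRegistry:
    """Ordered, id-unique kernel collection."""

    def __init__(self, kernels: Iterable[Kernel] = ()):
        self._kernels: dict[str, Kernel] = {}
        for k in kernels:
            self.register(k)

    def register(self, kernel: Kernel) -> None:
        if kernel.kernel_id in self._kernels:
            raise InteractRegError(f"kernel {kernel.kernel_id!r} already registered")
        self._kernels[kernel.kernel_id] = kernel

    def __contains__(self, kernel_id: str) -> bool:
        return kernel_id in self._kernels

    def __len__(self) -> int:
        return len(self._kernels)

    def __iter__(self) -> Iterator[Kernel]:
        return iter(self._kernels.values())

    @property
    def ids(self) -> list[str]:
        return list(self._kernels)

    def get(self, kernel_id: str) -> Kernel:
        try:
            return self._kernels[kernel_id]
        except KeyError:
            raise UnknownKernelError(f"kernel {kernel_id!r} not registered") from None

    def kernel_order(self, kernel_id: str) -> int:
        return self.ids.index(kernel_id)

    def evaluate(self, kernel_id: str, x, y) -> np.ndarray | float:
        k = self.get(kernel_id)
        out = k.func(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return float(out) if np.ndim(out) == 0 else out


def default_registry() -> KernelRegistry:
    """The default six kernels on the unit square."""
    return KernelRegistry(
        [
            Kernel("product", lambda x, y: x * y),
            Kernel("minimum", np.minimum),
            Kernel("maximum", np.maximum),
            Kernel("squared_mean", lambda x, y: ((x + y) / 2.0) ** 2),
            Kernel("abs_diff", lambda x, y: np.abs(x - y), self_admissible=False),
            Kernel("saturating_product", lambda x, y: 1.0 - (1.0 - x) * (1.0 - y)),
        ]
    )


def eval_kernel(registry: KernelRegistry, kernel_id: str, x, y):
    """Evaluate one registered kernel (vectorized over x, y)."""
    return registry.evaluate(kernel_id, x, y)


@dataclass(frozen=True, order=True)
class InteractionTerm:
    """A (variable pair, kernel) term; var_a == var_b is a self-interaction."""

    var_a: str
    var_b: str
    kernel_id: str

    @property
    def is_self(self) -> bool:
        return self.var_a == self.var_b

    def validate(self, catalogue: VariableCatalogue, registry: KernelRegistry) -> None:
        for v in (self.var_a, self.var_b):
            if v not in catalogue:
                raise UnknownVariableError(
                    f"interaction term references unknown variable {v!r}"
                )
        kernel = registry.get(self.kernel_id)
        if self.is_self and not kernel.self_admissible:
            raise InteractRegError(
                f"kernel {self.kernel_id!r} is not admissible as a self-interaction"
            )

    def canonical(self, catalogue: VariableCatalogue, registry: KernelRegistry
                  ) -> "InteractionTerm":
        """Order the pair by catalogue index when the kernel is symmetric."""
        if registry.get(self.kernel_id).symmetric and (
            catalogue.index(self.var_a) > catalogue.index(self.var_b)
        ):
            return InteractionTerm(self.var_b, self.var_a, self.kernel_id)
        return self

    def sort_key(self, catalogue: VariableCatalogue, registry: KernelRegistry):
        return (
            catalogue.index(self.var_a),
            catalogue.index(self.var_b),
            registry.kernel_order(self.kernel_id),
        )

    def to_dict(self) -> dict:
        return {"var_a": self.var_a, "var_b": self.var_b, "kernel_id": self.kernel_id}

    @classmethod
    def from_dict(cls, d: Mapping) -> "InteractionTerm":
        return cls(var_a=d["var_a"], var_b=d["var_b"], kernel_id=d["kernel_id"])


@dataclass
class InteractionMatrix:
    """Interaction columns Z aligned to an ordered term list."""

    terms: list[InteractionTerm]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != len(self.terms):
            raise InteractRegError("Z column count does not match term count")
        if self.Z.size and not np.all(np.isfinite(self.Z)):
            raise InteractRegError("non-finite interaction value")


def build_interaction_matrix(
    panel: SamplePanel,
    terms: Iterable[InteractionTerm],
    registry: KernelRegistry,
) -> InteractionMatrix:
    """Materialize Z[i, m] = K_m(X[i, var_a], X[i, var_b]) on a normalized panel."""
    if not panel.normalized:
        raise InteractRegError("interaction matrix requires a normalized panel")
    terms = list(terms)
    Z = np.empty((panel.n, len(terms)))
    for m, term in enumerate(terms):
        term.validate(panel.catalogue, registry)
        Z[:, m] = registry.get(term.kernel_id).func(
            panel.column(term.var_a), panel.column(term.var_b)
        )
    return InteractionMatrix(terms=terms, Z=Z)


def count_candidate_pairs(catalogue: VariableCatalogue, allow_self: bool = True) -> int:
    """Ordered variable pairs, including self-pairs when allowed: p² (or p²−p)."""
    p = len(catalogue)
    return p * p if allow_self else p * p - p


def count_candidate_terms(
    catalogue: VariableCatalogue,
    registry: KernelRegistry,
    allow_self: bool = True,
) -> int:
    """Candidate term count under the ordered-pair convention: for each kernel,
    p² pairs when self-admissible (and self allowed), else p²−p."""
    p = len(catalogue)
    total = 0
    for k in registry:
        total += p * p if (allow_self and k.self_admissible) else p * p - p
    return total


def enumerate_candidates(
    catalogue: VariableCatalogue,
    registry: KernelRegistry,
    allow_self: bool = True,
    pair_filter: Callable[[str, str], bool] | None = None,
    dedupe_symmetric: bool = False,
) -> Iterator[InteractionTerm]:
    """Lazily yield candidate interaction terms in canonical order.

    Ordered pairs (i, j) over the catalogue crossed with admissible kernels;
    with ``dedupe_symmetric`` the mirrored duplicate (j, i) of a symmetric
    kernel is skipped (the search uses this; reported pair counts keep the
    ordered p² convention).  ``pair_filter(var_a, var_b)`` may restrict pairs,
    e.g. to environment × management combinations.
    """
    names = catalogue.names
    kernels = list(registry)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j and not allow_self:
                continue
            if pair_filter is not None and not pair_filter(a, b):
                continue
            for k in kernels:
                if i == j and not k.self_admissible:
                    continue
                if dedupe_symmetric and k.symmetric and j < i:
                    continue
                yield InteractionTerm(a, b, k.kernel_id)
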