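"""Exception hierarchy shared across the package."""


class InteractRegError(Exception):
    """Base class for all interactreg errors."""


class PanelSchemaError(InteractRegError):
    """A panel file or in-memory panel violates the county-year schema."""


class DuplicateRowError(PanelSchemaError):
    """Two rows share the same (county_id, year) pair."""


class UnknownVariableError(InteractRegError):
    """A referenced variable name is not in the catalogue."""


class UnknownKernelError(InteractRegError):
    """A kernel_id is not present in the registry."""


class FoldError(InteractRegError):
    """A fold scheme cannot be built or violates its invariants."""


class FitError(InteractRegError):
    """A model fit is impossible (e.g. fewer samples than coefficients)."""


class ConfigError(InteractRegError):
    """A run configuration is invalid (unknown keys, missing seed, ...)."""
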