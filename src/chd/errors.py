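"""Exception hierarchy shared across the package."""


class ChdError(Exception):
    """Base class for all package errors."""


class InputError(ChdError, ValueError):
    """Invalid user-supplied data (bad indices, shapes, parameters)."""


class ConfigError(ChdError, ValueError):
    """Invalid configuration value."""


class IntegrityError(ChdError):
    """Artifact provenance mismatch (e.g. basis built from a different graph)."""


class FormatError(ChdError):
    """Malformed or truncated on-disk artifact."""


class SolverError(ChdError):
    """Eigensolver failed to converge or produced out-of-tolerance results."""


class DegenerateFitError(ChdError):
    """A distribution fit was requested on degenerate (e.g. all-zero) data."""
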