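"""Exception types shared across the package."""


class CravemodError(Exception):
    """Base class for package errors."""


class ConfigError(CravemodError, ValueError):
    """Invalid configuration (counts, proportions, windows, bounds)."""


class BalancingError(CravemodError, ValueError):
    """A requested exact balancing constraint cannot be satisfied."""


class PartitionError(CravemodError, ValueError):
    """No feasible Go/NoGo type partition exists; names the constraint."""


class EmptyErpError(CravemodError, ValueError):
    """All epochs of a condition were rejected; no ERP can be formed."""


class DataError(CravemodError, ValueError):
    """Malformed input records (negative times, missing cells, ...)."""
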