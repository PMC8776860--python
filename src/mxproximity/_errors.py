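"""Exception hierarchy shared across the package."""


class MxProximityError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MxProximityError):
    """A file does not conform to the expected tabular format."""


class ValidationError(MxProximityError):
    """Parsed data violates a declared invariant."""


class LinkageError(MxProximityError):
    """Cross-table identifiers (slide ids, sample ids) do not resolve."""


class ConfigError(MxProximityError):
    """A simulation or pipeline configuration is inconsistent."""


class DegenerateStatisticError(MxProximityError):
    """A statistic is undefined for the given input (e.g. all paired
    differences zero, constant vector)."""


class ConvergenceError(MxProximityError):
    """An iterative model fit failed to converge."""
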