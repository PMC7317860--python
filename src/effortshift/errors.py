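"""Exception types shared across the package."""


class EffortShiftError(Exception):
    """Base class for package-specific errors."""


class SchemaError(EffortShiftError, ValueError):
    """An input table does not match the documented schema."""


class EmptyInputError(EffortShiftError, ValueError):
    """An input file or selection contains no usable rows."""


class InsufficientDataError(EffortShiftError, ValueError):
    """Too few observations for the requested statistic."""


class MissingDataError(EffortShiftError, ValueError):
    """Missing entries present where a complete matrix is required."""


class AlignmentError(EffortShiftError, ValueError):
    """Two series or matrices do not share a common time index."""


class ConfigError(EffortShiftError, ValueError):
    """Invalid configuration value."""
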