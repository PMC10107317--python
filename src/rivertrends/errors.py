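"""Exception hierarchy shared across the package."""


class RiverTrendsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RiverTrendsError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(RiverTrendsError):
    """An input file does not match the documented dialect (e.g. missing column)."""


class AggregationError(RiverTrendsError):
    """A trait profile could not be aggregated (e.g. all member weights zero)."""


class AllocationError(RiverTrendsError):
    """A diet profile carries no information to allocate a trophic group from."""


class ClassificationError(RiverTrendsError):
    """A site cannot be assigned a river typology class."""


class DesignError(RiverTrendsError):
    """Model matrices cannot be built from the supplied records."""


class FitError(RiverTrendsError):
    """Model fitting failed on degenerate input."""


class UsageError(RiverTrendsError):
    """An operation was called with arguments outside its contract."""
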