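"""Exception types shared across the package."""


class StoichlimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(StoichlimError, ValueError):
    """Invalid generator or run configuration (names the offending field)."""


class SchemaError(StoichlimError, ValueError):
    """A cohort table violates the documented CSV schema."""


class AnalysisError(StoichlimError, ValueError):
    """A statistical stage received inputs it cannot analyse."""
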