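"""Exception taxonomy.

Three broad classes matter downstream: usage/configuration problems,
data-validation problems, and numerical/degenerate-geometry failures.
The CLI maps them to exit codes 2, 3 and 4 respectively.
"""


class VowelspaceError(Exception):
    """Base class for all package errors."""


class ConfigError(VowelspaceError):
    """Invalid configuration value or malformed config file."""


class SchemaError(VowelspaceError):
    """Input table is missing a required column or has the wrong layout."""


class DataValidationError(VowelspaceError):
    """A row or field violates the data contract (type, range, category)."""


class RangeError(DataValidationError):
    """A value falls outside its declared range (e.g. continuum step)."""


class SampleSizeError(VowelspaceError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(VowelspaceError):
    """Numerically degenerate input: zero variance, singular covariance,
    zero distance inside a log, all-one-category responses, zero MAD."""


class FitError(VowelspaceError):
    """Psychometric fit could not be used (unconverged or degenerate)."""
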