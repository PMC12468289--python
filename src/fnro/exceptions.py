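"""Error taxonomy shared across the package.

Every anticipated failure mode maps to one of these classes so callers (and
the CLI) can distinguish bad inputs from bad state from bad configuration.
"""


class FNROError(Exception):
    """Base class for all package errors."""


class FormatError(FNROError):
    """A file could not be parsed in the declared format."""


class SchemaError(FNROError):
    """The parsed file lacks a required column/attribute."""


class DomainError(FNROError, ValueError):
    """An argument violates a mathematical precondition."""


class StateError(FNROError, RuntimeError):
    """An operation was called on data in the wrong state (e.g. normalize
    before impute)."""


class ConfigError(FNROError, ValueError):
    """A configuration value is out of its legal range."""


class PipelineError(FNROError, RuntimeError):
    """A downstream component returned something unusable (e.g. non-finite
    fitness)."""
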