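"""Exception hierarchy.

``ConfigError`` maps to CLI exit status 2, ``DataValidationError`` (and
subclasses) to exit status 3.
"""


class StressDecompError(Exception):
    """Base class for all package errors."""


class ConfigError(StressDecompError):
    """Invalid configuration value or unknown configuration key."""


class DataValidationError(StressDecompError):
    """Input data violates a documented precondition."""


class InvalidDesignError(DataValidationError):
    """Study design is structurally invalid (counts, duplicates)."""


class StageError(DataValidationError):
    """An expression matrix was fed to a pipeline stage out of order."""


class MalformedOntologyError(DataValidationError):
    """Ontology file is cyclic, multi-rooted, or unparseable."""
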