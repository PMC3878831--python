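"""Exception hierarchy.

All pipeline errors derive from :class:`DetoxcatError` so callers (and the CLI)
can distinguish data problems (exit code 1) from configuration problems
(exit code 2).
"""


class DetoxcatError(Exception):
    """Base class for all detoxcat errors."""


class ValidationError(DetoxcatError):
    """A value violates a documented invariant (names the offending field)."""


class ParseError(DetoxcatError):
    """A file could not be parsed (malformed record or non-numeric field)."""


class SchemaError(DetoxcatError):
    """A tabular input is missing a required column."""


class ConfigError(DetoxcatError):
    """A configuration problem: missing input file, malformed ontology pattern."""
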