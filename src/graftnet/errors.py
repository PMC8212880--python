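"""Typed exceptions raised at the package boundaries.

Every reader, generator and statistical stage raises one of these instead of
silently coercing bad input; the pipeline runner catches them per stage.
"""


class GraftNetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GraftNetError, ValueError):
    """A file does not conform to its declared dialect (TSV/GMT/edge list)."""


class ParameterError(GraftNetError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class DataError(GraftNetError, ValueError):
    """Input data are structurally valid but unusable for the requested operation."""


class ConfigError(GraftNetError, ValueError):
    """A pipeline configuration key is missing, malformed or out of range."""
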