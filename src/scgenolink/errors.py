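"""Exception types shared across the package."""


class ScgenolinkError(Exception):
    """Base class for package-specific errors."""


class ParameterError(ScgenolinkError, ValueError):
    """A configuration or function parameter is invalid."""


class FormatError(ScgenolinkError, ValueError):
    """An input file violates its declared format."""


class ConsistencyError(ScgenolinkError, ValueError):
    """Two related inputs disagree (e.g. evidence referencing unknown cells)."""


class DependencyError(ScgenolinkError, RuntimeError):
    """A pipeline stage was run before its prerequisite stage."""
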