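"""Exception types shared across the package."""


class SvfTraceError(Exception):
    """Base class for all svftrace errors."""


class FormatError(SvfTraceError, ValueError):
    """An input file violates the expected format (names the offending property)."""


class ParameterError(SvfTraceError, ValueError):
    """A parameter value violates its documented constraint."""


class BoundsError(SvfTraceError, ValueError):
    """A coordinate falls outside the volume bounds."""


class SpecificationError(SvfTraceError, ValueError):
    """A phantom specification cannot be realised inside the requested volume."""
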