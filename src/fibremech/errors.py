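"""Exception hierarchy shared across the package."""


class FibreMechError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FibreMechError, ValueError):
    """A parameter violates a documented precondition."""


class DataFormatError(FibreMechError, ValueError):
    """An input file or in-memory container violates the documented format."""


class AnalysisError(FibreMechError, RuntimeError):
    """An analysis step could not produce a valid result."""
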