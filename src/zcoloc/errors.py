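"""Exception hierarchy."""


class ZColocError(Exception):
    """Base class for all zcoloc errors."""


class ValidationError(ZColocError, ValueError):
    """A precondition on inputs or parameters is violated."""


class FormatError(ZColocError, IOError):
    """An input file is unreadable or not a supported TIFF z-stack."""
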