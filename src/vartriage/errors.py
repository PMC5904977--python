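"""Exception hierarchy shared across the package."""


class VartriageError(Exception):
    """Base class for all package-specific errors."""


class InputError(VartriageError, ValueError):
    """Invalid user-supplied value (coordinate, contig, fraction, ...)."""


class VCFParseError(VartriageError):
    """A VCF record or header could not be parsed."""


class BEDParseError(VartriageError):
    """A BED line could not be parsed; message carries file and line number."""


class SchemaError(VartriageError):
    """Feature schema of a vector does not match the model's schema."""


class ConvergenceError(VartriageError):
    """The logistic solver hit its iteration cap; carries diagnostics."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter
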