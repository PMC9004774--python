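"""Exception hierarchy shared across the pipeline stages."""


class PhosphosigError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PhosphosigError):
    """A simulation or analysis configuration value is invalid.

    The message names the offending field.
    """


class ParseError(PhosphosigError):
    """A TSV/GMT input could not be parsed; the message carries the line number."""


class MissingAntibodyError(PhosphosigError):
    """Requested RPPA antibodies are absent from the matrix."""

    def __init__(self, missing: list[str], message: str | None = None):
        self.missing = list(missing)
        super().__init__(message or f"antibodies not found in RPPA matrix: {', '.join(self.missing)}")


class DegenerateDataError(PhosphosigError):
    """Data admit no answer (zero variance, identical values, too few samples)."""


class EmptySignatureError(PhosphosigError):
    """Signature assembly selected no gene for the up and/or down set.

    Carries the sizes actually selected and the nearest-miss threshold values so
    callers can report how far the data were from yielding a usable signature.
    """

    def __init__(self, up_size: int, down_size: int, detail: str = ""):
        self.up_size = up_size
        self.down_size = down_size
        empty = [name for name, n in (("up", up_size), ("down", down_size)) if n == 0]
        msg = f"empty signature set(s): {', '.join(empty)} (up={up_size}, down={down_size})"
        if detail:
            msg += f"; {detail}"
        super().__init__(msg)


class CoverageError(PhosphosigError):
    """Signature coverage in the scored matrix fell below the minimum fraction."""
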