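"""Exception hierarchy used across the package.

Every parser / contract violation raises a subclass of :class:`DifiError`
so the CLI can map failures to categorized exit codes.
"""


class DifiError(Exception):
    """Base class for all package errors."""


class ValidationError(DifiError):
    """An argument or domain-object contract was violated."""


class FormatError(DifiError):
    """Malformed on-disk input. Message names file, line and field."""

    def __init__(self, message: str, *, path=None, line=None, field=None):
        parts = [message]
        if path is not None:
            parts.append(f"file={path}")
        if line is not None:
            parts.append(f"line={line}")
        if field is not None:
            parts.append(f"field={field}")
        super().__init__(" | ".join(str(p) for p in parts))
        self.path, self.line, self.field = path, line, field


class EncodingError(DifiError):
    """A sequence contains symbols outside the declared alphabet."""


class DivergenceError(DifiError):
    """Training produced a non-finite loss."""
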