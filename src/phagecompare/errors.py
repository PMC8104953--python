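"""Exception hierarchy shared across the package."""


class PhageCompareError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhageCompareError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")


class CoordinateError(PhageCompareError):
    """A gene call does not fit on its contig."""


class ConfigError(PhageCompareError):
    """Invalid run configuration."""


class ConsistencyError(PhageCompareError):
    """Cross-references between inputs do not resolve (e.g. a hit naming an unknown gene)."""


class StageError(PhageCompareError):
    """A pipeline stage failed; carries the stage name and subject."""

    def __init__(self, stage: str, subject: str, cause: BaseException):
        self.stage = stage
        self.subject = subject
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for {subject}: {cause}")
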