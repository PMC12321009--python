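"""Diagnostic records shared by the parser and the validator.

A diagnostic carries a stable machine code, a severity, a human message and a
source range so editors (or the CLI) can underline the offending construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, auto

from .lexer import SourceRange


class Severity(Enum):
    ERROR = "error"
    WARNING = "warning"


class DiagnosticCode(Enum):
    # Syntactic errors detectable without a dictionary.
    EMPTY_FILE = auto()
    EMPTY_DATA_BLOCK = auto()
    MISSING_BLOCK_CODE = auto()
    MISSING_DATA_IDENTIFIER = auto()
    DUPLICATE_BLOCK_CODE = auto()
    DUPLICATE_DATA_NAME = auto()
    INVALID_LOOP = auto()
    MISSING_VALUE = auto()
    UNCLOSED_SAVE_FRAME = auto()
    LINE_TOO_LONG = auto()
    NAME_TOO_LONG = auto()
    STRING_FORMAT = auto()
    NON_ASCII = auto()
    # STAR reserved constructs (global_/stop_) that plain CIF data files do not use.
    RESERVED_CONSTRUCT = auto()
    # Dictionary-driven checks.
    NONSTANDARD_NAME = auto()
    TYPE_MISMATCH = auto()
    RANGE_VIOLATION = auto()
    ENUM_VIOLATION = auto()


#: Codes reported as warnings; everything else is an error.
_WARNING_CODES = {DiagnosticCode.NONSTANDARD_NAME, DiagnosticCode.RESERVED_CONSTRUCT}


def default_severity(code: DiagnosticCode) -> Severity:
    return Severity.WARNING if code in _WARNING_CODES else Severity.ERROR


@dataclass(frozen=True)
class Diagnostic:
    code: DiagnosticCode
    severity: Severity
    message: str
    range: SourceRange

    def to_dict(self) -> dict:
        """Machine-readable form with 0-based, end-exclusive positions."""
        return {
            "code": self.code.name,
            "severity": self.severity.value,
            "message": self.message,
            "range": {
                "start": {"line": self.range.start.line, "column": self.range.start.column},
                "end": {"line": self.range.end.line, "column": self.range.end.column},
            },
        }

    def format_human(self, filename: str = "<cif>") -> str:
        """1-based ``file:line:col [CODE] message`` line for terminal output."""
        pos = self.range.start
        return f"{filename}:{pos.line + 1}:{pos.column + 1} [{self.code.name}] {self.message}"


def make_diagnostic(code: DiagnosticCode, message: str, range_: SourceRange) -> Diagnostic:
    return Diagnostic(code, default_severity(code), message, range_)
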