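"""Regex-table tokenizer for CIF 1.1 and CIF 2.0.

The lexer holds an ordered table of (token kind, regular expression) rules.
At each offset the rules are tried in table order and the first match wins;
the matched text becomes one token annotated with its source range.  Rules
exist in a CIF 1.1 and a CIF 2.0 column: CIF 2.0 adds triple-quoted strings,
lists and tables, and relaxes the quoted-string rules, while CIF 1.1 allows
an embedded quote that is not followed by whitespace to stay inside a quoted
string.

Whitespace and newlines are kept as tokens, so concatenating the lexemes of
the token stream reproduces the input character for character.  A character
that no rule matches becomes a one-character error token (flagged on the
token, reported downstream as a string-format diagnostic) — the lexer is
total and never raises on malformed input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum, auto
from typing import Optional


class CifVersion(Enum):
    """CIF syntax level; selects which column of the rule table is active."""

    V1_1 = "1.1"
    V2_0 = "2.0"


#: Magic comment that opens a CIF 2.0 file (literally ``#\#CIF_2.0``).
CIF2_MAGIC = "#\\#CIF_2.0"


class TokenKind(Enum):
    TAG = auto()
    COMMENT = auto()
    DATA = auto()
    LOOP = auto()
    SAVE_END = auto()
    SAVE = auto()
    GLOBAL = auto()
    STOP = auto()
    CIF2_TRIPLE = auto()
    SINGLE = auto()
    DOUBLE = auto()
    MULTILINE = auto()
    NUMBER = auto()
    DOT = auto()
    QUESTION = auto()
    CIF2_LIST_START = auto()
    CIF2_LIST_END = auto()
    CIF2_TABLE_START = auto()
    CIF2_TABLE_DELIMITER = auto()
    CIF2_TABLE_END = auto()
    UNQUOTED = auto()
    WHITESPACE = auto()
    NEWLINE = auto()


@dataclass(frozen=True, order=True)
class SourcePosition:
    """0-based line/column position, columns counted in characters."""

    line: int
    column: int


@dataclass(frozen=True)
class SourceRange:
    """Half-open range: ``start`` inclusive, ``end`` exclusive."""

    start: SourcePosition
    end: SourcePosition

    def contains(self, position: SourcePosition) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class Token:
    kind: TokenKind
    lexeme: str
    range: SourceRange
    #: True for the one-character fallback tokens emitted when no rule matched.
    error: bool = False


@dataclass(frozen=True)
class ParsedNumber:
    """A CIF numeric value with its optional parenthesised standard uncertainty.

    ``0.52011(3)`` parses to value 0.52011 with su_digits "3": the digits give
    the uncertainty in the last decimal place(s) of the value.
    """

    value: float
    su_digits: Optional[str]
    raw: str


# Rule table: (kind, CIF 1.1 regex, CIF 2.0 regex or None when identical, flags).
# Row order is the matching order; SAVE_END precedes SAVE so a bare ``save_``
# terminator is never swallowed by the save-frame header rule.
_TABLE = [
    (TokenKind.TAG, r"_[^\s]+(?=($|\s))", None, 0),
    (TokenKind.COMMENT, r"#.*(?=($|\n))", None, 0),
    (TokenKind.DATA, r"DATA_[^\s]+(?=($|\s))", None, re.IGNORECASE),
    (TokenKind.LOOP, r"LOOP_(?=($|\s))", None, re.IGNORECASE),
    (TokenKind.SAVE_END, r"SAVE_(?=($|\s))", None, re.IGNORECASE),
    (TokenKind.SAVE, r"SAVE_[^\s]+(?=($|\s))", None, re.IGNORECASE),
    (TokenKind.GLOBAL, r"GLOBAL_(?=($|\s))", None, re.IGNORECASE),
    (TokenKind.STOP, r"STOP_(?=($|\s))", None, re.IGNORECASE),
    (TokenKind.CIF2_TRIPLE, None, r"'''(?!''').*'''", 0),
    (TokenKind.SINGLE, r"'(?:[^'\n]|'(?!\s|$))*'(?!\S)", r"'[^'\n]*'", 0),
    (TokenKind.DOUBLE, r'"(?:[^"\n]|"(?!\s|$))*"(?!\S)', r'"[^"\n]*"', 0),
    (TokenKind.MULTILINE, r"\n;(\n|.)*?\n;", None, 0),
    (
        TokenKind.NUMBER,
        r"([+-]?(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?)(\(\d+\))?(?=($|[\s]))",
        None,
        0,
    ),
    (TokenKind.DOT, r"(\.)(?=($|\s))", None, 0),
    (TokenKind.QUESTION, r"(\?)(?=($|\s))", None, 0),
    (TokenKind.CIF2_LIST_START, None, r"\[", 0),
    (TokenKind.CIF2_LIST_END, None, r"\](?=($|\s))", re.IGNORECASE),
    (TokenKind.CIF2_TABLE_START, None, r"\{", 0),
    (TokenKind.CIF2_TABLE_DELIMITER, None, r":", 0),
    (TokenKind.CIF2_TABLE_END, None, r"\}", 0),
    (TokenKind.UNQUOTED, r"[^\s]+", r"[^\s\]}]+", 0),
    (TokenKind.WHITESPACE, r"[^\S\n]+", None, 0),
    (TokenKind.NEWLINE, r"\n", None, 0),
]

# The MULTILINE rule requires a preceding newline; at offset 0 the lexer treats
# start-of-file as "after a newline" so a file opening with ``;`` still starts
# a text field.
_MULTILINE_BOF = re.compile(r";(\n|.)*?\n;")


def _compile(version: CifVersion):
    rules = []
    for kind, p11, p20, flags in _TABLE:
        pattern = p20 if (version is CifVersion.V2_0 and p20 is not None) else p11
        if pattern is None:
            continue  # CIF 2.0-only construct, inactive under 1.1
        rules.append((kind, re.compile(pattern, flags)))
    return rules


_RULES = {
    CifVersion.V1_1: _compile(CifVersion.V1_1),
    CifVersion.V2_0: _compile(CifVersion.V2_0),
}

_NUMBER_FULL = re.compile(
    r"([+-]?(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?)(\((\d+)\))?\Z"
)


def detect_version(source_text: str) -> CifVersion:
    """Choose the syntax level from the CIF 2.0 magic comment on line 1.

    A file whose first line begins with ``#\\#CIF_2.0`` is CIF 2.0; everything
    else defaults to CIF 1.1.  Callers (CLI flag, API argument) may override.
    """
    first_line = source_text.split("\n", 1)[0]
    if first_line.startswith(CIF2_MAGIC):
        return CifVersion.V2_0
    return CifVersion.V1_1


def _advance_position(line: int, column: int, lexeme: str) -> tuple[int, int]:
    newlines = lexeme.count("\n")
    if newlines:
        return line + newlines, len(lexeme) - (lexeme.rfind("\n") + 1)
    return line, column + len(lexeme)


def tokenize(source_text: str, version: CifVersion = CifVersion.V1_1) -> list[Token]:
    """Break ``source_text`` into a complete, position-annotated token stream.

    The stream partitions the input: lexemes concatenate back to the source
    exactly.  Never raises; unmatched characters yield error tokens.
    """
    rules = _RULES[version]
    tokens: list[Token] = []
    pos = 0
    line = 0
    column = 0
    n = len(source_text)
    while pos < n:
        match = None
        kind = None
        error = False
        for rule_kind, rx in rules:
            if rule_kind is TokenKind.MULTILINE and pos == 0:
                m = _MULTILINE_BOF.match(source_text, pos)
            else:
                m = rx.match(source_text, pos)
            if m and m.end() > pos:
                match, kind = m, rule_kind
                break
        if match is None:
            lexeme = source_text[pos]
            kind = TokenKind.UNQUOTED
            error = True
        else:
            lexeme = source_text[pos : match.end()]
        end_line, end_column = _advance_position(line, column, lexeme)
        tokens.append(
            Token(
                kind,
                lexeme,
                SourceRange(SourcePosition(line, column), SourcePosition(end_line, end_column)),
                error,
            )
        )
        pos += len(lexeme)
        line, column = end_line, end_column
    return tokens


def parse_numeric(lexeme: str) -> Optional[ParsedNumber]:
    """Parse a CIF number with optional standard uncertainty, or return None.

    The lexeme must consist of exactly the numeric part plus the optional
    parenthesised su digits; anything else (including ``.``, the inapplicable
    placeholder) is rejected.
    """
    m = _NUMBER_FULL.match(lexeme)
    if m is None or not lexeme:
        return None
    return ParsedNumber(value=float(m.group(1)), su_digits=m.group(3), raw=lexeme)


def token_at(tokens: list[Token], position: SourcePosition) -> Optional[Token]:
    """Return the non-whitespace token whose range contains ``position``."""
    for token in tokens:
        if token.kind in (TokenKind.WHITESPACE, TokenKind.NEWLINE):
            continue
        if token.range.contains(position):
            return token
        if token.range.start > position:
            break
    return None
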