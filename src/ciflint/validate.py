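"""Linter: syntactic checks, length/charset limits and dictionary validation.

The syntactic checks cover the common CIF mistakes seen in deposited files:
empty files and blocks, missing or duplicate block codes, duplicate data
names, malformed loops, tags without values, unclosed save frames, over-long
lines (2048 characters) and data names (80 characters), string-formatting
errors, and non-ASCII characters in CIF 1.1 (which is an ASCII-only format;
CIF 2.0 permits Unicode).  Dictionary validation compares every tag/value
association against the loaded definitions: unknown names are warned about
(opt-out), and values are checked for content type, permitted range and
enumeration membership.  The placeholders ``?`` (unknown) and ``.``
(inapplicable) are always exempt from value checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .diagnostics import Diagnostic, DiagnosticCode, Severity, make_diagnostic
from .dictionary import ContentType, DictionaryStore, lookup
from .lexer import (
    CifVersion,
    SourcePosition,
    SourceRange,
    Token,
    TokenKind,
    detect_version,
    tokenize,
)
from .parser import (
    DataBlock,
    Document,
    Item,
    Loop,
    Reserved,
    SaveFrame,
    Value,
    ValueKind,
    parse,
    value_text,
)

_ZERO = SourceRange(SourcePosition(0, 0), SourcePosition(0, 0))


@dataclass(frozen=True)
class LintOptions:
    version_override: Optional[CifVersion] = None
    warn_nonstandard: bool = True
    max_line_length: int = 2048
    max_name_length: int = 80


_DEFAULT_OPTIONS = LintOptions()


def _scopes(block: DataBlock):
    """Duplicate-name scopes: the block itself, then each save frame.

    Dictionaries legitimately reuse attribute tags across save frames, so each
    frame is its own scope.
    """
    top = [n for n in block.content if not isinstance(n, SaveFrame)]
    yield f"data block 'data_{block.code}'", top
    for node in block.content:
        if isinstance(node, SaveFrame):
            yield f"save frame '{node.header_lexeme}'", list(node.content)


def _scope_tags(content: list):
    for node in content:
        if isinstance(node, Item):
            yield node.tag, node.tag_range
        elif isinstance(node, Loop):
            yield from zip(node.tags, node.tag_ranges)


def _iter_loops(block: DataBlock):
    for node in block.content:
        if isinstance(node, Loop):
            yield node
        elif isinstance(node, SaveFrame):
            for inner in node.content:
                if isinstance(inner, Loop):
                    yield inner


def _iter_items(block: DataBlock):
    for node in block.content:
        if isinstance(node, Item):
            yield node
        elif isinstance(node, SaveFrame):
            for inner in node.content:
                if isinstance(inner, Item):
                    yield inner


def check_syntax(
    document: Document,
    tokens: list[Token],
    source_text: str,
    options: LintOptions = _DEFAULT_OPTIONS,
) -> list[Diagnostic]:
    """The enumerated syntactic checks, with source positions."""
    significant = [
        t for t in tokens if t.kind not in (TokenKind.WHITESPACE, TokenKind.NEWLINE, TokenKind.COMMENT)
    ]
    if not significant:
        return [make_diagnostic(DiagnosticCode.EMPTY_FILE, "file contains no CIF content", _ZERO)]

    diagnostics: list[Diagnostic] = list(document.diagnostics)

    if document.leading:
        first = document.leading[0]
        diagnostics.append(
            make_diagnostic(
                DiagnosticCode.MISSING_DATA_IDENTIFIER,
                "content appears before any data_ block",
                first.range,
            )
        )

    for token in tokens:
        if token.error:
            diagnostics.append(
                make_diagnostic(
                    DiagnosticCode.STRING_FORMAT,
                    f"character {token.lexeme!r} matches no CIF token",
                    token.range,
                )
            )
        elif token.kind is TokenKind.UNQUOTED and token.lexeme[0] in "'\"":
            diagnostics.append(
                make_diagnostic(
                    DiagnosticCode.STRING_FORMAT,
                    f"unterminated or malformed quoted string {token.lexeme!r}",
                    token.range,
                )
            )
        elif (
            token.kind is TokenKind.UNQUOTED
            and token.lexeme[0] == ";"
            and token.range.start.column == 0
        ):
            diagnostics.append(
                make_diagnostic(
                    DiagnosticCode.STRING_FORMAT,
                    "unterminated multi-line text field",
                    token.range,
                )
            )

    seen_codes: set[str] = set()
    for block in document.blocks:
        if block.code == "":
            diagnostics.append(
                make_diagnostic(
                    DiagnosticCode.MISSING_BLOCK_CODE,
                    "data_ keyword without a block code",
                    block.header_range,
                )
            )
        else:
            key = block.code.lower()
            if key in seen_codes:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.DUPLICATE_BLOCK_CODE,
                        f"duplicate data block name 'data_{block.code}'",
                        block.header_range,
                    )
                )
            seen_codes.add(key)

        if not block.content:
            diagnostics.append(
                make_diagnostic(
                    DiagnosticCode.EMPTY_DATA_BLOCK,
                    f"data block 'data_{block.code}' is empty",
                    block.header_range,
                )
            )

        for scope_label, content in _scopes(block):
            seen_tags: set[str] = set()
            for tag, tag_range in _scope_tags(content):
                key = tag.lower()
                if key in seen_tags:
                    diagnostics.append(
                        make_diagnostic(
                            DiagnosticCode.DUPLICATE_DATA_NAME,
                            f"duplicate data name '{tag}' in {scope_label}",
                            tag_range,
                        )
                    )
                seen_tags.add(key)

        for loop in _iter_loops(block):
            if not loop.tags:
                message = "loop_ has no data names"
            elif not loop.values:
                message = "loop_ has no data values"
            elif len(loop.values) % len(loop.tags) != 0:
                message = (
                    f"loop_ has {len(loop.values)} values for {len(loop.tags)} data names"
                    " (not a multiple)"
                )
            else:
                continue
            diagnostics.append(
                make_diagnostic(DiagnosticCode.INVALID_LOOP, message, loop.header_range)
            )

        for item in _iter_items(block):
            if item.value.is_placeholder:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.MISSING_VALUE,
                        f"data name '{item.tag}' has no value",
                        item.tag_range,
                    )
                )

        for node in block.content:
            if isinstance(node, SaveFrame) and not node.closed:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.UNCLOSED_SAVE_FRAME,
                        f"save frame '{node.header_lexeme}' is not closed by save_",
                        node.header_range,
                    )
                )
            elif isinstance(node, Reserved):
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.RESERVED_CONSTRUCT,
                        f"STAR reserved word '{node.lexeme}' is not used in CIF data files",
                        node.range,
                    )
                )

    return diagnostics


def check_limits(
    source_text: str,
    document: Document,
    options: LintOptions = _DEFAULT_OPTIONS,
) -> list[Diagnostic]:
    """Line-length and data-name-length limits (terminators excluded)."""
    diagnostics: list[Diagnostic] = []
    for line_number, line in enumerate(source_text.split("\n")):
        if len(line) > options.max_line_length:
            diagnostics.append(
                make_diagnostic(
                    DiagnosticCode.LINE_TOO_LONG,
                    f"line is {len(line)} characters long"
                    f" (limit {options.max_line_length})",
                    SourceRange(
                        SourcePosition(line_number, 0), SourcePosition(line_number, len(line))
                    ),
                )
            )
    for block in document.blocks:
        for _label, content in _scopes(block):
            for tag, tag_range in _scope_tags(content):
                if len(tag) > options.max_name_length:
                    diagnostics.append(
                        make_diagnostic(
                            DiagnosticCode.NAME_TOO_LONG,
                            f"data name is {len(tag)} characters long"
                            f" (limit {options.max_name_length})",
                            tag_range,
                        )
                    )
    return diagnostics


def check_charset(source_text: str, version: CifVersion) -> list[Diagnostic]:
    """Flag every non-ASCII character under CIF 1.1; CIF 2.0 allows Unicode."""
    if version is CifVersion.V2_0:
        return []
    diagnostics: list[Diagnostic] = []
    for line_number, line in enumerate(source_text.split("\n")):
        for column, char in enumerate(line):
            if ord(char) > 127:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.NON_ASCII,
                        f"non-ASCII character {char!r} is not allowed in CIF 1.1",
                        SourceRange(
                            SourcePosition(line_number, column),
                            SourcePosition(line_number, column + 1),
                        ),
                    )
                )
    return diagnostics


def _is_integral(value: Value) -> bool:
    # An integer value may not carry a decimal point, a negative exponent that
    # yields a fraction, or a standard uncertainty.
    assert value.number is not None
    if value.number.su_digits is not None:
        return False
    return float(value.number.value).is_integer() and "." not in value.number.raw.split("(")[0]


def check_dictionary(
    document: Document,
    store: DictionaryStore,
    options: LintOptions = _DEFAULT_OPTIONS,
) -> list[Diagnostic]:
    """Dictionary-driven validation of every tag/value association."""
    diagnostics: list[Diagnostic] = []

    def check_association(tag: str, tag_range: SourceRange, value: Value) -> None:
        definition = lookup(store, tag)
        if definition is None:
            if options.warn_nonstandard:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.NONSTANDARD_NAME,
                        f"data name '{tag}' is not defined in the loaded dictionaries",
                        tag_range,
                    )
                )
            return
        if value.is_placeholder or value.kind in (ValueKind.UNKNOWN, ValueKind.INAPPLICABLE):
            return  # '?' and '.' are exempt from value validation
        if definition.content_type in (ContentType.INTEGER, ContentType.REAL):
            if value.kind is not ValueKind.NUMBER or value.number is None:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.TYPE_MISMATCH,
                        f"'{tag}' requires a {definition.content_type.value} value,"
                        f" got '{value.raw.strip()}'",
                        value.range,
                    )
                )
                return
            if definition.content_type is ContentType.INTEGER and not _is_integral(value):
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.TYPE_MISMATCH,
                        f"'{tag}' requires an integer value, got '{value.raw}'",
                        value.range,
                    )
                )
                return
        if definition.range is not None and value.number is not None:
            # Range comparison uses the numeric part only; the parenthesised
            # standard uncertainty is ignored.
            if not definition.range.contains(value.number.value):
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.RANGE_VIOLATION,
                        f"'{tag}' value {value.number.value} is outside the permitted range",
                        value.range,
                    )
                )
        if definition.enumeration is not None:
            text = value_text(value)
            if text.lower() not in {state.lower() for state in definition.enumeration}:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.ENUM_VIOLATION,
                        f"'{tag}' value '{text}' is not one of the allowed enumerations",
                        value.range,
                    )
                )

    def walk(content: list) -> None:
        for node in content:
            if isinstance(node, Item):
                check_association(node.tag, node.tag_range, node.value)
            elif isinstance(node, Loop):
                n = len(node.tags)
                if n == 0:
                    continue
                for index, value in enumerate(node.values):
                    check_association(node.tags[index % n], node.tag_ranges[index % n], value)
            elif isinstance(node, SaveFrame):
                walk(list(node.content))

    for block in document.blocks:
        walk(block.content)
    return diagnostics


def _sort_key(diagnostic: Diagnostic):
    r = diagnostic.range
    return (
        r.start.line,
        r.start.column,
        r.end.line,
        r.end.column,
        diagnostic.code.name,
        diagnostic.message,
    )


def lint(
    source_text: str,
    options: LintOptions = _DEFAULT_OPTIONS,
    store: Optional[DictionaryStore] = None,
) -> list[Diagnostic]:
    """Run every check on raw CIF text; deterministic and position-sorted.

    Windows line endings are normalised to ``\\n`` before analysis, so
    reported positions refer to the normalised text (columns are unaffected).
    """
    source_text = source_text.replace("\r\n", "\n")
    version = options.version_override or detect_version(source_text)
    tokens = tokenize(source_text, version)
    document, _parse_diags = parse(tokens, version)
    diagnostics = check_syntax(document, tokens, source_text, options)
    if not (len(diagnostics) == 1 and diagnostics[0].code is DiagnosticCode.EMPTY_FILE):
        diagnostics.extend(check_limits(source_text, document, options))
        diagnostics.extend(check_charset(source_text, version))
        if store is not None:
            diagnostics.extend(check_dictionary(document, store, options))
    return sorted(diagnostics, key=_sort_key)


def has_errors(diagnostics: list[Diagnostic]) -> bool:
    return any(d.severity is Severity.ERROR for d in diagnostics)
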