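"""Error-tolerant recursive-descent parser for the CIF token stream.

The parser turns the lexer's token stream into a tree that records which data
block, save frame and loop every data value belongs to, and which data name it
answers to.  It is written for editor tooling: it never raises on malformed
input.  On an unexpected token it records the token, queues a diagnostic, and
resumes at the next anchor (tag, loop_, data_ or save frame boundary), so
hover and completion keep working to the right of an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, auto
from typing import Iterator, Optional, Union

from .diagnostics import Diagnostic, DiagnosticCode, make_diagnostic
from .lexer import (
    CifVersion,
    ParsedNumber,
    SourcePosition,
    SourceRange,
    Token,
    TokenKind,
    parse_numeric,
)

_SKIP = {TokenKind.WHITESPACE, TokenKind.NEWLINE, TokenKind.COMMENT}

_SCALAR_TOKENS = {
    TokenKind.SINGLE,
    TokenKind.DOUBLE,
    TokenKind.CIF2_TRIPLE,
    TokenKind.MULTILINE,
    TokenKind.NUMBER,
    TokenKind.DOT,
    TokenKind.QUESTION,
    TokenKind.UNQUOTED,
}

_QUOTED_TOKENS = {TokenKind.SINGLE, TokenKind.DOUBLE, TokenKind.CIF2_TRIPLE}

#: Recovery anchors: structural tokens descent resynchronises on.
_ANCHORS = {
    TokenKind.TAG,
    TokenKind.LOOP,
    TokenKind.DATA,
    TokenKind.SAVE,
    TokenKind.SAVE_END,
    TokenKind.GLOBAL,
    TokenKind.STOP,
}


class ValueKind(Enum):
    TEXT_SINGLE = auto()
    TEXT_DOUBLE = auto()
    TEXT_TRIPLE = auto()
    TEXT_MULTILINE = auto()
    TEXT_UNQUOTED = auto()
    NUMBER = auto()
    UNKNOWN = auto()        # "?"
    INAPPLICABLE = auto()   # "."
    LIST = auto()
    TABLE = auto()


@dataclass
class Value:
    kind: ValueKind
    raw: str
    range: SourceRange
    number: Optional[ParsedNumber] = None
    elements: list["Value"] = field(default_factory=list)
    entries: list[tuple[str, "Value"]] = field(default_factory=list)

    @property
    def is_placeholder(self) -> bool:
        """True for the zero-width UNKNOWN value attached to a tag without one."""
        return self.raw == ""


def value_text(value: Value) -> str:
    """The value's content with quoting/delimiters stripped (scalar kinds)."""
    raw = value.raw
    if value.kind is ValueKind.TEXT_SINGLE or value.kind is ValueKind.TEXT_DOUBLE:
        return raw[1:-1]
    if value.kind is ValueKind.TEXT_TRIPLE:
        return raw[3:-3]
    if value.kind is ValueKind.TEXT_MULTILINE:
        body = raw.lstrip("\n")  # token may carry the preceding newline
        return body[1:-2].strip("\n") if body.endswith("\n;") else body[1:].strip("\n")
    return raw


@dataclass
class Item:
    tag: str
    tag_range: SourceRange
    value: Value
    range: SourceRange


@dataclass
class Loop:
    header_range: SourceRange
    tags: list[str]
    tag_ranges: list[SourceRange]
    values: list[Value]
    range: SourceRange

    @property
    def well_formed(self) -> bool:
        return bool(self.tags) and bool(self.values) and len(self.values) % len(self.tags) == 0

    @property
    def n_rows(self) -> int:
        return len(self.values) // len(self.tags) if self.tags else 0


@dataclass
class Reserved:
    """A STAR reserved construct (global_/stop_) kept as a standalone node."""

    lexeme: str
    range: SourceRange


@dataclass
class StrayValue:
    """A bare value with no preceding data name; diagnosed, never dropped."""

    value: Value


@dataclass
class SaveFrame:
    code: str
    header_lexeme: str
    header_range: SourceRange
    content: list[Union[Item, Loop, Reserved, StrayValue]]
    closed: bool
    range: SourceRange


Node = Union[Item, Loop, SaveFrame, Reserved, StrayValue]


@dataclass
class DataBlock:
    code: str
    header_lexeme: str
    header_range: SourceRange
    content: list[Node]
    range: SourceRange


@dataclass
class Document:
    version: CifVersion
    blocks: list[DataBlock]
    #: Significant tokens appearing before the first data block.
    leading: list[Token]
    #: Structural diagnostics collected during parsing.
    diagnostics: list[Diagnostic] = field(default_factory=list)


class PathRole(Enum):
    BLOCK = auto()
    SAVE = auto()
    LOOP = auto()
    TAG = auto()
    VALUE = auto()


@dataclass(frozen=True)
class PathEntry:
    role: PathRole
    label: str


@dataclass(frozen=True)
class HierarchyPath:
    entries: tuple[PathEntry, ...]


def _zero_range(position: SourcePosition) -> SourceRange:
    return SourceRange(position, position)


class _Parser:
    def __init__(self, tokens: list[Token], version: CifVersion):
        self.version = version
        self.sig = [t for t in tokens if t.kind not in _SKIP]
        self.i = 0
        self.diags: list[Diagnostic] = []

    # -- token helpers ----------------------------------------------------

    def _peek(self) -> Optional[Token]:
        return self.sig[self.i] if self.i < len(self.sig) else None

    def _advance(self) -> Token:
        tok = self.sig[self.i]
        self.i += 1
        return tok

    def _diag(self, code: DiagnosticCode, message: str, range_: SourceRange) -> None:
        self.diags.append(make_diagnostic(code, message, range_))

    @staticmethod
    def _is_block_header(tok: Token) -> bool:
        # A bare ``data_`` fails the DATA rule and surfaces as UNQUOTED; it is
        # still a block header, just one with a missing block code.
        return tok.kind is TokenKind.DATA or (
            tok.kind is TokenKind.UNQUOTED
            and not tok.error
            and tok.lexeme.lower() == "data_"
        )

    def _starts_value(self, tok: Token) -> bool:
        return tok.kind in _SCALAR_TOKENS or tok.kind in (
            TokenKind.CIF2_LIST_START,
            TokenKind.CIF2_TABLE_START,
        )

    # -- grammar ----------------------------------------------------------

    def parse_document(self) -> Document:
        leading: list[Token] = []
        while (tok := self._peek()) is not None and not self._is_block_header(tok):
            leading.append(self._advance())
        blocks = []
        while self._peek() is not None:
            blocks.append(self._parse_block())
        return Document(self.version, blocks, leading, self.diags)

    def _parse_block(self) -> DataBlock:
        header = self._advance()
        code = header.lexeme[5:]  # text after "data_"; empty for bare data_
        content: list[Node] = []
        end = header.range.end
        while (tok := self._peek()) is not None and not self._is_block_header(tok):
            node = self._parse_block_member(tok, in_frame=False)
            if node is not None:
                content.append(node)
                end = _node_range(node).end
        return DataBlock(code, header.lexeme, header.range, content, SourceRange(header.range.start, end))

    def _parse_block_member(self, tok: Token, in_frame: bool) -> Optional[Node]:
        kind = tok.kind
        if kind is TokenKind.TAG:
            return self._parse_item()
        if kind is TokenKind.LOOP:
            return self._parse_loop()
        if kind is TokenKind.SAVE and not in_frame:
            return self._parse_save()
        if kind in (TokenKind.GLOBAL, TokenKind.STOP):
            t = self._advance()
            return Reserved(t.lexeme, t.range)
        if kind is TokenKind.SAVE_END:
            t = self._advance()
            self._diag(
                DiagnosticCode.STRING_FORMAT,
                "'save_' terminator without an open save frame",
                t.range,
            )
            return None
        if self._starts_value(tok):
            value = self._parse_value()
            self._diag(
                DiagnosticCode.STRING_FORMAT,
                f"data value '{value.raw.strip()}' has no preceding data name",
                value.range,
            )
            return StrayValue(value)
        t = self._advance()
        self._diag(DiagnosticCode.STRING_FORMAT, f"unexpected '{t.lexeme}'", t.range)
        return None

    def _parse_item(self) -> Item:
        tag_tok = self._advance()
        nxt = self._peek()
        if nxt is not None and self._starts_value(nxt):
            value = self._parse_value()
        else:
            # Missing value: attach a zero-width UNKNOWN placeholder so the
            # item still exists in the tree; the validator reports it.
            value = Value(ValueKind.UNKNOWN, "", _zero_range(tag_tok.range.end))
        return Item(
            tag_tok.lexeme,
            tag_tok.range,
            value,
            SourceRange(tag_tok.range.start, value.range.end if not value.is_placeholder else tag_tok.range.end),
        )

    def _parse_loop(self) -> Loop:
        header = self._advance()
        tags: list[str] = []
        tag_ranges: list[SourceRange] = []
        while (tok := self._peek()) is not None and tok.kind is TokenKind.TAG:
            t = self._advance()
            tags.append(t.lexeme)
            tag_ranges.append(t.range)
        values: list[Value] = []
        while (tok := self._peek()) is not None and self._starts_value(tok):
            values.append(self._parse_value())
        end = values[-1].range.end if values else (tag_ranges[-1].end if tag_ranges else header.range.end)
        return Loop(header.range, tags, tag_ranges, values, SourceRange(header.range.start, end))

    def _parse_save(self) -> SaveFrame:
        header = self._advance()
        code = header.lexeme[5:]
        content: list[Union[Item, Loop, Reserved, StrayValue]] = []
        closed = False
        end = header.range.end
        while (tok := self._peek()) is not None:
            if tok.kind is TokenKind.SAVE_END:
                end = self._advance().range.end
                closed = True
                break
            if self._is_block_header(tok) or tok.kind is TokenKind.SAVE:
                break  # nested/unterminated frame: leave unclosed
            node = self._parse_block_member(tok, in_frame=True)
            if node is not None:
                content.append(node)
                end = _node_range(node).end
        return SaveFrame(code, header.lexeme, header.range, content, closed, SourceRange(header.range.start, end))

    # -- values -----------------------------------------------------------

    def _parse_value(self) -> Value:
        tok = self._peek()
        assert tok is not None
        if tok.kind is TokenKind.CIF2_LIST_START:
            return self._parse_list()
        if tok.kind is TokenKind.CIF2_TABLE_START:
            return self._parse_table()
        tok = self._advance()
        return self._scalar(tok)

    _SCALAR_KIND = {
        TokenKind.SINGLE: ValueKind.TEXT_SINGLE,
        TokenKind.DOUBLE: ValueKind.TEXT_DOUBLE,
        TokenKind.CIF2_TRIPLE: ValueKind.TEXT_TRIPLE,
        TokenKind.MULTILINE: ValueKind.TEXT_MULTILINE,
        TokenKind.UNQUOTED: ValueKind.TEXT_UNQUOTED,
        TokenKind.DOT: ValueKind.INAPPLICABLE,
        TokenKind.QUESTION: ValueKind.UNKNOWN,
    }

    def _scalar(self, tok: Token) -> Value:
        if tok.kind is TokenKind.NUMBER:
            return Value(ValueKind.NUMBER, tok.lexeme, tok.range, number=parse_numeric(tok.lexeme))
        return Value(self._SCALAR_KIND[tok.kind], tok.lexeme, tok.range)

    def _parse_list(self) -> Value:
        start = self._advance()
        elements: list[Value] = []
        end = start.range.end
        closed = False
        while (tok := self._peek()) is not None:
            if tok.kind is TokenKind.CIF2_LIST_END:
                end = self._advance().range.end
                closed = True
                break
            if tok.kind in _ANCHORS:
                break
            if self._starts_value(tok):
                element = self._parse_value()
                elements.append(element)
                end = element.range.end
            else:
                t = self._advance()
                self._diag(DiagnosticCode.STRING_FORMAT, f"unexpected '{t.lexeme}' in list", t.range)
                end = t.range.end
        if not closed:
            self._diag(DiagnosticCode.STRING_FORMAT, "unterminated list", SourceRange(start.range.start, end))
        raw = "[" + " ".join(e.raw for e in elements) + ("]" if closed else "")
        return Value(ValueKind.LIST, raw, SourceRange(start.range.start, end), elements=elements)

    def _parse_table(self) -> Value:
        start = self._advance()
        entries: list[tuple[str, Value]] = []
        end = start.range.end
        closed = False
        while (tok := self._peek()) is not None:
            if tok.kind is TokenKind.CIF2_TABLE_END:
                end = self._advance().range.end
                closed = True
                break
            if tok.kind in _ANCHORS:
                break
            if tok.kind not in _QUOTED_TOKENS:
                t = self._advance()
                self._diag(
                    DiagnosticCode.STRING_FORMAT,
                    f"table key '{t.lexeme}' must be a quoted string",
                    t.range,
                )
                end = t.range.end
                continue
            key_tok = self._advance()
            key = self._scalar(key_tok)
            end = key_tok.range.end
            nxt = self._peek()
            if nxt is not None and nxt.kind is TokenKind.CIF2_TABLE_DELIMITER:
                end = self._advance().range.end
            else:
                self._diag(
                    DiagnosticCode.STRING_FORMAT,
                    f"table key {key_tok.lexeme} is not followed by ':'",
                    key_tok.range,
                )
            nxt = self._peek()
            if nxt is not None and self._starts_value(nxt):
                val = self._parse_value()
                end = val.range.end
            else:
                self._diag(
                    DiagnosticCode.STRING_FORMAT,
                    f"table key {key_tok.lexeme} has no value",
                    key_tok.range,
                )
                val = Value(ValueKind.UNKNOWN, "", _zero_range(end))
            entries.append((value_text(key), val))
        if not closed:
            self._diag(DiagnosticCode.STRING_FORMAT, "unterminated table", SourceRange(start.range.start, end))
        raw = (
            "{"
            + " ".join(f"'{k}':{v.raw}" for k, v in entries)
            + ("}" if closed else "")
        )
        return Value(ValueKind.TABLE, raw, SourceRange(start.range.start, end), entries=entries)


def _node_range(node: Node) -> SourceRange:
    if isinstance(node, StrayValue):
        return node.value.range
    return node.range


def parse(tokens: list[Token], version: CifVersion = CifVersion.V1_1) -> tuple[Document, list[Diagnostic]]:
    """Parse a token stream into a Document plus structural diagnostics.

    Total: never raises on malformed input.  The returned diagnostics are also
    stored on ``Document.diagnostics``.
    """
    parser = _Parser(tokens, version)
    document = parser.parse_document()
    return document, parser.diags


# -- navigation ------------------------------------------------------------


def _display_raw(value: Value) -> str:
    return value.raw.lstrip("\n") if value.raw else "?"


def _path_in_content(
    content: list[Node], base: list[PathEntry], position: SourcePosition
) -> Optional[HierarchyPath]:
    for node in content:
        if isinstance(node, Item):
            if node.tag_range.contains(position):
                return HierarchyPath(tuple(base + [PathEntry(PathRole.TAG, node.tag)]))
            if node.value.range.contains(position):
                return HierarchyPath(
                    tuple(
                        base
                        + [
                            PathEntry(PathRole.TAG, node.tag),
                            PathEntry(PathRole.VALUE, _display_raw(node.value)),
                        ]
                    )
                )
        elif isinstance(node, Loop):
            if not node.range.contains(position):
                continue
            loop_entry = PathEntry(PathRole.LOOP, "loop_")
            if node.header_range.contains(position):
                return HierarchyPath(tuple(base + [loop_entry]))
            for tag, tag_range in zip(node.tags, node.tag_ranges):
                if tag_range.contains(position):
                    return HierarchyPath(tuple(base + [loop_entry, PathEntry(PathRole.TAG, tag)]))
            n = len(node.tags)
            for index, value in enumerate(node.values):
                if value.range.contains(position):
                    entries = base + [loop_entry]
                    if n:
                        entries.append(PathEntry(PathRole.TAG, node.tags[index % n]))
                    entries.append(PathEntry(PathRole.VALUE, _display_raw(value)))
                    return HierarchyPath(tuple(entries))
        elif isinstance(node, SaveFrame):
            if not node.range.contains(position):
                continue
            save_entry = PathEntry(PathRole.SAVE, node.header_lexeme)
            if node.header_range.contains(position):
                return HierarchyPath(tuple(base + [save_entry]))
            inner = _path_in_content(list(node.content), base + [save_entry], position)
            if inner is not None:
                return inner
        elif isinstance(node, StrayValue):
            if node.value.range.contains(position):
                return HierarchyPath(
                    tuple(base + [PathEntry(PathRole.VALUE, _display_raw(node.value))])
                )
    return None


def path_of(document: Document, position: SourcePosition) -> Optional[HierarchyPath]:
    """The BLOCK [> SAVE] [> LOOP] > TAG > VALUE chain containing ``position``.

    Returns None outside any block, or on whitespace/comments within one.
    """
    for block in document.blocks:
        if not block.range.contains(position):
            continue
        base = [PathEntry(PathRole.BLOCK, block.header_lexeme)]
        if block.header_range.contains(position):
            return HierarchyPath(tuple(base))
        return _path_in_content(block.content, base, position)
    return None


def _iter_content_associations(
    content: list, include_frames: bool
) -> Iterator[tuple[str, SourceRange, Value]]:
    for node in content:
        if isinstance(node, Item):
            yield node.tag, node.tag_range, node.value
        elif isinstance(node, Loop):
            n = len(node.tags)
            if n == 0:
                continue
            for index, value in enumerate(node.values):
                yield node.tags[index % n], node.tag_ranges[index % n], value
        elif isinstance(node, SaveFrame) and include_frames:
            yield from _iter_content_associations(list(node.content), include_frames)


def items_of(document: Document, block_code: str) -> list[tuple[str, Value]]:
    """Every tag/value association of the named block, loop cells row-major.

    Block lookup is case-insensitive; save-frame content is included
    (flattened).  An unknown block code yields an empty list.
    """
    wanted = block_code.lower()
    for block in document.blocks:
        if block.code.lower() == wanted:
            return [
                (tag, value)
                for tag, _rng, value in _iter_content_associations(block.content, include_frames=True)
            ]
    return []


def dump(document: Document, indent: str = "  ") -> str:
    """Indented text rendering of the tree, for debugging."""
    lines: list[str] = []

    def walk(content: list, depth: int) -> None:
        for node in content:
            if isinstance(node, Item):
                lines.append(indent * depth + node.tag)
                lines.append(indent * (depth + 1) + _display_raw(node.value))
            elif isinstance(node, Loop):
                lines.append(indent * depth + "loop_")
                for tag in node.tags:
                    lines.append(indent * (depth + 1) + tag)
                for value in node.values:
                    lines.append(indent * (depth + 2) + _display_raw(value))
            elif isinstance(node, SaveFrame):
                lines.append(indent * depth + node.header_lexeme)
                walk(list(node.content), depth + 1)
            elif isinstance(node, Reserved):
                lines.append(indent * depth + node.lexeme)
            elif isinstance(node, StrayValue):
                lines.append(indent * depth + _display_raw(node.value))

    for block in document.blocks:
        lines.append(block.header_lexeme)
        walk(block.content, 1)
    return "\n".join(lines)
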