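"""CIF dictionary loading and the persistent registry of user dictionaries.

Dictionaries are themselves CIF files: modern IUCr dictionaries are written in
CIF 2.0 syntax using DDLm, with one save frame per defined data name.  This
module parses them with the package's own lexer/parser and extracts the four
attributes the validator needs — description, content type, permitted range
and enumeration states.  Full DDLm semantics (imports, dREL methods, category
relations) are out of scope.

Two dialects are accepted and routed through the same parser: DDLm save-frame
dictionaries, and a flat dialect where each data block holds one definition —
handy for miniature hand-written or generated dictionaries.

Recognised attribute tags (first match wins within a definition):

====================  =========================================================
``_definition.id`` / ``_name``        defined data name
``_description.text`` / ``_definition``  human description
``_type.contents`` / ``_type``        content type (Integer / Real / Text ...)
``_enumeration.range``                "min:max", an omitted endpoint unbounded
``_enumeration.range_exclusive``      fixture-dialect flag: min / max / both
``_enumeration_set.state``            loop of allowed states
====================  =========================================================
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

from .diagnostics import Diagnostic, DiagnosticCode, make_diagnostic
from .lexer import SourcePosition, SourceRange, detect_version, tokenize
from .parser import Item, Loop, SaveFrame, Value, parse, value_text

_DATA_DIR = Path(__file__).parent / "data"

#: Origins recorded for each loaded dictionary.
ORIGIN_BUNDLED = "bundled"
ORIGIN_USER = "user-added"


class ContentType(Enum):
    INTEGER = "integer"
    REAL = "real"
    TEXT = "text"
    ANY = "any"


@dataclass(frozen=True)
class ValueRange:
    minimum: Optional[float] = None
    maximum: Optional[float] = None
    min_exclusive: bool = False
    max_exclusive: bool = False

    def contains(self, value: float) -> bool:
        if self.minimum is not None:
            if value < self.minimum or (self.min_exclusive and value == self.minimum):
                return False
        if self.maximum is not None:
            if value > self.maximum or (self.max_exclusive and value == self.maximum):
                return False
        return True


@dataclass(frozen=True)
class Definition:
    name: str
    description: str
    content_type: ContentType
    range: Optional[ValueRange] = None
    enumeration: Optional[frozenset[str]] = None
    source: str = ""

    @property
    def name_key(self) -> str:
        return self.name.lower()


@dataclass
class DictionaryStore:
    """Case-insensitive definition lookup over all loaded dictionaries.

    Later-loaded dictionaries shadow earlier ones on name collision, so
    user-added dictionaries override bundled ones.
    """

    definitions: dict[str, Definition] = field(default_factory=dict)
    sources: list[tuple[str, str]] = field(default_factory=list)  # (identifier, origin)

    def add(self, definitions: list[Definition], identifier: str, origin: str) -> None:
        for definition in definitions:
            self.definitions[definition.name_key] = definition
        self.sources.append((identifier, origin))


def lookup(store: DictionaryStore, name: str) -> Optional[Definition]:
    """Case-insensitive exact lookup of a data name."""
    return store.definitions.get(name.lower())


_TYPE_MAP = {"integer": ContentType.INTEGER, "int": ContentType.INTEGER}


def _content_type_from_text(text: Optional[str]) -> ContentType:
    if text is None:
        return ContentType.ANY
    lowered = text.strip().lower()
    if lowered in _TYPE_MAP:
        return _TYPE_MAP[lowered]
    if lowered in ("real", "float") or "numb" in lowered:
        return ContentType.REAL
    return ContentType.TEXT


def _parse_range(text: str) -> Optional[ValueRange]:
    if ":" not in text:
        return None
    lo_text, hi_text = text.split(":", 1)
    try:
        minimum = float(lo_text) if lo_text.strip() else None
        maximum = float(hi_text) if hi_text.strip() else None
    except ValueError:
        return None
    return ValueRange(minimum=minimum, maximum=maximum)


def _definition_from_content(
    content: list, identifier: str, range_: SourceRange
) -> tuple[Optional[Definition], list[Diagnostic]]:
    items: dict[str, Value] = {}
    states: list[str] = []
    for node in content:
        if isinstance(node, Item):
            items.setdefault(node.tag.lower(), node.value)
        elif isinstance(node, Loop):
            for tag, tag_lower in ((t, t.lower()) for t in node.tags):
                if tag_lower == "_enumeration_set.state":
                    column = node.tags.index(tag)
                    n = len(node.tags)
                    states.extend(
                        value_text(v) for i, v in enumerate(node.values) if i % n == column
                    )
    name_value = items.get("_definition.id") or items.get("_name")
    if name_value is None:
        return None, [
            make_diagnostic(
                DiagnosticCode.NONSTANDARD_NAME,
                "dictionary definition without _definition.id or _name",
                range_,
            )
        ]
    name = value_text(name_value)
    description_value = items.get("_description.text") or items.get("_definition")
    description = value_text(description_value) if description_value is not None else ""
    type_value = items.get("_type.contents") or items.get("_type")
    content_type = _content_type_from_text(value_text(type_value) if type_value else None)
    value_range = None
    if "_enumeration.range" in items:
        value_range = _parse_range(value_text(items["_enumeration.range"]))
        if value_range is not None and "_enumeration.range_exclusive" in items:
            flag = value_text(items["_enumeration.range_exclusive"]).strip().lower()
            value_range = replace(
                value_range,
                min_exclusive=flag in ("min", "both"),
                max_exclusive=flag in ("max", "both"),
            )
    if "_enumeration_set.state" in items:  # single-item form
        states.append(value_text(items["_enumeration_set.state"]))
    enumeration = frozenset(states) if states else None
    return (
        Definition(
            name=name,
            description=description,
            content_type=content_type,
            range=value_range,
            enumeration=enumeration,
            source=identifier,
        ),
        [],
    )


def load_dictionary(source_text: str, identifier: str) -> tuple[list[Definition], list[Diagnostic]]:
    """Extract definitions from CIF dictionary text (DDLm or flat dialect).

    Unparseable frames yield diagnostics, never failure; an empty input yields
    an empty list plus a diagnostic.
    """
    diagnostics: list[Diagnostic] = []
    empty = SourceRange(SourcePosition(0, 0), SourcePosition(0, 0))
    if not source_text.strip():
        return [], [make_diagnostic(DiagnosticCode.EMPTY_FILE, f"dictionary '{identifier}' is empty", empty)]
    version = detect_version(source_text)
    tokens = tokenize(source_text, version)
    document, _parse_diags = parse(tokens, version)
    definitions: list[Definition] = []
    frames = [
        node for block in document.blocks for node in block.content if isinstance(node, SaveFrame)
    ]
    if frames:
        for frame in frames:
            definition, diags = _definition_from_content(list(frame.content), identifier, frame.range)
            diagnostics.extend(diags)
            if definition is not None:
                definitions.append(definition)
    else:
        for block in document.blocks:
            if not block.content:
                continue
            definition, diags = _definition_from_content(block.content, identifier, block.range)
            diagnostics.extend(diags)
            if definition is not None:
                definitions.append(definition)
    if not definitions:
        diagnostics.append(
            make_diagnostic(
                DiagnosticCode.NONSTANDARD_NAME,
                f"dictionary '{identifier}' defines no data names",
                empty,
            )
        )
    return definitions, diagnostics


# -- registry of user-added dictionaries -----------------------------------


@dataclass(frozen=True)
class RegistryConfig:
    user_dictionary_paths: tuple[str, ...] = ()
    warn_nonstandard: bool = True


class BundledDictionaryError(ValueError):
    """Raised when a caller tries to remove a bundled dictionary."""


def default_config_path() -> Path:
    base = os.environ.get("XDG_CONFIG_HOME", os.path.join(os.path.expanduser("~"), ".config"))
    return Path(base) / "ciflint" / "registry.json"


def load_registry(path: Path) -> RegistryConfig:
    if not Path(path).exists():
        return RegistryConfig()
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return RegistryConfig(
        user_dictionary_paths=tuple(dict.fromkeys(data.get("user_dictionary_paths", []))),
        warn_nonstandard=bool(data.get("warn_nonstandard", True)),
    )


def save_registry(config: RegistryConfig, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "user_dictionary_paths": list(config.user_dictionary_paths),
        "warn_nonstandard": config.warn_nonstandard,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def bundled_dictionary_paths() -> list[Path]:
    return sorted(_DATA_DIR.glob("*.dic"))


def _identifier_for(path: Path) -> str:
    return Path(path).stem


def add_dictionary(config: RegistryConfig, path: os.PathLike | str) -> RegistryConfig:
    """Register a user dictionary file; duplicates are ignored."""
    text_path = str(path)
    if text_path in config.user_dictionary_paths:
        return config
    return replace(config, user_dictionary_paths=config.user_dictionary_paths + (text_path,))


def remove_dictionary(config: RegistryConfig, identifier: str) -> RegistryConfig:
    """Remove a user-added dictionary by identifier (file stem) or path.

    Bundled dictionaries cannot be removed; attempting to raises
    BundledDictionaryError and the registry is left unchanged.
    """
    bundled = {_identifier_for(p) for p in bundled_dictionary_paths()}
    if identifier in bundled:
        raise BundledDictionaryError(
            f"'{identifier}' is a bundled dictionary and cannot be removed"
        )
    remaining = tuple(
        p
        for p in config.user_dictionary_paths
        if p != identifier and _identifier_for(Path(p)) != identifier
    )
    if remaining == config.user_dictionary_paths:
        raise KeyError(f"no user-added dictionary named '{identifier}'")
    return replace(config, user_dictionary_paths=remaining)


def build_store(config: Optional[RegistryConfig] = None) -> tuple[DictionaryStore, list[Diagnostic]]:
    """Deterministically rebuild the store: bundled dictionaries, then user ones."""
    store = DictionaryStore()
    diagnostics: list[Diagnostic] = []
    for path in bundled_dictionary_paths():
        definitions, diags = load_dictionary(path.read_text(encoding="utf-8"), _identifier_for(path))
        diagnostics.extend(diags)
        store.add(definitions, _identifier_for(path), ORIGIN_BUNDLED)
    if config is not None:
        for text_path in config.user_dictionary_paths:
            path = Path(text_path)
            try:
                text = path.read_text(encoding="utf-8", errors="replace")
            except OSError:
                diagnostics.append(
                    make_diagnostic(
                        DiagnosticCode.NONSTANDARD_NAME,
                        f"dictionary file '{text_path}' could not be read",
                        SourceRange(SourcePosition(0, 0), SourcePosition(0, 0)),
                    )
                )
                store.add([], _identifier_for(path), ORIGIN_USER)
                continue
            definitions, diags = load_dictionary(text, _identifier_for(path))
            diagnostics.extend(diags)
            store.add(definitions, _identifier_for(path), ORIGIN_USER)
    return store, diagnostics


def list_dictionaries(store: DictionaryStore) -> list[str]:
    """Loaded dictionary identifiers, bundled first, in load order."""
    return [identifier for identifier, _origin in store.sources]
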