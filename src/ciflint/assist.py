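"""Editor assistance: hover information and data-name completion.

Hover shows where a construct sits in the file — data block, save frame,
loop, data name, data value — as an indented hierarchy, and for data names
appends the description from the loaded dictionaries.  Completion matches a
typed fragment against every known data name: prefix matches first, then
matches anywhere inside the name (so ``_author`` surfaces names from the
_audit, _publ and _citation categories), alphabetical within each rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .dictionary import DictionaryStore, lookup
from .lexer import SourcePosition
from .parser import Document, HierarchyPath, PathRole, path_of


@dataclass(frozen=True)
class HoverInfo:
    path: HierarchyPath
    rendered: str
    description: Optional[str] = None


@dataclass(frozen=True)
class CompletionCandidate:
    name: str
    snippet: str
    source: str


@dataclass(frozen=True)
class CompletionList:
    candidates: tuple[CompletionCandidate, ...]


def render_path(path: HierarchyPath, indent: str = "  ") -> str:
    """One line per path entry, each nested one indentation step deeper."""
    return "\n".join(indent * depth + entry.label for depth, entry in enumerate(path.entries))


def hover(
    document: Document, store: Optional[DictionaryStore], position: SourcePosition
) -> Optional[HoverInfo]:
    """Hierarchy path at ``position``; plus the dictionary description on a tag."""
    path = path_of(document, position)
    if path is None:
        return None
    description = None
    if store is not None and path.entries[-1].role is PathRole.TAG:
        definition = lookup(store, path.entries[-1].label)
        if definition is not None and definition.description:
            description = definition.description
    return HoverInfo(path=path, rendered=render_path(path), description=description)


def _snippet(description: str, width: int = 80) -> str:
    first_line = description.strip().split("\n", 1)[0]
    return first_line if len(first_line) <= width else first_line[: width - 1] + "…"


def complete(store: DictionaryStore, typed_fragment: str = "") -> CompletionList:
    """Dictionary-driven name completion for a typed fragment.

    An empty fragment lists every definition once.  Matching is
    case-insensitive: names starting with the fragment rank first; names
    containing it (leading underscore stripped) follow; both alphabetical.
    """
    fragment = typed_fragment.lower()
    interior_needle = fragment.lstrip("_")
    prefix: list[CompletionCandidate] = []
    interior: list[CompletionCandidate] = []
    for name_key in sorted(store.definitions):
        definition = store.definitions[name_key]
        candidate = CompletionCandidate(
            name=definition.name,
            snippet=_snippet(definition.description),
            source=definition.source,
        )
        if not fragment or name_key.startswith(fragment):
            prefix.append(candidate)
        elif interior_needle and interior_needle in name_key:
            interior.append(candidate)
    return CompletionList(candidates=tuple(prefix + interior))
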