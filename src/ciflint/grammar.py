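"""TextMate grammar emitter for CIF syntax highlighting.

Emits the scope/regex rule set as a JSON TextMate grammar, the dialect most
editors consume.  The multi-line text field is the one begin/end pair (a
``;`` in column 0 opens and closes it); every other rule is a single match
regex.  Emission is deterministic byte for byte.
"""

from __future__ import annotations

import json

#: (scope name, match regex) in highlighting order; the multi-line string rule
#: is a (begin, end) pair instead of a match.
GRAMMAR_RULES: list[tuple[str, object]] = [
    ("variable.other.cif", r"(?:(?<=^)|(?<=\s))_[^\s]+(?=($|\s))"),
    ("comment.line.number-sign.cif", r"(?:(?<=^)|(?<=\s))#.*$"),
    ("entity.name.function.cif", r"(?:(?<=^)|(?<=\s))(?i)DATA_[^\s]+(?=($|\s))"),
    ("keyword.control.cif", r"(?:(?<=^)|(?<=\s))(?i)LOOP_(?=($|\s))"),
    ("entity.name.function.cif", r"(?:(?<=^)|(?<=\s))(?i)SAVE_[^\s]*(?=($|\s))"),
    ("entity.name.function.cif", r"(?:(?<=^)|(?<=\s))(?i)GLOBAL_(?=($|\s))"),
    ("entity.name.function.cif", r"(?:(?<=^)|(?<=\s))(?i)STOP_(?=($|\s))"),
    ("string.quoted.single.cif", r"'(?:[^']|'(?!\s|$))*'(?!\S)"),
    ("string.quoted.double.cif", r"\"(?:[^\"]|\"(?!\s|$))*\"(?!\S)"),
    ("string.quoted.other.cif", ("^;", "^;")),
    (
        "constant.numeric.cif",
        r"(?:(?<=^)|(?<=\s))([+-]?((\d+(?:\.\d*)?)|(\.\d+))(?:[eE][+-]?\d+)?)(\(\d+\))?(?=($|\s))",
    ),
    ("constant.language.cif", r"(?:(?<=^)|(?<=\s))(\.)(?=($|\s))"),
    ("constant.language.cif", r"(?:(?<=^)|(?<=\s))(\?)(?=($|\s))"),
    ("string.unquoted.cif", r"[^\s]+"),
]


def grammar_patterns() -> list[dict]:
    patterns: list[dict] = []
    for scope, rule in GRAMMAR_RULES:
        if isinstance(rule, tuple):
            begin, end = rule
            patterns.append({"name": scope, "begin": begin, "end": end})
        else:
            patterns.append({"name": scope, "match": rule})
    return patterns


def emit_textmate_grammar() -> str:
    """The full grammar document as deterministic JSON text."""
    grammar = {
        "name": "CIF",
        "scopeName": "source.cif",
        "fileTypes": ["cif", "dic"],
        "patterns": grammar_patterns(),
    }
    return json.dumps(grammar, indent=2) + "\n"
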