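"""Seeded synthetic CIF and dictionary generators.

Everything the test suite needs is generated here, offline and
deterministically: well-formed multi-block CIFs exercising every quoting
style the chosen syntax level allows, one minimal broken file per diagnostic
code (with its repaired twin), and miniature DDLm-style dictionaries for
round-trip checks.  Generated files use only the data names of the bundled
fixture dictionary, so a clean file lints without errors or warnings.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .diagnostics import DiagnosticCode, Severity
from .dictionary import ContentType, ValueRange
from .lexer import CIF2_MAGIC, CifVersion

_CELL_SETTINGS = [
    "triclinic",
    "monoclinic",
    "orthorhombic",
    "tetragonal",
    "trigonal",
    "hexagonal",
    "cubic",
    "rhombohedral",
]

_ELEMENTS = ["C", "N", "O", "S", "H", "Cl", "Na", "Fe", "Cu", "Zn"]

# Disjoint tag pools so several loops can share a block without duplicate names.
_LOOP_POOLS: list[list[str]] = [
    ["_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"],
    ["_atom_site_label", "_atom_site_type_symbol", "_atom_site_occupancy"],
    ["_publ_author_name"],
]


@dataclass(frozen=True)
class FixtureCase:
    """A broken CIF, the codes it must produce, and its repaired twin."""

    label: str
    source_text: str
    expected_codes: tuple[DiagnosticCode, ...]
    version: CifVersion
    seed: int
    repaired_text: str
    #: Severity at which expected_codes must appear (NONSTANDARD_NAME and
    #: RESERVED_CONSTRUCT are warnings; everything else errors).
    severity: Severity = Severity.ERROR


def _formula(rng: random.Random) -> str:
    parts = [f"{rng.choice(_ELEMENTS)}{rng.randint(1, 20)}" for _ in range(rng.randint(2, 4))]
    return " ".join(parts)


def _block_lines(rng: random.Random, code: str, version: CifVersion) -> list[str]:
    # Every quoting style legal for the version appears in every block, each
    # on its own data name: unquoted (the cell setting and the numbers),
    # single- and double-quoted, multi-line, and under CIF 2.0 also
    # triple-quoted plus list and table values.
    lines = [f"data_{code}"]
    lines.append(f"_cell_length_a {rng.uniform(5, 30):.4f}({rng.randint(1, 9)})")
    lines.append(f"_cell_angle_alpha {rng.uniform(60, 120):.2f}")
    lines.append(f"_cell_volume {rng.uniform(100, 5000):.2f}")
    lines.append(f"_chemical_formula_weight {rng.uniform(100, 900):.2f}")
    lines.append(f"_symmetry_cell_setting {rng.choice(_CELL_SETTINGS)}")
    lines.append(f"_symmetry_int_tables_number {rng.randint(1, 230)}")
    lines.append(f"_diffrn_ambient_temperature {rng.uniform(90, 300):.1f}")
    lines.append(f"_chemical_formula_sum '{_formula(rng)}'")
    lines.append(f'_audit_author_name "{rng.choice(["Smith", "Jones", "Lee"])}, A."')
    lines.append("_publ_section_title")
    lines.append(";")
    lines.append(f" Structure determination number {rng.randint(1, 999)}")
    lines.append(";")
    if version is CifVersion.V2_0:
        lines.append(f"_citation_author_id '''id {rng.randint(1, 99)}'''")
        values = " ".join(f"{rng.uniform(0, 1):.3f}" for _ in range(3))
        lines.append(f"_fixture_list_values [{values} ]")
        lines.append(
            f"_fixture_table_values {{'a':{rng.uniform(0, 1):.3f} 'b':{rng.uniform(0, 1):.3f} }}"
        )
    return lines


def _loop_lines(rng: random.Random, pool_index: int) -> list[str]:
    tags = _LOOP_POOLS[pool_index]
    lines = ["loop_"] + list(tags)
    for row in range(rng.randint(2, 4)):
        cells = []
        for tag in tags:
            if tag.endswith(("fract_x", "fract_y", "fract_z")):
                cells.append(f"{rng.uniform(0, 1):.5f}({rng.randint(1, 9)})")
            elif tag.endswith("occupancy"):
                cells.append(f"{rng.uniform(0.1, 1.0):.3f}")
            elif tag.endswith("label"):
                cells.append(f"{rng.choice(_ELEMENTS)}{row + 1}")
            elif tag.endswith("type_symbol"):
                cells.append(rng.choice(_ELEMENTS))
            elif tag.endswith("author_name"):
                cells.append(f"'{rng.choice(['Smith', 'Jones', 'Lee'])}, {rng.choice(['A.', 'B.', 'C.'])}'")
            else:
                cells.append(f"id{row + 1}")
        lines.append(" ".join(cells))
    return lines


def generate_valid_cif(
    seed: int,
    n_blocks: int = 2,
    n_loops: int = 2,
    version: CifVersion = CifVersion.V1_1,
) -> str:
    """A deterministic, error-free CIF using only fixture-dictionary names.

    Exercises every quoting style legal for ``version``.  Loops are spread
    over the blocks, at most three per block (one per disjoint tag pool).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n_loops > len(_LOOP_POOLS) * n_blocks:
        raise ValueError(f"at most {len(_LOOP_POOLS)} loops per block are supported")
    rng = random.Random(seed)
    lines: list[str] = []
    if version is CifVersion.V2_0:
        lines.append(CIF2_MAGIC)
    lines.append(f"# synthetic CIF, seed {seed}")
    loops_left = n_loops
    per_block = -(-n_loops // n_blocks)  # spread loops evenly over the blocks
    for index in range(n_blocks):
        lines.extend(_block_lines(rng, f"fixture{index + 1}s{seed}", version))
        for pool in range(min(per_block, loops_left, len(_LOOP_POOLS))):
            lines.extend(_loop_lines(rng, pool))
            loops_left -= 1
    return "\n".join(lines) + "\n"


def _case(
    label: str,
    code: DiagnosticCode,
    seed: int,
    broken: str,
    repaired: str,
    version: CifVersion = CifVersion.V1_1,
    severity: Severity = Severity.ERROR,
) -> FixtureCase:
    return FixtureCase(label, broken, (code,), version, seed, repaired, severity)


def generate_error_case(code: DiagnosticCode, seed: int = 0) -> FixtureCase:
    """A minimal file producing exactly ``code`` (at its severity) and no
    other error; the repaired twin lints without errors."""
    rng = random.Random(seed)
    volume = f"{rng.uniform(100, 5000):.2f}"
    length = f"{rng.uniform(5, 30):.4f}"
    suffix = rng.randint(1, 999)
    C = DiagnosticCode
    if code is C.EMPTY_FILE:
        return _case("empty file", code, seed, "# only a comment\n", f"data_a{suffix}\n_cell_volume {volume}\n")
    if code is C.EMPTY_DATA_BLOCK:
        return _case(
            "empty data block",
            code,
            seed,
            f"data_empty{suffix}\ndata_full{suffix}\n_cell_volume {volume}\n",
            f"data_full{suffix}\n_cell_volume {volume}\n",
        )
    if code is C.MISSING_BLOCK_CODE:
        return _case(
            "data_ without block code",
            code,
            seed,
            f"data_\n_cell_volume {volume}\n",
            f"data_a{suffix}\n_cell_volume {volume}\n",
        )
    if code is C.MISSING_DATA_IDENTIFIER:
        return _case(
            "content before any data block",
            code,
            seed,
            f"_cell_volume {volume}\ndata_a{suffix}\n_cell_length_a {length}\n",
            f"data_a{suffix}\n_cell_volume {volume}\n_cell_length_a {length}\n",
        )
    if code is C.DUPLICATE_BLOCK_CODE:
        return _case(
            "duplicate block name",
            code,
            seed,
            f"data_dup{suffix}\n_cell_volume {volume}\ndata_DUP{suffix}\n_cell_length_a {length}\n",
            f"data_dup{suffix}\n_cell_volume {volume}\ndata_other{suffix}\n_cell_length_a {length}\n",
        )
    if code is C.DUPLICATE_DATA_NAME:
        return _case(
            "duplicate data name",
            code,
            seed,
            f"data_a{suffix}\n_cell_volume {volume}\n_CELL_VOLUME {volume}\n",
            f"data_a{suffix}\n_cell_volume {volume}\n",
        )
    if code is C.INVALID_LOOP:
        return _case(
            "loop with dangling values",
            code,
            seed,
            f"data_a{suffix}\nloop_\n_publ_author_name\n_citation_author_id\n"
            "'Smith, A.' id1 'Jones, B.'\n",
            f"data_a{suffix}\nloop_\n_publ_author_name\n_citation_author_id\n"
            "'Smith, A.' id1 'Jones, B.' id2\n",
        )
    if code is C.MISSING_VALUE:
        return _case(
            "tag without value",
            code,
            seed,
            f"data_a{suffix}\n_cell_volume\n",
            f"data_a{suffix}\n_cell_volume {volume}\n",
        )
    if code is C.UNCLOSED_SAVE_FRAME:
        return _case(
            "unclosed save frame",
            code,
            seed,
            f"data_a{suffix}\nsave_frame{suffix}\n_cell_volume {volume}\n",
            f"data_a{suffix}\nsave_frame{suffix}\n_cell_volume {volume}\nsave_\n",
        )
    if code is C.LINE_TOO_LONG:
        return _case(
            "over-long line",
            code,
            seed,
            f"data_a{suffix}\n#{'x' * 2048}\n_cell_volume {volume}\n",
            f"data_a{suffix}\n#{'x' * 2047}\n_cell_volume {volume}\n",
        )
    if code is C.NAME_TOO_LONG:
        return _case(
            "over-long data name",
            code,
            seed,
            f"data_a{suffix}\n_{'x' * 80} ?\n",
            f"data_a{suffix}\n_{'x' * 79} ?\n",
        )
    if code is C.STRING_FORMAT:
        return _case(
            "unterminated quoted string",
            code,
            seed,
            f"data_a{suffix}\n_publ_section_title 'unterminated\n",
            f"data_a{suffix}\n_publ_section_title 'terminated'\n",
        )
    if code is C.NON_ASCII:
        return _case(
            "non-ASCII character under CIF 1.1",
            code,
            seed,
            f"data_a{suffix}\n_publ_section_title 'the α polymorph'\n",
            f"data_a{suffix}\n_publ_section_title 'the alpha polymorph'\n",
        )
    if code is C.TYPE_MISMATCH:
        return _case(
            "text where a number is required",
            code,
            seed,
            f"data_a{suffix}\n_cell_volume big\n",
            f"data_a{suffix}\n_cell_volume {volume}\n",
        )
    if code is C.RANGE_VIOLATION:
        return _case(
            "formula weight below its lower bound",
            code,
            seed,
            f"data_a{suffix}\n_chemical_formula_weight 0.9\n",
            f"data_a{suffix}\n_chemical_formula_weight 180.16\n",
        )
    if code is C.ENUM_VIOLATION:
        return _case(
            "cell setting outside the enumeration",
            code,
            seed,
            f"data_a{suffix}\n_symmetry_cell_setting pentagonal\n",
            f"data_a{suffix}\n_symmetry_cell_setting orthorhombic\n",
        )
    if code is C.NONSTANDARD_NAME:
        return _case(
            "private data name",
            code,
            seed,
            f"data_a{suffix}\n_my_private_tag 5\n",
            f"data_a{suffix}\n_cell_volume {volume}\n",
            severity=Severity.WARNING,
        )
    if code is C.RESERVED_CONSTRUCT:
        return _case(
            "STAR reserved word in a data file",
            code,
            seed,
            f"data_a{suffix}\nglobal_\n_cell_volume {volume}\n",
            f"data_a{suffix}\n_cell_volume {volume}\n",
            severity=Severity.WARNING,
        )
    raise ValueError(f"no fixture defined for {code}")


#: The thirteen syntactic error codes, in the order they are checked.
SYNTAX_ERROR_CODES: tuple[DiagnosticCode, ...] = (
    DiagnosticCode.EMPTY_FILE,
    DiagnosticCode.EMPTY_DATA_BLOCK,
    DiagnosticCode.MISSING_BLOCK_CODE,
    DiagnosticCode.MISSING_DATA_IDENTIFIER,
    DiagnosticCode.DUPLICATE_BLOCK_CODE,
    DiagnosticCode.DUPLICATE_DATA_NAME,
    DiagnosticCode.INVALID_LOOP,
    DiagnosticCode.MISSING_VALUE,
    DiagnosticCode.UNCLOSED_SAVE_FRAME,
    DiagnosticCode.LINE_TOO_LONG,
    DiagnosticCode.NAME_TOO_LONG,
    DiagnosticCode.STRING_FORMAT,
    DiagnosticCode.NON_ASCII,
)

#: Every code the generator covers (syntax, dictionary checks and warnings).
ALL_CASE_CODES: tuple[DiagnosticCode, ...] = SYNTAX_ERROR_CODES + (
    DiagnosticCode.TYPE_MISMATCH,
    DiagnosticCode.RANGE_VIOLATION,
    DiagnosticCode.ENUM_VIOLATION,
    DiagnosticCode.NONSTANDARD_NAME,
    DiagnosticCode.RESERVED_CONSTRUCT,
)


def fixture_suite(seed: int = 0) -> list[FixtureCase]:
    return [generate_error_case(code, seed) for code in ALL_CASE_CODES]


# -- miniature dictionaries -------------------------------------------------


@dataclass(frozen=True)
class DefinitionSpec:
    """Parameters for one generated dictionary definition."""

    name: str
    content_type: ContentType = ContentType.ANY
    range: Optional[ValueRange] = None
    enumeration: Optional[frozenset[str]] = None
    description: str = ""


def _format_bound(bound: Optional[float]) -> str:
    return repr(bound) if bound is not None else ""


def generate_mini_dictionary(spec: Sequence[DefinitionSpec], seed: int = 0) -> str:
    """Emit a DDLm save-frame dictionary that loads back field-for-field."""
    names = [d.name for d in spec]
    if len(set(names)) != len(names):
        raise ValueError("definition names must be unique")
    lines = [CIF2_MAGIC, f"data_MINI_FIXTURE_DIC_{seed}", "_dictionary.title MINI_FIXTURE_DIC", ""]
    type_text = {
        ContentType.INTEGER: "Integer",
        ContentType.REAL: "Real",
        ContentType.TEXT: "Text",
    }
    for definition in spec:
        lines.append(f"save_{definition.name}")
        lines.append(f"_definition.id '{definition.name}'")
        if definition.description:
            lines.append("_description.text")
            lines.append(";")
            lines.append(definition.description)
            lines.append(";")
        if definition.content_type is not ContentType.ANY:
            lines.append(f"_type.contents {type_text[definition.content_type]}")
        if definition.range is not None:
            # Quoted: an open lower endpoint (":10") would otherwise start
            # with a bare colon, which CIF 2.0 lexes as a table delimiter.
            lines.append(
                "_enumeration.range "
                f"'{_format_bound(definition.range.minimum)}:{_format_bound(definition.range.maximum)}'"
            )
            if definition.range.min_exclusive or definition.range.max_exclusive:
                flag = (
                    "both"
                    if definition.range.min_exclusive and definition.range.max_exclusive
                    else ("min" if definition.range.min_exclusive else "max")
                )
                lines.append(f"_enumeration.range_exclusive {flag}")
        if definition.enumeration:
            lines.append("loop_")
            lines.append("_enumeration_set.state")
            for state in sorted(definition.enumeration):
                lines.append(f"'{state}'")
        lines.append("save_")
        lines.append("")
    return "\n".join(lines)


def random_definition_specs(n: int, seed: int) -> list[DefinitionSpec]:
    """n seeded random definition specs, for generator/loader round-trips."""
    rng = random.Random(seed)
    words = ["alpha", "beta", "gamma", "delta", "omega", "site", "cell", "flag", "axis", "index"]
    specs: list[DefinitionSpec] = []
    used: set[str] = set()
    for i in range(n):
        name = f"_fixture_{rng.choice(words)}_{rng.choice(words)}_{i}"
        while name in used:
            name = name + "x"
        used.add(name)
        content_type = rng.choice(list(ContentType))
        value_range = None
        enumeration = None
        if content_type in (ContentType.INTEGER, ContentType.REAL) and rng.random() < 0.7:
            lo: Optional[float] = None
            hi: Optional[float] = None
            if rng.random() < 0.8:
                lo = float(rng.randint(-50, 50))
            if rng.random() < 0.8:
                hi = (lo if lo is not None else 0.0) + rng.randint(1, 100)
            if lo is not None or hi is not None:
                value_range = ValueRange(
                    minimum=lo,
                    maximum=hi,
                    min_exclusive=lo is not None and rng.random() < 0.3,
                    max_exclusive=hi is not None and rng.random() < 0.3,
                )
        if content_type is ContentType.TEXT and rng.random() < 0.5:
            enumeration = frozenset(rng.sample(words, rng.randint(2, 5)))
        description = f"Synthetic definition {i} about {rng.choice(words)}."
        specs.append(
            DefinitionSpec(
                name=name,
                content_type=content_type,
                range=value_range,
                enumeration=enumeration,
                description=description,
            )
        )
    return specs
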