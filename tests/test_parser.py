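"""Parser tests: tree shape, loop arithmetic, navigation, error tolerance."""

import pytest

from ciflint.fixtures import generate_valid_cif
from ciflint.lexer import CifVersion, SourcePosition, TokenKind, tokenize
from ciflint.parser import (
    Item,
    Loop,
    PathRole,
    SaveFrame,
    StrayValue,
    Value,
    ValueKind,
    dump,
    items_of,
    parse,
    path_of,
    value_text,
)

V1 = CifVersion.V1_1
V2 = CifVersion.V2_0


def parse_text(text, version=V1):
    return parse(tokenize(text, version), version)


def test_minimal_well_formed_file():
    document, diagnostics = parse_text("data_x\n_a 1\n")
    assert diagnostics == []
    assert len(document.blocks) == 1
    block = document.blocks[0]
    assert block.code == "x"
    (item,) = block.content
    assert isinstance(item, Item)
    assert item.tag == "_a"
    assert item.value.kind is ValueKind.NUMBER
    assert item.value.number.value == 1.0


def test_loop_rows_partition():
    document, diagnostics = parse_text(
        "data_x\nloop_\n_t1\n_t2\nv11 v12\nv21 v22\n"
    )
    assert diagnostics == []
    (loop,) = document.blocks[0].content
    assert isinstance(loop, Loop)
    assert loop.well_formed and loop.n_rows == 2
    # row r, column c is values[r*|tags| + c]
    assert value_text(loop.values[1 * 2 + 0]) == "v21"


def test_items_of_expands_loops_row_major():
    document, _ = parse_text("data_x\n_a 1\nloop_\n_t1\n_t2\nv11 v12 v21 v22\n")
    associations = items_of(document, "X")  # case-insensitive block lookup
    assert [(t, value_text(v)) for t, v in associations] == [
        ("_a", "1"),
        ("_t1", "v11"),
        ("_t2", "v12"),
        ("_t1", "v21"),
        ("_t2", "v22"),
    ]
    assert items_of(document, "no_such_block") == []


def test_items_of_empty_block():
    document, _ = parse_text("data_empty\n")
    assert items_of(document, "empty") == []


def test_value_ownership_in_loop(fig_fragment):
    document, diagnostics = parse_text(fig_fragment)
    assert diagnostics == []
    associations = items_of(document, "96107abs")
    assert ("_atom_site_fract_z", "0.52011(3)") in [
        (t, v.raw) for t, v in associations
    ]
    (loop,) = document.blocks[0].content
    owner = [(t, v.raw) for t, v in zip(
        [loop.tags[i % len(loop.tags)] for i in range(len(loop.values))],
        loop.values,
    )]
    assert owner[3] == ("_atom_site_fract_z", "0.52011(3)")


def test_path_of_positions(fig_fragment):
    document, _ = parse_text(fig_fragment)
    line = fig_fragment.split("\n")[6]
    path = path_of(document, SourcePosition(6, line.index("0.52011")))
    assert [(e.role, e.label) for e in path.entries] == [
        (PathRole.BLOCK, "data_96107abs"),
        (PathRole.LOOP, "loop_"),
        (PathRole.TAG, "_atom_site_fract_z"),
        (PathRole.VALUE, "0.52011(3)"),
    ]
    # on a tag the chain ends at TAG
    tag_path = path_of(document, SourcePosition(5, 3))
    assert tag_path.entries[-1].role is PathRole.TAG
    # outside any block / on nothing
    assert path_of(document, SourcePosition(99, 0)) is None


def test_path_of_index_arithmetic():
    # 7th value (index 6) of a 3-tag loop belongs to the loop's 1st tag.
    text = "data_x\nloop_\n_c1\n_c2\n_c3\na b c\nd e f\ng h i\n"
    document, _ = parse_text(text)
    path = path_of(document, SourcePosition(7, 0))  # value "g"
    assert path.entries[-2].label == "_c1"
    assert path.entries[-1].label == "g"


def test_path_of_skips_comments():
    document, _ = parse_text("data_x\n# a comment\n_a 1\n")
    assert path_of(document, SourcePosition(1, 3)) is None


def test_missing_value_placeholder():
    document, _ = parse_text("data_x\n_a\n_b 2\n")
    first = document.blocks[0].content[0]
    assert first.value.is_placeholder
    assert first.value.range.start == first.value.range.end


def test_bare_data_header_is_block_with_empty_code():
    document, _ = parse_text("data_\n_a 1\n")
    assert len(document.blocks) == 1
    assert document.blocks[0].code == ""
    assert len(document.blocks[0].content) == 1


def test_leading_content_recorded():
    document, _ = parse_text("_early 1\ndata_x\n_a 1\n")
    assert [t.kind for t in document.leading] == [TokenKind.TAG, TokenKind.NUMBER]


def test_stray_value_kept_and_diagnosed():
    document, diagnostics = parse_text("data_x\nlonely\n_a 1\n")
    block = document.blocks[0]
    assert any(isinstance(n, StrayValue) for n in block.content)
    assert diagnostics  # never dropped silently
    # descent resumed: the item after the stray value is still parsed
    assert any(isinstance(n, Item) and n.tag == "_a" for n in block.content)


def test_save_frames_and_nesting():
    document, _ = parse_text("data_d\nsave_one\n_a 1\nsave_\nsave_two\n_b 2\n")
    frames = [n for n in document.blocks[0].content if isinstance(n, SaveFrame)]
    assert [f.code for f in frames] == ["one", "two"]
    assert frames[0].closed and not frames[1].closed
    # nested save_ header ends the current frame and opens a sibling
    document2, _ = parse_text("data_d\nsave_outer\nsave_inner\n_a 1\nsave_\n")
    frames2 = [n for n in document2.blocks[0].content if isinstance(n, SaveFrame)]
    assert [f.code for f in frames2] == ["outer", "inner"]
    assert not frames2[0].closed and frames2[1].closed


def test_cif2_list_and_table_values():
    text = "#\\#CIF_2.0\ndata_x\n_l [1 2 [3 4] ]\n_t {'k':5 'm':'v' }\n"
    document, diagnostics = parse_text(text, V2)
    assert diagnostics == []
    items = {n.tag: n.value for n in document.blocks[0].content}
    lst = items["_l"]
    assert lst.kind is ValueKind.LIST and len(lst.elements) == 3
    assert lst.elements[2].kind is ValueKind.LIST
    table = items["_t"]
    assert table.kind is ValueKind.TABLE
    assert [(k, value_text(v)) for k, v in table.entries] == [("k", "5"), ("m", "v")]


def test_cif2_malformed_table_key_diagnosed():
    text = "#\\#CIF_2.0\ndata_x\n_t {bad:5 }\n"
    _document, diagnostics = parse_text(text, V2)
    assert any("quoted" in d.message for d in diagnostics)


def test_token_conservation():
    """Every tag and value token of a clean file lands in exactly one node."""
    text = generate_valid_cif(3, n_blocks=2, n_loops=3, version=V1)
    tokens = tokenize(text, V1)
    document, _ = parse_text(text)
    expected_tags = [t.lexeme for t in tokens if t.kind is TokenKind.TAG]
    got_tags = []
    for block in document.blocks:
        for node in block.content:
            if isinstance(node, Item):
                got_tags.append(node.tag)
            elif isinstance(node, Loop):
                got_tags.extend(node.tags)
    assert sorted(got_tags) == sorted(expected_tags)


def test_parse_is_deterministic():
    text = generate_valid_cif(4, version=V1)
    a = parse_text(text)
    b = parse_text(text)
    assert dump(a[0]) == dump(b[0]) and len(a[1]) == len(b[1]) == 0


def test_dump_is_indented(fig_fragment):
    document, _ = parse_text(fig_fragment)
    lines = dump(document).split("\n")
    assert lines[0] == "data_96107abs"
    assert lines[1].startswith("  loop_")
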