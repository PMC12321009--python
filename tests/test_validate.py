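"""Linter tests: every diagnostic code, thresholds, charset, dictionary checks."""

import pytest

from ciflint.diagnostics import DiagnosticCode, Severity
from ciflint.fixtures import ALL_CASE_CODES, generate_error_case, generate_valid_cif
from ciflint.lexer import CifVersion
from ciflint.validate import LintOptions, lint

V1 = CifVersion.V1_1
V2 = CifVersion.V2_0


def error_codes(diagnostics):
    return sorted(d.code.name for d in diagnostics if d.severity is Severity.ERROR)


def warning_codes(diagnostics):
    return sorted(d.code.name for d in diagnostics if d.severity is Severity.WARNING)


@pytest.mark.parametrize("code", ALL_CASE_CODES, ids=lambda c: c.name.lower())
@pytest.mark.parametrize("seed", [0, 17])
def test_each_fixture_case_produces_exactly_its_code(code, seed, store):
    """Each planted defect yields its code and nothing else at error severity,
    and the repaired twin lints without errors."""
    case = generate_error_case(code, seed)
    options = LintOptions(version_override=case.version)
    diagnostics = lint(case.source_text, options, store)
    if case.severity is Severity.ERROR:
        assert error_codes(diagnostics) == sorted(c.name for c in case.expected_codes)
    else:
        assert error_codes(diagnostics) == []
        assert code.name in warning_codes(diagnostics)
    repaired = lint(case.repaired_text, options, store)
    assert error_codes(repaired) == []


def test_well_formed_fixture_lints_empty(store):
    for version in (V1, V2):
        text = generate_valid_cif(9, n_blocks=2, n_loops=3, version=version)
        assert lint(text, LintOptions(), store) == []


def test_empty_file_reports_only_empty_file(store):
    diagnostics = lint("", LintOptions(), store)
    assert [d.code for d in diagnostics] == [DiagnosticCode.EMPTY_FILE]
    diagnostics = lint("# just\n# comments\n", LintOptions(), store)
    assert [d.code for d in diagnostics] == [DiagnosticCode.EMPTY_FILE]


@pytest.mark.parametrize(
    "length,flagged", [(2047, False), (2048, False), (2049, True)]
)
def test_line_length_threshold_is_sharp(length, flagged, store):
    text = f"data_a\n{'#' + 'x' * (length - 1)}\n_cell_volume 100.0\n"
    diagnostics = lint(text, LintOptions(), store)
    assert (DiagnosticCode.LINE_TOO_LONG in {d.code for d in diagnostics}) is flagged


@pytest.mark.parametrize("length,flagged", [(79, False), (80, False), (81, True)])
def test_name_length_threshold_is_sharp(length, flagged, store):
    text = f"data_a\n_{'x' * (length - 1)} ?\n"
    diagnostics = lint(text, LintOptions(), store)
    assert (DiagnosticCode.NAME_TOO_LONG in {d.code for d in diagnostics}) is flagged


def test_configurable_limits():
    options = LintOptions(max_line_length=10, max_name_length=5)
    text = "data_a\n# a longer line\n_abcdef 1\n"
    codes = {d.code for d in lint(text, options)}
    assert DiagnosticCode.LINE_TOO_LONG in codes
    assert DiagnosticCode.NAME_TOO_LONG in codes


def test_non_ascii_only_under_cif11(store):
    text = "data_x\n_publ_section_title 'α'\n"
    v1 = lint(text, LintOptions(version_override=V1), store)
    assert DiagnosticCode.NON_ASCII in {d.code for d in v1}
    v2 = lint(text, LintOptions(version_override=V2), store)
    assert DiagnosticCode.NON_ASCII not in {d.code for d in v2}
    clean = lint("data_x\n_cell_volume 100.0\n", LintOptions(version_override=V1), store)
    assert clean == []


def test_non_ascii_position_points_at_character(store):
    text = "data_x\n_publ_section_title 'aβc'\n"
    (diag,) = [d for d in lint(text, LintOptions(), store) if d.code is DiagnosticCode.NON_ASCII]
    assert diag.range.start.line == 1
    assert text.split("\n")[1][diag.range.start.column] == "β"


def test_duplicate_names_scoped_per_save_frame(store):
    # dictionaries legitimately reuse attribute tags across save frames
    text = (
        "data_d\n"
        "save_one\n_definition.id '_x'\nsave_\n"
        "save_two\n_definition.id '_y'\nsave_\n"
    )
    diagnostics = lint(text, LintOptions(warn_nonstandard=False))
    assert DiagnosticCode.DUPLICATE_DATA_NAME not in {d.code for d in diagnostics}
    text2 = "data_d\nsave_one\n_a 1\n_a 2\nsave_\n"
    diagnostics2 = lint(text2, LintOptions(warn_nonstandard=False))
    assert DiagnosticCode.DUPLICATE_DATA_NAME in {d.code for d in diagnostics2}


@pytest.mark.parametrize("placeholder", ["?", "."])
def test_placeholders_exempt_from_value_checks(placeholder, store):
    text = f"data_x\n_chemical_formula_weight {placeholder}\n"
    assert lint(text, LintOptions(), store) == []


def test_enum_membership_is_case_insensitive(store):
    text = "data_x\n_symmetry_cell_setting Orthorhombic\n"
    assert lint(text, LintOptions(), store) == []


def test_quoted_enum_value_accepted(store):
    text = "data_x\n_symmetry_cell_setting 'orthorhombic'\n"
    assert lint(text, LintOptions(), store) == []


def test_integer_type_rejects_fraction_and_su(store):
    base = "data_x\n_symmetry_int_tables_number {}\n"
    assert lint(base.format("14"), LintOptions(), store) == []
    for bad in ("14.5", "14(2)", "fourteen"):
        codes = {d.code for d in lint(base.format(bad), LintOptions(), store)}
        assert DiagnosticCode.TYPE_MISMATCH in codes, bad


def test_range_checks_ignore_su(store):
    # the su in parentheses is ignored for range purposes
    text = "data_x\n_atom_site_occupancy 0.999(5)\n"
    assert lint(text, LintOptions(), store) == []


def test_range_violation_in_loop_cell(store):
    text = (
        "data_x\nloop_\n_atom_site_label\n_atom_site_occupancy\n"
        "C1 0.5\nC2 1.5\n"
    )
    violations = [
        d for d in lint(text, LintOptions(), store) if d.code is DiagnosticCode.RANGE_VIOLATION
    ]
    assert len(violations) == 1
    assert violations[0].range.start.line == 5  # the 1.5 cell


def test_warn_nonstandard_toggle_only_removes_warnings(store):
    text = "data_x\n_my_private_tag 5\n_chemical_formula_weight 0.5\n"
    with_warn = lint(text, LintOptions(warn_nonstandard=True), store)
    without = lint(text, LintOptions(warn_nonstandard=False), store)
    assert error_codes(with_warn) == error_codes(without) == ["RANGE_VIOLATION"]
    assert "NONSTANDARD_NAME" in warning_codes(with_warn)
    assert "NONSTANDARD_NAME" not in warning_codes(without)


def test_reserved_construct_is_warning(store):
    diagnostics = lint("data_x\nstop_\n_cell_volume 1.0\n", LintOptions(), store)
    (reserved,) = [d for d in diagnostics if d.code is DiagnosticCode.RESERVED_CONSTRUCT]
    assert reserved.severity is Severity.WARNING


def test_lint_output_sorted_and_deterministic(store):
    text = (
        "data_x\n"
        "_cell_volume 100.0\n"
        "_cell_volume 100.0\n"
        "_chemical_formula_weight 0.5\n"
    )
    first = lint(text, LintOptions(), store)
    second = lint(text, LintOptions(), store)
    assert first == second
    assert [d.code.name for d in first] == ["DUPLICATE_DATA_NAME", "RANGE_VIOLATION"]
    starts = [(d.range.start.line, d.range.start.column) for d in first]
    assert starts == sorted(starts)


def test_crlf_input_is_normalised(store):
    text = "data_x\r\n_cell_volume 100.0\r\n"
    assert lint(text, LintOptions(), store) == []


def test_human_and_json_renderings():
    diagnostics = lint("data_dup\n_a 1\ndata_dup\n_b 2\n", LintOptions(warn_nonstandard=False))
    (diag,) = diagnostics
    human = diag.format_human("f.cif")
    assert human.startswith("f.cif:3:1 [DUPLICATE_BLOCK_CODE]")
    payload = diag.to_dict()
    assert payload["range"]["start"] == {"line": 2, "column": 0}
    assert payload["severity"] == "error"
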