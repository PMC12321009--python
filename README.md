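# ciflint

Editor-independent language tooling for crystallographic information files
(CIF). Crystallographers routinely open CIFs in a plain text editor — to fix
syntax before depositing with the CSD, ICSD or COD, to adjust bibliographic
items before journal submission, or simply to read a structure published by
another group. `ciflint` provides the analysis layer such editing needs,
as a Python library and a small CLI:

* a **regex-table lexer** for CIF 1.1 and (limited) CIF 2.0: an ordered table
  of regular expressions is tried at each offset, the first match wins, and
  every token carries its source range. CIF 1.1 is ASCII-only with one
  quoted-string subtlety (an embedded quote not followed by whitespace stays
  inside the string, so `'O'Neil'` is one string); CIF 2.0 adds Unicode,
  triple-quoted strings, lists `[...]` and tables `{...}`. The version is
  chosen by the `#\#CIF_2.0` magic comment on line 1, overridable.
* an **error-tolerant recursive-descent parser** that connects every data
  value to its data name, loop, save frame and data block, and keeps working
  past errors by resynchronising at the next structural token;
* a **linter** covering the common syntactic mistakes in deposited CIFs
  (empty files/blocks, missing or duplicate block codes, duplicate data
  names, invalid loop structures — a loop must hold a multiple of its tag
  count in values —, missing values, unclosed save frames, lines over
  2048 characters, data names over 80 characters, string-format errors,
  non-ASCII characters in CIF 1.1);
* **dictionary-driven validation**: DDLm-style dictionaries (themselves CIF
  files, parsed with the same parser) supply each data name's description,
  content type, permitted range and enumeration; values are checked against
  them, with `?` (unknown) and `.` (inapplicable) always exempt, and
  non-standard names warned about (opt-out);
* **editor assistance**: hover information rendering the
  block ▸ loop ▸ tag ▸ value hierarchy plus the dictionary description, and
  dictionary-driven name completion (`_publ` lists the publ category;
  `_author` finds matches across _audit, _publ and _citation);
* a **TextMate grammar emitter** for declarative syntax highlighting.

## Worked example

```sh
$ cat demo.cif
data_demo
_cell_volume        1542.6(3)
_chemical_formula_weight   0.9
_symmetry_cell_setting     pentagonal
loop_
_atom_site_label
_atom_site_fract_z
S1 0.52011(3)
O1

$ ciflint lint demo.cif
demo.cif:3:28 [RANGE_VIOLATION] '_chemical_formula_weight' value 0.9 is outside the permitted range
demo.cif:4:28 [ENUM_VIOLATION] '_symmetry_cell_setting' value 'pentagonal' is not one of the allowed enumerations
demo.cif:5:1 [INVALID_LOOP] loop_ has 3 values for 2 data names (not a multiple)
```

The formula weight must be a real number larger than 1.0, the cell setting
must be one of the crystal systems (e.g. `orthorhombic`), and the loop holds
three values for two data names. Exit status is 1 (errors found), 0 (clean)
or 2 (usage/IO failure). `--format json` emits the same diagnostics with
0-based ranges, byte-stably.

Hovering resolves a position to its place in the hierarchy — here the value
`0.52011(3)` (0.52011 with a standard uncertainty of 3 in the last digit):

```sh
$ ciflint hover demo.cif --line 8 --col 5
data_demo
  loop_
    _atom_site_fract_z
      0.52011(3)

$ ciflint complete --fragment _author
_audit_author_name	core_fixture	Name of an author of the current data block.
_citation_author_id	core_fixture	Identifier linking an author to a citation record.
_publ_author_name	core_fixture	Name of a publication author in 'Family, Given' form.
```

A miniature core dictionary is bundled; real IUCr dictionaries (or your own)
can be registered with `ciflint dict add my.dic` and inspected with
`ciflint dict list` / removed with `ciflint dict remove` (bundled ones
cannot be removed). `ciflint grammar` prints the TextMate grammar and
`ciflint fixtures --out DIR` writes the synthetic test files.

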