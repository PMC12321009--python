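# Methods

## Lexing: the regex rule table

The lexer is a regex-table design: an ordered list of (token kind, regular
expression) rules, tried top to bottom at each offset with the first match
winning. The order is semantic — the `save_`-terminator rule precedes the
save-frame-header rule, keywords (`data_`, `loop_`, `save_`, `global_`,
`stop_`, all case-insensitive) precede the generic unquoted-string rule, and
the number rule precedes it too, so `90.00` is a NUMBER but `90.00x` an
unquoted string. Rules exist in a CIF 1.1 and a CIF 2.0 column; the 2.0
column activates triple-quoted strings, list/table punctuation, and stricter
single/double-quote rules (CIF 1.1 lets an embedded quote that is not
followed by whitespace stay inside the string), and its unquoted rule
excludes `]` and `}` so list/table closers terminate bare values.

Decisions a lexer of this kind has to make, and how this one makes them:

* **Totality.** Editor tooling cannot crash on bad input. A character no
  rule matches (possible only under CIF 2.0 — e.g. `]` not followed by
  whitespace, which fails both the list-end rule's lookahead and the
  unquoted rule) becomes a one-character token flagged as an error, which
  the validator reports as a string-format diagnostic.
* **Whitespace is kept.** WHITESPACE and NEWLINE are ordinary tokens, so
  concatenating all lexemes reproduces the input exactly; the round-trip
  property is tested on arbitrary text (hypothesis) and on 1000 generated
  files.
* **Multi-line text fields.** The rule requires a preceding newline (`;`
  is only special in column 0); the consumed newline belongs to the token.
  Offset 0 is treated as "after a newline" so a file starting with `;`
  still opens a text field.
* **Line endings.** `\r\n` is normalised to `\n` before analysis (the rule
  table is written against `\n`); columns are unaffected, so diagnostic
  positions are valid for the original file.
* **Version detection.** The `#\#CIF_2.0` magic comment on line 1 selects
  CIF 2.0; anything else is CIF 1.1. An explicit override (API argument,
  `--cif-version`) wins.
* **Positions** are 0-based line/character-column pairs with end-exclusive
  ranges, the convention editor protocols use; the CLI prints 1-based.

Numbers carry their parenthesised standard uncertainty: `0.52011(3)` parses
to value 0.52011 with su digits "3". The su is kept as text (it scales with
the last decimal place) and is ignored for range comparisons.

## Parsing and error recovery

The parser is a hand-written recursive descent over the significant tokens
(whitespace, newlines and comments skipped). It produces a tree —
Document → DataBlock → {Item, Loop, SaveFrame, ...} — in file order, with a
source range on every node, so any position can be resolved to its
block ▸ [save] ▸ [loop] ▸ tag ▸ value chain (the hover hierarchy). Loop
cells are associated row-major: value *i* belongs to tag *i* mod |tags|.

Recovery strategy (the design was open; this is the package's choice): on an
unexpected token, record it, queue a diagnostic, and resume at the next
anchor (tag, `loop_`, `data_`, save-frame boundary, reserved word). Specific
cases:

* a bare value with no preceding tag is kept as a stray-value node and
  diagnosed — never dropped, so token conservation holds;
* a tag with no value gets a zero-width UNKNOWN placeholder; the validator
  reports the missing value;
* a bare `data_` (no block code) still opens a block, with an empty code,
  so its content is not cascaded into other diagnostics;
* a `save_` header inside an open frame ends the current frame (left
  unclosed, hence diagnosed) and opens a sibling — CIF does not nest frames;
* CIF 2.0 lists and tables parse recursively; a table key must be a quoted
  string followed by `:`, and violations are string-format diagnostics.

## Diagnostics

Eighteen codes: thirteen syntactic ones (empty file, empty data block,
missing block code, content before any data block, duplicate block code,
duplicate data name, invalid loop, missing value, unclosed save frame, line
over the limit, name over the limit, string-format error, non-ASCII under
CIF 1.1), a reserved-construct notice for the STAR words `global_`/`stop_`
(valid STAR, unused in CIF data files), and four dictionary checks
(non-standard name, type mismatch, range violation, enumeration violation).
Severity: non-standard names and reserved constructs are warnings,
everything else an error. Output is sorted by position then code, so
repeated runs are byte-identical.

Choices on the underdetermined points:

* "Missing data identifier" is read as content appearing before any
  `data_` block — the reading most distinct from "missing block code".
* Duplicate-name scope is the data block, with each save frame its own
  scope: dictionaries legitimately reuse attribute tags across frames.
* The 2048-character line limit counts characters excluding the
  terminator; the 80-character name limit counts the full tag including
  the leading underscore. Both are sharp (length L passes, L+1 fails) and
  configurable via LintOptions.
* The integer content-type check requires a numeric value with no decimal
  point, no fraction and no standard uncertainty.
* Range checks compare the numeric part only; enumeration membership is
  case-insensitive on the unquoted value text.
* `?` and `.` are exempt from all value checks (CIF semantics of unknown /
  inapplicable).
* Disabling the non-standard-name warning removes only those warnings;
  error output is unchanged (tested as a monotonicity property).

## Dictionaries

Dictionaries are parsed with the same lexer/parser (they are CIF files).
From each save frame (DDLm) or data block (flat dialect) the loader reads
the definition name (`_definition.id`/`_name`), description
(`_description.text`/`_definition`), content type (`_type.contents`/`_type`:
"Integer"→integer, "Real"/"numb"→real, other stated types→text, absent→any),
permitted range (`_enumeration.range`, "min:max", an omitted endpoint
unbounded) and enumeration states (`_enumeration_set.state` loop). DDLm
range endpoints are inclusive by default; exclusivity is a per-definition
flag read from the fixture-dialect tag `_enumeration.range_exclusive`
(`min`/`max`/`both`). The bundled miniature core dictionary uses it to
encode "formula weight strictly greater than 1.0". Full DDLm (imports,
dREL methods, category relations) is deliberately not interpreted.

The store maps lower-cased names to definitions; later-loaded dictionaries
shadow earlier ones, so user-added dictionaries override bundled ones. The
registry of user dictionaries is a small JSON file (default under
`~/.config/ciflint/`, overridable); bundled dictionaries cannot be removed.

## Assistance

Hover renders the hierarchy path one line per level, two spaces of
indentation per step, and appends the dictionary description when the
hovered element is a defined tag. Completion matches the typed fragment
case-insensitively against all definition names: prefix matches rank before
interior matches (fragment with its leading underscore stripped), each rank
alphabetical — so `_author` surfaces `_audit_author_name`,
`_citation_author_id` and `_publ_author_name` across categories. The
ranking rule is this package's choice.

## Synthetic fixtures

The generator is first-class, tested code and defines the conditions the
test suite runs under:

* `generate_valid_cif(seed, n_blocks, n_loops, version)` emits multi-block
  CIFs using only bundled-dictionary names with values inside their
  permitted ranges, so a clean file lints with no errors and no warnings.
  Every quoting style legal for the version appears in every block
  (unquoted, single, double, multi-line; under 2.0 also triple-quoted,
  list and table), and loops draw from disjoint tag pools so several can
  share a block without duplicate names. Defaults (2 blocks, 2 loops, 2–4
  loop rows) keep each file at realistic small-CIF scale; the round-trip
  suite runs 1000 of them in about a second.
* `generate_error_case(code, seed)` plants exactly one defect per
  diagnostic code and carries the repaired twin; the fixture invariant
  (exactly that code at its severity, repaired file error-free) is asserted
  for all eighteen codes at two seeds.
* `generate_mini_dictionary(spec, seed)` emits DDLm save-frame text that
  loads back field-for-field; the round-trip is tested with 50 seeded
  random definitions. Range values are quoted because an open lower
  endpoint (`:10`) would otherwise lex its leading colon as table
  punctuation under CIF 2.0.

What the fixtures do **not** emulate: real refinement output (hkl/res
embedded blocks, tens of thousands of lines), mmCIF category conventions,
dictionary imports, or files with mixed encodings. Passing tests therefore
demonstrate correctness of the language layer on representative small
files, not performance or coverage of every real-world CIF idiom.

On the parser side, correctness on clean files is additionally
cross-checked against gemmi's CIF reader (block → tag → value maps must
agree exactly); gemmi is used only as an independent oracle, never as the
implementation.

## Known limitations

* Whole-document analysis only; no incremental re-lexing.
* CIF 2.0 support is limited to the constructs in the rule table; notably
  a greedy triple-quote rule (two triple-quoted strings on one line would
  over-match) and no `'''`-spanning-newline strings.
* No CIF writing/reformatting, no semantic block merging, no
  crystallographic plausibility checks (that is a deposition service's
  job), no network access.
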