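#\#CIF_2.0
# Miniature core dictionary for offline use: a hand-written DDLm-style
# fixture covering the data names the test fixtures and examples exercise.
# It is a synthetic stand-in for the COMCIFS core dictionary, not a copy.
data_CORE_FIXTURE_DIC

_dictionary.title CORE_FIXTURE_DIC
_dictionary.version 1.0

save__cell_length_a
_definition.id '_cell_length_a'
_description.text
;
Length of the a axis of the unit cell in angstroms.
;
_type.contents Real
_enumeration.range 0.:
_enumeration.range_exclusive min
save_

save__cell_angle_alpha
_definition.id '_cell_angle_alpha'
_description.text
;
Angle between the b and c axes of the unit cell in degrees.
;
_type.contents Real
_enumeration.range 0.:180.
save_

save__cell_volume
_definition.id '_cell_volume'
_description.text
;
Volume of the unit cell in cubic angstroms.
;
_type.contents Real
_enumeration.range 0.:
_enumeration.range_exclusive min
save_

save__chemical_formula_weight
_definition.id '_chemical_formula_weight'
_description.text
;
Mass of the formula unit in daltons; must be a real number larger than 1.0.
;
_type.contents Real
_enumeration.range 1.0:
_enumeration.range_exclusive min
save_

save__chemical_formula_sum
_definition.id '_chemical_formula_sum'
_description.text
;
Chemical formula as element symbols with counts, e.g. 'C11 H9 N O2 S2'.
;
_type.contents Text
save_

save__symmetry_cell_setting
_definition.id '_symmetry_cell_setting'
_description.text
;
Crystal system of the structure; one of a fixed set of cell settings
such as orthorhombic.
;
_type.contents Text
loop_
_enumeration_set.state
'triclinic'
'monoclinic'
'orthorhombic'
'tetragonal'
'trigonal'
'hexagonal'
'cubic'
'rhombohedral'
save_

save__symmetry_int_tables_number
_definition.id '_symmetry_int_tables_number'
_description.text
;
Space-group number from the International Tables for Crystallography,
an integer between 1 and 230.
;
_type.contents Integer
_enumeration.range 1:230
save_

save__diffrn_ambient_temperature
_definition.id '_diffrn_ambient_temperature'
_description.text
;
Mean temperature in kelvins at which the intensities were measured.
;
_type.contents Real
_enumeration.range 0.:
_enumeration.range_exclusive min
save_

save__atom_site_label
_definition.id '_atom_site_label'
_description.text
;
Unique label identifying the atom site.
;
_type.contents Text
save_

save__atom_site_type_symbol
_definition.id '_atom_site_type_symbol'
_description.text
;
Element symbol (possibly with charge) for the atom site.
;
_type.contents Text
save_

save__atom_site_fract_x
_definition.id '_atom_site_fract_x'
_description.text
;
Fractional x coordinate of the atom site relative to the cell axes.
;
_type.contents Real
save_

save__atom_site_fract_y
_definition.id '_atom_site_fract_y'
_description.text
;
Fractional y coordinate of the atom site relative to the cell axes.
;
_type.contents Real
save_

save__atom_site_fract_z
_definition.id '_atom_site_fract_z'
_description.text
;
Fractional z coordinate of the atom site relative to the cell axes.
;
_type.contents Real
save_

save__atom_site_occupancy
_definition.id '_atom_site_occupancy'
_description.text
;
Fraction of the atom type present at this site.
;
_type.contents Real
_enumeration.range 0.:1.
save_

save__publ_author_name
_definition.id '_publ_author_name'
_description.text
;
Name of a publication author in 'Family, Given' form.
;
_type.contents Text
save_

save__publ_section_title
_definition.id '_publ_section_title'
_description.text
;
Title of the publication describing the structure.
;
_type.contents Text
save_

save__citation_author_id
_definition.id '_citation_author_id'
_description.text
;
Identifier linking an author to a citation record.
;
_type.contents Text
save_

save__audit_author_name
_definition.id '_audit_author_name'
_description.text
;
Name of an author of the current data block.
;
_type.contents Text
save_

save__fixture_list_values
_definition.id '_fixture_list_values'
_description.text
;
Synthetic fixture name whose value is a CIF 2.0 list; used only by the
generated test files.
;
save_

save__fixture_table_values
_definition.id '_fixture_table_values'
_description.text
;
Synthetic fixture name whose value is a CIF 2.0 table; used only by the
generated test files.
;
save_
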