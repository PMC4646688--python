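# Bordering (marker) gene definitions for the hematopoietic serine
# protease loci, as conserved across mammalian / fish genomes.
#
# Marker names vary by assembly; the aliases map alternative annotation
# names onto the canonical marker id (matching is case-insensitive).
#
# The granzyme A/K locus ships with empty marker lists: its flanking
# genes are conserved but not standardised by name here, so users must
# supply their own definition for that locus (see docs/methods.md).
definitions:
  chymase:
    left_markers: [RIPK3, NYNRIN, CBLN3, SDR39U1]
    right_markers: [STXBP6]
    center_markers: []
  met-ase:
    # only the centre of this locus is conserved between fish and
    # mammals; identification is anchored on the centre markers, with
    # contiguous flanking protease genes absorbed on either side
    left_markers: []
    right_markers: []
    center_markers: [POLRMT, FGF22, BSG, RNF126, FSTL3]
  fish_chymase:
    left_markers: [RABL3]
    right_markers: [CD276, ERCC1]
    center_markers: []
  granzyme_ak:
    left_markers: []
    right_markers: []
    center_markers: []

aliases:
  FGF22-OR-10-LIKE: FGF22
  FBGF-22-OR-10-LIKE: FGF22
  FGF10-LIKE: FGF22
  FSTL-3: FSTL3
  RABL3-LIKE: RABL3
  CD276-LIKE: CD276
  ERCC-1-LIKE: ERCC1
  ERCC1-LIKE: ERCC1
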