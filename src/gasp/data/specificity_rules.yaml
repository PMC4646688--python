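# Primary-specificity rules keyed on the S1-pocket triplet
# (residues at canonical positions 189, 216, 226).
#
# tier "exact": the triplet is the consensus of a well-characterised
#   enzyme group.  tier "putative": the assignment is a stated
#   likelihood, not a consensus.  label "unknown": the triplet is
#   recognised but no primary specificity can be assigned from it
#   (several fish triplets fall here; phage display has shown such
#   guesses can be wrong, e.g. a GTY enzyme proving to be a tryptase).
#
# Users may extend or override this table; see gasp.classify.load_rules.
triplets:
  DGG: {label: tryptase, tier: exact}            # consensus tryptase / granzyme A/K
  DGA: {label: tryptase, tier: exact}            # chicken CFD variant
  GSD: {label: tryptase, tier: exact}            # PRSS57 / NSP-4 group
  SGA: {label: chymase, tier: exact}             # consensus chymase
  SGG: {label: chymase, tier: putative}          # elephant-shark GzmA/K-like outlier
  SGN: {label: chymase, tier: putative}          # platypus, closest to SGA
  SGR: {label: asp-ase, tier: exact}             # granzyme B consensus
  TGR: {label: asp-ase, tier: exact}
  AGR: {label: asp-ase, tier: exact}
  SGK: {label: asp-ase, tier: putative}          # alligator CtsG-like, closest to SGR
  SGE: {label: chymase_with_tryptase, tier: exact}   # cathepsin G-like (human/chimp)
  AGE: {label: chymase_with_tryptase, tier: exact}   # human cathepsin G
  ASP: {label: met-ase, tier: exact}             # granzyme M consensus
  AST: {label: met-ase, tier: exact}             # rat granzyme M variant
  GVD: {label: elastase, tier: exact}            # N-elastase / proteinase 3
  GID: {label: elastase, tier: exact}
  NVA: {label: elastase, tier: exact}            # rodent alpha-chymase elastases
  NVS: {label: elastase, tier: exact}            # hamster chymase II
  SVN: {label: elastase, tier: putative}         # platypus
  NGE: {label: unknown, tier: unassigned}        # elephant shark, not assignable
  # Fish chymase-locus-related triplets with no mammalian homolog;
  # deliberately unassigned.
  GNN: {label: unknown, tier: unassigned}
  GGN: {label: unknown, tier: unassigned}
  GTH: {label: unknown, tier: unassigned}
  GSS: {label: unknown, tier: unassigned}
  GAY: {label: unknown, tier: unassigned}
  GSY: {label: unknown, tier: unassigned}
  GTY: {label: unknown, tier: unassigned}

# Fallback on position 189 alone, which dominates primary specificity
# (226 is secondary and can be shielded; 216 is least informative).
position_189:
  D: {label: tryptase, tier: putative}
  S: {label: chymase, tier: putative}
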