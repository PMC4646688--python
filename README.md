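# gasp — granule-associated serine protease annotation toolkit

Hematopoietic serine proteases — mast-cell chymases and tryptases,
neutrophil elastase/proteinase 3/cathepsin G, and the lymphocyte
granzymes — are trypsin-family enzymes stored in cytoplasmic granules
and encoded from a handful of conserved chromosomal loci (the chymase,
met-ase and granzyme A/K loci). Comparing them across species relies on
three conventions that `gasp` turns into tested, reusable code:

1. **Canonical chymotrypsinogen numbering.** Residues are named by
   their position in bovine chymotrypsinogen, so His57–Asp102–Ser195
   always denotes the catalytic triad regardless of indels. `gasp`
   assigns these labels by optimal global alignment (Needleman–Wunsch
   with affine gaps, BLOSUM62, gap open −11 / extend −1) against a
   bundled synthetic scaffold with the canonical sites at their
   textbook labels.
2. **S1-pocket specificity triplets.** The residues at canonical
   positions 189, 216 and 226 line the S1 pocket and largely set
   primary cleavage specificity: DGG marks a tryptase (basic P1), SGA a
   chymase (aromatic P1), SGR/TGR/AGR an asp-ase (acidic P1, granzyme
   B), ASP/AST a met-ase (granzyme M), GVD/GID/NVA/NVS an elastase.
   `gasp` extracts the triplet, the triad status (anything other than
   H/D/S at 57/102/195 marks the protein proteolytically inactive, as
   in azurocidin), the Cys93 dimerization feature that separates
   granzyme A dimers from granzyme K monomers, and the Cys191–Cys220
   bridge typical of fish proteases, then classifies the triplet with a
   tiered rule table (exact / putative / unassigned; incomplete
   triplets and broken triads are never force-assigned).
3. **Synteny-based locus identification.** Because protease gene names
   vary wildly between assemblies, loci are located by conserved
   non-protease *bordering genes* (e.g. RIPK3/NYNRIN/CBLN3/SDR39U1 and
   STXBP6 around the mammalian chymase locus). `gasp` reads GFF3/BED,
   finds the run of genes between the innermost matched markers,
   computes gene sizes and intergenic distances, flags marker strand
   inversions against a reference orientation, and renders to-scale SVG
   maps with protease genes drawn at double height.

A distance-phylogenetics module (p-distance / Poisson correction,
neighbor joining, 100-replicate column bootstrap, majority-rule
consensus, Newick I/O) and a synthetic-data simulator (protease
families evolving along trees with planted canonical sites; locus
annotations with duplications, losses and inversions; full replayable
event logs) round out the pipeline. Everything is deterministic under a
fixed seed.

## Worked example

```python
from gasp import profile_sequences
from gasp.simulate import make_root_sequence

sequences = [
    ("granzyme_like",   make_root_sequence(triplet="DGG", cys93=True)),
    ("chymase_like",    make_root_sequence(triplet="SGA")),
    ("azurocidin_like", make_root_sequence(triplet="SGA", triad_intact=False)),
]
table = profile_sequences(sequences)
print(table[["seq_id", "triplet", "triad_intact", "oligomer_call", "label", "tier"]]
      .to_string(index=False))
```

prints

```
         seq_id triplet  triad_intact oligomer_call    label     tier
  granzyme_like     DGG          True         dimer tryptase    exact
   chymase_like     SGA          True       monomer  chymase    exact
azurocidin_like     SGA         False       monomer  unknown inactive
```

Reading the rows: the first sequence carries the consensus tryptase
triplet DGG and an unpaired Cys at canonical 93, so it is called a
dimer-forming tryptase (granzyme A-like). The second carries the
consensus chymase triplet SGA with no Cys93 (granzyme K-style monomer).
The third has the same triplet but Ser195 mutated, so the triad is
broken and the classifier reports it inactive — its triplet carries no
significance, exactly how catalytically dead azurocidin-like proteins
must be treated.

The same machinery is available from the shell:

```bash
gasp profile   --fasta proteases.fasta --out profiles.tsv
gasp locus-map --gff annotation.gff3 --definition chymase --out map.svg
gasp tree      --aln aligned.fasta --model poisson --bootstrap 100 --seed 7 --out tree.nwk
gasp simulate  --seed 11 --out fixtures/
```

## Layout

```
src/gasp/numbering.py   canonical numbering by global alignment
src/gasp/features.py    S1 triplet, triad, cysteine features
src/gasp/classify.py    tiered specificity rules (data/specificity_rules.yaml)
src/gasp/locus.py       synteny locus reconstruction + SVG maps
src/gasp/phylogeny.py   distances, NJ, bootstrap, consensus, Newick
src/gasp/simulate.py    synthetic families/loci with replayable truth
src/gasp/pipeline.py    FASTA -> profile table, end to end
src/gasp/cli.py         `gasp` command-line entry points
docs/methods.md         models, parameters, design notes, limitations
```
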