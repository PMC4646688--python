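# Methods

This note documents the models and procedures `gasp` implements, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish about real genomes.

## Canonical numbering

Chymotrypsin-family proteases are compared on the residue coordinates
of bovine chymotrypsinogen. The field defines these coordinates
implicitly, through multiple alignments of large sequence panels; this
package instead anchors them with **pairwise global alignment to a
single bundled reference scaffold**. Canonical numbering is *defined*
relative to chymotrypsinogen, so a pairwise anchor is a faithful and —
unlike an MSA over a shifting sequence panel — a unit-testable
convention. The trade-off: per-sequence numbering ignores information
from intermediate homologs, so very divergent queries (beyond roughly
30–40 % identity loss, or with indels adjacent to a canonical site) may
mis-map individual labels where an MSA might not. Profiles of such
sequences surface the problem as `absent` residues or broken-triad
calls rather than silent errors.

The bundled scaffold is **synthetic**: 245 residues labelled 1..245,
generated once from a fixed random stream, with the canonical sites
planted at their textbook labels (His57, Asp102, Ser195; Ser189,
Gly216, Gly226; Cys191/Cys220; a non-cysteine at 93). No real database
sequence is required, and the test suite also runs against ad-hoc
scaffolds, so correctness never depends on a particular reference
accession. Which natural sequence would best anchor numbering is a
convention, not a fact this package can decide; users may supply their
own `ReferenceScaffold` (residues + strictly increasing labels + site
registry).

Alignment is Needleman–Wunsch with affine gaps (Gotoh three-state
recurrences): BLOSUM62, gap open −11, gap extend −1 (the conventional
pairing for this matrix class; a gap of length L costs
`open + (L−1)·extend`). `X` scores 0 against everything. Traceback
ties resolve diagonal > up > left (and match-state first within a
direction), making outputs bit-reproducible across platforms. Query
residues falling in reference gaps receive **no label** — no 95A-style
insertion codes, which the numbering convention used here never needs.
Optimality is checked against an independent memoized-recursion oracle
on hundreds of random instances.

## Feature extraction and classification

The S1-pocket triplet is the concatenation of the residues at labels
189, 216, 226 (a `-` where the label falls in a gap). The triad check
demands exactly H/D/S at 57/102/195 — no conservative substitutions —
because catalytic inactivity is treated as binary: a protein with any
triad replacement is reported `inactive` and its triplet is never
interpreted. Cys at 93 ⇒ `dimer`, any other mapped residue ⇒
`monomer`, unmapped ⇒ `indeterminate`; this is a sequence-level
heuristic (flanking cysteines that could re-pair a Cys93 are not
modelled). The 191+220 bridge flag likewise reports two cysteines
present, not an assigned disulfide.

Classification is a deterministic lookup with precedence
`inactive > literal rule > position-189 fallback > unassigned`. The
packaged table (`data/specificity_rules.yaml`) holds 20 literal
triplet rules (tryptase, chymase, asp-ase, met-ase, elastase,
chymase-with-tryptase-activity, each tiered exact or putative) plus
seven fish-protease triplets (GNN, GGN, GTH, GSS, GAY, GSY, GTY)
deliberately mapped to `unknown`/`unassigned`: phage-display evidence
shows triplet-based guesses fail for this group (a GTY enzyme proved a
strict tryptase), so refusing to guess is the correct behaviour. The
fallback keys on position 189 alone (D → tryptase, S → chymase, both
putative) because 189 sits at the bottom of the pocket and dominates
primary specificity, 226 is secondary and can be shielded, and 216 is
least informative. SGK is shipped as asp-ase/putative — the literal
rule deliberately outranks the S-at-189 chymase fallback. No rule is
shipped for duodenases (dual tryptic/chymotryptic ruminant enzymes):
no triplet consensus separates them, so they classify by their 189
residue like any other sequence. Users can extend or replace the table
via `load_rules(path)`; every triplet over the 20 amino acids yields a
defined outcome (enumerated exhaustively in the tests).

## Locus reconstruction and maps

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted on read/write, BED passes through. Malformed annotation
lines are skipped and logged with their line number (a file with no
valid record raises); records with non-positive span are rejected the
same way. Marker matching is case-insensitive with an alias table,
since bordering-gene names vary by assembly (`ERCC-1-like`,
`FGF22-or-10-like`, ...).

A locus candidate is the run of genes between the **innermost**
matched left and right markers on one contig (smallest index gap,
position tie-break); multiple candidate regions — paralogous loci are
real, e.g. the second fish CFD locus — are all returned, ranked by
matched-marker count. When the two marker sides only ever resolve to
different contigs (platypus-style fragmentary assemblies), partial
maps flagged `split` are returned instead. The met-ase definition
anchors on its conserved *centre* markers (POLRMT, FGF22, BSG, RNF126,
FSTL3) and absorbs contiguous flanking protease genes, since only the
centre of that locus is conserved between fish and mammals. The
granzyme A/K locus ships **without** default markers: its flanking
genes are conserved but not named consistently enough to package, so
that definition is user-supplied. Pseudogene status, where present in
source annotation attributes, is carried through as display metadata,
never recomputed from sequence.

Geometry is plain arithmetic (size = end − start; gap = next.start −
prev.end, clamped at 0 with an overlap flag), so for non-overlapping
loci sizes + gaps telescope exactly to the locus span — an invariant
the tests enforce. Maps are SVG with base-pair-proportional glyph
widths, strand-arrowed glyphs, and protease genes at exactly twice the
marker height; rendering is byte-deterministic for fixed input and
style, and scale-equivariant (doubling coordinates doubles widths).

## Phylogenetics

Two distance models are shipped: p-distance (mismatches over columns
where both sequences are non-gap and non-X) and Poisson correction
`−ln(1−p)`. The maximum-likelihood JTT distance used by classic
PHYLIP workflows is intentionally not re-implemented: the downstream
inferences rest on topology robustness, and for topology the simpler
corrections suffice while keeping closed forms available for testing.
The model name travels in output metadata. Saturated pairs (p ≥ 0.95,
configurable) are capped at `−ln(0.05)` with a warning; a pair with no
comparable columns is an error, not a silent zero. Poisson-corrected
distances can violate the triangle inequality; no test or invariant
assumes it.

Neighbor joining is the standard Q-criterion algorithm with
lowest-index tie-breaking and negative branch lengths clamped to zero
with a warning (PHYLIP-compatible behaviour). On additive matrices it
recovers the unique generating topology with exact branch lengths,
verified against an exhaustive least-squares search over all unrooted
topologies up to 8 leaves, and cross-checked against scikit-bio's NJ
on generic matrices. Bootstrap follows the classic protocol: resample
alignment columns with replacement, rebuild each replicate with the
same distance model and NJ, and annotate each internal edge of the
full-data tree with the percentage of replicates containing its
bipartition. The default is **100 replicates**. One seeded generator
drives everything; replicate *i* uses substream *i*, so adding
replicates never perturbs earlier ones and runs are bit-identical for
a fixed seed. Majority-rule consensus includes exactly the
bipartitions with frequency strictly above the threshold (default 0.5;
thresholds below 0.5 are rejected because compatibility is no longer
guaranteed) and performs no greedy completion. Least-squares tree
fitting (Fitch–Margoliash-style) is not implemented separately — for
these purposes it is redundant with NJ — and Bayesian MCMC and
maximum-likelihood inference are out of scope; trees from such tools
can be read via Newick and fed to the consensus/bipartition machinery.

Newick I/O uses dendropy underneath; round-trips preserve topology,
branch lengths to 1e-9, quoted labels with spaces, and integer support
values written as internal-node labels.

## Synthetic data

`simulate_family` evolves a scaffold-derived root (with a chosen
planted triplet, triad state and cysteine features) along a supplied
or randomly sampled tree. Substitutions follow a **uniform 20-state
jump model** (Jukes–Cantor generalisation) rather than an empirical
matrix: per branch of length *t* each mutable site draws a
Poisson(rate·t) number of jumps to uniformly chosen other residues,
which gives the closed-form per-site mismatch probability
`(19/20)(1 − e^(−20d/19))` used by the calibration tests. Canonical
registry sites are frozen by default, so planted features survive any
divergence; optional short indels (1–3 residues) never land within ±3
residues of a frozen site, keeping alignment-based recovery exact in
the mild-divergence regime (≲30 % expected substitutions per site —
the regime the end-to-end tests simulate; above it, alignment gap
placement can legitimately slide past a site). Every substitution and
indel is logged with its branch and position, and the log replays to
the emitted leaf sequences byte for byte.

`simulate_locus` builds `left markers | proteases | right markers`
(centre markers between the proteases when the definition has them)
and applies duplication (adjacent copy), loss, and marker strand
inversion events — forced events first, then per-step Bernoulli draws
with the configured probabilities. Gene sizes (1.5–3.6 kb) and
intergenic gaps (5–10 kb) are a fixed cyclic function of gene index:
stylised but genome-scaled, and it makes the event log alone
sufficient to reproduce the annotation exactly.

One master seed drives named substreams (tree, sequences, locus), so
regeneration is byte-identical and adding a feature never perturbs
existing draws. `make_fixture_suite` packages the standard test set:
one sequence per literal classifier rule, a broken-triad sequence, a
6-taxon family with its true tree and event log, a locus with a forced
duplication and marker inversion, and a split locus on two contigs.

**What passing these tests shows — and does not.** The synthetic
generator produces exactly the structure the pipeline assumes: planted
sites at known labels, markers with exact (alias-resolvable) names,
clean coordinates. Success on it demonstrates the machinery is
algorithmically correct and deterministic; it does not demonstrate
robustness to real-genome pathologies (fragmented assemblies beyond
simple two-contig splits, mis-annotated gene models, deep divergence
where pairwise numbering degrades, heterogeneous substitution
processes). Those remain the user's responsibility to assess on real
data.

## Problem sizes and determinism of the validation suite

The shipped validation uses: 200 random alignment instances up to 60
residues against the exhaustive DP oracle; 100 additive matrices on
4–8 taxa against the exhaustive topology search; 100-replicate
bootstraps on 10 taxa × 200 columns; ~1200 mutable sites for the
closed-form divergence check (3-SE acceptance band). These sizes make
the whole suite run in a few minutes on one CPU while keeping each
check statistically meaningful; all randomness is seed-derived.
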