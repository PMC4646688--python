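"""S1-pocket triplet, catalytic-triad and cysteine feature extraction.

Works on :class:`~gasp.numbering.NumberedSequence` objects, reading
residues at the canonical sites:

* 189 / 216 / 226 — the S1-pocket specificity triplet (in that order);
* 57 / 102 / 195 — the His/Asp/Ser catalytic triad; anything other than
  exactly H, D, S marks the enzyme proteolytically inactive
  (azurocidin-style);
* 93 — an unpaired cysteine here drives dimerization (granzyme A
  dimers vs granzyme K monomers);
* 191 + 220 — cysteines at both positions indicate the extra disulfide
  bridge seen in fish chymase-locus-related proteases.

The 191/220 call is sequence-level only (two cysteines present), not a
structural disulfide assignment, and the oligomer call is a heuristic:
flanking cysteines that could re-pair Cys93 are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from gasp.numbering import NumberedSequence, residue_at

TRIPLET_LABELS = (189, 216, 226)
TRIAD_LABELS = (57, 102, 195)


@dataclass(frozen=True)
class SpecificityProfile:
    """Extracted canonical-site features of one protease sequence."""

    seq_id: str
    triplet: str  # residues at 189/216/226, "-" where the label is absent
    triad_intact: bool
    triad_residues: tuple[str, str, str]  # at 57/102/195, "absent" allowed
    has_cys93: bool
    has_bridge_191_220: bool
    oligomer_call: str  # dimer | monomer | indeterminate

    def __post_init__(self) -> None:
        assert len(self.triplet) == 3


def _site(numbered: NumberedSequence, label: int) -> str:
    return residue_at(numbered, label)


def extract_triplet(numbered: NumberedSequence) -> str:
    """Residues at canonical 189, 216, 226; ``-`` where a label is absent."""
    out = []
    for lab in TRIPLET_LABELS:
        res = _site(numbered, lab)
        out.append("-" if res == "absent" else res)
    return "".join(out)


def check_triad(numbered: NumberedSequence) -> tuple[bool, tuple[str, str, str]]:
    """Catalytic-triad status: intact iff 57/102/195 are exactly H/D/S."""
    residues = tuple(_site(numbered, lab) for lab in TRIAD_LABELS)
    intact = residues == ("H", "D", "S")
    return intact, residues  # type: ignore[return-value]


def cysteine_features(numbered: NumberedSequence) -> tuple[bool, bool, str]:
    """Cys93 dimerization flag, Cys191–Cys220 bridge flag, oligomer call.

    The oligomer call is ``dimer`` when 93 is a cysteine, ``monomer``
    when 93 is mapped to any other residue, and ``indeterminate`` when
    label 93 falls in an alignment gap.
    """
    r93 = _site(numbered, 93)
    has_cys93 = r93 == "C"
    if r93 == "absent":
        oligomer = "indeterminate"
    elif has_cys93:
        oligomer = "dimer"
    else:
        oligomer = "monomer"
    bridge = _site(numbered, 191) == "C" and _site(numbered, 220) == "C"
    return has_cys93, bridge, oligomer


def extract_profile(numbered: NumberedSequence) -> SpecificityProfile:
    """Full feature profile of one numbered sequence."""
    triad_intact, triad_residues = check_triad(numbered)
    has_cys93, bridge, oligomer = cysteine_features(numbered)
    return SpecificityProfile(
        seq_id=numbered.seq_id,
        triplet=extract_triplet(numbered),
        triad_intact=triad_intact,
        triad_residues=triad_residues,
        has_cys93=has_cys93,
        has_bridge_191_220=bridge,
        oligomer_call=oligomer,
    )
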