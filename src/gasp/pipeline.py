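"""End-to-end sequence annotation: numbering → features → classification."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from gasp.classify import RuleTable, classify_batch
from gasp.features import extract_profile
from gasp.io import read_fasta
from gasp.numbering import AlignmentParams, ReferenceScaffold, default_scaffold, number_sequence


def profile_sequences(
    sequences: Iterable[tuple[str, str]] | str | Path,
    reference: ReferenceScaffold | None = None,
    params: AlignmentParams | None = None,
    rules: RuleTable | None = None,
) -> pd.DataFrame:
    """Annotate protease sequences end to end.

    ``sequences`` is either an iterable of ``(seq_id, sequence)`` pairs
    or a FASTA path.  Each sequence is globally aligned to the reference
    scaffold, canonically numbered, feature-extracted (S1 triplet,
    catalytic triad, cysteines) and classified.  Returns one row per
    sequence with an ``alignment_score`` column appended.
    """
    if isinstance(sequences, (str, Path)):
        sequences = read_fasta(sequences)
    reference = reference or default_scaffold()
    numbered = [
        number_sequence(seq, reference, params, seq_id=sid) for sid, seq in sequences
    ]
    profiles = [extract_profile(ns) for ns in numbered]
    table = classify_batch(profiles, rules)
    table["alignment_score"] = [ns.alignment_score for ns in numbered]
    return table
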