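"""FASTA and tabular I/O helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gasp.numbering import NumberedSequence


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(seq_id, sequence), ...]``."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(seq_id, sequence)`` pairs as FASTA, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")  # biopython wraps at 60


def numbering_report(numbered: Sequence[NumberedSequence]) -> pd.DataFrame:
    """Long-format numbering table: seq_id, label, query_index, residue."""
    rows = [
        {
            "seq_id": ns.seq_id,
            "label": lab,
            "query_index": idx,
            "residue": ns.sequence[idx],
        }
        for ns in numbered
        for lab, idx in sorted(ns.numbering.items())
    ]
    return pd.DataFrame(rows, columns=["seq_id", "label", "query_index", "residue"])


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
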