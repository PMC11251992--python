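"""Small format helpers shared across modules."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def read_fasta(path) -> dict[str, str]:
    """Protein FASTA to an id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path
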