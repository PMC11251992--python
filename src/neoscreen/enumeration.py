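"""Neoantigen windows and mutation-spanning candidate neoepitopes.

A point mutation at protein position p defines a neoantigen *window*: the
mutant residue plus up to ``flank`` residues of native context on each side
(default 12, giving a 25-mer for interior mutations). Every 8-11-mer
substring of the window that covers the mutated residue is a candidate
neoepitope; an interior mutation yields exactly 8 + 9 + 10 + 11 = 38 of
them. The screen manifest is the deduplicated Cartesian product of all
candidates with the selected HLA alleles.

Coordinates are 1-based inclusive throughout, matching protein-change
nomenclature such as "G12D".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ReferenceMismatchError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class NeoantigenVariant:
    """A single amino-acid substitution with its mutant sequence window."""

    variant_id: str
    protein_id: str
    protein_position: int  # 1-based position of the substitution in the protein
    ref_residue: str
    alt_residue: str
    window_seq: str  # mutant window, <= 2*flank + 1 residues
    mutation_offset: int  # 1-based position of the mutated residue in window_seq

    def __post_init__(self):
        if not 1 <= self.mutation_offset <= len(self.window_seq):
            raise ValueError("mutation_offset outside window_seq")
        if self.window_seq[self.mutation_offset - 1] != self.alt_residue:
            raise ValueError(
                "window_seq does not carry alt_residue at mutation_offset"
            )


@dataclass(frozen=True)
class CandidatePeptide:
    """A mutation-spanning 8-11-mer candidate neoepitope."""

    sequence: str
    variant_id: str
    start_in_window: int  # 1-based
    mutation_pos_in_peptide: int  # 1-based

    def __post_init__(self):
        if not 1 <= self.mutation_pos_in_peptide <= len(self.sequence):
            raise ValueError("mutation position outside peptide")


def build_window(
    protein_seq: str,
    position: int,
    ref: str,
    alt: str,
    flank: int = 12,
    variant_id: str | None = None,
    protein_id: str = "",
) -> NeoantigenVariant:
    """Cut the mutant window around a point substitution.

    ``position`` is 1-based. The window spans
    [max(1, position - flank), min(L, position + flank)] with the mutated
    residue substituted in. Raises :class:`ReferenceMismatchError` if the
    protein does not carry ``ref`` at ``position``.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(
            "only single amino-acid substitutions are supported (no indels)"
        )
    if ref == alt:
        raise ValueError("alt residue equals ref residue; not a mutation")
    if not 1 <= position <= len(protein_seq):
        raise ValueError(
            f"position {position} outside protein of length {len(protein_seq)}"
        )
    found = protein_seq[position - 1]
    if found != ref:
        raise ReferenceMismatchError(protein_id or "<protein>", position, ref, found)

    start = max(1, position - flank)
    end = min(len(protein_seq), position + flank)
    window = list(protein_seq[start - 1 : end])
    offset = position - start + 1
    window[offset - 1] = alt
    if variant_id is None:
        variant_id = f"{protein_id}:{ref}{position}{alt}" if protein_id else f"{ref}{position}{alt}"
    return NeoantigenVariant(
        variant_id=variant_id,
        protein_id=protein_id,
        protein_position=position,
        ref_residue=ref,
        alt_residue=alt,
        window_seq="".join(window),
        mutation_offset=offset,
    )


def enumerate_candidates(
    variant: NeoantigenVariant, lengths: Sequence[int] = DEFAULT_LENGTHS
) -> list[CandidatePeptide]:
    """Every substring of the window covering the mutated residue, per length.

    Ordered by length, then start position. Windows shorter than a requested
    length, or mutations near a terminus, simply yield fewer peptides.
    """
    if any(not 8 <= k <= 11 for k in lengths):
        raise ValueError("candidate lengths must lie in [8, 11]")
    window = variant.window_seq
    m = variant.mutation_offset
    out: list[CandidatePeptide] = []
    for k in sorted(set(lengths)):
        lo = max(1, m - k + 1)
        hi = min(len(window) - k + 1, m)
        for s in range(lo, hi + 1):
            out.append(
                CandidatePeptide(
                    sequence=window[s - 1 : s + k - 1],
                    variant_id=variant.variant_id,
                    start_in_window=s,
                    mutation_pos_in_peptide=m - s + 1,
                )
            )
    return out


@dataclass
class ScreenManifest:
    """Unique (peptide, allele) pairs with provenance to contributing variants."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["peptide", "allele", "variant_ids"]
        )
    )
    n_sequence_collisions: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["peptide"], self.table["allele"]))


def build_manifest(
    variants: Iterable[NeoantigenVariant],
    alleles: Sequence[str],
    excluded_alleles: Sequence[str] = (),
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> ScreenManifest:
    """Cartesian product of candidate peptides with retained alleles, deduplicated.

    Identical sequences arising from overlapping variants collapse to one
    manifest entry whose ``variant_ids`` lists every contributor; the number
    of such collisions is logged and recorded on the manifest.
    """
    kept_alleles = [a for a in alleles if a not in set(excluded_alleles)]
    seq_to_variants: dict[str, list[str]] = {}
    n_collisions = 0
    for variant in variants:
        for cand in enumerate_candidates(variant, lengths):
            owners = seq_to_variants.setdefault(cand.sequence, [])
            if cand.variant_id not in owners:
                if owners:
                    n_collisions += 1
                owners.append(cand.variant_id)
    if n_collisions:
        logger.info(
            "%d candidate sequences are shared between overlapping variants",
            n_collisions,
        )
    rows = [
        {"peptide": seq, "allele": allele, "variant_ids": tuple(owners)}
        for seq, owners in seq_to_variants.items()
        for allele in kept_alleles
    ]
    table = pd.DataFrame(rows, columns=["peptide", "allele", "variant_ids"])
    if len(table):
        table = table.sort_values(["allele", "peptide"]).reset_index(drop=True)
    return ScreenManifest(table=table, n_sequence_collisions=n_collisions)


def read_variants(path, proteins: dict[str, str], flank: int = 12) -> list[NeoantigenVariant]:
    """Read a variant TSV (variant_id, protein_id, position, ref, alt) and build windows."""
    df = pd.read_csv(path, sep="\t")
    required = ["variant_id", "protein_id", "position", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant table is missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        if row.protein_id not in proteins:
            raise KeyError(f"protein {row.protein_id!r} not found in FASTA input")
        out.append(
            build_window(
                proteins[row.protein_id],
                int(row.position),
                row.ref,
                row.alt,
                flank=flank,
                variant_id=row.variant_id,
                protein_id=row.protein_id,
            )
        )
    return out


def write_manifest(manifest: ScreenManifest, path) -> None:
    df = manifest.table.copy()
    df["variant_ids"] = df["variant_ids"].map(";".join)
    df.to_csv(path, sep="\t", index=False)
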