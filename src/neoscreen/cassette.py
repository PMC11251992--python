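"""Polyantigen cassette design and combinatorial (MIRA-style) peptide pooling.

A polyantigen cassette concatenates many ~25-aa neoantigen segments (plus
control epitopes) into a single transgene, optionally separated by short
flexible Gly/Ser linkers. The design here is pure amino-acid bookkeeping:
deterministic concatenation with an exact 1-based coordinate map, and a
locator that classifies where a detected peptide falls (inside a segment,
inside a linker, or spanning a junction -- junction peptides are artifacts
of concatenation rather than genuine neoepitopes).

Pooling assigns each peptide a unique k-of-n combination of stimulation
pools so that the set of activated pools identifies the antigen
(deconvolution); the classic configuration is 6 of 11 pools, addressing up
to C(11,6) = 462 peptides.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import PoolCapacityError

logger = logging.getLogger(__name__)

DEFAULT_LINKER = "GGSGGS"
JUNCTION = "JUNCTION"
LINKER = "LINKER"


@dataclass
class CassetteDesign:
    """An ordered concatenation of segments with an exact coordinate map."""

    segments: list[tuple[str, str]]  # (segment_id, sequence), neoantigens first
    linker: str
    controls: list[tuple[str, str]]
    full_seq: str
    coord_map: dict[str, tuple[int, int]]  # segment_id -> 1-based [start, end]

    def segment_order(self) -> list[str]:
        return [sid for sid, _ in self.segments] + [sid for sid, _ in self.controls]

    def segment_index(self, segment_id: str) -> int:
        """1-based position of a segment within the cassette order."""
        return self.segment_order().index(segment_id) + 1


def design_cassette(
    segments: Sequence[tuple[str, str]],
    linker: str = "",
    controls: Sequence[tuple[str, str]] = (),
) -> CassetteDesign:
    """Concatenate segments (and trailing controls) with optional linkers.

    Segments are joined in input order; when ``linker`` is non-empty it is
    inserted between every pair of consecutive segments, including before the
    control block. Linkers are expected to be Gly/Ser ("flexible"); other
    residues trigger a warning only. Returns the design with a 1-based,
    inclusive coordinate map covering every non-linker residue.
    """
    if not segments:
        raise ValueError("need at least one segment")
    ordered = list(segments) + list(controls)
    ids = [sid for sid, _ in ordered]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate segment ids: {dupes}")
    if linker and set(linker) - set("GS"):
        logger.warning(
            "linker %r contains residues outside {G, S}; not a canonical "
            "flexible linker", linker,
        )
    parts: list[str] = []
    coord_map: dict[str, tuple[int, int]] = {}
    pos = 0
    for i, (sid, seq) in enumerate(ordered):
        if not seq:
            raise ValueError(f"segment {sid!r} is empty")
        if i > 0 and linker:
            parts.append(linker)
            pos += len(linker)
        coord_map[sid] = (pos + 1, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    return CassetteDesign(
        segments=list(segments),
        linker=linker,
        controls=list(controls),
        full_seq="".join(parts),
        coord_map=coord_map,
    )


def locate_peptide(
    peptide: str, design: CassetteDesign
) -> list[tuple[str, int, int]]:
    """All occurrences of a peptide in the cassette, classified by origin.

    Returns ``(label, start, end)`` per occurrence (1-based, inclusive) where
    label is a segment id when the match lies fully inside that segment,
    ``"LINKER"`` when fully inside a linker, and ``"JUNCTION"`` when it spans
    segment/linker boundaries. An absent peptide yields an empty list.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    # per-residue ownership labels
    owner = [LINKER] * len(design.full_seq)
    for sid, (s, e) in design.coord_map.items():
        for i in range(s - 1, e):
            owner[i] = sid
    out: list[tuple[str, int, int]] = []
    start = design.full_seq.find(peptide)
    while start != -1:
        end = start + len(peptide)  # exclusive
        labels = set(owner[start:end])
        label = labels.pop() if len(labels) == 1 else JUNCTION
        out.append((label, start + 1, end))
        start = design.full_seq.find(peptide, start + 1)
    return out


@dataclass
class PoolAssignment:
    """A unique k-of-n pool combination per item."""

    combinations: dict[str, frozenset[int]]  # item_id -> k pool indices (1-based)
    n_pools: int
    k: int

    members: dict[int, list[str]] = field(init=False)

    def __post_init__(self):
        sizes = {len(c) for c in self.combinations.values()}
        if sizes and sizes != {self.k}:
            raise ValueError("every combination must have exactly k pools")
        if len(set(self.combinations.values())) != len(self.combinations):
            raise ValueError("pool combinations must be distinct per item")
        self.members = {p: [] for p in range(1, self.n_pools + 1)}
        for item, combo in self.combinations.items():
            for p in sorted(combo):
                self.members[p].append(item)

    def __getitem__(self, item_id: str) -> frozenset[int]:
        return self.combinations[item_id]


def assign_pools(
    item_ids: Sequence[str],
    n_pools: int = 11,
    k: int = 6,
    seed: int | None = None,
) -> PoolAssignment:
    """Assign each item a distinct k-subset of the n pools.

    Deterministic: lexicographic k-subsets matched to items in input order.
    With ``seed`` the subsets are shuffled reproducibly first, spreading
    items across pool patterns. Raises :class:`PoolCapacityError` when items
    outnumber C(n_pools, k).
    """
    items = list(item_ids)
    if len(set(items)) != len(items):
        raise ValueError("item ids must be unique")
    capacity = math.comb(n_pools, k)
    if len(items) > capacity:
        raise PoolCapacityError(len(items), n_pools, k, capacity)
    combos = list(itertools.combinations(range(1, n_pools + 1), k))
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(combos)
    assignment = {
        item: frozenset(combo) for item, combo in zip(items, combos)
    }
    return PoolAssignment(combinations=assignment, n_pools=n_pools, k=k)


def deconvolve(
    activated_pools: Iterable[int],
    assignment: PoolAssignment,
    mode: str = "exact",
) -> list[str]:
    """Invert the pooling scheme: which items explain the activated pools?

    ``exact`` returns items whose combination equals the activated set (one
    responding antigen); ``subset`` returns items whose combination is a
    subset of it (several responders superimposed).
    """
    activated = frozenset(activated_pools)
    if not activated <= set(range(1, assignment.n_pools + 1)):
        raise ValueError("activated pools outside the pool index range")
    if mode == "exact":
        return [i for i, c in assignment.combinations.items() if c == activated]
    if mode == "subset":
        return [i for i, c in assignment.combinations.items() if c <= activated]
    raise ValueError("mode must be 'exact' or 'subset'")
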