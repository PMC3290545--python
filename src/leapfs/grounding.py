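"""Mapping text residues onto physical residues in linked structures.

A *text residue* is the per-abstract grouping of all mentions sharing a
sequence position.  Grounding proceeds in four steps:

1. group an abstract's mentions by position;
2. discard groups whose wild-type (primary) amino-acid names conflict;
3. match the remaining groups against the protein chains of every
   structure linked to the abstract, joining the position to the author
   residue number and the primary (or any mutant) code to the residue
   name — so a mutant structure is still matched through the mutation's
   target code;
4. within one structure, accept multiple matching residues only when
   they all come from the same molecular entity (e.g. the two chains of
   a homodimer); matches across different entities are ambiguous and
   dropped.

Text positions are matched against residues with a blank insertion code
only, and no renumbering offsets are attempted: an exact position match
is required.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .mentions import NormalizedMention
from .structure_io import StructureData

GROUNDED = "grounded"
AMBIGUOUS_TEXT = "ambiguous_text"
AMBIGUOUS_PHYSICAL = "ambiguous_physical"
UNMATCHED = "unmatched"


class PhysicalResidue(NamedTuple):
    pdb_id: str
    chain_id: str
    auth_seq_num: int
    comp_id: str
    entity_id: str


@dataclass(eq=False)
class TextResidue:
    pmid: str
    position: int
    primary_codes: frozenset[str]
    mutation_codes: frozenset[str]
    n_occurrences: int

    @property
    def is_unambiguous(self) -> bool:
        return len(self.primary_codes) == 1

    @property
    def primary_code(self) -> str:
        if not self.is_unambiguous:
            raise ValueError(f"ambiguous text residue at position {self.position}")
        return next(iter(self.primary_codes))


@dataclass(eq=False)
class GroundedTextResidue:
    text_residue: TextResidue
    pdb_id: str | None
    status: str
    matches: tuple[PhysicalResidue, ...] = field(default_factory=tuple)


def group_text_residues(mentions: Iterable[NormalizedMention], pmid: str) -> list[TextResidue]:
    """One group per position; mutations contribute wild type as primary."""
    by_pos: dict[int, list[NormalizedMention]] = defaultdict(list)
    for m in mentions:
        by_pos[m.position].append(m)
    out = []
    for pos in sorted(by_pos):
        group = by_pos[pos]
        primaries = frozenset(m.wt_code for m in group)
        muts = frozenset(m.mut_code for m in group if m.mut_code)
        out.append(TextResidue(pmid, pos, primaries, muts, len(group)))
    return out


def check_text_ambiguity(group: TextResidue) -> bool:
    """True when the group has a single primary amino-acid name."""
    return group.is_unambiguous


def match_physical(
    text_residue: TextResidue,
    structure: StructureData,
    use_mutation_codes: bool = True,
) -> list[PhysicalResidue]:
    """Candidate residues in a structure's protein chains.

    A candidate has the text position as author residue number (blank
    insertion code) and the primary — or, unless disabled, any mutant —
    code as residue name.
    """
    codes = set(text_residue.primary_codes)
    if use_mutation_codes:
        codes |= text_residue.mutation_codes
    out = []
    for r in structure.protein_residues():
        if r.icode:
            continue
        if r.auth_seq_num == text_residue.position and r.comp_id.upper() in codes:
            out.append(PhysicalResidue(
                structure.structure_id, r.chain_id, r.auth_seq_num,
                r.comp_id.upper(), r.entity_id))
    return out


def resolve_entity_ambiguity(
    text_residue: TextResidue,
    pdb_id: str,
    candidates: list[PhysicalResidue],
) -> GroundedTextResidue:
    """Accept matches within one entry only if they share one entity."""
    if not candidates:
        return GroundedTextResidue(text_residue, pdb_id, UNMATCHED)
    entities = {c.entity_id for c in candidates}
    if len(entities) > 1:
        return GroundedTextResidue(text_residue, pdb_id, AMBIGUOUS_PHYSICAL)
    return GroundedTextResidue(text_residue, pdb_id, GROUNDED, tuple(candidates))


def ground_abstract(
    mentions: Iterable[NormalizedMention],
    pmid: str,
    linked_structures: dict[str, StructureData],
    use_mutation_codes: bool = True,
) -> list[GroundedTextResidue]:
    """Run the full grounding pipeline for one abstract.

    Yields one record per (text residue, linked entry), plus a single
    ``unmatched`` record when no structure is linked, and an
    ``ambiguous_text`` record for groups with conflicting primaries.
    """
    out: list[GroundedTextResidue] = []
    for group in group_text_residues(mentions, pmid):
        if not check_text_ambiguity(group):
            out.append(GroundedTextResidue(group, None, AMBIGUOUS_TEXT))
            continue
        if not linked_structures:
            out.append(GroundedTextResidue(group, None, UNMATCHED))
            continue
        for pdb_id in sorted(linked_structures):
            cands = match_physical(group, linked_structures[pdb_id],
                                   use_mutation_codes=use_mutation_codes)
            out.append(resolve_entity_ambiguity(group, pdb_id, cands))
    return out


def grounded_residue_keys(groundings: Iterable[GroundedTextResidue]) -> set[tuple]:
    """(pdb, chain, auth_seq_num) keys of all grounded matches."""
    keys = set()
    for g in groundings:
        if g.status == GROUNDED:
            for m in g.matches:
                keys.add((m.pdb_id, m.chain_id, m.auth_seq_num))
    return keys
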