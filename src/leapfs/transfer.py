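"""Annotation transfer across multiple sequence alignments.

Domains within a SCOP-style family are aligned at two levels.  A
*protein-level* MSA aligns the domains sharing one protein id; a
*family-level* MSA aligns one representative domain per protein (the
longest, ties broken by first SID alphabetically), and requires at
least two distinct protein ids.  Composing the two gives a *virtual
alignment* assigning family columns to every domain reachable through
its representative.

Annotations (NSM, NSM-valid, CSA, text residues) propagate along
aligned columns, but only between residues whose amino acids fall in
the same "fuzzy" group — an equivalence class of chemically similar
side chains shipped as an explicit, overridable table
(``data/fuzzy_groups.yaml``).

Residues are addressed by (domain id, residue index), where the index
counts non-gap positions of the domain's aligned sequence from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

from ._aa import ONE_TO_THREE, THREE_TO_ONE

logger = logging.getLogger(__name__)

GAP_CHARS = "-."


class FuzzyGroups:
    """Equivalence classes of amino acids for annotation transfer."""

    def __init__(self, groups: Iterable[Iterable[str]]):
        self._group_of: dict[str, int] = {}
        for gi, group in enumerate(groups):
            for code in group:
                self._group_of[code.upper()] = gi

    def compatible(self, aa1: str, aa2: str) -> bool:
        a, b = aa1.upper(), aa2.upper()
        if a == b and a in THREE_TO_ONE:
            return True
        for code in (a, b):
            if code not in THREE_TO_ONE:
                logger.warning("unknown amino-acid code %r in fuzzy comparison", code)
                return False
        ga, gb = self._group_of.get(a), self._group_of.get(b)
        return ga is not None and ga == gb


def load_fuzzy_groups(path: str | Path | None = None) -> FuzzyGroups:
    """Load the default packaged grouping table, or a user override."""
    if path is None:
        text = resources.files("leapfs.data").joinpath("fuzzy_groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    return FuzzyGroups(data["groups"])


_DEFAULT_GROUPS: FuzzyGroups | None = None


def fuzzy_compatible(aa1: str, aa2: str, groups: FuzzyGroups | None = None) -> bool:
    """True iff two 3-letter codes are identical or co-grouped."""
    global _DEFAULT_GROUPS
    if groups is None:
        if _DEFAULT_GROUPS is None:
            _DEFAULT_GROUPS = load_fuzzy_groups()
        groups = _DEFAULT_GROUPS
    return groups.compatible(aa1, aa2)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> ordered {sequence id: aligned sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: rows have unequal aligned lengths {sorted(lengths)}")
    return out


def _res_to_col(aligned: str) -> dict[int, int]:
    """Residue index (non-gap ordinal) -> alignment column."""
    out = {}
    i = 0
    for col, ch in enumerate(aligned):
        if ch not in GAP_CHARS:
            out[i] = col
            i += 1
    return out


def _col_to_res(aligned: str) -> dict[int, int]:
    return {col: i for i, col in _res_to_col(aligned).items()}


def ungapped(aligned: str) -> str:
    return "".join(ch for ch in aligned if ch not in GAP_CHARS)


def select_representatives(
    protein_members: dict[str, dict[str, str]],
) -> dict[str, str]:
    """Longest domain per protein id; ties by first SID alphabetically."""
    reps = {}
    for pid, members in protein_members.items():
        reps[pid] = min(members, key=lambda sid: (-len(ungapped(members[sid])), sid))
    return reps


@dataclass(eq=False)
class VirtualAlignment:
    family_id: str
    #: ungapped 1-letter sequence per domain
    seqs: dict[str, str]
    #: protein id of each domain
    protein_of: dict[str, str]
    #: per-domain residue index -> family column (empty if unreachable)
    family_map: dict[str, dict[int, int]]
    #: per-domain residue index -> protein-MSA column, per protein
    protein_maps: dict[str, dict[str, dict[int, int]]]
    #: how each domain reached the family columns
    provenance: dict[str, str] = field(default_factory=dict)

    def members(self) -> list[str]:
        return sorted(self.seqs)


def merge_alignments(
    protein_msas: dict[str, dict[str, str]],
    family_msa: dict[str, str],
    representatives: dict[str, str] | None = None,
    family_id: str = "family",
) -> VirtualAlignment:
    """Compose protein-level MSAs with the family MSA of representatives.

    Every domain of a protein inherits family columns through its
    representative's row in the family MSA; residues falling in a gap of
    the representative stay unmapped.  With fewer than two distinct
    protein ids in the family MSA no family-level mapping is produced.
    A representative missing from the family MSA leaves that protein's
    domains protein-level only (with a warning).
    """
    if representatives is None:
        representatives = select_representatives(protein_msas)

    seqs: dict[str, str] = {}
    protein_of: dict[str, str] = {}
    protein_maps: dict[str, dict[str, dict[int, int]]] = {}
    for pid, members in protein_msas.items():
        protein_maps[pid] = {}
        for sid, aligned in members.items():
            seqs[sid] = ungapped(aligned)
            protein_of[sid] = pid
            protein_maps[pid][sid] = _res_to_col(aligned)
    for sid, aligned in family_msa.items():
        seqs.setdefault(sid, ungapped(aligned))

    family_map: dict[str, dict[int, int]] = {sid: {} for sid in seqs}
    provenance: dict[str, str] = {}
    family_ok = len({pid for pid, rep in representatives.items() if rep in family_msa}) >= 2

    if family_ok:
        rep_maps = {sid: _res_to_col(aligned) for sid, aligned in family_msa.items()}
        for pid, members in protein_msas.items():
            rep = representatives.get(pid)
            if rep is None or rep not in family_msa:
                logger.warning(
                    "protein %s has no representative in the family MSA; "
                    "its domains stay protein-level only", pid)
                continue
            rep_res_to_fam = rep_maps[rep]
            rep_col_to_res = _col_to_res(members[rep]) if rep in members else None
            for sid, aligned in members.items():
                if sid == rep:
                    family_map[sid] = dict(rep_res_to_fam)
                    provenance[sid] = "family-level"
                    continue
                if rep_col_to_res is None:
                    continue
                mapping = {}
                for res_idx, col in protein_maps[pid][sid].items():
                    rep_res = rep_col_to_res.get(col)
                    if rep_res is not None and rep_res in rep_res_to_fam:
                        mapping[res_idx] = rep_res_to_fam[rep_res]
                family_map[sid] = mapping
                provenance[sid] = "protein-level"
        # family rows not tied to any protein MSA map directly
        for sid, aligned in family_msa.items():
            if sid not in provenance and sid in seqs and not family_map[sid]:
                family_map[sid] = dict(rep_maps[sid])
                provenance[sid] = "family-level"
    else:
        if family_msa:
            logger.warning(
                "family %s has fewer than two distinct protein ids; "
                "no family-level mapping", family_id)

    return VirtualAlignment(family_id, seqs, protein_of, family_map,
                            protein_maps, provenance)


@dataclass(frozen=True)
class Annotation:
    domain_id: str
    res_index: int
    ann_type: str  # NSM | NSM-valid | CSA | TextResidue


@dataclass(frozen=True)
class TransferredAnnotation:
    target: tuple[str, int]
    source: tuple[str, int]
    ann_type: str
    level: str  # direct | protein | family


def _aa3_at(valign: VirtualAlignment, sid: str, idx: int) -> str | None:
    seq = valign.seqs.get(sid)
    if seq is None or not 0 <= idx < len(seq):
        return None
    return ONE_TO_THREE.get(seq[idx])


def _protein_targets(valign: VirtualAlignment, ann: "Annotation") -> set[tuple[str, int]]:
    targets: set[tuple[str, int]] = set()
    pid = valign.protein_of.get(ann.domain_id)
    if pid is None:
        return targets
    maps = valign.protein_maps[pid]
    col = maps.get(ann.domain_id, {}).get(ann.res_index)
    if col is None:
        return targets
    for sid, m in maps.items():
        if sid == ann.domain_id:
            continue
        for res_idx, c in m.items():
            if c == col:
                targets.add((sid, res_idx))
    return targets


def _family_targets(valign: VirtualAlignment, ann: "Annotation") -> set[tuple[str, int]]:
    targets: set[tuple[str, int]] = set()
    col = valign.family_map.get(ann.domain_id, {}).get(ann.res_index)
    if col is None:
        return targets
    for sid, m in valign.family_map.items():
        if sid == ann.domain_id:
            continue
        for res_idx, c in m.items():
            if c == col:
                targets.add((sid, res_idx))
    return targets


def transfer_annotations(
    annotations: Iterable[Annotation],
    valign: VirtualAlignment,
    level: str,
    fuzzy_groups: FuzzyGroups | None = None,
) -> list[TransferredAnnotation]:
    """Propagate annotations to aligned, fuzzy-compatible residues.

    ``level="protein"`` transfers only between domains of the same
    protein id; ``level="family"`` across the whole family via the
    virtual alignment.  Direct annotations are retained with
    ``level="direct"``; duplicates collapse to one record.
    """
    if level not in ("protein", "family"):
        raise ValueError(f"level must be 'protein' or 'family', got {level!r}")
    out: dict[tuple, TransferredAnnotation] = {}

    def add(target, source, ann_type, lvl):
        key = (target, ann_type)
        if key not in out or (out[key].level != "direct" and lvl == "direct"):
            out[key] = TransferredAnnotation(target, source, ann_type, lvl)

    for ann in annotations:
        src = (ann.domain_id, ann.res_index)
        add(src, src, ann.ann_type, "direct")
        src_aa = _aa3_at(valign, ann.domain_id, ann.res_index)
        if src_aa is None:
            continue

        # family scope is a strict widening: it always includes the
        # protein-level targets, so transfers grow monotonically in scope
        targets: set[tuple[str, int]] = set(_protein_targets(valign, ann))
        if level == "family":
            targets |= _family_targets(valign, ann)

        for sid, res_idx in sorted(targets):
            tgt_aa = _aa3_at(valign, sid, res_idx)
            if tgt_aa is None:
                continue
            if fuzzy_compatible(src_aa, tgt_aa, fuzzy_groups):
                add((sid, res_idx), src, ann.ann_type, level)
    return sorted(out.values(), key=lambda t: (t.target, t.ann_type))
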