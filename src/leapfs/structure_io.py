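"""Structure parsing and site annotation.

Reads PDB/mmCIF files (via gemmi), extracts SCOP-style domains, finds
residues near co-crystallized small molecules (NSM sites), and attaches
curation labels from MOAD-style ligand-validity records and CSA-style
catalytic-residue records.

Conventions
-----------
* A residue is keyed by ``(chain_id, auth_seq_num, icode)`` with the
  insertion code defaulting to ``""``.
* "Small molecule" means any mmCIF chain (gemmi subchain) that is not
  part of a protein chain associated with a domain: organic compounds,
  ions, saccharides, nucleic acids, and short peptides all qualify.
  Water is excluded.
* All distance computations use heavy atoms only; hydrogens are kept in
  the atom lists but flagged and ignored.
* When a file provides several alternate locations for an atom, the
  first one is kept.

File dialects
-------------
``load_moad`` reads CSV rows ``pdb_id,hetero_codes,validity`` where
``hetero_codes`` is an ordered list separated by spaces or hyphens
(e.g. ``GLU-CYS-GLY``) and ``validity`` is ``valid`` or ``invalid``.

``load_csa`` reads CSV rows ``pdb_id,chain_id,auth_seq_num,comp_id,
evidence``; only ``LIT`` evidence is retained, ``PSI-BLAST`` rows are
silently dropped, anything else is skipped with a warning.

SCOP-style domain definitions are lines of the form
``<sid> <pdb_id> <chain>:<start>-<end>[,<chain>:<start>-<end>...]``
where the range part may be empty (whole chain) or ``-`` (everything).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed structure contains no atoms."""


class EmptyDomainError(ValueError):
    """Raised when a domain definition selects zero residues."""


@dataclass(eq=False)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    chain_id: str
    auth_seq_num: int
    icode: str
    comp_id: str
    entity_id: str
    is_heavy: bool


@dataclass(eq=False)
class ResidueRecord:
    chain_id: str
    auth_seq_num: int
    icode: str
    comp_id: str
    entity_id: str
    subchain_id: str
    is_polymer_aa: bool
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.auth_seq_num, self.icode)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass(eq=False)
class Molecule:
    """One non-protein mmCIF chain: a candidate small molecule."""

    subchain_id: str
    comp_ids: tuple[str, ...]  # ordered as in the source file
    residues: list[ResidueRecord]

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for r in self.residues for a in r.atoms if a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass(eq=False)
class StructureData:
    """All residues of one entry, prior to domain extraction."""

    structure_id: str
    residues: list[ResidueRecord]

    def protein_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.is_polymer_aa]


@dataclass(eq=False)
class DomainStructure:
    domain_id: str
    residues: list[ResidueRecord]  # ordered, domain only
    cochains: list[Molecule]       # non-domain chains
    index: dict[ResidueKey, ResidueRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {r.key: r for r in self.residues}

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()]).reshape(-1, 3)

    def ca_coords(self) -> np.ndarray:
        """One Calpha per residue (residues lacking CA are skipped)."""
        pts = []
        for r in self.residues:
            for a in r.atoms:
                if a.name == "CA" and a.is_heavy:
                    pts.append(a.coords)
                    break
        return np.array(pts, dtype=float).reshape(-1, 3)

    def residue_of_heavy_atom(self) -> list[ResidueKey]:
        """Residue key for each atom returned by :meth:`heavy_atoms`."""
        keys = []
        for r in self.residues:
            keys.extend(r.key for a in r.atoms if a.is_heavy)
        return keys


@dataclass(eq=False)
class NSMSite:
    site_id: str
    molecule: tuple[str, ...]      # ordered hetero codes
    subchain_id: str
    residues: frozenset[ResidueKey]
    validity: str = "uncurated"    # valid | invalid | uncurated


@dataclass(frozen=True)
class CatalyticAnnotation:
    pdb_id: str
    chain_id: str
    auth_seq_num: int
    comp_id: str
    evidence: str


@dataclass(frozen=True)
class MoadRecord:
    pdb_id: str
    codes: tuple[str, ...]
    validity: str


@dataclass(frozen=True)
class DomainDef:
    domain_id: str
    pdb_id: str
    # (chain_id, start, end); start/end None means the whole chain
    segments: tuple[tuple[str, int | None, int | None], ...]


_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")


def parse_domain_def(line: str) -> DomainDef:
    """Parse one SCOP dir.cla-style line: sid, pdb id, residue ranges."""
    parts = line.split()
    if len(parts) < 3:
        raise ValueError(f"not a domain definition line: {line!r}")
    sid, pdb_id, ranges = parts[0], parts[1], parts[2]
    segments = []
    for seg in ranges.split(","):
        if ":" in seg:
            chain, rng = seg.split(":", 1)
        else:
            chain, rng = seg, ""
        if chain == "-":
            chain = ""
        if rng in ("", "-"):
            segments.append((chain, None, None))
            continue
        m = _RANGE_RE.match(rng)
        if not m:
            raise ValueError(f"unparseable residue range {seg!r} in {line!r}")
        segments.append((chain, int(m.group(1)), int(m.group(2))))
    return DomainDef(sid, pdb_id, tuple(segments))


def read_structure(path: str | Path, structure_id: str | None = None) -> StructureData:
    """Read a PDB or mmCIF file into a flat residue table.

    Keeps the first alternate location when several exist, flags
    hydrogens as non-heavy, and records the mmCIF chain (subchain) and
    molecular entity of every residue.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    entity_of_subchain: dict[str, str] = {}
    polymer_subchains: set[str] = set()
    for ent in st.entities:
        for sub in ent.subchains:
            entity_of_subchain[sub] = ent.name
            if ent.entity_type == gemmi.EntityType.Polymer:
                polymer_subchains.add(sub)

    model = st[0]
    residues: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            sub = res.subchain
            info = gemmi.find_tabulated_residue(res.name)
            is_poly_aa = (
                sub in polymer_subchains and info.found() and info.is_amino_acid()
            )
            rec = ResidueRecord(
                chain_id=chain.name,
                auth_seq_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
                comp_id=res.name,
                entity_id=entity_of_subchain.get(sub, sub),
                subchain_id=sub,
                is_polymer_aa=is_poly_aa,
            )
            for atom in res.first_conformer():
                el = atom.element
                rec.atoms.append(
                    Atom(
                        name=atom.name,
                        element=el.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        chain_id=chain.name,
                        auth_seq_num=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        comp_id=res.name,
                        entity_id=rec.entity_id,
                        is_heavy=not el.is_hydrogen,
                    )
                )
            residues.append(rec)
    if not any(r.atoms for r in residues):
        raise EmptyStructureError(f"{path}: structure contains no atoms")
    return StructureData(structure_id or st.name.lower() or path.stem, residues)


def _in_segments(res: ResidueRecord, segments) -> bool:
    for chain, start, end in segments:
        if chain and res.chain_id != chain:
            continue
        if start is None:
            return True
        if start <= res.auth_seq_num <= end:
            return True
    return False


def extract_domain(
    structure: StructureData,
    domain_def: DomainDef,
    protein_chains: set[str] | None = None,
) -> DomainStructure:
    """Restrict a structure to one domain; everything else becomes cochains.

    ``protein_chains`` lists author chains associated with *any* domain
    of the entry (defaults to the chains of ``domain_def``); polymer
    amino-acid subchains on those chains are never treated as small
    molecules even when outside the domain's residue range.
    """
    chains_in_def = {c for c, _, _ in domain_def.segments if c}
    if protein_chains is None:
        protein_chains = chains_in_def
    present = {r.chain_id for r in structure.residues}
    missing = chains_in_def - present
    if missing:
        raise EmptyDomainError(
            f"{domain_def.domain_id}: chains {sorted(missing)} absent from structure"
        )

    domain_res = [
        r for r in structure.residues
        if r.is_polymer_aa and _in_segments(r, domain_def.segments)
    ]
    if not domain_res:
        raise EmptyDomainError(f"{domain_def.domain_id}: no residues in range")

    domain_subchains = {r.subchain_id for r in domain_res}
    cochains: dict[str, list[ResidueRecord]] = {}
    for r in structure.residues:
        if r.subchain_id in domain_subchains:
            continue
        if r.is_polymer_aa and r.chain_id in protein_chains:
            continue  # part of a protein chain, not a small molecule
        cochains.setdefault(r.subchain_id, []).append(r)

    molecules = [
        Molecule(sub, tuple(res.comp_id for res in rlist), rlist)
        for sub, rlist in cochains.items()
    ]
    return DomainStructure(domain_def.domain_id, domain_res, molecules)


def find_nsm_sites(
    domain: DomainStructure,
    cochains: list[Molecule] | None = None,
    cutoff: float = 5.0,
) -> list[NSMSite]:
    """Residues near each small molecule (heavy-atom distance <= cutoff).

    One site per molecule with at least one near residue; molecules with
    no residue in range yield no site.
    """
    if cochains is None:
        cochains = domain.cochains
    heavy = domain.heavy_coords()
    if heavy.size == 0:
        return []
    keys = domain.residue_of_heavy_atom()
    tree = cKDTree(heavy)
    sites = []
    for i, mol in enumerate(cochains):
        mol_pts = mol.heavy_coords()
        if mol_pts.size == 0:
            continue
        idx = tree.query_ball_point(mol_pts, r=cutoff)
        near = frozenset(keys[j] for hits in idx for j in hits)
        if near:
            sites.append(
                NSMSite(
                    site_id=f"{domain.domain_id}.nsm{i}",
                    molecule=mol.comp_ids,
                    subchain_id=mol.subchain_id,
                    residues=near,
                )
            )
    return sites


_CODE_SPLIT = re.compile(r"[\s\-:;]+")


def _canonical_codes(codes, synonyms: dict[str, str] | None) -> tuple[str, ...]:
    if not synonyms:
        return tuple(codes)
    return tuple(synonyms.get(c, c) for c in codes)


def load_moad(path: str | Path) -> list[MoadRecord]:
    """Read ligand-validity records (``pdb_id,codes,validity`` CSV)."""
    records = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 3:
                logger.warning("ligand record line %d malformed, skipped: %r", lineno, row)
                continue
            pdb_id, codes_raw, validity = row[0].strip(), row[1].strip(), row[2].strip().lower()
            codes = tuple(c.upper() for c in _CODE_SPLIT.split(codes_raw) if c)
            if not pdb_id or not codes or validity not in ("valid", "invalid"):
                logger.warning("ligand record line %d malformed, skipped: %r", lineno, row)
                continue
            records.append(MoadRecord(pdb_id.lower(), codes, validity))
    return records


def match_moad(
    sites: list[NSMSite],
    moad_records: list[MoadRecord],
    pdb_id: str,
    synonyms: dict[str, str] | None = None,
) -> list[NSMSite]:
    """Label sites valid/invalid by ordered hetero-code list matching.

    A site's code list must equal a record's list for that PDB id
    (after optional synonym canonicalization, e.g. GGL<->GLU); unmatched
    sites stay ``uncurated``. One record labels every matching molecule
    instance.
    """
    by_codes: dict[tuple[str, ...], str] = {}
    for rec in moad_records:
        if rec.pdb_id.lower() == pdb_id.lower():
            by_codes[_canonical_codes(rec.codes, synonyms)] = rec.validity
    for site in sites:
        validity = by_codes.get(_canonical_codes(site.molecule, synonyms))
        if validity is not None:
            site.validity = validity
    return sites


def load_csa(path: str | Path) -> list[CatalyticAnnotation]:
    """Read catalytic-residue records, keeping only LIT evidence."""
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() in ("pdb_id", "pdb id"):
                continue  # header
            if len(row) < 5:
                logger.warning("catalytic record line %d malformed, skipped: %r", lineno, row)
                continue
            pdb_id, chain, num, comp, evidence = (c.strip() for c in row[:5])
            ev = evidence.upper()
            if ev == "PSI-BLAST":
                continue  # transitive annotations are derived separately
            if ev != "LIT":
                logger.warning("unknown evidence %r on line %d, skipped", evidence, lineno)
                continue
            try:
                seq = int(num)
            except ValueError:
                logger.warning("catalytic record line %d malformed, skipped: %r", lineno, row)
                continue
            out.append(CatalyticAnnotation(pdb_id.lower(), chain, seq, comp.upper(), ev))
    return out
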