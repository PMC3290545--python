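"""Synthetic study generators.

Every stage of the pipeline is testable without downloads: this module
writes genuine PDB files, plain-text abstracts, PMID->PDB link tables
and aligned FASTA pairs, together with exhaustive gold tables for every
planted feature.  Identical seeds give byte-identical output.

The synthetic protein is a V-shaped two-arm Calpha/Cbeta scaffold: two
jittered arms diverge from a hinge, so the cleft between them forms a
concave pocket (small relative to the total surface, which keeps the
perturbation field right-skewed the way pocketed proteins are), and a
small hetero molecule can be placed inside the cleft.  The gold set of
pocket residues is computed by a direct all-pairs distance scan over
the same rounded coordinates that are written to the file.  The
scaffold is not a physically realistic fold; it exists to give the
geometry the pipeline needs (a surface, a pocket, a nearby ligand)
under full control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._aa import ONE_TO_THREE, THREE_TO_ONE
from .mentions import NormalizedMention

AA_CODES = sorted(THREE_TO_ONE)
FIRST_RESNUM = 10
DEFAULT_PDB_ID = "1syn"
DEFAULT_PMID = "90000001"

#: text fragments that look like mentions but are not (gene, cell-line
#: and plasmid names); gold marks them as non-mentions
DISTRACTORS = [
    "the E2F transcription factor",
    "T47D cells",
    "plasmid R377",
    "HeLa extracts",
]


@dataclass
class SyntheticStudy:
    seed: int
    pdb_id: str
    pmid: str
    pdb_text: str
    abstract: str
    links: dict[str, list[str]]
    gold_nsm_resnums: list[int]
    gold_mentions: list[NormalizedMention]
    #: (wt3, position, mut3 or None) tuples planted as real residues
    planted_residues: list[tuple]
    sequence: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "structure": outdir / f"{self.pdb_id}.pdb",
            "abstract": outdir / f"{self.pmid}.txt",
            "links": outdir / "pmid2pdb.tsv",
            "gold_nsm": outdir / "gold_nsm.tsv",
            "gold_mentions": outdir / "gold_mentions.tsv",
        }
        paths["structure"].write_text(self.pdb_text)
        paths["abstract"].write_text(self.abstract)
        paths["links"].write_text(f"{self.pmid}\t{self.pdb_id}\n")
        paths["gold_nsm"].write_text(
            "".join(f"{self.pdb_id}\tA\t{n}\n" for n in self.gold_nsm_resnums))
        lines = []
        for m in self.gold_mentions:
            lines.append(f"{self.pmid}\t{m.span[0]}\t{m.span[1]}\t{m.wt_code}"
                         f"\t{m.position}\t{m.mut_code or ''}\n")
        paths["gold_mentions"].write_text("".join(lines))
        return paths


ARM_HALF_ANGLE_DEG = 20.0


def _vfold_backbone(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """Calpha positions of two jittered arms diverging from a hinge."""
    half = n_residues // 2
    arms = []
    for k, sign in enumerate((+1, -1)):
        t = np.arange(half + (n_residues % 2) * k) * 3.8
        ang = math.radians(ARM_HALF_ANGLE_DEG) * sign
        arm = np.column_stack([
            t * math.cos(ang),
            t * math.sin(ang),
            0.3 * sign * np.sin(t / 5.0),
        ])
        arms.append(arm)
    ca = np.vstack(arms)
    ca += rng.normal(scale=0.25, size=ca.shape)
    return ca


def _structure_from_arrays(pdb_id, seq3, ca, cb, ligand_xyz):
    st = gemmi.Structure()
    st.name = pdb_id
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for i, code in enumerate(seq3):
        res = gemmi.Residue()
        res.name = code
        res.seqid = gemmi.SeqId(FIRST_RESNUM + i, " ")
        for name, el, xyz in [("CA", "C", ca[i]), ("CB", "C", cb[i])]:
            if name == "CB" and code == "GLY":
                continue
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*xyz)
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    if ligand_xyz is not None:
        lig_chain = gemmi.Chain("X")
        res = gemmi.Residue()
        res.name = "LIG"
        res.seqid = gemmi.SeqId(1, " ")
        res.het_flag = "H"
        for k, xyz in enumerate(ligand_xyz):
            at = gemmi.Atom()
            at.name = f"C{k + 1}"
            at.element = gemmi.Element("C")
            at.pos = gemmi.Position(*xyz)
            res.add_atom(at)
        lig_chain.add_residue(res)
        model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    return st


def make_structure(
    n_residues: int = 30,
    pocket_depth: float = 4.0,
    ligand: bool = True,
    seed: int = 0,
    pdb_id: str = DEFAULT_PDB_ID,
    _attempt: int = 0,
) -> tuple[str, list[int], list[str]]:
    """Synthetic PDB text, gold pocket residue numbers, and the sequence.

    ``pocket_depth`` is the perpendicular distance (A) from the planted
    ligand to each arm's axis; it places the ligand inside the cleft.
    Gold residues are exactly those with a heavy atom within 5 A of a
    ligand heavy atom, found by a direct all-pairs scan over the
    coordinates as written (3 decimals).  If a requested ligand ends up
    touching no residue the generator retries with a fresh seed a few
    times before giving up.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed + 1000 * _attempt)
    ca = _vfold_backbone(n_residues, rng)
    # side-chain proxy atoms alternate above/below the cleft plane
    cb = ca + np.array([0.0, 0.0, 1.53]) * np.where(
        np.arange(n_residues)[:, None] % 2 == 0, 1.0, -1.0)
    cb += rng.normal(scale=0.1, size=ca.shape)

    seq3 = [AA_CODES[i] for i in rng.integers(0, len(AA_CODES), n_residues)]

    ligand_xyz = None
    if ligand:
        # on the cleft bisector (x axis), pocket_depth from each arm axis
        d = pocket_depth / math.sin(math.radians(ARM_HALF_ANGLE_DEG))
        lig_center = np.array([d, 0.0, 0.0])
        offsets = np.array([[0, 0, 0], [1.3, 0.4, 0.2], [-0.5, 1.2, -0.3]])
        ligand_xyz = lig_center + offsets

    st = _structure_from_arrays(pdb_id, seq3, ca, cb, ligand_xyz)
    pdb_text = st.make_pdb_string()

    gold: list[int] = []
    if ligand:
        # gold by brute force over the rounded coordinates that were written
        ca_r, cb_r, lig_r = (np.round(x, 3) for x in (ca, cb, ligand_xyz))
        for i in range(n_residues):
            atoms = [ca_r[i]] if seq3[i] == "GLY" else [ca_r[i], cb_r[i]]
            near = any(
                np.linalg.norm(a - l) <= 5.0 for a in atoms for l in lig_r
            )
            if near:
                gold.append(FIRST_RESNUM + i)
        if not gold:
            if _attempt >= 5:
                raise RuntimeError("could not place a ligand near any residue")
            return make_structure(n_residues, pocket_depth, ligand, seed,
                                  pdb_id, _attempt + 1)
    return pdb_text, gold, seq3


# --- abstracts ------------------------------------------------------------

_FULL_OF = {
    "ALA": "alanine", "ARG": "arginine", "ASN": "asparagine",
    "ASP": "aspartate", "CYS": "cysteine", "GLN": "glutamine",
    "GLU": "glutamate", "GLY": "glycine", "HIS": "histidine",
    "ILE": "isoleucine", "LEU": "leucine", "LYS": "lysine",
    "MET": "methionine", "PHE": "phenylalanine", "PRO": "proline",
    "SER": "serine", "THR": "threonine", "TRP": "tryptophan",
    "TYR": "tyrosine", "VAL": "valine",
}

STYLES = ("compact", "hyphen", "full", "mutation_short", "mutation_linguistic",
          "arrow")


def _render(style: str, wt: str, pos: int, mut: str | None):
    """Return (text, [(rel_start, rel_end, wt, pos, mut), ...])."""
    wt_t = wt.capitalize()
    if style == "compact":
        t = f"{wt_t}{pos}"
        return t, [(0, len(t), wt, pos, None)]
    if style == "hyphen":
        t = f"{wt_t}-{pos}"
        return t, [(0, len(t), wt, pos, None)]
    if style == "full":
        t = f"{_FULL_OF[wt]} {pos}"
        return t, [(0, len(t), wt, pos, None)]
    if mut is None:
        raise ValueError(f"style {style!r} needs a mutant code")
    if style == "mutation_short":
        t = f"{THREE_TO_ONE[wt]}{pos}{THREE_TO_ONE[mut]}"
        return t, [(0, len(t), wt, pos, mut)]
    if style == "arrow":
        t = f"{wt_t}{pos}→{mut.capitalize()}"
        return t, [(0, len(t), wt, pos, mut)]
    if style == "mutation_linguistic":
        t = f"{wt_t}-{pos} was mutated to {_FULL_OF[mut]}"
        return t, [(0, len(t), wt, pos, mut)]
    raise ValueError(f"unknown style {style!r}")


def make_abstract(
    residues: list[tuple],
    styles: tuple[str, ...] = STYLES,
    n_distractors: int = 2,
    seed: int = 0,
    pmid: str = DEFAULT_PMID,
) -> tuple[str, list[NormalizedMention]]:
    """Abstract text with planted mentions and exhaustive gold spans.

    ``residues`` holds ``(wt3, position)`` or ``(wt3, position, mut3)``
    tuples; each is rendered in the next style from ``styles`` (mutation
    styles fall back to "compact" for tuples without a mutant code).
    Distractors are gene/cell-line lookalikes that the gold table marks
    as non-mentions.
    """
    rng = np.random.default_rng(seed)
    parts = ["We determined the crystal structure of the synthetic protein."]
    gold: list[NormalizedMention] = []
    text = parts[0]
    style_cycle = [s for s in styles if s in STYLES] or ["compact"]
    for i, tup in enumerate(residues):
        wt, pos = tup[0].upper(), int(tup[1])
        mut = tup[2].upper() if len(tup) > 2 and tup[2] else None
        style = style_cycle[i % len(style_cycle)]
        if mut is None and style in ("mutation_short", "mutation_linguistic", "arrow"):
            style = "compact"
        rendered, spans = _render(style, wt, pos, mut)
        lead = " Site-directed analysis implicated "
        text += lead + rendered + " in catalysis."
        offset = len(text) - len(" in catalysis.") - len(rendered)
        for rs, re_, w, p, m in spans:
            gold.append(NormalizedMention(w, p, m, (offset + rs, offset + re_), pmid))
    for d in rng.permutation(DISTRACTORS)[:n_distractors]:
        text += f" Experiments used {d}."
    return text, gold


# --- alignments -----------------------------------------------------------

def make_msa(
    n_proteins: int = 4,
    domains_per_protein: int = 2,
    n_columns: int = 20,
    conserved_columns: tuple[int, ...] = (5, 12),
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], dict[str, str], dict]:
    """Protein- and family-level aligned FASTA data with gold conservation.

    Returns ``(protein_msas, family_msa, gold)``.  Conserved columns
    carry one fixed amino acid in every row (gold H.norm exactly 1);
    other columns are drawn near-uniformly.  Each protein's second and
    later domains are shortened by a two-column internal gap, so the
    longest (representative) domain is always the first, and gap
    propagation is exercised.
    """
    if n_proteins < 2:
        raise ValueError("family-level alignment needs at least two proteins")
    rng = np.random.default_rng(seed)
    letters = sorted(ONE_TO_THREE)
    conserved_aa = {c: letters[int(rng.integers(0, 20))] for c in conserved_columns}

    family_msa: dict[str, str] = {}
    protein_msas: dict[str, dict[str, str]] = {}
    gold_rows: dict[str, str] = {}
    for p in range(n_proteins):
        pid = f"prot{p + 1}"
        rep_sid = f"d{pid}a"
        cols = []
        for c in range(n_columns):
            if c in conserved_aa:
                cols.append(conserved_aa[c])
            else:
                cols.append(letters[int(rng.integers(0, 20))])
        rep_seq = "".join(cols)
        family_msa[rep_sid] = rep_seq
        gold_rows[rep_sid] = rep_seq
        members = {rep_sid: rep_seq}
        gap_at = n_columns // 2
        for d in range(1, domains_per_protein):
            sid = f"d{pid}{chr(ord('a') + d)}"
            aligned = rep_seq[:gap_at] + "--" + rep_seq[gap_at + 2:]
            members[sid] = aligned
        protein_msas[pid] = members
    gold = {
        "conserved_columns": sorted(conserved_columns),
        "conserved_aa": {c: conserved_aa[c] for c in conserved_columns},
        "n_rows_family": n_proteins,
    }
    return protein_msas, family_msa, gold


def write_msa_fasta(rows: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in rows.items():
            fh.write(f">{sid}\n{seq}\n")


# --- whole study ----------------------------------------------------------

def make_study(seed: int = 0, n_residues: int = 30) -> SyntheticStudy:
    """A matched structure + abstract + link table with full gold tables.

    Three pocket residues are mentioned in the abstract (one of them as
    a point mutation whose wild type is the residue actually present in
    the structure), alongside distractor tokens whose positions do not
    exist in the structure.
    """
    pdb_text, gold_nsm, seq3 = make_structure(
        n_residues=n_residues, ligand=True, seed=seed)
    rng = np.random.default_rng(seed + 7)

    pocket = gold_nsm if len(gold_nsm) >= 3 else list(
        range(FIRST_RESNUM, FIRST_RESNUM + n_residues))
    picks = sorted(rng.choice(len(pocket), size=min(3, len(pocket)), replace=False))
    mentioned = [pocket[i] for i in picks]
    planted = []
    for j, resnum in enumerate(mentioned):
        wt = seq3[resnum - FIRST_RESNUM]
        if j == len(mentioned) - 1:  # last one as a mutation mention
            mut = "ALA" if wt != "ALA" else "GLY"
            planted.append((wt, resnum, mut))
        else:
            planted.append((wt, resnum, None))

    abstract, gold_mentions = make_abstract(
        planted, styles=("compact", "full", "mutation_short"),
        n_distractors=2, seed=seed)
    return SyntheticStudy(
        seed=seed,
        pdb_id=DEFAULT_PDB_ID,
        pmid=DEFAULT_PMID,
        pdb_text=pdb_text,
        abstract=abstract,
        links={DEFAULT_PMID: [DEFAULT_PDB_ID]},
        gold_nsm_resnums=gold_nsm,
        gold_mentions=gold_mentions,
        planted_residues=planted,
        sequence=seq3,
    )
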