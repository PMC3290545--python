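import numpy as np
import pytest

from leapfs import fixtures
from leapfs.structure_io import (
    Atom,
    DomainStructure,
    Molecule,
    ResidueRecord,
)


def make_residue(chain, num, comp, atom_xyz, entity="1", subchain="Axp", icode=""):
    """A ResidueRecord with carbon heavy atoms at the given coordinates."""
    rec = ResidueRecord(chain, num, icode, comp, entity, subchain,
                        is_polymer_aa=True)
    for i, xyz in enumerate(atom_xyz):
        rec.atoms.append(Atom(
            name="CA" if i == 0 else f"C{i}", element="C",
            coords=np.asarray(xyz, dtype=float), chain_id=chain,
            auth_seq_num=num, icode=icode, comp_id=comp, entity_id=entity,
            is_heavy=True,
        ))
    return rec


def make_molecule(comp_ids, atom_xyz, subchain="Xx1"):
    residues = []
    per = max(1, len(atom_xyz) // len(comp_ids))
    chunks = [atom_xyz[i * per:(i + 1) * per] for i in range(len(comp_ids))]
    chunks[-1] = atom_xyz[(len(comp_ids) - 1) * per:]
    for k, (comp, xyz) in enumerate(zip(comp_ids, chunks)):
        rec = ResidueRecord("X", k + 1, "", comp, "9", subchain,
                            is_polymer_aa=False)
        for i, p in enumerate(xyz):
            rec.atoms.append(Atom(
                name=f"C{i}", element="C", coords=np.asarray(p, dtype=float),
                chain_id="X", auth_seq_num=k + 1, icode="", comp_id=comp,
                entity_id="9", is_heavy=True,
            ))
        residues.append(rec)
    return Molecule(subchain, tuple(comp_ids), residues)


def make_domain(residues, cochains=(), domain_id="dtest"):
    return DomainStructure(domain_id, list(residues), list(cochains))


@pytest.fixture(scope="session")
def study():
    """One synthetic study shared across tests (read-only)."""
    return fixtures.make_study(seed=1)


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    study.write(d)
    return d
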