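"""Reading and writing complexes: PDB receptors, SDF/MOL ligands.

Receptors are parsed with gemmi; hydrogens, waters and hetero groups are
dropped, and one virtual RING_CENTER pseudo-atom is appended at the centroid
of each aromatic residue ring (His/Phe/Tyr/Trp).  Ligands are parsed with
RDKit from SDF/MOL V2000 blocks; their bond set is taken from the file.
"""

from __future__ import annotations

import numpy as np

import gemmi
from rdkit import Chem

from .complexes import (
    RING_CENTER,
    AtomRecord,
    AtomTypeVocabulary,
    ComplexError,
    MolecularComplex,
    canonical_bond,
    perceive_bonds,
)


class FormatError(ValueError):
    """Input file could not be parsed in the expected format."""


class EmptyLigandError(ValueError):
    """Ligand contains no heavy atoms."""


_AROMATIC_RING_ATOMS = {
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _pocket_bonds(atoms: list[AtomRecord]) -> set[tuple[int, int]]:
    """Covalent pocket bonds: 1.9 Å perception restricted to same or
    adjacent residues (peptide C-N links)."""
    real = [a for a in atoms if a.role in ("backbone", "sidechain")]
    if len(real) < 2:
        return set()
    coords = np.array([a.coords for a in real])
    bonds = set()
    for i, j in perceive_bonds(coords, cutoff=1.9):
        ai, aj = real[i], real[j]
        if abs(ai.residue_id - aj.residue_id) <= 1:
            bonds.add(canonical_bond(ai.index, aj.index))
    return bonds


def _read_receptor_atoms(receptor_path: str, vocab: AtomTypeVocabulary) -> list[AtomRecord]:
    try:
        st = gemmi.read_pdb(str(receptor_path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB {receptor_path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{receptor_path}: no model in PDB file")
    atoms: list[AtomRecord] = []
    rid = 0
    for chain in st[0]:
        for res in chain:
            if res.name in _WATER_NAMES or res.het_flag == "H":
                continue
            placed = 0
            for at in res:
                if at.element.is_hydrogen:
                    continue
                el = at.element.name
                token = vocab.protein_token_for(at.name, el)
                role = "backbone" if at.name in ("N", "CA", "C", "O") else "sidechain"
                atoms.append(
                    AtomRecord(len(atoms), el, token,
                               np.array([at.pos.x, at.pos.y, at.pos.z]), rid, role)
                )
                placed += 1
            if placed and res.name in _AROMATIC_RING_ATOMS:
                names = _AROMATIC_RING_ATOMS[res.name]
                ring = [at for at in res if at.name in names]
                if ring:
                    center = np.mean(
                        [[at.pos.x, at.pos.y, at.pos.z] for at in ring], axis=0
                    )
                    atoms.append(
                        AtomRecord(len(atoms), "X", RING_CENTER, center, rid, "virtual")
                    )
            if placed:
                rid += 1
    return atoms


def _read_ligand_mol(ligand_path: str) -> Chem.Mol:
    suppl = Chem.SDMolSupplier(str(ligand_path), removeHs=False, sanitize=False)
    mol = None
    for m in suppl:
        if m is not None:
            mol = m
            break
    if mol is None:
        raise FormatError(f"cannot parse SDF/MOL {ligand_path}")
    try:
        mol = Chem.RemoveHs(mol, sanitize=False)
    except Exception:
        pass
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        raise EmptyLigandError(f"{ligand_path}: ligand has no heavy atoms")
    return mol


def read_complex(
    receptor_path: str | None,
    ligand_path: str,
    vocabulary: AtomTypeVocabulary | None = None,
    max_atoms: int = 400,
) -> MolecularComplex:
    """Load receptor PDB + ligand SDF into one pocket-then-ligand complex.

    ``receptor_path`` may be None for a ligand-only complex.  Hydrogens are
    dropped everywhere; ligand bonds come from the SDF connection table.
    """
    vocab = vocabulary or AtomTypeVocabulary()
    atoms = _read_receptor_atoms(receptor_path, vocab) if receptor_path else []
    bonds = _pocket_bonds(atoms)

    mol = _read_ligand_mol(ligand_path)
    conf = mol.GetConformer()
    base = len(atoms)
    keep: dict[int, int] = {}
    for a in mol.GetAtoms():
        if a.GetAtomicNum() <= 1:
            continue
        pos = conf.GetAtomPosition(a.GetIdx())
        el = a.GetSymbol()
        token = el if el in vocab.ligand_elements else "UNK"
        keep[a.GetIdx()] = base + len(keep)
        atoms.append(
            AtomRecord(base + len(keep) - 1, el, token,
                       np.array([pos.x, pos.y, pos.z]), -1, "ligand")
        )
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in keep and j in keep:
            bonds.add(canonical_bond(keep[i], keep[j]))
    return MolecularComplex(atoms, bonds, max_atoms)


# ---------------------------------------------------------------------------
# writing


def write_complex(
    complex: MolecularComplex,
    pdb_path: str,
    sdf_path: str,
    bond_orders: dict[tuple[int, int], int] | None = None,
) -> None:
    """Write the pocket as PDB and the ligand (with its bond set) as SDF.

    Virtual ring-center atoms are not written; they are regenerated from ring
    geometry on reading.  Ligand bonds default to single order unless
    ``bond_orders`` provides an explicit order per (canonical) pair.
    """
    _write_pocket_pdb(complex, pdb_path)
    _write_ligand_sdf(complex, sdf_path, bond_orders)


def _write_pocket_pdb(complex: MolecularComplex, path: str) -> None:
    lines = []
    serial = 0
    sc_counts: dict[tuple[int, str], int] = {}
    for a in complex.atoms:
        if a.role not in ("backbone", "sidechain"):
            continue
        serial += 1
        if a.atom_type.startswith("BB_"):
            name = a.atom_type[3:]
        else:
            k = sc_counts.get((a.residue_id, a.element), 0) + 1
            sc_counts[(a.residue_id, a.element)] = k
            name = f"{a.element}{k}"
        name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = a.coords
        lines.append(
            f"ATOM  {serial:5d} {name_f} GLY A{a.residue_id + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}\n"
        )
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def _write_ligand_sdf(
    complex: MolecularComplex,
    path: str,
    bond_orders: dict[tuple[int, int], int] | None = None,
) -> None:
    lig_idx = np.flatnonzero(complex.ligand_mask)
    if lig_idx.size == 0:
        raise ComplexError("complex has no ligand atoms to write")
    remap = {int(gi): k for k, gi in enumerate(lig_idx)}
    mol = Chem.RWMol()
    conf = Chem.Conformer(len(lig_idx))
    for k, gi in enumerate(lig_idx):
        a = complex.atoms[int(gi)]
        idx = mol.AddAtom(Chem.Atom(a.element))
        conf.SetAtomPosition(idx, tuple(float(v) for v in a.coords))
    orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for i, j in sorted(complex.ligand_bonds):
        order = (bond_orders or {}).get(canonical_bond(i, j), 1)
        mol.AddBond(remap[i], remap[j], orders.get(order, Chem.BondType.SINGLE))
    m = mol.GetMol()
    m.AddConformer(conf)
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        w.write(m)
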