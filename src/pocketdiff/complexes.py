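"""Domain types for pocket+ligand complexes and geometric primitives.

A complex is a flat, ordered list of heavy atoms (pocket first, then ligand)
with a bond set over atom indices.  Hydrogens are excluded throughout the
package; "atoms" always means heavy atoms.  Virtual RING_CENTER pseudo-atoms
mark the centroid of aromatic residue rings (His/Phe/Tyr/Trp) and belong to
the pocket side of the representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

RING_CENTER = "RING_CENTER"
UNK = "UNK"

ROLES = ("backbone", "sidechain", "ligand", "virtual")

#: maximum heavy-atom valence used by bond-order assignment and the fixture
#: generator; S may expand to 6 in sulfones but 2 is the default cap.
MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5,
               "F": 1, "Cl": 1, "Br": 1, "I": 1}

BACKBONE_NAMES = ("N", "CA", "C", "O")


class ComplexError(ValueError):
    """Raised when a complex violates a structural invariant."""


@dataclass(frozen=True)
class AtomTypeVocabulary:
    """Bijective token <-> index mapping for the categorical diffusion.

    The vocabulary concatenates ligand element tokens, protein atom-name
    derived tokens (four backbone tokens plus per-element side-chain tokens),
    and two specials: RING_CENTER for aromatic-ring pseudo-atoms and UNK for
    anything outside the lists.  ``K`` is the total category count seen by the
    discrete diffusion.
    """

    ligand_elements: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    protein_tokens: tuple[str, ...] = (
        "BB_N", "BB_CA", "BB_C", "BB_O", "SC_C", "SC_N", "SC_O", "SC_S",
    )

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.ligand_elements + self.protein_tokens + (RING_CENTER, UNK)

    @property
    def K(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            return self.tokens.index(UNK)

    def __contains__(self, token: str) -> bool:
        return token in self.tokens

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    def is_ligand_element(self, token: str) -> bool:
        return token in self.ligand_elements

    def protein_token_for(self, atom_name: str, element: str) -> str:
        """Collapse a PDB atom name to a vocabulary token."""
        if atom_name in BACKBONE_NAMES:
            return "BB_" + atom_name
        tok = "SC_" + element
        return tok if tok in self.protein_tokens else UNK


@dataclass
class AtomRecord:
    """One heavy atom (or virtual pseudo-atom) of a complex."""

    index: int
    element: str
    atom_type: str
    coords: np.ndarray
    residue_id: int
    role: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ComplexError(f"atom {self.index}: non-finite coordinates")
        if self.role not in ROLES:
            raise ComplexError(f"atom {self.index}: unknown role {self.role!r}")
        if (self.role == "ligand") != (self.residue_id == -1):
            raise ComplexError(
                f"atom {self.index}: ligand role and residue_id=-1 must coincide"
            )
        if self.role == "virtual" and self.atom_type != RING_CENTER:
            raise ComplexError(f"atom {self.index}: virtual atoms must be {RING_CENTER}")


@dataclass
class MolecularComplex:
    """Pocket + ligand as one ordered atom list with a bond set.

    Atoms are ordered pocket-side first (including virtual ring centers),
    ligand last.  Bonds are unordered index pairs; ligand bonds come from the
    input SDF or from distance perception, pocket bonds from intra/inter
    residue distance perception at load time.
    """

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    max_atoms: int = 400

    def __post_init__(self) -> None:
        self.bonds = {canonical_bond(i, j) for i, j in self.bonds}
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        if n > self.max_atoms:
            raise ComplexError(f"{n} atoms exceeds maximum of {self.max_atoms}")
        for pos, atom in enumerate(self.atoms):
            if atom.index != pos:
                raise ComplexError("atom indices must match list positions")
        seen_ligand = False
        for atom in self.atoms:
            if atom.role == "ligand":
                seen_ligand = True
            elif seen_ligand:
                raise ComplexError("pocket atoms must precede all ligand atoms")
        coords = self.coords
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ComplexError(f"bond ({i},{j}) out of range")
            if np.linalg.norm(coords[i] - coords[j]) >= 3.0:
                raise ComplexError(f"bond ({i},{j}) longer than 3 A at load time")

    # -- views --------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def pocket_mask(self) -> np.ndarray:
        return np.array([a.role in ("backbone", "sidechain") for a in self.atoms])

    @property
    def ligand_mask(self) -> np.ndarray:
        return np.array([a.role == "ligand" for a in self.atoms])

    @property
    def virtual_mask(self) -> np.ndarray:
        return np.array([a.role == "virtual" for a in self.atoms])

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=int)

    @property
    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    def type_indices(self, vocab: AtomTypeVocabulary) -> np.ndarray:
        return np.array([vocab.index(a.atom_type) for a in self.atoms], dtype=int)

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == "ligand"]

    @property
    def ligand_bonds(self) -> set[tuple[int, int]]:
        lig = set(np.flatnonzero(self.ligand_mask))
        return {b for b in self.bonds if b[0] in lig and b[1] in lig}

    def pocket_centroid(self) -> np.ndarray:
        mask = self.pocket_mask
        if not mask.any():
            mask = self.ligand_mask
        return self.coords[mask].mean(axis=0)

    def centered(self) -> "MolecularComplex":
        """Copy translated so the pocket centroid sits at the origin."""
        shift = self.pocket_centroid()
        atoms = [
            AtomRecord(a.index, a.element, a.atom_type, a.coords - shift,
                       a.residue_id, a.role)
            for a in self.atoms
        ]
        return MolecularComplex(atoms, set(self.bonds), self.max_atoms)

    def with_coords(self, coords: np.ndarray) -> "MolecularComplex":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            AtomRecord(a.index, a.element, a.atom_type, coords[k], a.residue_id, a.role)
            for k, a in enumerate(self.atoms)
        ]
        # bond-length invariant is a load-time check; intermediate diffusion
        # geometry is unconstrained, so rebuild without bonds when violated
        try:
            return MolecularComplex(atoms, set(self.bonds), self.max_atoms)
        except ComplexError:
            return MolecularComplex(atoms, set(), self.max_atoms)


def canonical_bond(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ComplexError(f"self-bond on atom {i}")
    return (i, j) if i < j else (j, i)


def perceive_bonds(coords: np.ndarray, cutoff: float = 1.9) -> set[tuple[int, int]]:
    """All unordered atom pairs strictly closer than ``cutoff`` (Å).

    Distance-based covalent bond identification; the default 1.9 Å covers
    standard heavy-atom single/double bond lengths while excluding 1-3
    (geminal) distances.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if n < 2:
        return set()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: set[tuple[int, int]] = set()
    for i, j in pairs:
        # query_pairs uses <=; the bond rule is strict <
        if np.linalg.norm(coords[i] - coords[j]) < cutoff:
            out.add(canonical_bond(int(i), int(j)))
    return out


def extract_pocket(complex: MolecularComplex, cutoff: float = 6.0) -> MolecularComplex:
    """Restrict the pocket to residues with any atom within ``cutoff`` of the ligand.

    Residues are kept or dropped atomically (virtual ring centers follow their
    residue).  The rule is inclusive: a residue whose nearest atom sits at
    exactly ``cutoff`` Å is retained.  The ligand is never modified.
    """
    lig_mask = complex.ligand_mask
    if not lig_mask.any():
        raise ComplexError("extract_pocket requires at least one ligand atom")
    coords = complex.coords
    lig_coords = coords[lig_mask]

    keep_res: set[int] = set()
    res_ids = complex.residue_ids
    pocket_like = ~lig_mask
    for rid in np.unique(res_ids[pocket_like]):
        if rid < 0:
            continue
        sel = pocket_like & (res_ids == rid) & ~complex.virtual_mask
        if not sel.any():
            sel = pocket_like & (res_ids == rid)
        dmin = cdist(coords[sel], lig_coords).min()
        if dmin <= cutoff:
            keep_res.add(int(rid))

    if not keep_res and pocket_like.any():
        warnings.warn("no residue within cutoff of the ligand; returning empty pocket")

    keep = np.array(
        [a.role == "ligand" or a.residue_id in keep_res for a in complex.atoms]
    )
    old_to_new = {}
    atoms: list[AtomRecord] = []
    for a in complex.atoms:
        if keep[a.index]:
            old_to_new[a.index] = len(atoms)
            atoms.append(AtomRecord(len(atoms), a.element, a.atom_type,
                                    a.coords.copy(), a.residue_id, a.role))
    bonds = {
        canonical_bond(old_to_new[i], old_to_new[j])
        for i, j in complex.bonds
        if keep[i] and keep[j]
    }
    return MolecularComplex(atoms, bonds, complex.max_atoms)
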