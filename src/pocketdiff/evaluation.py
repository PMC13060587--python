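"""Molecule- and pocket-quality metrics for generated structures.

Covers: chemical validity (sanitization + valence audit), connectivity,
large-ring (>6-membered cycle) detection, drug-likeness (QED, Lipinski rule
of five, synthetic accessibility score), SMARTS-based functional-group
census, fingerprint Tanimoto similarity, pocket RMSD (optionally after
Kabsch superposition) and residue-ligand minimum distances.  Metrics that
need a sanitized molecule are only computed for valid AND connected
molecules; otherwise they are None in the report.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, RDConfig

from .complexes import MolecularComplex

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (Ertl & Schuffenhauer SA score, ships with RDKit)


# --------------------------------------------------------------------------
# functional group library


_DEFAULT_PATTERNS: tuple[tuple[str, str], ...] = (
    ("carboxylic_acid", "C(=O)[OH]"),
    ("ester", "C(=O)O[#6]"),
    ("amide", "C(=O)[NX3]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("primary_secondary_amine", "[NX3;H2,H1;!$(NC=O)]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=*);!a]"),
    ("alcohol", "[OX2H][CX4]"),
    ("phenol", "[OX2H]c"),
    ("ether", "[OD2]([#6])[#6]"),
    ("epoxide", "C1OC1"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("sulfonamide", "S(=O)(=O)[NX3]"),
    ("halogen", "[F,Cl,Br,I]"),
    ("aromatic_ring", "[aR]"),
    ("cyclopropane", "[CX4]1[CX4][CX4]1"),
    ("cyclobutane", "[CX4]1[CX4][CX4][CX4]1"),
    ("cyclobutene", "C1=CCC1"),
)


class FunctionalGroupLibrary:
    """Ordered (name, SMARTS) library; extensible from a TSV of name\tSMARTS."""

    def __init__(self, patterns: tuple[tuple[str, str], ...] = _DEFAULT_PATTERNS):
        names = [n for n, _ in patterns]
        if len(set(names)) != len(names):
            raise ValueError("functional group names must be unique")
        self.patterns: list[tuple[str, Chem.Mol]] = []
        for name, smarts in patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"SMARTS for {name!r} does not compile: {smarts}")
            self.patterns.append((name, query))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.patterns]

    @classmethod
    def from_tsv(cls, path: str) -> "FunctionalGroupLibrary":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, smarts = line.split("\t")[:2]
                rows.append((name, smarts))
        return cls(tuple(rows))

    def matches(self, mol: Chem.Mol) -> dict[str, bool]:
        return {name: mol.HasSubstructMatch(q) for name, q in self.patterns}


# --------------------------------------------------------------------------
# per-molecule checks


def _as_mol(molecule) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"cannot parse SMILES {molecule!r}")
        return mol
    raise TypeError(f"expected RDKit Mol or SMILES, got {type(molecule)}")


def _sanitized(molecule) -> Chem.Mol | None:
    mol = Chem.Mol(_as_mol(molecule))
    try:
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def check_connectivity(molecule) -> bool:
    """True iff all atoms form a single bonded component."""
    mol = _as_mol(molecule)
    if mol.GetNumAtoms() == 0:
        return False
    return len(Chem.GetMolFrags(mol)) == 1


def connectivity_from_bonds(n_atoms: int, bonds: set[tuple[int, int]]) -> bool:
    """Graph-level connectivity for raw (atom count, bond set) input."""
    if n_atoms == 0:
        return False
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(bonds)
    return nx.number_connected_components(g) == 1


def check_large_ring(molecule) -> bool | None:
    """True iff the SSSR contains a ring of more than six atoms.

    Returns None for molecules that cannot be sanitized.
    """
    mol = _sanitized(molecule)
    if mol is None:
        return None
    return any(len(ring) > 6 for ring in Chem.GetSymmSSSR(mol))


def check_validity(molecule) -> bool:
    """Sanitization succeeds and no atom exceeds its allowed valence."""
    mol = Chem.Mol(_as_mol(molecule))
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return False
    for atom in mol.GetAtoms():
        pt = Chem.GetPeriodicTable()
        allowed = pt.GetValenceList(atom.GetAtomicNum())
        if allowed and max(allowed) > 0 and atom.GetTotalValence() > max(allowed):
            return False
    return True


def drug_likeness(molecule) -> tuple[float | None, bool | None, float | None]:
    """(QED, RO5 pass, SAS) for a sanitizable molecule, else (None,)*3.

    RO5 pass means at most one violation of {MW ≤ 500, logP ≤ 5, HBD ≤ 5,
    HBA ≤ 10}; QED is the Bickerton composite in [0, 1]; SAS the Ertl &
    Schuffenhauer score in [1, 10] (1 = easy to synthesize).
    """
    mol = _sanitized(molecule)
    if mol is None:
        return None, None, None
    violations = sum([
        Descriptors.MolWt(mol) > 500.0,
        Crippen.MolLogP(mol) > 5.0,
        Lipinski.NumHDonors(mol) > 5,
        Lipinski.NumHAcceptors(mol) > 10,
    ])
    return QED.qed(mol), violations <= 1, sascorer.calculateScore(mol)


def ro5_violation_count(molecule) -> int | None:
    mol = _sanitized(molecule)
    if mol is None:
        return None
    return sum([
        Descriptors.MolWt(mol) > 500.0,
        Crippen.MolLogP(mol) > 5.0,
        Lipinski.NumHDonors(mol) > 5,
        Lipinski.NumHAcceptors(mol) > 10,
    ])


def tanimoto_similarity(mol_a, mol_b) -> float | None:
    """Tanimoto coefficient over RDKit topological (Daylight-like) fingerprints."""
    a, b = _sanitized(mol_a), _sanitized(mol_b)
    if a is None or b is None:
        return None
    fa, fb = Chem.RDKFingerprint(a), Chem.RDKFingerprint(b)
    return DataStructs.TanimotoSimilarity(fa, fb)


def functional_group_census(
    molecules,
    library: FunctionalGroupLibrary | None = None,
    count_occurrences: bool = False,
) -> pd.Series:
    """Per-group fraction of molecules containing at least one match.

    With ``count_occurrences`` the mean number of (unique) matches per
    molecule is returned instead of the containment fraction.
    """
    library = library or FunctionalGroupLibrary()
    mols = [_sanitized(m) for m in molecules]
    mols = [m for m in mols if m is not None]
    if not mols:
        warnings.warn("empty molecule set; all census frequencies are zero")
        return pd.Series(0.0, index=library.names)
    out = {}
    for name, query in library.patterns:
        if count_occurrences:
            vals = [len(m.GetSubstructMatches(query)) for m in mols]
        else:
            vals = [m.HasSubstructMatch(query) for m in mols]
        out[name] = float(np.mean(vals))
    return pd.Series(out)


# --------------------------------------------------------------------------
# geometry metrics


def kabsch_rmsd(a: np.ndarray, b: np.ndarray, align: bool = True) -> float:
    """RMSD between matched coordinate sets, after optimal proper-rotation
    superposition when ``align`` is True."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have matching shapes")
    if not align:
        return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(a.shape[0]))


def pocket_rmsd(
    generated: MolecularComplex,
    native: MolecularComplex,
    align: bool = True,
) -> float:
    """Heavy-atom RMSD between generated and native pocket (Kabsch by default)."""
    gm, nm = generated.pocket_mask, native.pocket_mask
    if gm.sum() != nm.sum():
        raise ValueError("pocket atom counts differ; no correspondence")
    return kabsch_rmsd(generated.coords[gm], native.coords[nm], align=align)


def min_residue_ligand_distance(
    complex: MolecularComplex,
    residue_id: int,
    non_carbon: bool = False,
) -> float | None:
    """Minimum residue-atom to ligand-atom distance (Å).

    With ``non_carbon`` only non-carbon atoms on both sides are considered
    ("Min (Non-C)" mode).  Returns None when no qualifying atom pair exists.
    """
    res_sel = [a for a in complex.atoms
               if a.residue_id == residue_id and a.role in ("backbone", "sidechain")]
    if not res_sel:
        raise ValueError(f"residue {residue_id} not in complex")
    lig_sel = [a for a in complex.atoms if a.role == "ligand"]
    if non_carbon:
        res_sel = [a for a in res_sel if a.element != "C"]
        lig_sel = [a for a in lig_sel if a.element != "C"]
    if not res_sel or not lig_sel:
        return None
    d = cdist(np.array([a.coords for a in res_sel]),
              np.array([a.coords for a in lig_sel]))
    return float(d.min())


def compare_ligand_to_reference(
    gen_coords: np.ndarray,
    gen_types: np.ndarray,
    ref_coords: np.ndarray,
    ref_types: np.ndarray,
    n_starts: int = 24,
    seed: int = 0,
) -> tuple[float, float]:
    """(RMSD, type accuracy) under the best rotation + atom assignment.

    Generated atoms carry no index correspondence to the reference (the
    sampler is permutation-equivariant and starts from i.i.d. noise), so the
    comparison alternates Kabsch superposition and Hungarian matching from
    multiple random initial rotations and keeps the lowest-RMSD solution.
    """
    g = np.asarray(gen_coords, float)
    r = np.asarray(ref_coords, float)
    if g.shape != r.shape:
        raise ValueError("atom counts differ")
    gt = np.asarray(gen_types)
    rt = np.asarray(ref_types)
    gc = g - g.mean(axis=0)
    rc = r - r.mean(axis=0)
    rng = np.random.default_rng(seed)
    best = (np.inf, 0.0)
    for s in range(n_starts):
        rot = (Rotation.identity() if s == 0 else Rotation.random(random_state=rng))
        cur = rot.apply(gc)
        prev_cols = None
        for _ in range(15):
            # rows: generated atoms, cols: reference slots
            rows, cols = linear_sum_assignment(cdist(cur, rc) ** 2)
            fit, _ = Rotation.align_vectors(rc[cols], cur[rows])
            cur = fit.apply(cur)
            if prev_cols is not None and np.array_equal(cols, prev_cols):
                break
            prev_cols = cols
        rmsd = float(np.sqrt(((cur[rows] - rc[cols]) ** 2).sum(axis=1).mean()))
        if rmsd < best[0]:
            acc = float(np.mean(gt[rows] == rt[cols]))
            best = (rmsd, acc)
    return best


# --------------------------------------------------------------------------
# reports


@dataclass
class MoleculeReport:
    """Per-molecule metric record."""

    n_heavy_atoms: int
    valid: bool
    connected: bool
    has_large_ring: bool | None
    qed: float | None
    ro5_pass: bool | None
    sas: float | None
    functional_groups: dict[str, bool] = field(default_factory=dict)
    tanimoto_to_reference: float | None = None


def evaluate_molecule(
    molecule,
    reference=None,
    library: FunctionalGroupLibrary | None = None,
) -> MoleculeReport:
    """Full metric record for one molecule.

    Sanitization-dependent metrics (large ring, QED, RO5, SAS, functional
    groups, Tanimoto) are None unless the molecule is valid and connected.
    """
    mol = _as_mol(molecule)
    n_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    valid = check_validity(mol)
    connected = check_connectivity(mol)
    if not (valid and connected):
        return MoleculeReport(n_heavy, valid, connected, None, None, None, None)
    library = library or FunctionalGroupLibrary()
    sane = _sanitized(mol)
    qed, ro5, sas = drug_likeness(sane)
    tan = tanimoto_similarity(sane, reference) if reference is not None else None
    return MoleculeReport(
        n_heavy_atoms=n_heavy,
        valid=valid,
        connected=connected,
        has_large_ring=check_large_ring(sane),
        qed=qed,
        ro5_pass=ro5,
        sas=sas,
        functional_groups=library.matches(sane),
        tanimoto_to_reference=tan,
    )


def evaluate_set(
    molecules,
    reference=None,
    library: FunctionalGroupLibrary | None = None,
    size_bins: tuple[int, ...] = (0, 10, 15, 20, 25, 30, 35, 1000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-molecule table plus metric means binned by heavy-atom count."""
    reports = [evaluate_molecule(m, reference, library) for m in molecules]
    rows = []
    for rep in reports:
        row = {
            "n_heavy_atoms": rep.n_heavy_atoms,
            "valid": rep.valid,
            "connected": rep.connected,
            "has_large_ring": rep.has_large_ring,
            "qed": rep.qed,
            "ro5_pass": rep.ro5_pass,
            "sas": rep.sas,
            "tanimoto_to_reference": rep.tanimoto_to_reference,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    binned = df.copy()
    binned["size_bin"] = pd.cut(binned["n_heavy_atoms"], bins=list(size_bins))
    summary = binned.groupby("size_bin", observed=True)[
        ["valid", "connected", "has_large_ring", "qed", "ro5_pass", "sas"]
    ].mean(numeric_only=False)
    return df, summary
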