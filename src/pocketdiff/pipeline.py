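"""Sampling orchestration, trajectory recording, bond reconstruction and the
leakage-controlled dataset split.

Sampling initialises every coordinate from scaled Gaussian noise centred on
the pocket centroid and every ligand type uniformly at random, then runs the
learned reverse diffusion for N_s steps, recording each intermediate state.
Bonds of the final ligand are perceived from distances (1.9 Å) and bond
orders assigned by a greedy valence-filling heuristic.
"""

from __future__ import annotations

import csv
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from rdkit import Chem

from .complexes import (
    MAX_VALENCE,
    AtomRecord,
    AtomTypeVocabulary,
    MolecularComplex,
    canonical_bond,
    perceive_bonds,
)
from .diffusion import (
    NoiseSchedule,
    reverse_step_coords,
    reverse_step_types,
    sample_com_free_noise,
)
from .e3former import E3former
from .featurization import featurize


@dataclass
class Trajectory:
    """Ordered denoising states (t strictly decreasing N_s -> 0)."""

    states: list[tuple[int, np.ndarray, np.ndarray]]  # (t, coords, types)
    complex_ref: str = ""
    schedule_ref: str = ""

    def __post_init__(self) -> None:
        ts = [t for t, _, _ in self.states]
        if ts != sorted(ts, reverse=True) or len(set(ts)) != len(ts):
            raise ValueError("trajectory steps must be strictly decreasing")
        counts = {c.shape[0] for _, c, _ in self.states}
        if len(counts) > 1:
            raise ValueError("all states must have the same atom count")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def coords(self) -> np.ndarray:
        """(n_states, N, 3) array in recorded (denoising) order."""
        return np.stack([c for _, c, _ in self.states])

    @property
    def types(self) -> np.ndarray:
        return np.stack([ty for _, _, ty in self.states])

    # -- on-disk format: JSON manifest + per-step CSV (token,x,y,z) ---------
    def save(self, directory: str, vocabulary: AtomTypeVocabulary | None = None) -> None:
        vocab = vocabulary or AtomTypeVocabulary()
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "complex_ref": self.complex_ref,
            "schedule_ref": self.schedule_ref,
            "steps": [int(t) for t, _, _ in self.states],
            "n_atoms": int(self.states[0][1].shape[0]),
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        for t, coords, types in self.states:
            with open(os.path.join(directory, f"step_{t:04d}.csv"), "w",
                      newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["token", "x", "y", "z"])
                for k in range(coords.shape[0]):
                    w.writerow([vocab.token(int(types[k])),
                                f"{coords[k,0]:.6f}", f"{coords[k,1]:.6f}",
                                f"{coords[k,2]:.6f}"])

    @classmethod
    def load(cls, directory: str,
             vocabulary: AtomTypeVocabulary | None = None) -> "Trajectory":
        vocab = vocabulary or AtomTypeVocabulary()
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        states = []
        for t in manifest["steps"]:
            coords, types = [], []
            with open(os.path.join(directory, f"step_{t:04d}.csv")) as fh:
                for row in list(csv.reader(fh))[1:]:
                    types.append(vocab.index(row[0]))
                    coords.append([float(v) for v in row[1:4]])
            states.append((int(t), np.array(coords), np.array(types, dtype=int)))
        return cls(states, manifest["complex_ref"], manifest["schedule_ref"])


def sample(
    model: E3former,
    pocket_template: MolecularComplex,
    n_ligand_atoms: int | None,
    seed: int,
    schedule: NoiseSchedule | None = None,
    vocabulary: AtomTypeVocabulary | None = None,
    prior_scale: float = 1.0,
    diffuse_pocket_coords: bool = True,
    size_prior: list[int] | None = None,
) -> tuple[MolecularComplex, Trajectory]:
    """Generate one pocket+ligand structure conditioned on a pocket template.

    The template supplies pocket atom identities (types are fixed
    conditioning); its ligand atoms, if any, are ignored.  All coordinates
    start from ``prior_scale``-scaled Gaussian noise centred on the pocket
    centroid (unless ``diffuse_pocket_coords`` is False, which freezes the
    native pocket geometry), and ligand types start uniform over the
    vocabulary.  ``n_ligand_atoms`` may be None, in which case the size is
    drawn from ``size_prior`` (e.g. the training-set ligand-size
    distribution).  Deterministic given (seed, checkpoint).
    """
    schedule = schedule or NoiseSchedule()
    vocab = vocabulary or AtomTypeVocabulary()
    if n_ligand_atoms is None:
        if not size_prior:
            raise ValueError("either n_ligand_atoms or size_prior is required")
        size_rng = np.random.default_rng((seed, 1))
        n_ligand_atoms = int(size_rng.choice(size_prior))
    if n_ligand_atoms < 1:
        raise ValueError("n_ligand_atoms must be >= 1")

    pocket_atoms = [a for a in pocket_template.atoms if a.role != "ligand"]
    n = len(pocket_atoms) + n_ligand_atoms
    if n > pocket_template.max_atoms:
        raise ValueError(f"{n} atoms exceeds maximum {pocket_template.max_atoms}")

    atoms: list[AtomRecord] = []
    for a in pocket_atoms:
        atoms.append(AtomRecord(len(atoms), a.element, a.atom_type,
                                a.coords.copy(), a.residue_id, a.role))
    for _ in range(n_ligand_atoms):
        atoms.append(AtomRecord(len(atoms), "C", "C", np.zeros(3), -1, "ligand"))
    pocket_bonds = {
        b for b in pocket_template.bonds
        if b[0] < len(pocket_atoms) and b[1] < len(pocket_atoms)
    }
    template = MolecularComplex(atoms, pocket_bonds,
                                pocket_template.max_atoms).centered()

    rng = np.random.default_rng(seed)
    lig_mask = template.ligand_mask
    coord_mask = np.ones(n, bool) if diffuse_pocket_coords else lig_mask.copy()
    centroid = template.pocket_centroid()

    coords = template.coords.copy()
    noise = sample_com_free_noise(rng, n)
    coords[coord_mask] = (centroid + prior_scale * noise)[coord_mask]

    types = template.type_indices(vocab)
    types[lig_mask] = rng.integers(0, vocab.K, size=int(lig_mask.sum()))

    states = [(schedule.n_steps, coords.copy(), types.copy())]
    for t in range(schedule.n_steps, 0, -1):
        feats = featurize(template, coords_override=coords, types_override=types,
                          vocabulary=vocab)
        eps_hat, logits = model.predict(feats, coords, t, schedule.n_steps)
        eps_hat = eps_hat - eps_hat[coord_mask].mean(axis=0)
        new_coords = reverse_step_coords(coords, eps_hat, t, rng, schedule,
                                         com_mask=coord_mask)
        coords[coord_mask] = new_coords[coord_mask]
        types = reverse_step_types(types, logits, t, rng, schedule, lig_mask)
        states.append((t - 1, coords.copy(), types.copy()))

    final_atoms: list[AtomRecord] = []
    for k, a in enumerate(template.atoms):
        token = a.atom_type if not lig_mask[k] else vocab.token(int(types[k]))
        element = a.element if not lig_mask[k] else (
            token if vocab.is_ligand_element(token) else "C"
        )
        final_atoms.append(AtomRecord(k, element, token, coords[k],
                                      a.residue_id, a.role))
    lig_idx = np.flatnonzero(lig_mask)
    lig_bonds = {
        canonical_bond(int(lig_idx[i]), int(lig_idx[j]))
        for i, j in perceive_bonds(coords[lig_mask])
    }
    pocket_bonds_ok = {
        b for b in pocket_bonds
        if np.linalg.norm(coords[b[0]] - coords[b[1]]) < 3.0
    }
    result = MolecularComplex(final_atoms, lig_bonds | pocket_bonds_ok,
                              pocket_template.max_atoms)
    traj = Trajectory(states, complex_ref=f"sample(seed={seed})",
                      schedule_ref=f"vp-cosine-{schedule.n_steps}")
    return result, traj


# --------------------------------------------------------------------------
# bond reconstruction


def reconstruct_molecule(
    coords: np.ndarray,
    types: list[str] | np.ndarray,
    cutoff: float = 1.9,
    vocabulary: AtomTypeVocabulary | None = None,
) -> tuple[Chem.Mol, bool]:
    """Build an RDKit molecule from bare ligand atoms.

    Connectivity comes from distance perception at ``cutoff``; bond orders
    from greedy valence filling: all bonds start single, then the shortest
    bonds are upgraded to double while both partners have spare valence
    (C≤4, N≤3, O≤2, S≤2, P≤5, halogens≤1).  Returns (mol, connected); a
    disconnected molecule is flagged, not an error.
    """
    vocab = vocabulary or AtomTypeVocabulary()
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    symbols = []
    for ty in types:
        tok = vocab.token(int(ty)) if not isinstance(ty, str) else ty
        symbols.append(tok if vocab.is_ligand_element(tok) else "C")

    bonds = sorted(perceive_bonds(coords, cutoff))
    degree = np.zeros(len(symbols), int)
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    spare = np.array([MAX_VALENCE.get(s, 4) for s in symbols]) - degree

    order = {b: 1 for b in bonds}
    by_length = sorted(bonds, key=lambda b: np.linalg.norm(coords[b[0]] - coords[b[1]]))
    for i, j in by_length:
        if spare[i] > 0 and spare[j] > 0:
            order[(i, j)] = 2
            spare[i] -= 1
            spare[j] -= 1

    mol = Chem.RWMol()
    conf = Chem.Conformer(len(symbols))
    for k, s in enumerate(symbols):
        idx = mol.AddAtom(Chem.Atom(s))
        conf.SetAtomPosition(idx, tuple(float(v) for v in coords[k]))
    bond_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE}
    for (i, j), o in order.items():
        mol.AddBond(i, j, bond_types[o])
    m = mol.GetMol()
    m.AddConformer(conf)

    g = nx.Graph()
    g.add_nodes_from(range(len(symbols)))
    g.add_edges_from(bonds)
    connected = nx.number_connected_components(g) == 1 if len(symbols) else False
    if not connected:
        warnings.warn("reconstructed molecule is disconnected")
    return m, connected


# --------------------------------------------------------------------------
# dataset split


@dataclass
class SplitAssignment:
    groups: list[list[str]]
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def split_dataset(
    ids: list[str],
    seq_identity: np.ndarray,
    pocket_rmsd: np.ndarray,
    ligand_tanimoto: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
    identity_threshold: float = 30.0,
    rmsd_threshold: float = 2.0,
    tanimoto_threshold: float = 0.85,
) -> SplitAssignment:
    """Leakage-controlled train/test split.

    Complexes are linked when sequence identity > 30%, pocket RMSD < 2 Å, or
    ligand Tanimoto > 0.85; connected components of the resulting graph are
    indivisible groups assigned greedily (in seed-shuffled order) to reach a
    train:test ratio of ``ratio`` : 1−``ratio``.  Similarity matrices are
    inputs (computed externally in production use).
    """
    n = len(ids)
    for name, m in (("seq_identity", seq_identity),
                    ("pocket_rmsd", pocket_rmsd),
                    ("ligand_tanimoto", ligand_tanimoto)):
        m = np.asarray(m)
        if m.shape != (n, n):
            raise ValueError(f"{name} must be {n}x{n}")
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} must be symmetric")

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if (seq_identity[i, j] > identity_threshold
                    or pocket_rmsd[i, j] < rmsd_threshold
                    or ligand_tanimoto[i, j] > tanimoto_threshold):
                g.add_edge(i, j)

    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    rng = np.random.default_rng(seed)
    rng.shuffle(comps)

    if max(len(c) for c in comps) > 0.8 * n:
        warnings.warn("largest similarity group exceeds 80% of the data; "
                      "the requested ratio is unsatisfiable")

    target_test = int(round((1.0 - ratio) * n))
    test: list[int] = []
    train: list[int] = []
    for comp in comps:
        if len(test) + len(comp) <= target_test:
            test.extend(comp)
        else:
            train.extend(comp)
    groups = [[ids[i] for i in comp] for comp in comps]
    return SplitAssignment(
        groups=groups,
        train_ids=[ids[i] for i in sorted(train)],
        test_ids=[ids[i] for i in sorted(test)],
    )


# --------------------------------------------------------------------------
# naive similarity providers for fixtures


def pairwise_sequence_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch, match=1/mismatch=0/gap=0) identity in %.

    A deliberately simple stand-in for alignment tools when exercising the
    split logic on synthetic inputs; identity = matches / max(len).
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    score = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + (a[i - 1] == b[j - 1]),
                score[i - 1, j],
                score[i, j - 1],
            )
    return 100.0 * score[la, lb] / max(la, lb)
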