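"""Denoising-trajectory analytics: atom-type transitions, convergence RMSD,
bond-length evolution and bond formation/breaking bookkeeping.

All step indices here run in denoising order: index 0 is the start of the
reverse process (pure noise) and the last index is the final structure.
RMSD-to-final is computed raw (no superposition) because the trajectory
lives in a single fixed frame and superposition would hide the coordinate
convergence being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import perceive_bonds
from .pipeline import Trajectory


@dataclass
class TypeChangeMatrix:
    """M[i, s] = 1 iff atom i's type at denoising step s differs from step s−1.

    The matrix has one column per transition (n_states − 1 columns); the
    initial state has no predecessor.  ``per_step_mean`` is the average
    number of changes per atom at each transition, ``per_atom_total`` the
    total flips each atom undergoes.
    """

    M: np.ndarray

    @property
    def per_step_mean(self) -> np.ndarray:
        return self.M.mean(axis=0)

    @property
    def per_atom_total(self) -> np.ndarray:
        return self.M.sum(axis=1)


def type_change_matrix(traj: Trajectory) -> TypeChangeMatrix:
    if len(traj) < 2:
        raise ValueError("trajectory needs at least two states")
    types = traj.types  # (n_states, N), denoising order
    M = (types[1:] != types[:-1]).T.astype(np.int8)
    return TypeChangeMatrix(M)


def rmsd_to_final(traj: Trajectory) -> np.ndarray:
    """Raw per-step RMSD of each state's coordinates to the final state."""
    coords = traj.coords
    final = coords[-1]
    return np.sqrt(((coords - final) ** 2).sum(axis=2).mean(axis=1))


def bond_length_evolution(
    traj: Trajectory,
    final_bonds: set[tuple[int, int]] | None = None,
    cutoff: float = 1.9,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Lengths of the final structure's bonds at every step.

    Returns (lengths (n_states, n_bonds), bond list).  When ``final_bonds``
    is not given it is perceived from the last state at ``cutoff``.
    """
    coords = traj.coords
    if final_bonds is None:
        final_bonds = perceive_bonds(coords[-1], cutoff)
    bonds = sorted(final_bonds)
    if not bonds:
        raise ValueError("final structure has no bonds to track")
    i = np.array([b[0] for b in bonds])
    j = np.array([b[1] for b in bonds])
    lengths = np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=2)
    return lengths, bonds


def bond_event_counts(
    traj: Trajectory, cutoff: float = 1.9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step (n_formed, n_broken, n_total) from re-perceived bonds.

    Bonds are re-perceived at every state; formed/broken count the set
    differences across consecutive states (length n_states − 1, aligned with
    transitions), n_total has length n_states.  The bookkeeping identity
    n_total[s] = n_total[s−1] + n_formed[s−1] − n_broken[s−1] holds exactly.
    """
    if len(traj) < 2:
        raise ValueError("trajectory needs at least two states")
    coords = traj.coords
    bond_sets = [perceive_bonds(c, cutoff) for c in coords]
    n_total = np.array([len(b) for b in bond_sets])
    n_formed = np.array([
        len(b1 - b0) for b0, b1 in zip(bond_sets[:-1], bond_sets[1:])
    ])
    n_broken = np.array([
        len(b0 - b1) for b0, b1 in zip(bond_sets[:-1], bond_sets[1:])
    ])
    return n_formed, n_broken, n_total


def analysis_tables(traj: Trajectory, cutoff: float = 1.9) -> dict[str, np.ndarray]:
    """All analytics in one pass, keyed for CSV export."""
    tcm = type_change_matrix(traj)
    n_formed, n_broken, n_total = bond_event_counts(traj, cutoff)
    tables = {
        "type_change_matrix": tcm.M,
        "type_changes_per_step": tcm.per_step_mean,
        "type_changes_per_atom": tcm.per_atom_total,
        "rmsd_to_final": rmsd_to_final(traj),
        "bonds_formed": n_formed,
        "bonds_broken": n_broken,
        "bonds_total": n_total,
    }
    try:
        lengths, _ = bond_length_evolution(traj, cutoff=cutoff)
        tables["bond_lengths"] = lengths
        tables["bond_length_mean"] = lengths.mean(axis=1)
    except ValueError:
        # structure ended bond-free (e.g. an untrained sampler)
        n_states = len(traj)
        tables["bond_lengths"] = np.zeros((n_states, 0))
        tables["bond_length_mean"] = np.full(n_states, np.nan)
    return tables


def plot_analysis(traj: Trajectory, out_dir: str, cutoff: float = 1.9) -> list[str]:
    """Write diagnostic panels (type-change heatmap, per-step change rate,
    RMSD convergence, bond-length evolution, bond events) as PNGs."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    tables = analysis_tables(traj, cutoff)
    paths = []

    fig, axes = plt.subplots(2, 3, figsize=(14, 7))
    axes[0, 0].imshow(tables["type_change_matrix"], aspect="auto",
                      cmap="PRGn_r", interpolation="nearest")
    axes[0, 0].set(title="atom-type changes", xlabel="denoising step",
                   ylabel="atom")
    axes[0, 1].plot(tables["type_changes_per_step"])
    axes[0, 1].set(title="mean type changes / step", xlabel="denoising step")
    axes[0, 2].plot(tables["rmsd_to_final"])
    axes[0, 2].set(title="RMSD to final (Å)", xlabel="denoising step")
    axes[1, 0].plot(tables["bond_length_mean"])
    axes[1, 0].set(title="mean final-bond length (Å)", xlabel="denoising step")
    axes[1, 1].plot(tables["bonds_formed"], label="formed")
    axes[1, 1].plot(tables["bonds_broken"], label="broken")
    axes[1, 1].legend()
    axes[1, 1].set(title="bond events", xlabel="transition")
    axes[1, 2].plot(tables["bonds_total"])
    axes[1, 2].set(title="total bonds", xlabel="denoising step")
    fig.tight_layout()
    path = os.path.join(out_dir, "trajectory_analysis.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths
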