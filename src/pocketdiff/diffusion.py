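"""Dual diffusion: variance-preserving Gaussian diffusion on coordinates and
a uniform-kernel discrete diffusion (D3PM) on ligand atom types.

Coordinates follow x_t = α_t x_0 + σ_t ε with α_t² + σ_t² = 1 on a cosine
(i.e. α_t = cos θ_t, θ linear in t) schedule of N_s = 100 steps; the network
predicts the noise ε and sampling uses the ancestral DDPM posterior.  Atom
types follow a Markov chain of row-stochastic matrices
Q_t = (1−β_t) I + (β_t/K) 𝟙𝟙ᵀ; the network predicts logits for the clean
types (x0-parameterisation) and the reverse step samples the exact posterior
q(s_{t−1} | s_t, ŝ_0).

All coordinates (pocket and ligand) diffuse by default — pocket flexibility
is the point — while only ligand atom TYPES diffuse; pocket types are fixed
conditioning.  Noise for coordinate diffusion during training/sampling is
projected onto the zero-center-of-mass subspace of the diffused atoms, which
keeps the process consistent with the translation-invariant denoiser.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np

from .complexes import AtomTypeVocabulary, MolecularComplex
from .e3former import E3former
from .featurization import featurize
from .nn import Adam, Tensor, log_softmax

DEFAULT_N_STEPS = 100


class NoiseSchedule:
    """Variance-preserving schedule for coordinates plus β_t for types.

    α_t = cos θ_t, σ_t = sin θ_t with θ_t linear from 0 to just under π/2,
    so α_0 = 1, σ_0 = 0 exactly and the terminal state is (almost) pure
    noise while α_t stays strictly positive.  β_t rises linearly from
    ``beta_min`` to ``beta_max`` over the chain.
    """

    def __init__(
        self,
        n_steps: int = DEFAULT_N_STEPS,
        theta_margin: float = 0.01,
        beta_min: float = 0.001,
        beta_max: float = 0.1,
    ):
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self.n_steps = n_steps
        theta = np.linspace(0.0, np.pi / 2 - theta_margin, n_steps + 1)
        self.alpha = np.cos(theta)
        self.sigma = np.sin(theta)
        self.beta = np.concatenate(
            [[0.0], np.linspace(beta_min, beta_max, n_steps)]
        )
        self._qbar_cache: dict[int, np.ndarray] = {}

    # -- per-step transition quantities (x_t = a_t x_{t-1} + s_t ε_t) -------
    def step_coeff(self, t: int) -> tuple[float, float]:
        a = self.alpha[t] / self.alpha[t - 1]
        s2 = self.sigma[t] ** 2 - a ** 2 * self.sigma[t - 1] ** 2
        return float(a), float(max(s2, 0.0))

    def transition_matrix(self, t: int, K: int) -> np.ndarray:
        return d3pm_transition_matrix(float(self.beta[t]), K)

    def cumulative_matrix(self, t: int, K: int) -> np.ndarray:
        """Q̄_t = Q_1 Q_2 ... Q_t (identity at t = 0)."""
        key = (t, K)
        if key not in self._qbar_cache:
            if t == 0:
                self._qbar_cache[key] = np.eye(K)
            else:
                self._qbar_cache[key] = (
                    self.cumulative_matrix(t - 1, K) @ self.transition_matrix(t, K)
                )
        return self._qbar_cache[key]


@dataclass
class DiffusionState:
    """One point of the diffusion chain for a complex."""

    coords: np.ndarray        # (N, 3)
    types: np.ndarray         # (N,) vocabulary indices
    t: int
    ligand_mask: np.ndarray
    fixed_types: np.ndarray = field(default=None)  # native types of fixed atoms

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.types = np.asarray(self.types, dtype=int)
        if self.fixed_types is None:
            self.fixed_types = self.types[~self.ligand_mask].copy()
        if not np.array_equal(self.types[~self.ligand_mask], self.fixed_types):
            raise ValueError("types of fixed (non-ligand) atoms must stay native")


def d3pm_transition_matrix(beta: float, K: int) -> np.ndarray:
    """Uniform-kernel single-step matrix (1−β) I + (β/K) 𝟙𝟙ᵀ."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    return (1.0 - beta) * np.eye(K) + (beta / K) * np.ones((K, K))


def forward_diffuse_coords(
    x0: np.ndarray, t: int, noise: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """x_t = α_t x0 + σ_t ε for the given noise realisation."""
    if not 0 <= t <= schedule.n_steps:
        raise ValueError(f"t={t} outside [0, {schedule.n_steps}]")
    return schedule.alpha[t] * np.asarray(x0) + schedule.sigma[t] * np.asarray(noise)


def sample_com_free_noise(
    rng: np.random.Generator, n: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Standard normal (n, 3) noise projected to zero mean over ``mask``."""
    eps = rng.standard_normal((n, 3))
    sel = slice(None) if mask is None else mask
    eps[sel] -= eps[sel].mean(axis=0)
    return eps


def forward_diffuse_types(
    types0: np.ndarray,
    t: int,
    rng: np.random.Generator,
    schedule: NoiseSchedule,
    K: int,
    ligand_mask: np.ndarray,
) -> np.ndarray:
    """Draw each ligand atom's type from its row of Q̄_t; others untouched."""
    types0 = np.asarray(types0, dtype=int)
    out = types0.copy()
    if t == 0 or not ligand_mask.any():
        return out
    qbar = schedule.cumulative_matrix(t, K)
    for i in np.flatnonzero(ligand_mask):
        out[i] = rng.choice(K, p=qbar[types0[i]])
    return out


def reverse_step_coords(
    x_t: np.ndarray,
    eps_hat: np.ndarray,
    t: int,
    rng: np.random.Generator,
    schedule: NoiseSchedule,
    com_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Ancestral DDPM posterior step x_t -> x_{t-1}.

    x̂0 = (x_t − σ_t ε̂)/α_t; the posterior q(x_{t−1} | x_t, x̂0) is Gaussian
    with mean c1 x_t + c2 x̂0 and variance σ²_{t−1} s²_t / σ²_t.  At t = 1 the
    posterior variance is zero (σ_0 = 0), so the final step injects no noise.
    Injected noise is projected zero-center-of-mass like the forward noise.
    """
    if t < 1:
        raise ValueError("reverse step requires t >= 1")
    a_t, s2_t = schedule.step_coeff(t)
    sig_t2 = schedule.sigma[t] ** 2
    sig_p2 = schedule.sigma[t - 1] ** 2
    x_t = np.asarray(x_t, dtype=float)
    x0_hat = (x_t - schedule.sigma[t] * np.asarray(eps_hat)) / schedule.alpha[t]
    if sig_t2 <= 0.0:
        return x0_hat
    c1 = a_t * sig_p2 / sig_t2
    c2 = schedule.alpha[t - 1] * s2_t / sig_t2
    mean = c1 * x_t + c2 * x0_hat
    std = np.sqrt(max(sig_p2 * s2_t / sig_t2, 0.0))
    if std == 0.0:
        return mean
    return mean + std * sample_com_free_noise(rng, x_t.shape[0], com_mask)


def reverse_step_types(
    types_t: np.ndarray,
    type_logits: np.ndarray,
    t: int,
    rng: np.random.Generator,
    schedule: NoiseSchedule,
    ligand_mask: np.ndarray,
) -> np.ndarray:
    """Sample s_{t−1} from the D3PM posterior with ŝ0 = softmax(logits).

    posterior(j) ∝ Q_t[j, s_t] · Σ_{s0} p̂(s0) Q̄_{t−1}[s0, j] / Q̄_t[s0, s_t].
    Zero-probability rows fall back to uniform with a warning.
    """
    if t < 1:
        raise ValueError("reverse step requires t >= 1")
    types_t = np.asarray(types_t, dtype=int)
    K = type_logits.shape[-1]
    Qt = schedule.transition_matrix(t, K)
    Qbar_t = schedule.cumulative_matrix(t, K)
    Qbar_p = schedule.cumulative_matrix(t - 1, K)
    out = types_t.copy()
    logits = np.asarray(type_logits, dtype=float)
    for i in np.flatnonzero(ligand_mask):
        z = logits[i] - logits[i].max()
        p0 = np.exp(z)
        p0 /= p0.sum()
        s = types_t[i]
        w = p0 / np.maximum(Qbar_t[:, s], 1e-30)
        post = Qt[:, s] * (w @ Qbar_p)
        total = post.sum()
        if total <= 0.0 or not np.isfinite(total):
            warnings.warn("degenerate type posterior; falling back to uniform")
            post = np.full(K, 1.0 / K)
        else:
            post /= total
        out[i] = rng.choice(K, p=post)
    return out


# --------------------------------------------------------------------------
# losses and training


def training_loss(
    model: E3former,
    complex: MolecularComplex,
    t: int,
    rng: np.random.Generator,
    schedule: NoiseSchedule,
    vocabulary: AtomTypeVocabulary | None = None,
    lam: float = 1.0,
    diffuse_pocket_coords: bool = True,
) -> tuple[Tensor, Tensor, Tensor]:
    """One masked denoising-loss evaluation at step ``t``.

    Returns (total, loss_coords, loss_types) as autodiff Tensors:
    loss_coords is the mean over diffused atoms of ‖ε̂ − ε‖² and loss_types
    the cross-entropy between type logits and the clean ligand types.
    """
    vocab = vocabulary or AtomTypeVocabulary()
    lig = complex.ligand_mask
    coord_mask = np.ones(complex.n_atoms, bool) if diffuse_pocket_coords else lig.copy()
    x0 = complex.coords
    types0 = complex.type_indices(vocab)

    if not coord_mask.any() and not lig.any():
        warnings.warn("degenerate mask: no diffused atoms; losses are zero")
        zero = Tensor(np.zeros(()))
        return zero, zero, zero

    eps = np.zeros_like(x0)
    if coord_mask.any():
        eps[coord_mask] = sample_com_free_noise(rng, int(coord_mask.sum()))
    x_t = x0.copy()
    x_t[coord_mask] = forward_diffuse_coords(x0, t, eps, schedule)[coord_mask]
    types_t = forward_diffuse_types(types0, t, rng, schedule, vocab.K, lig)

    feats = featurize(complex, coords_override=x_t, types_override=types_t,
                      vocabulary=vocab)
    eps_hat, logits = model.forward(feats, x_t, t, schedule.n_steps)

    if coord_mask.any():
        m = coord_mask.astype(float)[:, None]
        resid = (eps_hat - Tensor(eps)) * Tensor(m)
        loss_coords = (resid * resid).sum() * (1.0 / coord_mask.sum())
    else:
        loss_coords = Tensor(np.zeros(()))

    if lig.any():
        logp = log_softmax(logits, axis=-1)
        picked = logp[np.arange(complex.n_atoms), types0]
        loss_types = -(picked * Tensor(lig.astype(float))).sum() * (1.0 / lig.sum())
    else:
        loss_types = Tensor(np.zeros(()))

    total = loss_coords + lam * loss_types
    return total, loss_coords, loss_types


@dataclass
class TrainingConfig:
    n_steps: int = 2000
    lr: float = 2e-3
    lam: float = 1.0
    seed: int = 0
    lr_decay: float = 1.0       # multiplicative factor applied each step
    diffuse_pocket_coords: bool = True
    log_path: str | None = None  # CSV of per-step losses

    @classmethod
    def from_yaml(cls, path: str) -> "TrainingConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown training-config keys: {sorted(unknown)}")
        return cls(**data)


class Trainer:
    """Fit the denoiser to one or more complexes by stochastic denoising.

    Each step draws a complex, a uniform timestep t ∈ [1, N_s] and a noise
    realisation, and takes one Adam step on the combined loss.
    """

    def __init__(
        self,
        model: E3former,
        complexes: MolecularComplex | list[MolecularComplex],
        schedule: NoiseSchedule | None = None,
        config: TrainingConfig | None = None,
        vocabulary: AtomTypeVocabulary | None = None,
    ):
        self.model = model
        self.complexes = (
            [complexes] if isinstance(complexes, MolecularComplex) else list(complexes)
        )
        self.schedule = schedule or NoiseSchedule()
        self.config = config or TrainingConfig()
        self.vocab = vocabulary or AtomTypeVocabulary()
        self.history: list[tuple[int, float, float]] = []

    def run(self) -> list[tuple[int, float, float]]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.model.parameters(), lr=cfg.lr)
        for step in range(cfg.n_steps):
            cx = self.complexes[rng.integers(len(self.complexes))]
            t = int(rng.integers(1, self.schedule.n_steps + 1))
            total, lc, lt = training_loss(
                self.model, cx, t, rng, self.schedule, self.vocab,
                lam=cfg.lam, diffuse_pocket_coords=cfg.diffuse_pocket_coords,
            )
            self.model.zero_grad()
            total.backward()
            opt.lr = cfg.lr * cfg.lr_decay ** step
            opt.step()
            self.history.append((step, float(lc.data), float(lt.data)))
        if cfg.log_path:
            with open(cfg.log_path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["step", "loss_coords", "loss_types"])
                w.writerows(self.history)
        return self.history
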