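"""Evoformer-style denoising network with an E(3)-equivariant coordinate head.

The network operates on per-atom sequence embeddings and per-pair embeddings.
Each block runs, in order: sequence attention with pair bias, sequence
transition, sequence outer product (into the pair track), triangle
multiplication (outgoing, incoming), triangle attention (starting, ending),
and pair transition.  There is no MSA track and no positional encoding; atoms
are an unordered set.  After the block stack a coordinate head turns pair
embeddings into per-atom displacements by aggregating weighted unit direction
vectors between atoms — exactly translation-invariant and rotation-equivariant
by construction — and a linear head on the sequence embedding emits atom-type
logits (rotation-invariant, since all inputs are).

Triangle operations follow the AlphaFold Evoformer formulation (gated,
with residual-branch output projections zero-initialised).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .featurization import FeatureBundle
from .nn import (
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
    concat,
    einsum,
    relu,
    sigmoid,
    softmax,
)

#: small length (Å) guarding direction-vector normalisation at coincident atoms
DIRECTION_EPS = 1e-6

TIME_EMB_DIM = 16


@dataclass
class E3formerConfig:
    n_blocks: int = 2
    d_seq: int = 32
    d_pair: int = 16
    n_heads: int = 4
    d_hidden_transition: int = 64
    d_outer: int = 8
    dropout: float = 0.0
    n_types: int = 19          # vocabulary size K
    d_seq_in: int = 23         # K + |roles|
    d_pair_in: int = 18        # same-residue + raw distance + 16 RBF

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.d_seq, self.d_pair, self.n_heads,
               self.d_hidden_transition) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.d_seq % self.n_heads or self.d_pair % self.n_heads:
            raise ValueError("d_seq and d_pair must be divisible by n_heads")


@dataclass
class NetworkState:
    """Embeddings plus current coordinates flowing through the stack."""

    seq_emb: Tensor    # (N, d_seq)
    pair_emb: Tensor   # (N, N, d_pair)
    coords: np.ndarray  # (N, 3), Å — data, not differentiated


def timestep_embedding(t: int, n_steps: int, dim: int = TIME_EMB_DIM) -> np.ndarray:
    """Sinusoidal embedding of the diffusion step on dim/2 frequencies."""
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    angles = (t / max(n_steps, 1)) * freqs
    return np.concatenate([np.sin(angles), np.cos(angles)])


class SequenceAttention(Module):
    """Multi-head self-attention over atoms with additive pair bias, gated."""

    def __init__(self, cfg: E3formerConfig, rng: np.random.Generator):
        d, h = cfg.d_seq, cfg.n_heads
        self.h = h
        self.dh = d // h
        self.norm = LayerNorm(d)
        self.q = Linear(d, d, rng, bias=False)
        self.k = Linear(d, d, rng, bias=False)
        self.v = Linear(d, d, rng, bias=False)
        self.bias = Linear(cfg.d_pair, h, rng, bias=False)
        self.gate = Linear(d, d, rng)
        self.out = Linear(d, d, rng, zero_init=True)

    def attention_weights(self, seq: Tensor, pair: Tensor) -> Tensor:
        """(h, N, N) softmax-normalised attention, exposed for testing."""
        x = self.norm(seq)
        n = x.shape[0]
        q = self.q(x).reshape(n, self.h, self.dh)
        k = self.k(x).reshape(n, self.h, self.dh)
        logits = einsum("ihd,jhd->hij", q, k) * (1.0 / np.sqrt(self.dh))
        logits = logits + self.bias(pair).transpose(2, 0, 1)
        return softmax(logits, axis=-1)

    def __call__(self, seq: Tensor, pair: Tensor) -> Tensor:
        x = self.norm(seq)
        n = x.shape[0]
        att = self.attention_weights(seq, pair)
        v = self.v(x).reshape(n, self.h, self.dh)
        ctx = einsum("hij,jhd->ihd", att, v).reshape(n, self.h * self.dh)
        gated = sigmoid(self.gate(x)) * ctx
        return seq + self.out(gated)


class Transition(Module):
    """Position-wise two-layer MLP with residual; identity at init."""

    def __init__(self, d: int, d_hidden: int, rng: np.random.Generator):
        self.norm = LayerNorm(d)
        self.fc1 = Linear(d, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.fc2(relu(self.fc1(self.norm(x))))


class OuterProduct(Module):
    """Project seq embeddings to two small vectors and add their outer
    product (flattened, linearly projected) into every pair slot."""

    def __init__(self, cfg: E3formerConfig, rng: np.random.Generator):
        c = cfg.d_outer
        self.c = c
        self.norm = LayerNorm(cfg.d_seq)
        self.a = Linear(cfg.d_seq, c, rng)
        self.b = Linear(cfg.d_seq, c, rng)
        self.out = Linear(c * c, cfg.d_pair, rng, zero_init=True)

    def __call__(self, seq: Tensor, pair: Tensor) -> Tensor:
        x = self.norm(seq)
        n = x.shape[0]
        a = self.a(x)
        b = self.b(x)
        outer = einsum("ic,jd->ijcd", a, b).reshape(n, n, self.c * self.c)
        return pair + self.out(outer)


class TriangleMultiplication(Module):
    """Gated triangle multiplicative update, outgoing or incoming edges."""

    def __init__(self, cfg: E3formerConfig, rng: np.random.Generator,
                 mode: str = "outgoing"):
        if mode not in ("outgoing", "incoming"):
            raise ValueError(mode)
        self.mode = mode
        d, c = cfg.d_pair, cfg.d_pair
        self.c = c
        self.norm = LayerNorm(d)
        self.a = Linear(d, c, rng)
        self.a_gate = Linear(d, c, rng)
        self.b = Linear(d, c, rng)
        self.b_gate = Linear(d, c, rng)
        self.norm_out = LayerNorm(c)
        self.out = Linear(c, d, rng, zero_init=True)
        self.gate = Linear(d, d, rng)

    def __call__(self, pair: Tensor) -> Tensor:
        z = self.norm(pair)
        a = sigmoid(self.a_gate(z)) * self.a(z)
        b = sigmoid(self.b_gate(z)) * self.b(z)
        if self.mode == "outgoing":
            prod = einsum("ikc,jkc->ijc", a, b)
        else:
            prod = einsum("kic,kjc->ijc", a, b)
        update = sigmoid(self.gate(z)) * self.out(self.norm_out(prod))
        return pair + update


class TriangleAttention(Module):
    """Triangle self-attention around starting or ending node.

    Starting mode: for each edge (i, j), attend over edges (i, k) with an
    additive bias from the closing edge (j, k).  Ending mode is the same
    operation on the transposed pair tensor.
    """

    def __init__(self, cfg: E3formerConfig, rng: np.random.Generator,
                 mode: str = "starting"):
        if mode not in ("starting", "ending"):
            raise ValueError(mode)
        self.mode = mode
        d, h = cfg.d_pair, cfg.n_heads
        self.h = h
        self.dh = d // h
        self.norm = LayerNorm(d)
        self.q = Linear(d, d, rng, bias=False)
        self.k = Linear(d, d, rng, bias=False)
        self.v = Linear(d, d, rng, bias=False)
        self.bias = Linear(d, h, rng, bias=False)
        self.gate = Linear(d, d, rng)
        self.out = Linear(d, d, rng, zero_init=True)

    def attention_weights(self, pair: Tensor) -> Tensor:
        """(h, N, N, N) attention over the third index, rows sum to 1."""
        z = self.norm(pair if self.mode == "starting" else pair.transpose(1, 0, 2))
        n = z.shape[0]
        q = self.q(z).reshape(n, n, self.h, self.dh)
        k = self.k(z).reshape(n, n, self.h, self.dh)
        logits = einsum("ijhd,ikhd->hijk", q, k) * (1.0 / np.sqrt(self.dh))
        logits = logits + self.bias(z).transpose(2, 0, 1).reshape(self.h, 1, n, n)
        return softmax(logits, axis=-1)

    def __call__(self, pair: Tensor) -> Tensor:
        transposed = self.mode == "ending"
        z = self.norm(pair.transpose(1, 0, 2) if transposed else pair)
        n = z.shape[0]
        att = self.attention_weights(pair)
        v = self.v(z).reshape(n, n, self.h, self.dh)
        ctx = einsum("hijk,ikhd->ijhd", att, v).reshape(n, n, self.h * self.dh)
        update = self.out(sigmoid(self.gate(z)) * ctx)
        if transposed:
            update = update.transpose(1, 0, 2)
        return pair + update


class CoordinateHead(Module):
    """Aggregate weighted unit direction vectors into displacements.

    Δx_i = Σ_{j≠i} w(pair_ij) · (x_j − x_i) / (‖x_j − x_i‖ + δ).  Weights are
    a scalar projection of the (normalised) pair embedding; directions depend
    only on relative positions, so the output is translation-invariant and
    transforms with any rotation applied to the input coordinates.
    """

    def __init__(self, cfg: E3formerConfig, rng: np.random.Generator):
        self.norm = LayerNorm(cfg.d_pair)
        self.w = Linear(cfg.d_pair, 1, rng, zero_init=True)

    def weights(self, pair: Tensor) -> Tensor:
        n = pair.shape[0]
        w = self.w(self.norm(pair)).reshape(n, n)
        mask = 1.0 - np.eye(n)
        return w * mask

    def __call__(self, pair: Tensor, coords: np.ndarray) -> Tensor:
        coords = np.asarray(coords, dtype=float)
        diff = coords[None, :, :] - coords[:, None, :]
        norm = np.linalg.norm(diff, axis=-1, keepdims=True)
        dirs = diff / (norm + DIRECTION_EPS)
        return einsum("ij,ijc->ic", self.weights(pair), Tensor(dirs))


class E3formerBlock(Module):
    def __init__(self, cfg: E3formerConfig, rng: np.random.Generator):
        self.seq_att = SequenceAttention(cfg, rng)
        self.seq_trans = Transition(cfg.d_seq, cfg.d_hidden_transition, rng)
        self.outer = OuterProduct(cfg, rng)
        self.tri_mul_out = TriangleMultiplication(cfg, rng, "outgoing")
        self.tri_mul_in = TriangleMultiplication(cfg, rng, "incoming")
        self.tri_att_start = TriangleAttention(cfg, rng, "starting")
        self.tri_att_end = TriangleAttention(cfg, rng, "ending")
        self.pair_trans = Transition(cfg.d_pair, cfg.d_hidden_transition, rng)

    def __call__(self, seq: Tensor, pair: Tensor) -> tuple[Tensor, Tensor]:
        seq = self.seq_att(seq, pair)
        seq = self.seq_trans(seq)
        pair = self.outer(seq, pair)
        pair = self.tri_mul_out(pair)
        pair = self.tri_mul_in(pair)
        pair = self.tri_att_start(pair)
        pair = self.tri_att_end(pair)
        pair = self.pair_trans(pair)
        return seq, pair


class E3former(Module):
    """Full stack: input projections, blocks, coordinate and type heads."""

    def __init__(self, config: E3formerConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.seq_in = Linear(config.d_seq_in + TIME_EMB_DIM, config.d_seq, rng)
        self.pair_in = Linear(config.d_pair_in, config.d_pair, rng)
        self.blocks = [E3formerBlock(config, rng) for _ in range(config.n_blocks)]
        self.coord_head = CoordinateHead(config, rng)
        self.type_norm = LayerNorm(config.d_seq)
        self.type_head = Linear(config.d_seq, config.n_types, rng)

    def forward(
        self,
        features: FeatureBundle,
        coords: np.ndarray,
        t: int,
        n_steps: int,
    ) -> tuple[Tensor, Tensor]:
        """Return (noise_prediction (N,3), type_logits (N,K)) as Tensors."""
        n = features.n_atoms
        t_emb = np.broadcast_to(
            timestep_embedding(t, n_steps), (n, TIME_EMB_DIM)
        )
        seq = self.seq_in(concat([Tensor(features.seq), Tensor(t_emb.copy())], axis=-1))
        pair = self.pair_in(Tensor(features.pair))
        for block in self.blocks:
            seq, pair = block(seq, pair)
        eps_hat = self.coord_head(pair, coords)
        if not np.all(np.isfinite(eps_hat.data)):
            raise FloatingPointError("non-finite activations in coordinate head")
        logits = self.type_head(self.type_norm(seq))
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite activations in type head")
        return eps_hat, logits

    def predict(
        self, features: FeatureBundle, coords: np.ndarray, t: int, n_steps: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Inference helper returning plain arrays."""
        eps_hat, logits = self.forward(features, coords, t, n_steps)
        return eps_hat.data, logits.data

    # ---------------------------------------------------------- persistence
    def save(self, path: str) -> None:
        """Checkpoint: config (JSON) + flat parameter arrays, NPZ container."""
        state = self.state_dict()
        meta = json.dumps({"config": asdict(self.config), "seed": self.seed})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path: str) -> "E3former":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(E3formerConfig(**meta["config"]), seed=meta["seed"])
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__meta__"}
            )
        return model
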