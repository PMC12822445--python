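"""The slide-level network: projection, 2D positional encoding, a cls-token
agent-attention transformer block, and a sigmoid MLP regression head.

A bag of n tile feature vectors is linearly projected to ``embed_dim`` with
a ReLU, summed with sinusoidal 2D positional encodings of the tile-grid
coordinates, and concatenated with a learned cls token.  One pre-norm
transformer layer with multi-head agent attention (agents pooled from the
query rows as contiguous segment means) and a 2-layer feed-forward block
updates the sequence; the cls position is layer-normed and mapped through a
single linear unit with a sigmoid to the continuous risk probability in
(0, 1).

Per-tile importance is the cls row of the head-averaged attention-rollout
product restricted to tile columns; it is computed alongside every forward
pass and drives the heatmap and phenotype modules.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .attention import agent_pooling_matrix
from .autodiff import Tensor, concat_rows, layer_norm, softmax_rows
from .data import TileBag

__all__ = [
    "ModelConfig",
    "BagPrediction",
    "init_params",
    "positional_encoding",
    "project_tiles",
    "forward_bag",
    "forward_with_graph",
    "embed_tile",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and loss hyperparameters.

    Defaults: one transformer layer with four heads, 256-dim latent
    projections, feed-forward hidden width 512.  The number of agent tokens
    ``n_agents`` matters little for accuracy (only for cost); 16 is the
    package default.
    """

    input_dim: int
    embed_dim: int = 256
    n_heads: int = 4
    n_layers: int = 1
    ff_hidden_dim: int = 512
    n_agents: int = 16
    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("input_dim", "embed_dim", "n_heads", "n_layers",
                     "ff_hidden_dim", "n_agents"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


@dataclass
class BagPrediction:
    risk_probability: float
    tile_scores_raw: np.ndarray  # n raw rollout scores (cls row, tile columns)
    embedding_cls: np.ndarray  # post-transformer cls state, embed_dim


def _kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Kaiming-uniform initialization of all learnable tensors."""
    rng = np.random.default_rng(seed)
    D, H, C = config.embed_dim, config.ff_hidden_dim, config.input_dim

    def w(fan_in, shape):
        return Tensor(_kaiming_uniform(rng, fan_in, shape), requires_grad=True)

    def zeros(shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(shape):
        return Tensor(np.ones(shape), requires_grad=True)

    params: dict[str, Tensor] = {
        "proj_W": w(C, (C, D)),
        "proj_b": zeros((D,)),
        "cls_token": Tensor(rng.normal(0.0, 0.02, size=(1, D)), requires_grad=True),
        "ln1_g": ones((D,)),
        "ln1_b": zeros((D,)),
        "Wq": w(D, (D, D)),
        "bq": zeros((D,)),
        "Wk": w(D, (D, D)),
        "bk": zeros((D,)),
        "Wv": w(D, (D, D)),
        "bv": zeros((D,)),
        "Wo": w(D, (D, D)),
        "bo": zeros((D,)),
        "ln2_g": ones((D,)),
        "ln2_b": zeros((D,)),
        "ff_W1": w(D, (D, H)),
        "ff_b1": zeros((H,)),
        "ff_W2": w(H, (H, D)),
        "ff_b2": zeros((D,)),
        "head_ln_g": ones((D,)),
        "head_ln_b": zeros((D,)),
        "head_W": w(D, (D, 1)),
        "head_b": zeros((1,)),
    }
    return params


def positional_encoding(coords: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal 2D absolute positional encoding of tile-grid coordinates.

    The first ``dim/2`` channels encode the column index, the last ``dim/2``
    the row, each as interleaved sin/cos at geometric wavelengths
    ``10000**(2i/(dim/2))``.  Values lie in [-1, 1]; identical coordinates
    map to identical encodings.
    """
    if dim % 4:
        raise ValueError(f"encoding dim must be divisible by 4, got {dim}")
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    half = dim // 2
    i = np.arange(half // 2)
    freqs = 1.0 / (10000.0 ** (2.0 * i / half))  # (dim/4,)
    pe = np.empty((len(coords), dim))
    for axis, offset in ((0, 0), (1, half)):  # column then row
        angles = coords[:, axis : axis + 1] * freqs  # n x dim/4
        pe[:, offset + 0 : offset + half : 2] = np.sin(angles)
        pe[:, offset + 1 : offset + half : 2] = np.cos(angles)
    return pe


def project_tiles(features: np.ndarray, params: dict[str, Tensor]) -> np.ndarray:
    """ReLU(features @ W + b) — the tile projection, as plain NumPy."""
    features = np.asarray(features, dtype=float)
    W, b = params["proj_W"].data, params["proj_b"].data
    if features.shape[1] != W.shape[0]:
        raise ValueError(
            f"feature channels {features.shape[1]} != projection input {W.shape[0]}"
        )
    return np.maximum(features @ W + b, 0.0)


def _split_heads(t: Tensor, h: int, dh: int) -> list[Tensor]:
    return [t[:, i * dh : (i + 1) * dh] for i in range(h)]


def forward_with_graph(
    bag: TileBag,
    params: dict[str, Tensor],
    config: ModelConfig,
    agents: Optional[np.ndarray] = None,
):
    """Run the full forward pass, returning the autodiff output node too.

    Parameters
    ----------
    agents
        Optional fixed agent tokens, a (k x embed_dim) array used directly
        (split per head) instead of pooling agents from the query rows.
        With fixed agents the bag prediction is exactly invariant to tile
        order; with pooled agents (the default) it is invariant only up to
        the pooling's dependence on row order.

    Returns
    -------
    (pred_node, prediction)
        ``pred_node`` is the scalar sigmoid output as a differentiable
        tensor; ``prediction`` a :class:`BagPrediction` of plain arrays.
    """
    n = bag.n_tiles
    if n < 1:
        raise ValueError("empty bag")
    if bag.n_channels != config.input_dim:
        raise ValueError(
            f"bag has {bag.n_channels} channels, model expects {config.input_dim}"
        )
    D, nh, dh = config.embed_dim, config.n_heads, config.head_dim

    feats = Tensor(np.asarray(bag.features, dtype=float))
    X = (feats @ params["proj_W"] + params["proj_b"]).relu()
    X = X + Tensor(positional_encoding(bag.coords, D))
    S = concat_rows([X, params["cls_token"]])  # (n+1) x D, cls last

    seq_len = n + 1
    k_eff = min(config.n_agents, seq_len)

    # --- pre-norm agent-attention block ---
    Z = layer_norm(S, params["ln1_g"], params["ln1_b"])
    Q = Z @ params["Wq"] + params["bq"]
    K = Z @ params["Wk"] + params["bk"]
    V = Z @ params["Wv"] + params["bv"]
    scale = 1.0 / np.sqrt(dh)
    pool = Tensor(agent_pooling_matrix(seq_len, k_eff))

    head_outputs: list[Tensor] = []
    rollout_heads: list[np.ndarray] = []
    for h, (Qh, Kh, Vh) in enumerate(
        zip(_split_heads(Q, nh, dh), _split_heads(K, nh, dh), _split_heads(V, nh, dh))
    ):
        if agents is not None:
            fixed = np.asarray(agents, dtype=float)
            if fixed.shape[1] != D:
                raise ValueError(f"fixed agents must have {D} columns")
            Ah = Tensor(fixed[:, h * dh : (h + 1) * dh])
        else:
            Ah = pool @ Qh
        attn1 = softmax_rows((Ah @ Kh.T) * scale)  # k x (n+1)
        v_agent = attn1 @ Vh
        attn2 = softmax_rows((Qh @ Ah.T) * scale)  # (n+1) x k
        head_outputs.append(attn2 @ v_agent)
        rollout_heads.append(attn2.data @ attn1.data)

    O = concat_rows([h.T for h in head_outputs]).T  # (n+1) x D
    S = S + (O @ params["Wo"] + params["bo"])

    # --- feed-forward block ---
    Z2 = layer_norm(S, params["ln2_g"], params["ln2_b"])
    F = ((Z2 @ params["ff_W1"] + params["ff_b1"]).relu()) @ params["ff_W2"]
    S = S + (F + params["ff_b2"])

    cls_row = S[n : n + 1, :]  # 1 x D
    embedding_cls = cls_row.data[0].copy()

    # --- MLP regression head ---
    hnorm = layer_norm(cls_row, params["head_ln_g"], params["head_ln_b"])
    logit = hnorm @ params["head_W"] + params["head_b"]
    pred_node = logit.sigmoid()
    prob = float(pred_node.data.reshape(()))
    if not np.isfinite(prob):
        raise FloatingPointError("non-finite activation in forward pass")

    rollout = np.mean(rollout_heads, axis=0)  # (n+1) x (n+1), head-averaged
    tile_scores_raw = rollout[n, :n].copy()

    prediction = BagPrediction(
        risk_probability=prob,
        tile_scores_raw=tile_scores_raw,
        embedding_cls=embedding_cls,
    )
    return pred_node, prediction


def forward_bag(
    bag: TileBag,
    params: dict[str, Tensor],
    config: ModelConfig,
    agents: Optional[np.ndarray] = None,
) -> BagPrediction:
    """Predict the continuous risk probability for one bag."""
    _, prediction = forward_with_graph(bag, params, config, agents=agents)
    return prediction


def embed_tile(
    tile_features: np.ndarray,
    coords: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
) -> np.ndarray:
    """Post-transformer cls embedding of a single tile (singleton bag)."""
    tile_features = np.asarray(tile_features, dtype=float).reshape(1, -1)
    coords = np.asarray(coords, dtype=int).reshape(1, 2)
    bag = TileBag(
        slide_id="_single", patient_id="_single",
        features=tile_features, coords=coords,
    )
    return forward_bag(bag, params, config).embedding_cls


# ---------------------------------------------------------------------------
# Checkpoints (NumPy archive + JSON-serialized config)
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig,
                    seed: int = 0) -> None:
    arrays = {f"param/{k}": v.data for k, v in params.items()}
    meta = json.dumps({"config": asdict(config), "seed": int(seed)})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig, int]:
    with np.load(path, allow_pickle=False) as f:
        if "__meta__" not in f:
            raise ValueError(f"{path}: missing '__meta__' entry")
        meta = json.loads(str(f["__meta__"]))
        params = {
            k.removeprefix("param/"): Tensor(f[k], requires_grad=True)
            for k in f.files
            if k.startswith("param/")
        }
    config = ModelConfig(**meta["config"])
    return params, config, int(meta["seed"])
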