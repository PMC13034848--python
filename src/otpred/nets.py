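"""The two prior-initialized off-target sub-models and their mean fusion.

The M-model starts from the mismatch-tolerance (MTP) prior, the D-model from
the normalized DNA-RNA interaction (DRICS) prior.  Both share the same
shape: a trainable scalar embedding over (position, pair-type) cells, an
Inception block of parallel same-padded 1-D convolutions (kernel sizes 3 and
5, 20 kernels each) with an identity residual branch, a bidirectional LSTM
stack (two layers of hidden size 25 for M, one layer of hidden size 20 for
D), and a dense head (80 -> 20 -> 1) ending in a sigmoid off-target
probability.  The embedding is updated jointly with the downstream weights
during backpropagation; freezing it yields the "no-update" ablation, and
dropping the Inception or BiLSTM block yields the architecture ablations.

The ensemble prediction is the arithmetic mean of the two sub-model
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .alphabet import EncodedPair
from .priors import PriorEmbedding, read_embedding, write_embedding

__all__ = [
    "SubModelConfig",
    "SubModel",
    "build_submodel",
    "predict",
    "ensemble_predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class SubModelConfig:
    """Architecture hyperparameters of one sub-model.

    ``kind`` selects the prior family: "M" (MTP) or "D" (DRICS).  Defaults
    follow the validated architecture: conv kernels (3, 5) x 20, BiLSTM
    hidden 25 x 2 layers (M) or 20 x 1 layer (D), head (80, 20, 1).
    """

    kind: str = "M"
    conv_kernel_sizes: tuple[int, ...] = (3, 5)
    kernels_per_branch: int = 20
    residual_branch: bool = True
    recurrent_layers: int | None = None
    recurrent_hidden: int | None = None
    head_sizes: tuple[int, ...] = (80, 20, 1)
    embedding_trainable: bool = True
    use_inception: bool = True
    use_bilstm: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("M", "D"):
            raise ValueError(f"kind must be 'M' or 'D', got {self.kind!r}")
        if self.head_sizes[-1] != 1:
            raise ValueError("the final head layer must have one neuron")
        if self.kernels_per_branch <= 0:
            raise ValueError("kernels_per_branch must be positive")
        if self.recurrent_layers is None:
            object.__setattr__(self, "recurrent_layers", 2 if self.kind == "M" else 1)
        if self.recurrent_hidden is None:
            object.__setattr__(self, "recurrent_hidden", 25 if self.kind == "M" else 20)
        if self.recurrent_hidden <= 0 or self.recurrent_layers <= 0:
            raise ValueError("recurrent block sizes must be positive")


@dataclass
class SubModel:
    """One built sub-model: config, live embedding layer, downstream net."""

    config: SubModelConfig
    prior: PriorEmbedding
    seed: int
    embedding: nn.EmbeddingLookup
    net: nn.Sequential = field(repr=False)

    @property
    def L(self) -> int:
        return self.prior.conv.L

    def params(self) -> list[nn.Param]:
        return self.embedding.params() + self.net.params()

    def forward_logits(self, cols0: np.ndarray) -> np.ndarray:
        return self.net.forward(self.embedding.forward(cols0))

    def backward(self, dlogits: np.ndarray) -> None:
        self.embedding.backward(self.net.backward(dlogits))

    def embedding_matrix(self) -> np.ndarray:
        """Current (possibly updated) L x 16 embedding values."""
        return self.embedding.W.value.copy()


def build_submodel(config: SubModelConfig, prior: PriorEmbedding, seed: int) -> SubModel:
    """Assemble a sub-model with the embedding initialized exactly to the prior.

    Downstream weights are drawn from ``seed``; two builds with the same
    arguments are parameter-identical.
    """
    expected_prior = {"M": "MTP", "D": "DRICS"}[config.kind]
    if prior.kind != expected_prior:
        raise ValueError(f"{config.kind}-model requires a {expected_prior} prior, got {prior.kind}")
    if prior.kind == "DRICS" and not prior.normalized:
        raise ValueError("DRICS prior must be normalized before model construction")

    rng = np.random.default_rng(seed)
    embedding = nn.EmbeddingLookup(prior.matrix, trainable=config.embedding_trainable)
    L = prior.conv.L
    layers: list[nn.Layer] = []
    channels = 1
    if config.use_inception:
        inception = nn.Inception(
            channels,
            config.conv_kernel_sizes,
            config.kernels_per_branch,
            rng,
            residual=config.residual_branch,
        )
        layers.append(inception)
        channels = inception.c_out
    if config.use_bilstm:
        bilstm = nn.BiLSTM(channels, config.recurrent_hidden, config.recurrent_layers, rng)
        layers.append(bilstm)
        channels = bilstm.c_out
    layers.append(nn.Flatten())
    width = L * channels
    for i, h in enumerate(config.head_sizes):
        layers.append(nn.Dense(width, h, rng, name=f"head{i}"))
        if i < len(config.head_sizes) - 1:
            layers.append(nn.ReLU())
        width = h
    return SubModel(config=config, prior=prior, seed=seed, embedding=embedding, net=nn.Sequential(layers))


def encode_batch(pairs: list[EncodedPair], L: int) -> np.ndarray:
    """Stack encoded pairs into a 0-based (B, L) index array."""
    cols = np.empty((len(pairs), L), dtype=np.int64)
    for i, p in enumerate(pairs):
        if p.L != L:
            raise ValueError(f"pair length {p.L} != model L={L}")
        cols[i] = p.cols - 1
    return cols


def predict(model: SubModel, batch: list[EncodedPair] | np.ndarray, batch_size: int = 1024) -> np.ndarray:
    """Off-target probabilities for a batch, order-preserving, in (0, 1).

    Accepts a list of :class:`EncodedPair` or a pre-stacked 0-based index
    array of shape (B, L).
    """
    cols0 = batch if isinstance(batch, np.ndarray) else encode_batch(batch, model.L)
    if cols0.shape[1] != model.L:
        raise ValueError(f"batch L={cols0.shape[1]} != model L={model.L}")
    out = np.empty(len(cols0))
    for start in range(0, len(cols0), batch_size):
        chunk = cols0[start : start + batch_size]
        out[start : start + len(chunk)] = nn.sigmoid(model.forward_logits(chunk).ravel())
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def ensemble_predict(p_m: np.ndarray, p_d: np.ndarray) -> np.ndarray:
    """Mean fusion of the two sub-model probability vectors."""
    p_m = np.asarray(p_m, dtype=np.float64)
    p_d = np.asarray(p_d, dtype=np.float64)
    if p_m.shape != p_d.shape:
        raise ValueError(f"length mismatch: {p_m.shape} vs {p_d.shape}")
    return 0.5 * (p_m + p_d)


def save_checkpoint(model: SubModel, outdir: str | Path) -> None:
    """Write a checkpoint: init + current embedding TSVs, weights, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_embedding(model.prior, outdir, "embedding_init")
    from dataclasses import replace

    current = replace(model.prior, matrix=model.embedding_matrix())
    write_embedding(current, outdir, "embedding_current")
    weights = {p.name: p.value for p in model.net.params()}
    np.savez(outdir / "weights.npz", **weights)
    meta = {"config": asdict(model.config), "seed": model.seed}
    (outdir / "model.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(outdir: str | Path) -> SubModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    cfg_d = dict(meta["config"])
    for key in ("conv_kernel_sizes", "head_sizes"):
        cfg_d[key] = tuple(cfg_d[key])
    config = SubModelConfig(**cfg_d)
    prior = read_embedding(outdir, "embedding_init")
    model = build_submodel(config, prior, seed=meta["seed"])
    current = read_embedding(outdir, "embedding_current")
    model.embedding.W.value[...] = current.matrix
    with np.load(outdir / "weights.npz") as blob:
        for p in model.net.params():
            p.value[...] = blob[p.name]
    return model
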