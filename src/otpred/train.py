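"""Training with synchronous prior-embedding updates and multi-seed repeats.

One training run jointly updates the prior embedding and the downstream
network by backpropagation (the embedding can be frozen to obtain the
"no-update" ablation), monitors AUPRC on a validation split after every
epoch, and early-stops when it fails to improve for ``patience`` epochs,
restoring the best-epoch parameters.  Because random initialization moves
the learned embedding, the run is repeated across several seeds
(default 5); each :class:`SeedRun` keeps the initial and updated embedding
matrices so the update-pattern analysis can difference them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from . import nn
from .alphabet import EncodedPair, GuideTargetPair, PositionConvention, encode_pair
from .nets import SubModel, SubModelConfig, build_submodel, encode_batch, predict
from .priors import PriorEmbedding

__all__ = ["TrainConfig", "SeedRun", "train_submodel", "run_seeds"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; architecture lives in :class:`SubModelConfig`."""

    epochs_max: int = 30
    patience: int = 5
    batch_size: int = 256
    learning_rate: float = 1e-3
    loss: str = "bce"  # "bce" | "weighted_bce"
    pos_weight: float = 1.0
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if len(self.seeds) < 1:
            raise ValueError("at least one seed is required")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError(f"duplicate seeds in {self.seeds}")
        if self.patience > self.epochs_max:
            raise ValueError("patience must not exceed epochs_max")
        if self.loss not in ("bce", "weighted_bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class SeedRun:
    """Result of one seeded training run."""

    seed: int
    model: SubModel
    m_init: np.ndarray
    m_update: np.ndarray
    val_history: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def delta(self) -> np.ndarray:
        return self.m_update - self.m_init


def _as_cols(
    data: list[GuideTargetPair] | list[EncodedPair], conv: PositionConvention
) -> tuple[np.ndarray, np.ndarray]:
    encoded = [
        p if isinstance(p, EncodedPair) else encode_pair(p, conv) for p in data
    ]
    labels = np.array(
        [p.label if isinstance(p, GuideTargetPair) else 0 for p in data], dtype=np.int64
    )
    return encode_batch(encoded, conv.L), labels


def train_submodel(
    train_set: list[GuideTargetPair],
    val_set: list[GuideTargetPair],
    config: SubModelConfig,
    tc: TrainConfig,
    prior: PriorEmbedding,
    seed: int,
) -> SeedRun:
    """Train one sub-model from its prior; reproducible given ``seed``.

    The same seed drives weight initialization and the per-epoch shuffling
    order, so distinct seeds differ in both, and a repeated call is
    bit-reproducible.
    """
    conv = prior.conv
    x_train, y_train = _as_cols(train_set, conv)
    x_val, y_val = _as_cols(val_set, conv)
    if y_val.min() == y_val.max():
        raise ValueError("validation set must contain both classes (AUPRC stopping)")

    model = build_submodel(config, prior, seed)
    m_init = model.embedding_matrix()
    pos_weight = tc.pos_weight if tc.loss == "weighted_bce" else 1.0
    opt = nn.Adam(model.params(), lr=tc.learning_rate)
    shuffler = np.random.default_rng(seed)

    best_val = -np.inf
    best_state: list[np.ndarray] | None = None
    best_epoch = 0
    stale = 0
    history: list[float] = []
    n = len(x_train)
    for epoch in range(1, tc.epochs_max + 1):
        order = shuffler.permutation(n)
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            logits = model.forward_logits(x_train[idx])
            _, dlogits = nn.bce_loss_and_grad(logits, y_train[idx], pos_weight)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
        p_val = predict(model, x_val)
        val_auprc = float(average_precision_score(y_val, p_val))
        history.append(val_auprc)
        if val_auprc > best_val:
            best_val = val_auprc
            best_state = [p.value.copy() for p in model.params()]
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break
    assert best_state is not None
    for p, v in zip(model.params(), best_state):
        p.value[...] = v
    return SeedRun(
        seed=seed,
        model=model,
        m_init=m_init,
        m_update=model.embedding_matrix(),
        val_history=history,
        stopped_epoch=len(history),
        best_epoch=best_epoch,
    )


def run_seeds(
    train_set: list[GuideTargetPair],
    val_set: list[GuideTargetPair],
    config: SubModelConfig,
    tc: TrainConfig,
    prior: PriorEmbedding,
) -> list[SeedRun]:
    """One independent :func:`train_submodel` run per configured seed."""
    return [
        train_submodel(train_set, val_set, config, tc, prior, seed)
        for seed in tc.seeds
    ]
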