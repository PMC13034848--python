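"""Analysis of how training moves the prior embedding spaces.

Training across several random seeds yields several updated embeddings; the
analysis first differences each against the shared initial matrix, then
fuses the per-seed deltas by majority-direction voting: a cell's primary
direction is the sign agreed by more than half of the seeds, and the fused
delta is the mean over the agreeing seeds only, so a minority seed pulling
the other way cannot dilute a consistent trend.  Adding the fused delta back
onto the initial matrix gives the fused embedding used for all distribution
summaries.

On top of the fused quantities the module computes

* per-biological-position distributions of the 12 mismatch values (violin
  data, mean, population variance);
* a weighted mismatch-pair similarity combining the Pearson correlation of
  two tokens' per-position value vectors with (one minus) their min-max
  normalized Euclidean distance, Phi = (1-alpha) P + alpha (1 - Norm(E));
* intra-/inter-group similarity summaries over the guide-base groups
  rA/rC/rG/rT;
* cross-dataset concordance: Pearson correlations between the flattened
  fused deltas of datasets, and a mean-similarity ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .alphabet import MISMATCH_GROUPS, MISMATCH_TOKENS, PositionConvention, token_index
from .train import SeedRun

__all__ = [
    "DeltaStack",
    "FusedUpdate",
    "SimilarityMatrix",
    "delta_stack",
    "vote_fuse",
    "position_stats",
    "pair_similarity",
    "group_similarity_summary",
    "cross_dataset_concordance",
]

_REGIONS = {"seed": range(1, 11), "nonseed": range(11, 21), "all": range(1, 21)}


@dataclass(frozen=True)
class DeltaStack:
    """Per-seed embedding deltas: (n_seeds, L, 16), plus the shared init."""

    deltas: np.ndarray
    seeds: tuple[int, ...]
    m_init: np.ndarray

    @property
    def n(self) -> int:
        return len(self.seeds)


@dataclass(frozen=True)
class FusedUpdate:
    """Majority-vote fusion of a :class:`DeltaStack`.

    ``T`` holds the primary direction per cell (+1/-1; 0 only on an even-n
    tie), ``support`` the number of agreeing seeds, ``delta_fusion`` the
    mean delta over agreeing seeds, and ``m_fusion = m_init + delta_fusion``.
    """

    T: np.ndarray
    delta_fusion: np.ndarray
    m_fusion: np.ndarray
    support: np.ndarray
    n: int


def delta_stack(runs: list[SeedRun]) -> DeltaStack:
    """Stack per-seed updates as differences from the shared initial matrix."""
    if not runs:
        raise ValueError("at least one run is required")
    m_init = runs[0].m_init
    for r in runs[1:]:
        if not np.array_equal(r.m_init, m_init):
            raise ValueError("runs do not share the same initial embedding")
    deltas = np.stack([r.m_update - m_init for r in runs])
    return DeltaStack(deltas=deltas, seeds=tuple(r.seed for r in runs), m_init=m_init)


def vote_fuse(stack: DeltaStack) -> FusedUpdate:
    """Fuse per-seed deltas by majority-direction voting.

    A strictly positive delta votes +1, otherwise -1 (an exact zero counts
    as the non-increase branch).  The primary direction ``T`` is the sign of
    the vote sum (0 on an even-n tie, where the fused delta is 0); the fused
    delta is the mean of the deltas from seeds agreeing with ``T``.
    """
    d = stack.deltas
    t = np.where(d > 0, 1, -1)
    vote = t.sum(axis=0)
    T = np.sign(vote).astype(int)
    agree = t == T[None, :, :]
    support = agree.sum(axis=0)
    with np.errstate(invalid="ignore"):
        delta_fusion = np.where(
            support > 0, (d * agree).sum(axis=0) / np.maximum(support, 1), 0.0
        )
    return FusedUpdate(
        T=T,
        delta_fusion=delta_fusion,
        m_fusion=stack.m_init + delta_fusion,
        support=support,
        n=stack.n,
    )


def position_stats(
    embedding: np.ndarray,
    conv: PositionConvention | None = None,
    tokens: tuple[str, ...] = MISMATCH_TOKENS,
    stage: str = "update",
) -> pd.DataFrame:
    """Long-format per-position distribution of the given tokens' values.

    One row per (biological position, token); ``mean`` and population
    ``variance`` are repeated per position for convenience (violin-ready).
    """
    conv = conv or PositionConvention()
    if embedding.shape != (conv.L, 16):
        raise ValueError(f"embedding shape {embedding.shape} != (L={conv.L}, 16)")
    rows = []
    for bio in range(1, conv.n_guide + 1):
        r = conv.row_of_bio(bio) - 1
        vals = np.array([embedding[r, token_index(t) - 1] for t in tokens])
        mean = float(vals.mean())
        var = float(vals.var())  # population variance
        for t, v in zip(tokens, vals):
            rows.append((bio, t, float(v), mean, var, stage))
    return pd.DataFrame(
        rows, columns=["bio_pos", "token", "value", "mean", "variance", "stage"]
    )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Weighted mismatch-pair similarity Phi over one guide region."""

    phi: pd.DataFrame
    pearson: pd.DataFrame
    norm_euclid: pd.DataFrame
    region: str
    alpha: float


def pair_similarity(
    embedding: np.ndarray,
    conv: PositionConvention | None = None,
    region: str = "all",
    alpha: float = 0.5,
    tokens: tuple[str, ...] = MISMATCH_TOKENS,
) -> SimilarityMatrix:
    """Phi = (1-alpha) * Pearson + alpha * (1 - Norm(Euclidean)).

    Each token's profile is its value vector over the region's biological
    positions ("seed" = 1-10, "nonseed" = 11-20, "all" = 1-20).  Norm() is
    min-max over the unordered distinct token pairs of the region, so
    1 - Norm(E) spans [0, 1] like Pearson's scale.  Zero-variance profiles
    make Pearson undefined; those entries are NaN (flagged).
    """
    conv = conv or PositionConvention()
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {sorted(_REGIONS)}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    positions = list(_REGIONS[region])
    if len(positions) < 3:
        raise ValueError("region must span at least 3 positions")
    rows = [conv.row_of_bio(b) - 1 for b in positions]
    profiles = {
        t: embedding[rows, token_index(t) - 1].astype(float) for t in tokens
    }
    k = len(tokens)
    P = np.full((k, k), np.nan)
    E = np.zeros((k, k))
    for i, ti in enumerate(tokens):
        for j, tj in enumerate(tokens):
            vi, vj = profiles[ti], profiles[tj]
            E[i, j] = float(np.linalg.norm(vi - vj))
            si, sj = vi.std(), vj.std()
            # numerically-zero spread (constant profile) makes Pearson undefined
            if si <= 1e-12 * (1.0 + abs(vi).max()) or sj <= 1e-12 * (1.0 + abs(vj).max()):
                continue  # leave NaN (flagged)
            P[i, j] = float(np.corrcoef(vi, vj)[0, 1])
    off = ~np.eye(k, dtype=bool)
    e_vals = E[off]
    e_min, e_max = float(e_vals.min()), float(e_vals.max())
    span = e_max - e_min
    if span == 0.0:
        norm_e = np.zeros_like(E)
    else:
        norm_e = (E - e_min) / span
    phi = (1.0 - alpha) * P + alpha * (1.0 - norm_e)
    idx = list(tokens)
    return SimilarityMatrix(
        phi=pd.DataFrame(phi, index=idx, columns=idx),
        pearson=pd.DataFrame(P, index=idx, columns=idx),
        norm_euclid=pd.DataFrame(norm_e, index=idx, columns=idx),
        region=region,
        alpha=alpha,
    )


def group_similarity_summary(sim: SimilarityMatrix) -> pd.DataFrame:
    """Mean Phi within each guide-base group and between group pairs.

    Intra-group means average the 3 unordered token pairs of a group;
    inter-group means average all 9 cross-group token pairs.
    """
    phi = sim.phi
    rows = []
    for g, toks in MISMATCH_GROUPS.items():
        vals = [phi.loc[a, b] for a, b in combinations(toks, 2)]
        rows.append((g, g, float(np.nanmean(vals)), len(vals)))
    for (g1, t1), (g2, t2) in combinations(MISMATCH_GROUPS.items(), 2):
        vals = [phi.loc[a, b] for a in t1 for b in t2]
        rows.append((g1, g2, float(np.nanmean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_phi", "n_pairs"])


def _update_distribution(fused: FusedUpdate, conv: PositionConvention) -> np.ndarray:
    """Flattened fused deltas over the 240 guide-row mismatch cells."""
    rows = [conv.row_of_bio(b) - 1 for b in range(1, conv.n_guide + 1)]
    cols = [token_index(t) - 1 for t in MISMATCH_TOKENS]
    return fused.delta_fusion[np.ix_(rows, cols)].ravel()


def cross_dataset_concordance(
    fused: dict[str, FusedUpdate], conv: PositionConvention | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of fused update distributions.

    Returns the symmetric correlation matrix and a per-dataset ranking by
    mean similarity to the other datasets (descending).  A dataset whose
    flattened update vector is constant has undefined correlations and is
    flagged with NaN.
    """
    conv = conv or PositionConvention()
    if len(fused) < 2:
        raise ValueError("at least two datasets are required")
    names = list(fused)
    vecs = {k: _update_distribution(f, conv) for k, f in fused.items()}
    m = len(names)
    corr = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            vi, vj = vecs[names[i]], vecs[names[j]]
            if vi.std() == 0.0 or vj.std() == 0.0:
                continue
            corr[i, j] = float(np.corrcoef(vi, vj)[0, 1])
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    mean_sim = {
        k: float(np.nanmean([corr_df.loc[k, o] for o in names if o != k]))
        for k in names
    }
    ranking = (
        pd.DataFrame(
            {"dataset": list(mean_sim), "mean_similarity": list(mean_sim.values())}
        )
        .sort_values("mean_similarity", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return corr_df, ranking
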