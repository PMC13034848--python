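"""Synthetic prior tables and sgRNA/off-target datasets with planted effects.

Real training corpora (millions of aligned guide/site pairs labelled by
genome-wide cleavage assays) cannot ship with the package, so every stage is
exercised on data drawn from a known generative model:

* :func:`gen_prior_table` emulates the literature prior tables — mismatch
  tolerances in (0, 1] for the MTP space, and raw interaction contribution
  scores spanning the reported [-5.5, 0.6] range for the DRICS space.
* :func:`gen_dataset` plants a 20 x 16 position-by-pair effect matrix ``w``
  (penalties at mismatch cells, a fixed baseline at match cells), draws
  random guides, mutates each candidate site at sampled positions, and
  labels sites by a Bernoulli draw whose success probability follows either
  a logistic-sum link (logit p = intercept + sum of the mismatch penalties)
  or a product-of-tolerances link.  The intercept is calibrated so the
  positive prevalence hits a target (default 2%), emulating the extreme
  class imbalance of genome-wide off-target screens.  Splits are
  guide-disjoint so evaluation never sees a training guide.

Because ``w`` is known, downstream claims become checkable: embedding
updates learned from the data can be rank-correlated against the planted
penalties, and a frozen-prior ablation has a known disadvantage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import MISMATCH_TOKENS, TOKENS, GuideTargetPair, token_index
from .priors import PriorTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "default_planted_w",
    "gen_prior_table",
    "gen_dataset",
    "site_probability",
    "write_pairs",
    "read_pairs",
]

_BASES = np.array(list("ACGT"))

#: fixed per-token penalty multipliers (nonconstant across the 12 mismatch
#: tokens; the two wobble pairs TC (rU-dG) and GA (rG-dT) are the mildest)
_TOKEN_FACTOR = {
    "AC": 1.30, "AG": 0.90, "AT": 1.10,
    "CA": 1.50, "CG": 0.70, "CT": 1.20,
    "GA": 0.40, "GC": 1.40, "GT": 0.80,
    "TA": 1.00, "TC": 0.45, "TG": 1.60,
}


def default_planted_w(match_baseline: float = 0.0) -> np.ndarray:
    """Default 20 x 16 planted effect matrix (rows = biological positions).

    Penalties are the product of a positional severity (strong in the
    PAM-proximal seed region, fading towards the PAM-distal end) and a
    per-token factor; match cells sit at ``match_baseline``.
    """
    pos_factor = np.linspace(2.5, 0.5, 20)  # bio position 1 (seed) .. 20
    w = np.full((20, 16), match_baseline, dtype=np.float64)
    for tok, f in _TOKEN_FACTOR.items():
        w[:, token_index(tok) - 1] = -pos_factor * f
    return w


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_guides: int = 20
    sites_per_guide: int = 2000
    mismatch_count_range: tuple[int, int] = (1, 6)
    planted_w: np.ndarray = field(default_factory=default_planted_w)
    link: str = "logistic_sum"
    target_prevalence: float = 0.02
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.link not in ("logistic_sum", "product_tolerance"):
            raise ValueError(f"unknown link {self.link!r}")
        if not 0 < self.target_prevalence < 0.5:
            raise ValueError("target prevalence must lie in (0, 0.5)")
        w = np.asarray(self.planted_w, dtype=np.float64)
        if w.shape != (20, 16):
            raise ValueError("planted_w must be 20 x 16 (biological positions x tokens)")
        mis_idx = [token_index(t) - 1 for t in MISMATCH_TOKENS]
        if np.ptp(w[:, mis_idx]) == 0:
            raise ValueError("planted_w mismatch cells must not be constant")
        lo, hi = self.mismatch_count_range
        if not 1 <= lo <= hi <= 20:
            raise ValueError("mismatch_count_range must satisfy 1 <= lo <= hi <= 20")
        object.__setattr__(self, "planted_w", w)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated pairs, their guide-disjoint splits, and provenance."""

    pairs: tuple[GuideTargetPair, ...]
    splits: dict[str, tuple[GuideTargetPair, ...]]
    spec: SyntheticSpec
    intercept: float
    achieved_prevalence: float


def gen_prior_table(kind: str, seed: int, ranges: dict | None = None) -> PriorTable:
    """Random prior-table fixture emulating the literature value ranges.

    MTP: tolerances uniform over (0, 1] at the 12 mismatch tokens x 20
    positions.  DRICS: all 16 tokens x 20 positions, match scores uniform
    over (0, 0.6] and mismatch scores uniform over [-5.5, 0), the raw range
    reported for the source contribution scores.
    """
    ranges = ranges or {}
    rng = np.random.default_rng(seed)
    entries = []
    if kind == "MTP":
        lo, hi = ranges.get("mismatch", (0.0, 1.0))
        for pos in range(1, 21):
            for tok in MISMATCH_TOKENS:
                entries.append((pos, tok, float(hi - (hi - lo) * rng.random())))
    elif kind == "DRICS":
        mlo, mhi = ranges.get("match", (0.0, 0.6))
        xlo, xhi = ranges.get("mismatch", (-5.5, 0.0))
        for pos in range(1, 21):
            for tok in TOKENS:
                if tok in MISMATCH_TOKENS:
                    entries.append((pos, tok, float(xlo + (xhi - xlo) * rng.random())))
                else:
                    entries.append((pos, tok, float(mhi - (mhi - mlo) * rng.random())))
    else:
        raise ValueError(f"kind must be MTP or DRICS, got {kind!r}")
    return PriorTable(entries=tuple(entries), kind=kind, provenance=f"synthetic(seed={seed})")


def site_probability(
    spec: SyntheticSpec, bio_positions: np.ndarray, tokens: list[str], intercept: float
) -> float:
    """Planted off-target probability of one site given its mismatches."""
    s = sum(
        spec.planted_w[p - 1, token_index(t) - 1] for p, t in zip(bio_positions, tokens)
    )
    if spec.link == "logistic_sum":
        return float(1.0 / (1.0 + np.exp(-(intercept + s))))
    # product link: tolerances tau = exp(w) in (0, 1]; base activity sigmoid(intercept)
    return float(1.0 / (1.0 + np.exp(-intercept)) * np.exp(s))


def _mutate(guide20: np.ndarray, rng: np.random.Generator, spec: SyntheticSpec):
    lo, hi = spec.mismatch_count_range
    m = int(rng.integers(lo, hi + 1))
    bio_pos = rng.choice(20, size=m, replace=False) + 1  # 1 = PAM-proximal
    target = guide20.copy()
    toks = []
    for bp in bio_pos:
        i = 20 - bp  # 5'->3' index within the 20-mer
        choices = [b for b in "ACGT" if b != guide20[i]]
        nb = choices[int(rng.integers(3))]
        target[i] = nb
        toks.append(guide20[i] + nb)
    return target, np.asarray(bio_pos), toks


def _calibrate_intercept(spec: SyntheticSpec, penalty_sums: np.ndarray) -> float:
    """Bisection on the intercept so mean planted p hits the target prevalence."""
    target = spec.target_prevalence

    def mean_p(c: float) -> float:
        if spec.link == "logistic_sum":
            return float(np.mean(1.0 / (1.0 + np.exp(-(c + penalty_sums)))))
        return float(np.mean(1.0 / (1.0 + np.exp(-c)) * np.exp(penalty_sums)))

    lo, hi = -30.0, 30.0
    if mean_p(hi) < target:
        import warnings

        warnings.warn(
            f"target prevalence {target} infeasible; achieved {mean_p(hi):.4g}",
            stacklevel=2,
        )
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw guides, mutate candidate sites, label them by the planted model.

    Emitted sequences are 24 nt: a shared 5' pad base, the 20-mer
    protospacer, and the PAM (guide ``NGG``, target ``bGG``).  Splits are
    guide-disjoint with fractions ``spec.split_fractions``.
    """
    rng = np.random.default_rng(spec.seed)
    guides = [
        "".join(rng.choice(_BASES, size=20)) for _ in range(spec.n_guides)
    ]
    # sample all site mutation patterns first so the intercept can be
    # calibrated on the realized penalty distribution
    sites = []
    penalty_sums = np.empty(spec.n_guides * spec.sites_per_guide)
    k = 0
    for gi, g in enumerate(guides):
        g_arr = np.array(list(g))
        for _ in range(spec.sites_per_guide):
            target, bio_pos, toks = _mutate(g_arr, rng, spec)
            s = sum(
                spec.planted_w[p - 1, token_index(t) - 1]
                for p, t in zip(bio_pos, toks)
            )
            sites.append((gi, target))
            penalty_sums[k] = s
            k += 1
    intercept = _calibrate_intercept(spec, penalty_sums)
    if spec.link == "logistic_sum":
        probs = 1.0 / (1.0 + np.exp(-(intercept + penalty_sums)))
    else:
        probs = 1.0 / (1.0 + np.exp(-intercept)) * np.exp(penalty_sums)
    labels = (rng.random(len(probs)) < probs).astype(int)

    pairs = []
    pad_pam = []
    for g in guides:
        pad = str(rng.choice(_BASES))
        pam_b = str(rng.choice(_BASES))
        pad_pam.append((pad, pam_b))
    for (gi, target), y in zip(sites, labels):
        pad, pam_b = pad_pam[gi]
        pairs.append(
            GuideTargetPair(
                sgrna_id=f"sg{gi:03d}",
                guide_seq=pad + guides[gi] + "NGG",
                target_seq=pad + "".join(target) + pam_b + "GG",
                label=int(y),
                dataset_id=f"synthetic_seed{spec.seed}",
            )
        )

    # guide-disjoint splits
    order = rng.permutation(spec.n_guides)
    f_train, f_val, _ = spec.split_fractions
    n_train = max(1, int(round(f_train * spec.n_guides)))
    n_val = max(1, int(round(f_val * spec.n_guides)))
    n_train = min(n_train, spec.n_guides - 2) if spec.n_guides >= 3 else n_train
    train_g = set(order[:n_train])
    val_g = set(order[n_train : n_train + n_val])
    splits = {"train": [], "val": [], "test": []}
    for (gi, _), pair in zip(sites, pairs):
        if gi in train_g:
            splits["train"].append(pair)
        elif gi in val_g:
            splits["val"].append(pair)
        else:
            splits["test"].append(pair)
    return SyntheticDataset(
        pairs=tuple(pairs),
        splits={k: tuple(v) for k, v in splits.items()},
        spec=spec,
        intercept=float(intercept),
        achieved_prevalence=float(labels.mean()),
    )


def write_pairs(pairs, path: str | Path) -> None:
    """Write pairs as the canonical TSV (one aligned pair per row)."""
    pd.DataFrame(
        [
            (p.sgrna_id, p.guide_seq, p.target_seq, p.label, p.dataset_id)
            for p in pairs
        ],
        columns=["sgrna_id", "guide_seq", "target_seq", "label", "dataset_id"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> tuple[GuideTargetPair, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return tuple(
        GuideTargetPair(
            sgrna_id=row.sgrna_id,
            guide_seq=row.guide_seq,
            target_seq=row.target_seq,
            label=int(row.label),
            dataset_id=row.dataset_id if isinstance(row.dataset_id, str) else "",
        )
        for row in df.itertuples(index=False)
    )
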