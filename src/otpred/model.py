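"""Model/Results facade over the ensemble pipeline.

:class:`OffTargetModel` bundles the data (train/validation pair sets), the
two priors and the architecture/training configuration; ``fit()`` trains
both sub-models across the configured seeds and returns an
:class:`OffTargetResults` carrying the seed runs, prediction and evaluation
methods, the vote-fused embedding updates, and a text ``summary()``.

This is a convenience layer: everything it does is a composition of the
library modules (``train``, ``nets``, ``metrics``, ``updatelens``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import GuideTargetPair, PositionConvention, encode_pair
from .io import RunConfig
from .metrics import DatasetMetrics, evaluate_dataset, wilcoxon_one_sided
from .nets import ensemble_predict, predict as net_predict
from .priors import PriorEmbedding
from .train import SeedRun, run_seeds
from .updatelens import FusedUpdate, delta_stack, vote_fuse

__all__ = ["OffTargetModel", "OffTargetResults"]


@dataclass
class OffTargetModel:
    """Ensemble off-target model specification bound to training data."""

    train_set: list[GuideTargetPair]
    val_set: list[GuideTargetPair]
    mtp_prior: PriorEmbedding
    drics_prior: PriorEmbedding
    config: RunConfig = field(default_factory=RunConfig)

    @classmethod
    def from_dataframes(
        cls,
        train_df: pd.DataFrame,
        val_df: pd.DataFrame,
        mtp_prior: PriorEmbedding,
        drics_prior: PriorEmbedding,
        config: RunConfig | None = None,
    ) -> "OffTargetModel":
        """Build from pair tables with the canonical five columns."""

        def rows(df: pd.DataFrame) -> list[GuideTargetPair]:
            return [
                GuideTargetPair(
                    sgrna_id=str(r.sgrna_id),
                    guide_seq=str(r.guide_seq),
                    target_seq=str(r.target_seq),
                    label=int(r.label),
                    dataset_id=str(getattr(r, "dataset_id", "")),
                )
                for r in df.itertuples(index=False)
            ]

        return cls(rows(train_df), rows(val_df), mtp_prior, drics_prior,
                   config or RunConfig())

    def fit(self, seeds: tuple[int, ...] | None = None) -> "OffTargetResults":
        """Train both sub-models across seeds and wrap the outcome."""
        tc = self.config.train
        if seeds is not None:
            from dataclasses import replace

            tc = replace(tc, seeds=tuple(seeds))
        m_runs = run_seeds(self.train_set, self.val_set, self.config.m_config, tc, self.mtp_prior)
        d_runs = run_seeds(self.train_set, self.val_set, self.config.d_config, tc, self.drics_prior)
        return OffTargetResults(model=self, m_runs=m_runs, d_runs=d_runs)


@dataclass
class OffTargetResults:
    """Fitted ensemble: per-seed runs plus prediction/analysis helpers."""

    model: OffTargetModel
    m_runs: list[SeedRun]
    d_runs: list[SeedRun]

    @property
    def conv(self) -> PositionConvention:
        return self.model.mtp_prior.conv

    @property
    def seeds(self) -> tuple[int, ...]:
        return tuple(r.seed for r in self.m_runs)

    def predict(self, pairs: list[GuideTargetPair], seed: int | None = None) -> pd.DataFrame:
        """Predictions table (p_m, p_d, p_ensemble) for one seed's models."""
        seed = seed if seed is not None else self.seeds[0]
        m_run = next(r for r in self.m_runs if r.seed == seed)
        d_run = next(r for r in self.d_runs if r.seed == seed)
        encoded = [encode_pair(p, self.conv) for p in pairs]
        p_m = net_predict(m_run.model, encoded)
        p_d = net_predict(d_run.model, encoded)
        return pd.DataFrame(
            {
                "sgrna_id": [p.sgrna_id for p in pairs],
                "guide_seq": [p.guide_seq for p in pairs],
                "target_seq": [p.target_seq for p in pairs],
                "label": [p.label for p in pairs],
                "p_m": p_m,
                "p_d": p_d,
                "p_ensemble": ensemble_predict(p_m, p_d),
            }
        )

    def evaluate(
        self, pairs: list[GuideTargetPair], score_col: str = "p_ensemble",
        seed: int | None = None,
    ) -> DatasetMetrics:
        """Per-sgRNA evaluation of one seed's ensemble on a pair set."""
        return evaluate_dataset(
            self.predict(pairs, seed=seed), score_col=score_col,
            threshold=self.model.config.metrics_threshold,
        )

    def seedwise_auprc(self, pairs: list[GuideTargetPair], score_col: str = "p_ensemble") -> list[float]:
        """Dataset AUPRC of every seed's ensemble (for paired comparisons)."""
        return [
            self.evaluate(pairs, score_col=score_col, seed=s).auprc for s in self.seeds
        ]

    def compare_seedwise(self, x: list[float], y: list[float]) -> float:
        """One-sided exact signed-rank p-value that x beats y seed-wise."""
        return wilcoxon_one_sided(x, y)

    def fused_update(self, kind: str = "M") -> FusedUpdate:
        """Vote-fused embedding update of one sub-model family."""
        runs = {"M": self.m_runs, "D": self.d_runs}[kind]
        return vote_fuse(delta_stack(runs))

    def summary(self, test_pairs: list[GuideTargetPair] | None = None) -> str:
        """Human-readable fit summary; includes test metrics when given."""
        lines = [
            "Prior-informed off-target ensemble",
            "==================================",
            f"seeds: {list(self.seeds)}",
            f"L = {self.conv.L} (pad {self.conv.n_pad}, guide 20, PAM {self.conv.n_pam})",
            f"train pairs: {len(self.model.train_set)}  val pairs: {len(self.model.val_set)}",
        ]
        for kind, runs in (("M", self.m_runs), ("D", self.d_runs)):
            best = [max(r.val_history) for r in runs]
            stop = [r.stopped_epoch for r in runs]
            lines.append(
                f"{kind}-model: best val AUPRC per seed "
                f"{np.round(best, 4).tolist()} (stopped at epochs {stop})"
            )
            fused = self.fused_update(kind)
            moved = int((fused.delta_fusion != 0).sum())
            lines.append(
                f"  fused update: {moved}/{fused.delta_fusion.size} cells moved, "
                f"mean |delta| {np.abs(fused.delta_fusion).mean():.4f}"
            )
        if test_pairs is not None:
            for col in ("p_m", "p_d", "p_ensemble"):
                dm = self.evaluate(test_pairs, score_col=col)
                lines.append(
                    f"test {col}: AUPRC {dm.auprc:.4f}  AUROC {dm.auroc:.4f}  (N={dm.N})"
                )
        return "\n".join(lines)
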