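"""Dataset hygiene, file validation and run configuration.

The guide-similarity filter guards against train/test leakage: a candidate
guide whose ungapped positional identity to any reference (training) guide
reaches the threshold (default 90%) is excluded.  Identity is the fraction
of matching positions over the 20-mer protospacer — a declared, reported
stand-in for sequence similarity, since the pairs arrive pre-aligned and
bulges are out of scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alphabet import PositionConvention
from .nets import SubModelConfig
from .train import TrainConfig

__all__ = [
    "RunConfig",
    "filter_similar_guides",
    "guide_identity",
    "validate_pairs_file",
]


def guide_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length guides."""
    if len(a) != len(b):
        raise ValueError(f"guides must be equal length, got {len(a)} and {len(b)}")
    if len(a) == 0:
        raise ValueError("guides must be non-empty")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def filter_similar_guides(
    candidate_guides: list[str],
    reference_guides: list[str],
    threshold: float = 0.9,
) -> tuple[list[str], pd.DataFrame]:
    """Drop candidates too similar to any reference guide.

    Returns the kept candidates and a removal report listing, per removed
    candidate, its best-matching reference and the identity to it.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    kept = []
    removed = []
    for cand in candidate_guides:
        best_ref, best_id = None, -1.0
        for ref in reference_guides:
            ident = guide_identity(cand, ref)
            if ident > best_id:
                best_ref, best_id = ref, ident
        if best_ref is not None and best_id >= threshold:
            removed.append((cand, best_ref, best_id))
        else:
            kept.append(cand)
    report = pd.DataFrame(removed, columns=["candidate", "best_reference", "identity"])
    return kept, report


_PAIR_COLUMNS = ["sgrna_id", "guide_seq", "target_seq", "label", "dataset_id"]


def validate_pairs_file(
    path: str | Path, conv: PositionConvention | None = None
) -> dict:
    """Row-wise validation of a pair TSV; returns a summary report.

    Fatal rows: wrong column count, non-ACGTN bases, non-binary label,
    guide/target length mismatch, length incompatible with the convention.
    Rows needing left-padding (length L - n_pad) are valid but counted as
    warnings.
    """
    conv = conv or PositionConvention()
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    fatal: list[tuple[int, str]] = []
    warnings: list[tuple[int, str]] = []
    if list(df.columns) != _PAIR_COLUMNS:
        return {
            "path": str(path),
            "n_rows": 0,
            "fatal": [(1, f"bad header: {list(df.columns)}")],
            "warnings": [],
            "ok": False,
        }
    for i, row in enumerate(df.itertuples(index=False), start=2):
        g, t = str(row.guide_seq), str(row.target_seq)
        if str(row.label) not in ("0", "1"):
            fatal.append((i, f"label {row.label!r} is not binary"))
            continue
        if len(g) != len(t):
            fatal.append((i, f"length mismatch {len(g)} vs {len(t)}"))
            continue
        if set(g + t) - set("ACGTN"):
            fatal.append((i, "non-ACGTN base"))
            continue
        if len(g) == conv.L - conv.n_pad:
            warnings.append((i, f"length {len(g)}: will be left-padded to L={conv.L}"))
        elif len(g) != conv.L:
            fatal.append((i, f"length {len(g)} incompatible with L={conv.L}"))
    return {
        "path": str(path),
        "n_rows": int(len(df)),
        "fatal": fatal,
        "warnings": warnings,
        "ok": not fatal,
    }


@dataclass(frozen=True)
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML."""

    convention: PositionConvention = field(default_factory=PositionConvention)
    m_config: SubModelConfig = field(default_factory=lambda: SubModelConfig(kind="M"))
    d_config: SubModelConfig = field(default_factory=lambda: SubModelConfig(kind="D"))
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics_threshold: float = 0.5
    analysis_alpha: float = 0.5

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "convention": asdict(self.convention),
            "m_config": asdict(self.m_config),
            "d_config": asdict(self.d_config),
            "train": asdict(self.train),
            "metrics_threshold": self.metrics_threshold,
            "analysis_alpha": self.analysis_alpha,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())

        def tup(d: dict, *keys: str) -> dict:
            return {k: (tuple(v) if k in keys and v is not None else v) for k, v in d.items()}

        return cls(
            convention=PositionConvention(**doc["convention"]),
            m_config=SubModelConfig(**tup(doc["m_config"], "conv_kernel_sizes", "head_sizes")),
            d_config=SubModelConfig(**tup(doc["d_config"], "conv_kernel_sizes", "head_sizes")),
            train=TrainConfig(**tup(doc["train"], "seeds")),
            metrics_threshold=float(doc["metrics_threshold"]),
            analysis_alpha=float(doc["analysis_alpha"]),
        )

    def digest(self) -> str:
        """Stable hash of the full configuration (for run logs)."""
        doc = json.dumps(
            {
                "convention": asdict(self.convention),
                "m_config": asdict(self.m_config),
                "d_config": asdict(self.d_config),
                "train": asdict(self.train),
                "metrics_threshold": self.metrics_threshold,
                "analysis_alpha": self.analysis_alpha,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(doc.encode()).hexdigest()[:16]
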