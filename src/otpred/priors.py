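"""Construction of the prior-informed embedding matrices.

Two literature-derived prior spaces initialize the trainable embedding
layers:

* **MTP** (mismatch tolerance profile): per-position, per-mismatch tolerance
  scores.  PAM rows, pad rows and match tokens carry no literature value and
  are filled with 1; mismatch entries absent from the table also default to 1.
* **DRICS** (DNA-RNA interaction contribution scores): per-position scores
  for all 16 pair types.  PAM and pad rows are filled with 0.  Because raw
  scores span an asymmetric range (matches mostly in (0, 0.6], mismatches in
  [-5.5, 0)), the matrix is normalized piecewise: nonnegative entries are
  divided by the raw maximum, negative entries by the magnitude of the raw
  minimum, mapping the two sign classes onto [0, 1] and [-1, 0] while
  preserving sign and within-class order.

Tables are 1-based in *biological* coordinates (position 1 = PAM-proximal);
the position convention maps them onto matrix rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import (
    MATCH_TOKENS,
    MISMATCH_TOKENS,
    TOKENS,
    PositionConvention,
    token_index,
)

__all__ = [
    "PriorTable",
    "PriorEmbedding",
    "load_prior_table",
    "build_mtp_init",
    "build_drics_init",
    "normalize_drics",
    "write_prior_table",
    "write_embedding",
    "read_embedding",
]


class PriorTableError(ValueError):
    """Malformed prior table (bad token/position, duplicate key, missing entry)."""


class NormalizationError(ValueError):
    """Degenerate or repeated normalization request."""


@dataclass(frozen=True)
class PriorTable:
    """Long-format prior values: (biological position 1-20, token, raw value)."""

    entries: tuple[tuple[int, str, float], ...]
    kind: str  # "MTP" | "DRICS"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("MTP", "DRICS"):
            raise PriorTableError(f"kind must be MTP or DRICS, got {self.kind!r}")
        seen: set[tuple[int, str]] = set()
        for pos, token, value in self.entries:
            if not 1 <= int(pos) <= 20:
                raise PriorTableError(f"position {pos} outside 1..20")
            if token not in TOKENS:
                raise PriorTableError(f"invalid token {token!r}")
            if (pos, token) in seen:
                raise PriorTableError(f"duplicate entry for position {pos}, token {token}")
            seen.add((pos, token))
            float(value)

    def as_dict(self) -> dict[tuple[int, str], float]:
        return {(int(p), t): float(v) for p, t, v in self.entries}


@dataclass(frozen=True)
class PriorEmbedding:
    """An L x 16 prior matrix plus the metadata needed to interpret it."""

    matrix: np.ndarray
    kind: str
    conv: PositionConvention
    normalized: bool = False
    v_max: float | None = None
    v_min: float | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.conv.L, 16):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != (L={self.conv.L}, 16)"
            )

    def value(self, bio_pos: int, token: str) -> float:
        """Entry at a biological guide position (1 = PAM-proximal)."""
        return float(self.matrix[self.conv.row_of_bio(bio_pos) - 1, token_index(token) - 1])


def load_prior_table(path: str | Path, kind: str) -> PriorTable:
    """Read a TSV prior table with header ``position  token  value``."""
    df = pd.read_csv(path, sep="\t", dtype={"position": str, "token": str, "value": str})
    required = ["position", "token", "value"]
    if list(df.columns)[:3] != required:
        raise PriorTableError(f"expected columns {required}, got {list(df.columns)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            pos = int(row.position)
            val = float(row.value)
        except ValueError as exc:
            raise PriorTableError(f"line {i}: unparsable position/value: {exc}") from None
        if row.token not in TOKENS:
            raise PriorTableError(f"line {i}: invalid token {row.token!r}")
        entries.append((pos, row.token, val))
    try:
        return PriorTable(entries=tuple(entries), kind=kind, provenance=str(path))
    except PriorTableError as exc:
        raise PriorTableError(f"{path}: {exc}") from None


def write_prior_table(table: PriorTable, path: str | Path) -> None:
    pd.DataFrame(table.entries, columns=["position", "token", "value"]).to_csv(
        path, sep="\t", index=False
    )


def build_mtp_init(
    table: PriorTable, conv: PositionConvention | None = None
) -> PriorEmbedding:
    """Build the initial MTP matrix.

    PAM and pad rows and match-token columns are 1 everywhere; known mismatch
    tolerances are copied from the table; mismatch entries missing from the
    table default to 1 (absent prior = fully tolerated).
    """
    conv = conv or PositionConvention()
    if table.kind != "MTP":
        raise PriorTableError(f"expected an MTP table, got kind={table.kind!r}")
    m = np.ones((conv.L, 16), dtype=np.float64)
    for (pos, token), value in table.as_dict().items():
        if token in MATCH_TOKENS:
            raise PriorTableError(
                f"MTP table must not assign match token {token} (position {pos})"
            )
        m[conv.row_of_bio(pos) - 1, token_index(token) - 1] = value
    return PriorEmbedding(matrix=m, kind="MTP", conv=conv)


def build_drics_init(
    table: PriorTable, conv: PositionConvention | None = None
) -> PriorEmbedding:
    """Build the initial (raw, unnormalized) DRICS matrix.

    PAM and pad rows are 0; every guide-row entry (all 16 tokens at all 20
    positions) must be present in the table.
    """
    conv = conv or PositionConvention()
    if table.kind != "DRICS":
        raise PriorTableError(f"expected a DRICS table, got kind={table.kind!r}")
    vals = table.as_dict()
    missing = [
        (pos, tok)
        for pos in range(1, 21)
        for tok in TOKENS
        if (pos, tok) not in vals
    ]
    if missing:
        raise PriorTableError(
            f"DRICS table incomplete: {len(missing)} missing entries, first {missing[0]}"
        )
    m = np.zeros((conv.L, 16), dtype=np.float64)
    for (pos, token), value in vals.items():
        m[conv.row_of_bio(pos) - 1, token_index(token) - 1] = value
    return PriorEmbedding(matrix=m, kind="DRICS", conv=conv)


def normalize_drics(emb: PriorEmbedding) -> PriorEmbedding:
    """Piecewise-normalize a raw DRICS matrix onto [-1, 1].

    Nonnegative entries are divided by ``v_max`` and negative entries by
    ``|v_min|``, where the extrema are scanned over guide rows only (the
    constant PAM/pad fill is not a score).  Requires raw entries of both
    signs; re-normalizing an already-normalized matrix is an error.
    """
    if emb.kind != "DRICS":
        raise NormalizationError("only DRICS embeddings are normalized")
    if emb.normalized:
        raise NormalizationError("embedding is already normalized")
    guide_idx = np.array(emb.conv.guide_rows) - 1
    raw = emb.matrix[guide_idx]
    v_max = float(raw.max())
    v_min = float(raw.min())
    if v_max <= 0 or v_min >= 0:
        raise NormalizationError(
            f"degenerate raw range [{v_min}, {v_max}]: both signs are required"
        )
    out = np.where(emb.matrix >= 0, emb.matrix / v_max, emb.matrix / abs(v_min))
    return replace(emb, matrix=out, normalized=True, v_max=v_max, v_min=v_min)


def write_embedding(emb: PriorEmbedding, outdir: str | Path, stem: str) -> None:
    """Write an embedding as a labelled TSV matrix plus a JSON side-car."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conv = emb.conv
    labels = []
    for row in range(1, conv.L + 1):
        if row in conv.guide_rows:
            labels.append(f"row_{row}/bio_{conv.bio_pos(row)}")
        elif row in conv.pam_rows:
            labels.append(f"row_{row}/pam")
        else:
            labels.append(f"row_{row}/pad")
    pd.DataFrame(emb.matrix, index=labels, columns=list(TOKENS)).to_csv(
        outdir / f"{stem}.tsv", sep="\t", index_label="row"
    )
    meta = {
        "kind": emb.kind,
        "L": conv.L,
        "n_pad": conv.n_pad,
        "n_pam": conv.n_pam,
        "pad_token": conv.pad_token,
        "normalized": emb.normalized,
        "v_max": emb.v_max,
        "v_min": emb.v_min,
    }
    (outdir / f"{stem}.meta.json").write_text(json.dumps(meta, indent=2))


def read_embedding(outdir: str | Path, stem: str) -> PriorEmbedding:
    """Inverse of :func:`write_embedding`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}.meta.json").read_text())
    df = pd.read_csv(outdir / f"{stem}.tsv", sep="\t", index_col=0)
    conv = PositionConvention(
        L=meta["L"], n_pad=meta["n_pad"], n_pam=meta["n_pam"], pad_token=meta["pad_token"]
    )
    return PriorEmbedding(
        matrix=df.to_numpy(dtype=np.float64),
        kind=meta["kind"],
        conv=conv,
        normalized=meta["normalized"],
        v_max=meta["v_max"],
        v_min=meta["v_min"],
    )
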