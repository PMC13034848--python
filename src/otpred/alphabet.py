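"""Base-pair alphabet and guide/target pair encoding.

A guide RNA aligned against a protospacer-strand DNA site is described, per
position, by a two-letter base-pair token: the first letter is the guide base
(written in DNA letters, T standing for U) and the second the DNA base.  The
16 tokens over {A,C,G,T} are kept in lexicographic order, which fixes the
column index of every token in the position-by-pair embedding matrices.

Four tokens (AA, CC, GG, TT) are Watson-Crick matches; the 12 remaining
tokens are mismatches, grouped by their guide base into rA, rG, rC and rT
(so e.g. TC is the rU-dG wobble and GA the rG-dT wobble).

The row layout of the length-``L`` encoding (default ``L = 24``) is carried
by :class:`PositionConvention`: one 5' pad row, the 20 protospacer rows, and
three PAM rows.  Biological coordinates run PAM-proximal first (position 1 is
adjacent to the PAM, positions 1-10 are the seed region), which is the
opposite direction to the 5'->3' row order; ``bio_map`` converts between the
two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "TOKENS",
    "MATCH_TOKENS",
    "MISMATCH_TOKENS",
    "MISMATCH_GROUPS",
    "PairAlphabet",
    "GuideTargetPair",
    "EncodedPair",
    "PositionConvention",
    "pair_token",
    "token_index",
    "mismatch_group",
    "encode_pair",
    "decode_pair",
]

_BASES = "ACGT"

#: the 16 base-pair tokens in canonical (lexicographic) order
TOKENS: tuple[str, ...] = tuple(a + b for a, b in product(_BASES, _BASES))

MATCH_TOKENS: frozenset[str] = frozenset({"AA", "CC", "GG", "TT"})
MISMATCH_TOKENS: tuple[str, ...] = tuple(t for t in TOKENS if t not in MATCH_TOKENS)

#: mismatch tokens grouped by guide base (rN = guide base N)
MISMATCH_GROUPS: dict[str, tuple[str, str, str]] = {
    "rA": ("AC", "AG", "AT"),
    "rC": ("CA", "CG", "CT"),
    "rG": ("GA", "GC", "GT"),
    "rT": ("TA", "TC", "TG"),
}

_TOKEN_INDEX = {t: i for i, t in enumerate(TOKENS)}


class InvalidBaseError(ValueError):
    """A nucleotide outside {A, C, G, T} (or an unresolvable N)."""


class LengthError(ValueError):
    """Sequence length incompatible with the position convention."""


class NotAMismatchError(ValueError):
    """A match token was passed where a mismatch token is required."""


@dataclass(frozen=True)
class PairAlphabet:
    """The 16-token base-pair alphabet with its match/mismatch structure."""

    tokens: tuple[str, ...] = TOKENS
    match_set: frozenset[str] = MATCH_TOKENS
    mismatch_groups: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: dict(MISMATCH_GROUPS)
    )

    def index(self, token: str) -> int:
        """1-based canonical column index of *token*."""
        return _TOKEN_INDEX[token] + 1


@dataclass(frozen=True)
class GuideTargetPair:
    """One aligned sgRNA / putative off-target site with its binary label."""

    sgrna_id: str
    guide_seq: str
    target_seq: str
    label: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if len(self.guide_seq) != len(self.target_seq):
            raise LengthError(
                f"guide ({len(self.guide_seq)} nt) and target "
                f"({len(self.target_seq)} nt) differ in length"
            )
        for seq in (self.guide_seq, self.target_seq):
            bad = set(seq) - set("ACGTN")
            if bad:
                raise InvalidBaseError(f"invalid base(s) {sorted(bad)} in {seq!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class EncodedPair:
    """Row/column index form of one pair: rows 1..L, cols 1..16."""

    rows: np.ndarray
    cols: np.ndarray
    L: int

    def __post_init__(self) -> None:
        if len(self.rows) != self.L or len(self.cols) != self.L:
            raise LengthError("rows/cols length must equal L")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(TOKENS[c - 1] for c in self.cols)


def pair_token(guide_base: str, target_base: str) -> str:
    """Two-letter token for one position, guide base first.

    Parameters
    ----------
    guide_base, target_base : str
        Single characters in {A, C, G, T}.
    """
    if guide_base not in _BASES or target_base not in _BASES:
        raise InvalidBaseError(
            f"bases must be one of A/C/G/T, got ({guide_base!r}, {target_base!r})"
        )
    return guide_base + target_base


def token_index(token: str) -> int:
    """1-based canonical column index of *token* (AA=1 ... TT=16)."""
    try:
        return _TOKEN_INDEX[token] + 1
    except KeyError:
        raise InvalidBaseError(f"unknown token {token!r}") from None


def mismatch_group(token: str) -> str:
    """Group key (rA/rC/rG/rT, by guide base) of a mismatch token."""
    if token in MATCH_TOKENS:
        raise NotAMismatchError(f"{token!r} is a match token, not a mismatch")
    if token not in _TOKEN_INDEX:
        raise InvalidBaseError(f"unknown token {token!r}")
    return "r" + token[0]


@dataclass(frozen=True)
class PositionConvention:
    """Row layout of the L-position encoding and its biological coordinates.

    Default layout for ``L = 24`` (5'->3'): row 1 is a pad row, rows 2-21 the
    20 protospacer positions, rows 22-24 the PAM.  Biological position 1 is
    PAM-proximal, i.e. row 21; positions 1-10 form the seed region.
    """

    L: int = 24
    n_pad: int = 1
    n_guide: int = 20
    n_pam: int = 3
    pad_token: str = "AA"

    def __post_init__(self) -> None:
        if self.n_guide != 20:
            raise ValueError("the guide region must span 20 positions")
        if self.n_pad + self.n_guide + self.n_pam != self.L:
            raise ValueError("pad + guide + PAM rows must partition 1..L")
        if self.pad_token not in MATCH_TOKENS:
            raise ValueError("pad token must be a match token")

    @property
    def pad_rows(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_pad + 1))

    @property
    def guide_rows(self) -> tuple[int, ...]:
        return tuple(range(self.n_pad + 1, self.n_pad + self.n_guide + 1))

    @property
    def pam_rows(self) -> tuple[int, ...]:
        return tuple(range(self.n_pad + self.n_guide + 1, self.L + 1))

    def bio_pos(self, row: int) -> int:
        """Biological position (1 = PAM-proximal) of a guide row."""
        if row not in self.guide_rows:
            raise ValueError(f"row {row} is not a guide row")
        # guide rows run 5'->3'; biological numbering runs 3'->5' of the guide
        return self.n_pad + self.n_guide + 1 - row

    def row_of_bio(self, bio: int) -> int:
        """Guide row holding biological position *bio* (1-20)."""
        if not 1 <= bio <= self.n_guide:
            raise ValueError(f"biological position must be 1..{self.n_guide}")
        return self.n_pad + self.n_guide + 1 - bio

    def bio_of_guide_rows(self) -> np.ndarray:
        """Vector of biological positions for guide rows in row order."""
        return np.array([self.bio_pos(r) for r in self.guide_rows])


def _resolve(guide_base: str, target_base: str, row: int, conv: PositionConvention) -> str:
    """Token for one row; N is resolved only on pad/PAM rows (as a match of
    the observed partner base), since those rows carry constant prior values."""
    if guide_base in _BASES and target_base in _BASES:
        return pair_token(guide_base, target_base)
    if row in conv.guide_rows:
        raise InvalidBaseError(
            f"ambiguous base N at guide row {row}; guide-region bases must be A/C/G/T"
        )
    known = target_base if target_base in _BASES else guide_base
    if known not in _BASES:
        return conv.pad_token
    return known + known


def encode_pair(pair: GuideTargetPair, conv: PositionConvention | None = None) -> EncodedPair:
    """Encode an aligned pair into (row, column) index sequences.

    Sequences of length ``L`` are encoded directly.  Sequences of length
    ``L - n_pad`` are left-padded with the convention's pad token (a matched,
    information-free context row).  Any other length is an error.
    """
    conv = conv or PositionConvention()
    n = len(pair.guide_seq)
    if n == conv.L:
        guide, target = pair.guide_seq, pair.target_seq
        pad_cols: list[int] = []
        start_row = 1
    elif n == conv.L - conv.n_pad:
        guide, target = pair.guide_seq, pair.target_seq
        pad_cols = [token_index(conv.pad_token)] * conv.n_pad
        start_row = conv.n_pad + 1
    else:
        raise LengthError(
            f"sequence length {n} is neither L={conv.L} nor L-n_pad={conv.L - conv.n_pad}"
        )
    cols = pad_cols + [
        token_index(_resolve(g, t, start_row + i, conv))
        for i, (g, t) in enumerate(zip(guide, target))
    ]
    return EncodedPair(
        rows=np.arange(1, conv.L + 1), cols=np.asarray(cols, dtype=np.int64), L=conv.L
    )


def decode_pair(enc: EncodedPair) -> tuple[str, str]:
    """Recover the (guide, target) length-L sequences from an encoding."""
    toks = enc.tokens
    return "".join(t[0] for t in toks), "".join(t[1] for t in toks)
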