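"""Projection scoring of texts and the dictionary-ratio baseline.

The projection score of a text is the dot product of its mean token
vector with a construct's unit axis.  All cleaned tokens count in the
averaging denominator: out-of-vocabulary tokens contribute zero vectors,
pulling sparse texts toward the neutral point rather than inflating
their scores.  The closed-vocabulary baseline scores a text by the
normalized difference of positive and negative anchor hits; it covers
only texts containing at least one anchor word, which is exactly the
coverage gap projection scoring is designed to close.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axes import AnchorSet, ConstructAxis
from .corpus import UserWeekText
from .embeddings import EmbeddingSpace

__all__ = [
    "ProjectionScore",
    "DictionaryScore",
    "text_vector",
    "wepa_score",
    "self_efficacy_composite",
    "dictionary_score",
    "coverage",
    "score_user_weeks",
]


@dataclass(frozen=True)
class ProjectionScore:
    user_id: str
    week_index: int
    construct: str
    wepa_score: float  # NaN when missing
    n_tokens: int
    n_invocab: int

    @property
    def missing(self) -> bool:
        return self.n_tokens == 0


@dataclass(frozen=True)
class DictionaryScore:
    pos_hits: int
    neg_hits: int

    @property
    def dict_score(self) -> float:
        return (self.pos_hits - self.neg_hits) / (self.pos_hits + self.neg_hits + 1)

    @property
    def covered(self) -> bool:
        return self.pos_hits + self.neg_hits > 0


def text_vector(tokens: list[str], space: EmbeddingSpace) -> np.ndarray | None:
    """Mean embedding over ALL tokens; OOV tokens add zero vectors but stay
    in the denominator.  Returns None (missing) only for an empty list."""
    if not tokens:
        return None
    mat, _ = space.embed_many(tokens)
    return mat.sum(axis=0) / len(tokens)


def wepa_score(text_vec: np.ndarray, axis: ConstructAxis) -> float:
    """Scalar projection of a text vector onto the construct axis.

    Positive values indicate language closer to the positive pole.
    """
    text_vec = np.asarray(text_vec, dtype=float)
    if text_vec.shape[0] != axis.dimension:
        raise ValueError(
            f"text vector has dimension {text_vec.shape[0]}, axis {axis.dimension}"
        )
    return float(text_vec @ axis.axis_vec)


def self_efficacy_composite(
    mast: float, vic: float, soc: float, phy: float
) -> float:
    """Overall self-efficacy: sum of the four source-dimension scores.

    Missing (NaN) in any dimension makes the composite missing.
    """
    parts = np.array([mast, vic, soc, phy], dtype=float)
    if np.isnan(parts).any():
        return float("nan")
    return float(parts.sum())


def dictionary_score(
    tokens: list[str], anchors_pos: AnchorSet, anchors_neg: AnchorSet
) -> DictionaryScore:
    """Anchor-hit ratio score; hits are distinct word TYPES present in
    both the text and the anchor set (token multiplicity ignored)."""
    if set(anchors_pos.words) & set(anchors_neg.words):
        raise ValueError("anchor pole sets must be disjoint")
    types = set(tokens)
    return DictionaryScore(
        pos_hits=len(types & set(anchors_pos.words)),
        neg_hits=len(types & set(anchors_neg.words)),
    )


def coverage(flags) -> float:
    """Percent of texts with a non-missing/covered score."""
    flags = list(flags)
    if not flags:
        raise ValueError("coverage of an empty sequence is undefined")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def score_user_weeks(
    records: list[UserWeekText],
    axes: dict[str, ConstructAxis],
    space: EmbeddingSpace,
    anchors: dict[str, tuple[AnchorSet, AnchorSet]] | None = None,
) -> pd.DataFrame:
    """Score every user-week on every construct axis.

    Returns one row per (user, week, construct) with the projection score
    and, when ``anchors`` is given, the dictionary baseline and its
    coverage flag.
    """
    rows = []
    for r in records:
        vec = text_vector(r.tokens, space)
        if vec is None:
            n_invocab = 0
        else:
            _, mask = space.embed_many(r.tokens)
            n_invocab = int(mask.sum())
        for name, axis in axes.items():
            row = {
                "user_id": r.user_id,
                "week_index": r.week_index,
                "construct": name,
                "wepa_score": float("nan") if vec is None else wepa_score(vec, axis),
                "n_tokens": len(r.tokens),
                "n_invocab": n_invocab,
                "valid_str_len": r.valid_str_len,
                "str_len": r.str_len,
            }
            if anchors is not None and name in anchors:
                ds = dictionary_score(r.tokens, *anchors[name])
                row["dict_score"] = ds.dict_score
                row["covered"] = ds.covered
            rows.append(row)
    return pd.DataFrame(rows)
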