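"""Bipolar construct axes from anchor words.

A construct (e.g. goal commitment) is represented by two opposed anchor
sets.  Each pole's prototype is the mean of its anchors' vectors; the
unit-normalized difference (positive minus negative prototype) is the
semantic axis onto which text vectors are projected.  Anchors are
screened against the vocabulary once, at build time; axes are immutable
thereafter so scores stay comparable across samples and time.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSpace, cosine

__all__ = [
    "AnchorSet",
    "ConstructAxis",
    "PoleDiagnostics",
    "EmptyPoleError",
    "read_anchor_file",
    "screen_anchors",
    "prototype",
    "build_axis",
    "make_axis",
    "pole_diagnostics",
]


class EmptyPoleError(ValueError):
    """A pole has no in-vocabulary anchor words left."""


@dataclass(frozen=True)
class AnchorSet:
    """Anchor words for one pole of one construct."""

    construct: str
    pole: str  # "pos" or "neg"
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pole not in ("pos", "neg"):
            raise ValueError(f"pole must be 'pos' or 'neg', got {self.pole!r}")
        if not self.words:
            raise ValueError(f"empty anchor set for {self.construct}/{self.pole}")
        if len(set(self.words)) != len(self.words):
            raise ValueError(f"duplicate anchor words in {self.construct}/{self.pole}")


@dataclass(frozen=True)
class ConstructAxis:
    construct: str
    anchors_pos: AnchorSet
    anchors_neg: AnchorSet
    proto_pos: np.ndarray
    proto_neg: np.ndarray
    axis_vec: np.ndarray

    @property
    def dimension(self) -> int:
        return self.axis_vec.shape[0]


@dataclass(frozen=True)
class PoleDiagnostics:
    """Mean pairwise cosines within and between poles.

    ``within_*`` are means over unordered same-pole pairs (self-pairs
    excluded, so a single-word pole yields NaN); ``between`` is the mean
    over all cross-pole pairs.  ``passes`` is true when both within-pole
    means exceed the between-pole mean — the expected bipolar separation.
    """

    within_pos: float
    within_neg: float
    between: float

    @property
    def passes(self) -> bool:
        return bool(
            np.isfinite(self.within_pos)
            and np.isfinite(self.within_neg)
            and self.within_pos > self.between
            and self.within_neg > self.between
        )


def read_anchor_file(path: str | Path) -> list[AnchorSet]:
    """Read anchor dictionaries from CSV (construct,pole,word) or JSON
    ({construct: {"pos": [...], "neg": [...]}})."""
    path = Path(path)
    grouped: dict[tuple[str, str], list[str]] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        for construct, poles in data.items():
            for pole, words in poles.items():
                grouped[(construct, pole)] = list(words)
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                grouped.setdefault((row["construct"], row["pole"]), []).append(
                    row["word"]
                )
    sets = [
        AnchorSet(construct=c, pole=p, words=tuple(words))
        for (c, p), words in grouped.items()
    ]
    by_construct: dict[str, dict[str, AnchorSet]] = {}
    for s in sets:
        by_construct.setdefault(s.construct, {})[s.pole] = s
    for construct, poles in by_construct.items():
        if "pos" in poles and "neg" in poles:
            overlap = set(poles["pos"].words) & set(poles["neg"].words)
            if overlap:
                raise ValueError(
                    f"anchors shared between poles of {construct}: {sorted(overlap)}"
                )
    return sets


def screen_anchors(
    candidates: list[AnchorSet], space: EmbeddingSpace
) -> tuple[list[AnchorSet], pd.DataFrame]:
    """Drop out-of-vocabulary anchor words; error if a pole empties.

    Returns the retained sets plus a report of dropped words per
    construct/pole.
    """
    retained = []
    rows = []
    for s in candidates:
        kept = tuple(w for w in s.words if w in space)
        dropped = [w for w in s.words if w not in space]
        rows.append(
            {
                "construct": s.construct,
                "pole": s.pole,
                "n_candidates": len(s.words),
                "n_retained": len(kept),
                "dropped": ";".join(dropped),
            }
        )
        if not kept:
            raise EmptyPoleError(
                f"all anchors of {s.construct}/{s.pole} are out of vocabulary"
            )
        retained.append(AnchorSet(s.construct, s.pole, kept))
    return retained, pd.DataFrame(rows)


def prototype(anchors: AnchorSet, space: EmbeddingSpace) -> np.ndarray:
    """Pole centroid: arithmetic mean of the anchor vectors.

    Anchors must already be screened; an OOV anchor here is an error, not
    a silent zero.
    """
    vecs = []
    for w in anchors.words:
        v, ok = space.embed(w)
        if not ok:
            raise KeyError(
                f"anchor {w!r} of {anchors.construct}/{anchors.pole} "
                "is out of vocabulary; screen anchors first"
            )
        vecs.append(v)
    return np.mean(vecs, axis=0)


def build_axis(proto_pos: np.ndarray, proto_neg: np.ndarray) -> np.ndarray:
    """Unit vector from the negative to the positive prototype."""
    diff = np.asarray(proto_pos, dtype=float) - np.asarray(proto_neg, dtype=float)
    norm = np.linalg.norm(diff)
    if norm == 0.0:
        raise ValueError("identical pole prototypes: axis direction undefined")
    return diff / norm


def make_axis(
    construct: str,
    anchors_pos: AnchorSet,
    anchors_neg: AnchorSet,
    space: EmbeddingSpace,
) -> ConstructAxis:
    """Screen both poles against ``space`` and build the construct axis."""
    screened, _ = screen_anchors([anchors_pos, anchors_neg], space)
    pos, neg = screened
    proto_pos = prototype(pos, space)
    proto_neg = prototype(neg, space)
    return ConstructAxis(
        construct=construct,
        anchors_pos=pos,
        anchors_neg=neg,
        proto_pos=proto_pos,
        proto_neg=proto_neg,
        axis_vec=build_axis(proto_pos, proto_neg),
    )


def pole_diagnostics(
    anchors_pos: AnchorSet, anchors_neg: AnchorSet, space: EmbeddingSpace
) -> PoleDiagnostics:
    """Average cosine similarity within each pole and between poles."""

    def vecs(s: AnchorSet) -> list[np.ndarray]:
        out = []
        for w in s.words:
            v, ok = space.embed(w)
            if not ok:
                raise KeyError(f"anchor {w!r} is out of vocabulary; screen first")
            out.append(v)
        return out

    pos_vecs = vecs(anchors_pos)
    neg_vecs = vecs(anchors_neg)

    def mean_within(vs: list[np.ndarray]) -> float:
        pairs = [cosine(u, v) for u, v in combinations(vs, 2)]
        return float(np.mean(pairs)) if pairs else float("nan")

    between = float(
        np.mean([cosine(u, v) for u, v in product(pos_vecs, neg_vecs)])
    )
    return PoleDiagnostics(
        within_pos=mean_within(pos_vecs),
        within_neg=mean_within(neg_vecs),
        between=between,
    )
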