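"""Cross-temporal stability of construct axes.

Period-specific embedding spaces are estimated independently, so their
coordinate systems differ by an arbitrary rotation.  Orthogonal
Procrustes alignment (rotation + reflection, no scaling or translation)
maps each period space onto a reference space over their shared
vocabulary, after which two indicators are meaningful: the cosine
between the period axis and the reference axis (axis orientation), and
the Spearman correlation of anchor-word projections (rank-order
consistency of the internal semantic structure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .axes import AnchorSet, ConstructAxis, make_axis
from .embeddings import EmbeddingSpace, cosine

__all__ = [
    "AlignmentResult",
    "orthogonal_procrustes",
    "axis_stability",
    "anchor_rank_consistency",
    "stability_report",
]


@dataclass
class AlignmentResult:
    rotation: np.ndarray          # d x d orthogonal
    shared_vocab: list[str]
    residual: float               # Frobenius norm of post-alignment mismatch
    aligned_space: EmbeddingSpace


def default_shared_vocab(
    source: EmbeddingSpace, reference: EmbeddingSpace, top_n: int = 5000
) -> list[str]:
    """Intersection of vocabularies restricted to the first ``top_n``
    reference tokens (vocabulary order proxies frequency order)."""
    src = set(source.tokens)
    return [t for t in reference.tokens[:top_n] if t in src]


def orthogonal_procrustes(
    source: EmbeddingSpace,
    reference: EmbeddingSpace,
    shared_vocab: list[str] | None = None,
    top_n: int = 5000,
) -> AlignmentResult:
    """Fit the orthogonal map R minimizing ||source @ R - reference||_F
    over the shared vocabulary and return the fully rotated source space.

    Solved by SVD of the cross-covariance (scipy's closed form).  Fewer
    shared tokens than dimensions leaves the rotation ill-conditioned and
    triggers a warning.
    """
    if shared_vocab is None:
        shared_vocab = default_shared_vocab(source, reference, top_n)
    if not shared_vocab:
        raise ValueError("shared vocabulary is empty; cannot align")
    missing = [t for t in shared_vocab if t not in source or t not in reference]
    if missing:
        raise KeyError(f"shared tokens absent from a space: {missing[:5]}")
    d = source.dimension
    if reference.dimension != d:
        raise ValueError("spaces differ in dimension")
    if len(shared_vocab) < d:
        warnings.warn(
            f"only {len(shared_vocab)} shared tokens for dimension {d}; "
            "alignment may be ill-conditioned",
            stacklevel=2,
        )
    A = np.array([source.embed(t)[0] for t in shared_vocab])
    B = np.array([reference.embed(t)[0] for t in shared_vocab])
    R, _ = scipy.linalg.orthogonal_procrustes(A, B)
    residual = float(np.linalg.norm(A @ R - B))
    aligned = EmbeddingSpace(
        tokens=list(source.tokens),
        vectors=source.vectors @ R,
        source_tag=f"{source.source_tag}|aligned",
    )
    return AlignmentResult(
        rotation=R, shared_vocab=list(shared_vocab), residual=residual,
        aligned_space=aligned,
    )


def axis_stability(
    period_space_aligned: EmbeddingSpace,
    reference_space: EmbeddingSpace,
    anchors_pos: AnchorSet,
    anchors_neg: AnchorSet,
) -> float:
    """Cosine between the construct axis built in the aligned period space
    and the axis built in the reference space.  Anchors are screened per
    space (an anchor missing from one period drops from that axis)."""
    axis_period = make_axis(
        anchors_pos.construct, anchors_pos, anchors_neg, period_space_aligned
    )
    axis_ref = make_axis(
        anchors_pos.construct, anchors_pos, anchors_neg, reference_space
    )
    return cosine(axis_period.axis_vec, axis_ref.axis_vec)


def anchor_rank_consistency(
    anchors: list[str],
    period_space_aligned: EmbeddingSpace,
    reference_space: EmbeddingSpace,
    reference_axis: ConstructAxis,
    period_axis: ConstructAxis | None = None,
) -> float:
    """Spearman correlation of anchor projections on the construct axis
    between the two spaces; ties get average ranks.

    Only anchors present in both vocabularies enter; fewer than 3 common
    anchors is an error.  When ``period_axis`` is omitted the reference
    axis direction is used in both spaces (valid after alignment).
    """
    common = [
        t for t in anchors if t in period_space_aligned and t in reference_space
    ]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 anchors in both vocabularies, have {len(common)}"
        )
    ax_p = period_axis.axis_vec if period_axis is not None else reference_axis.axis_vec
    proj_period = [period_space_aligned.embed(t)[0] @ ax_p for t in common]
    proj_ref = [reference_space.embed(t)[0] @ reference_axis.axis_vec for t in common]
    rho = scipy.stats.spearmanr(proj_period, proj_ref).statistic
    return float(rho)


def stability_report(
    period_spaces: dict[str, EmbeddingSpace],
    reference: EmbeddingSpace,
    anchor_pairs: dict[str, tuple[AnchorSet, AnchorSet]],
    shared_vocab: list[str] | None = None,
    top_n: int = 5000,
) -> pd.DataFrame:
    """Align each period space to the reference and compute per
    (construct, period) axis-cosine and anchor rank-order consistency."""
    rows = []
    for period, space in period_spaces.items():
        aligned = orthogonal_procrustes(space, reference, shared_vocab, top_n)
        for construct, (pos, neg) in anchor_pairs.items():
            ref_axis = make_axis(construct, pos, neg, reference)
            per_axis = make_axis(construct, pos, neg, aligned.aligned_space)
            all_anchors = list(pos.words) + list(neg.words)
            used = [
                t for t in all_anchors
                if t in aligned.aligned_space and t in reference
            ]
            rows.append(
                {
                    "construct": construct,
                    "period": period,
                    "axis_cosine": cosine(per_axis.axis_vec, ref_axis.axis_vec),
                    "anchor_rank_rho": anchor_rank_consistency(
                        all_anchors, aligned.aligned_space, reference,
                        ref_axis, per_axis,
                    ),
                    "n_anchors_used": len(used),
                }
            )
    return pd.DataFrame(rows)
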