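"""Synthetic study fixtures with planted ground truth.

Real platform corpora and their embeddings cannot be redistributed, so
every stage of the pipeline is exercised on generated data in the same
formats: an embedding space with planted bipolar construct directions,
anchor dictionaries, a user-week post stream whose positive/negative
anchor-token mixture encodes a latent construct intensity, and a
next-week behavioral outcome that is an individual fixed effect plus a
linear construct effect plus noise.  Because the latent states, effect
sizes, and individual effects are returned alongside the observable
data, parameter-recovery and attenuation properties can be checked
exactly.

All randomness flows from a single spec seed, split into independent
child streams per sub-generator, so adding a generator never perturbs
existing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import AnchorSet
from .corpus import RawPost
from .embeddings import EmbeddingSpace, save_embedding_space

__all__ = [
    "ConstructSpec",
    "SyntheticSpec",
    "make_space",
    "make_panel",
    "make_benchmark",
    "make_numeric_panel",
    "make_eiv_rows",
    "write_fixture_bundle",
]

_EPOCH = datetime(2020, 1, 6)  # synthetic registration date (a Monday)


@dataclass(frozen=True)
class ConstructSpec:
    name: str
    n_pos_anchors: int = 8
    n_neg_anchors: int = 8
    n_pole_neighbors: int = 20     # construct-related words NOT in the dictionaries
    pole_separation: float = 3.0   # distance between pole centers
    within_pole_sd: float = 0.5    # anchor scatter around its pole center
    true_beta: float = 0.5         # effect of latent z on next-week outcome


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int                      # mandatory; no unseeded generation
    dimension: int = 50
    vocab_size: int = 500
    constructs: tuple[ConstructSpec, ...] = (ConstructSpec("goal_commit"),)
    n_users: int = 300
    n_weeks: int = 8
    token_count_range: tuple[int, int] = (10, 40)
    signal_strength: float = 0.6   # share of tokens drawn from anchor sets
    oov_rate: float = 0.05         # share of tokens replaced by OOV strings
    fixed_effect_sd: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.dimension < 2 or self.vocab_size < 1:
            raise ValueError("dimension and vocab_size must be positive")
        total_anchors = sum(
            c.n_pos_anchors + c.n_neg_anchors + 2 * c.n_pole_neighbors
            for c in self.constructs
        )
        if self.vocab_size < total_anchors:
            raise ValueError(
                f"vocab_size {self.vocab_size} below total anchor and "
                f"pole-neighbor count {total_anchors}"
            )
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        lo, hi = self.token_count_range
        if lo < 1 or hi < lo:
            raise ValueError("infeasible token_count_range")
        if any(c.pole_separation < 0 for c in self.constructs):
            raise ValueError("pole_separation must be nonnegative")


def _streams(spec: SyntheticSpec) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(3)
    names = ("space", "panel", "benchmark")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def make_space(spec: SyntheticSpec) -> tuple[EmbeddingSpace, list[AnchorSet]]:
    """Embedding space with one planted bipolar direction per construct.

    Positive anchors scatter around +(delta/2) e_c and negative anchors
    around -(delta/2) e_c with isotropic sd sigma_a; the construct
    directions e_c are mutually orthogonal; filler tokens are isotropic
    about the origin.  Each pole additionally gets ``n_pole_neighbors``
    tokens drawn from the same pole distribution but NOT listed in the
    anchor dictionaries — construct-related community vocabulary that a
    closed word list misses while projection scoring still reads it.
    """
    rng = _streams(spec)["space"]
    d = spec.dimension
    n_constructs = len(spec.constructs)
    raw = rng.normal(size=(d, n_constructs))
    q, _ = np.linalg.qr(raw)
    directions = {c.name: q[:, i] for i, c in enumerate(spec.constructs)}

    tokens: list[str] = []
    vectors: list[np.ndarray] = []
    anchor_sets: list[AnchorSet] = []
    for c in spec.constructs:
        e = directions[c.name]
        for pole, n_words, sign in (("pos", c.n_pos_anchors, 1.0),
                                    ("neg", c.n_neg_anchors, -1.0)):
            words = []
            center = sign * (c.pole_separation / 2.0) * e
            for i in range(n_words):
                w = f"{c.name}_{pole}{i:02d}"
                words.append(w)
                tokens.append(w)
                vectors.append(center + rng.normal(0, c.within_pole_sd, size=d))
            anchor_sets.append(AnchorSet(c.name, pole, tuple(words)))
            for i in range(c.n_pole_neighbors):
                tokens.append(f"{c.name}_{pole}nb{i:02d}")
                vectors.append(center + rng.normal(0, c.within_pole_sd, size=d))
    n_filler = spec.vocab_size - len(tokens)
    for i in range(n_filler):
        tokens.append(f"filler{i:04d}")
        vectors.append(rng.normal(0, 1.0, size=d))
    space = EmbeddingSpace(tokens, np.array(vectors), source_tag=f"synthetic-seed{spec.seed}")
    return space, anchor_sets


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_panel(
    spec: SyntheticSpec,
    space: EmbeddingSpace,
    anchors: list[AnchorSet],
) -> tuple[list[RawPost], pd.DataFrame, pd.DataFrame]:
    """Posts, behavioral panel, and hidden truth.

    Latent z[c, i, t] ~ N(0, 1) drives the token mixture: a token is an
    anchor with probability ``signal_strength`` (positive-pole with
    probability sigmoid(z), negative otherwise), a filler token from the
    remaining vocabulary else; a slice of tokens is replaced by
    out-of-vocabulary strings.  The outcome follows the panel model

        ex_dur[i, t] = alpha_i + sum_c beta_c * z[c, i, t-1] + noise,

    so regressing next week's outcome on this week's score targets
    beta_c.  Returns (posts, panel, truth); ``panel`` holds user_id,
    week_index and ex_dur; ``truth`` additionally holds alpha and every
    latent z.
    """
    rng = _streams(spec)["panel"]
    constructs = [c for c in spec.constructs]
    # pole pools = anchors plus unlisted pole neighbors (prefix convention)
    by_pole = {
        (c.name, p): [t for t in space.tokens if t.startswith(f"{c.name}_{p}")]
        for c in constructs
        for p in ("pos", "neg")
    }
    pole_tokens = {t for pool in by_pole.values() for t in pool}
    fillers = [t for t in space.tokens if t not in pole_tokens]
    lo, hi = spec.token_count_range

    def draw_tokens(n_tokens: int, z: dict[str, float]) -> list[str]:
        """Mixture draw: anchor tokens with prob signal_strength (pole
        weighted by sigmoid(z)), fillers otherwise; an oov_rate slice is
        replaced by out-of-vocabulary strings."""
        is_anchor = rng.random(n_tokens) < spec.signal_strength
        c_idx = rng.integers(len(constructs), size=n_tokens)
        pole_u = rng.random(n_tokens)
        pool_pick = rng.random(n_tokens)
        toks = []
        for j in range(n_tokens):
            if constructs and is_anchor[j]:
                c = constructs[int(c_idx[j])]
                pole = "pos" if pole_u[j] < _sigmoid(z[c.name]) else "neg"
                pool = by_pole[(c.name, pole)]
            else:
                pool = fillers
            toks.append(pool[int(pool_pick[j] * len(pool))])
        n_oov = int(np.round(spec.oov_rate * n_tokens))
        if n_oov:
            for j in rng.choice(n_tokens, size=n_oov, replace=False):
                toks[j] = f"oov{rng.integers(10**6):06d}x"
        return toks

    posts: list[RawPost] = []
    panel_rows = []
    truth_rows = []
    for u in range(spec.n_users):
        user_id = f"u{u:05d}"
        alpha = rng.normal(0, spec.fixed_effect_sd)
        z_prev = {c.name: rng.normal() for c in constructs}
        for t in range(spec.n_weeks):
            z = {c.name: rng.normal() for c in constructs}
            n_tokens = int(rng.integers(lo, hi + 1))
            toks = draw_tokens(n_tokens, z)
            ts = _EPOCH + timedelta(days=7 * t + 1)
            posts.append(RawPost(user_id=user_id, timestamp=ts, text=" ".join(toks)))
            ex_dur = (
                alpha
                + sum(c.true_beta * z_prev[c.name] for c in constructs)
                + rng.normal(0, spec.noise_sd)
            )
            panel_rows.append(
                {"user_id": user_id, "week_index": t, "ex_dur": ex_dur}
            )
            truth_rows.append(
                {"user_id": user_id, "week_index": t, "alpha": alpha,
                 **{f"z_{c.name}": z[c.name] for c in constructs}}
            )
            z_prev = z
    return posts, pd.DataFrame(panel_rows), pd.DataFrame(truth_rows)


def make_benchmark(
    spec: SyntheticSpec,
    space: EmbeddingSpace,
    anchors: list[AnchorSet],
    n_texts: int = 500,
    n_levels: int = 5,
    construct: str | None = None,
) -> pd.DataFrame:
    """Short texts with ordinal ground-truth labels.

    The label (centered ordinal scale) drives the positive/negative
    anchor mixture exactly as in ``make_panel``; used for rank-agreement
    comparisons of projection vs dictionary scoring.
    """
    rng = _streams(spec)["benchmark"]
    construct = construct or spec.constructs[0].name
    pos_pool = [t for t in space.tokens if t.startswith(f"{construct}_pos")]
    neg_pool = [t for t in space.tokens if t.startswith(f"{construct}_neg")]
    pole_tokens = set(pos_pool) | set(neg_pool)
    fillers = [t for t in space.tokens if t not in pole_tokens]
    lo, hi = spec.token_count_range
    levels = np.arange(n_levels) - (n_levels - 1) / 2.0

    rows = []
    for i in range(n_texts):
        label = levels[int(rng.integers(n_levels))]
        n_tokens = int(rng.integers(lo, hi + 1))
        toks = []
        for _ in range(n_tokens):
            if rng.random() < spec.signal_strength:
                pool = pos_pool if rng.random() < _sigmoid(label) else neg_pool
            else:
                pool = fillers
            toks.append(pool[int(rng.integers(len(pool)))])
        rows.append({"text_id": i, "label": label, "tokens": toks,
                     "text": " ".join(toks)})
    return pd.DataFrame(rows)


def make_numeric_panel(
    n_users: int,
    n_weeks: int,
    beta: float,
    seed: int,
    fixed_effect_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Purely numeric panel for estimator checks: an exactly observed
    regressor x[i, t] ~ N(0, 1) and outcome y[i, t+1] = alpha_i + beta x
    + noise.  Returns estimation rows with columns user_id, week_index,
    x and y_lead (already paired)."""
    rng = np.random.default_rng(seed)
    rows = []
    for u in range(n_users):
        alpha = rng.normal(0, fixed_effect_sd)
        x = rng.normal(size=n_weeks)
        eps = rng.normal(0, noise_sd, size=n_weeks)
        y_lead = alpha + beta * x + eps  # y at t+1 paired with x at t
        for t in range(n_weeks):
            rows.append(
                {"user_id": f"u{u:05d}", "week_index": t,
                 "x": x[t], "y_lead": y_lead[t]}
            )
    return pd.DataFrame(rows)


def make_eiv_rows(
    n_users: int,
    n_weeks: int,
    beta: float,
    reliability: float,
    seed: int,
    fixed_effect_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Classical errors-in-variables panel: the true regressor x ~ N(0,1)
    is observed as x_obs = x + u with u ~ N(0, sigma_u^2) where
    sigma_u^2 = (1 - r)/r for reliability r.  Returns (rows, sigma_u^2);
    rows carry the noisy x_obs and the outcome generated from the TRUE x,
    so the naive coefficient on x_obs is attenuated by roughly r."""
    if not 0 < reliability < 1:
        raise ValueError("reliability must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma_u2 = (1.0 - reliability) / reliability
    rows = []
    for u in range(n_users):
        alpha = rng.normal(0, fixed_effect_sd)
        x = rng.normal(size=n_weeks)
        x_obs = x + rng.normal(0, np.sqrt(sigma_u2), size=n_weeks)
        y_lead = alpha + beta * x + rng.normal(0, noise_sd, size=n_weeks)
        for t in range(n_weeks):
            rows.append(
                {"user_id": f"u{u:05d}", "week_index": t,
                 "x_obs": x_obs[t], "y_lead": y_lead[t]}
            )
    return pd.DataFrame(rows), sigma_u2


def write_fixture_bundle(out_dir: str | Path, spec: SyntheticSpec) -> dict[str, Path]:
    """Write a complete fixture bundle in the real pipeline's formats:
    word2vec-text embeddings, anchors CSV, corpus JSONL, panel and truth
    CSVs.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    space, anchors = make_space(spec)
    posts, panel, truth = make_panel(spec, space, anchors)

    paths = {
        "embeddings": out / "embeddings.w2v.txt",
        "anchors": out / "anchors.csv",
        "corpus": out / "corpus.jsonl",
        "panel": out / "panel.csv",
        "truth": out / "truth.csv",
        "users": out / "users.csv",
    }
    save_embedding_space(space, paths["embeddings"])
    pd.DataFrame(
        [
            {"construct": a.construct, "pole": a.pole, "word": w}
            for a in anchors
            for w in a.words
        ]
    ).to_csv(paths["anchors"], index=False)
    with paths["corpus"].open("w", encoding="utf-8") as fh:
        import json

        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "user_id": p.user_id,
                        "timestamp": p.timestamp.isoformat(),
                        "text": p.text,
                    }
                )
                + "\n"
            )
    panel.to_csv(paths["panel"], index=False)
    truth.to_csv(paths["truth"], index=False)
    pd.DataFrame(
        {"user_id": sorted({p.user_id for p in posts}),
         "registration_date": _EPOCH.isoformat()}
    ).to_csv(paths["users"], index=False)
    return paths
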