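"""Seeded validation experiments on synthetic fixtures.

These are the package's stochastic self-checks: end-to-end parameter
recovery through the full text pipeline, clustered-confidence-interval
coverage of the within estimator, SIMEX bias reduction under classical
errors-in-variables, and monotone degradation of axis stability under
embedding drift.  Each function is deterministic given its seed and
returns plain numbers so callers can assert on or report them.
"""

from __future__ import annotations

import numpy as np

from .axes import make_axis
from .corpus import aggregate_week
from .embeddings import EmbeddingSpace
from .panel import estimate_focal_beta, fe_regression
from .scoring import score_user_weeks
from .simex import SimexConfig, simex
from .stability import axis_stability, orthogonal_procrustes
from .synthetic import (
    SyntheticSpec,
    make_eiv_rows,
    make_numeric_panel,
    make_panel,
    make_space,
)

__all__ = [
    "pipeline_beta",
    "recovery_rate",
    "ci_coverage",
    "simex_improvement_rate",
    "drift_axis_cosines",
]

_REGISTRATION = "2020-01-06"


def pipeline_beta(seed: int, **spec_kwargs) -> tuple[float, float]:
    """Run the complete pipeline on one synthetic world and return the
    focal FE coefficient and its clustered SE.

    Generates a planted-axis space, emits posts, aggregates them to
    user-weeks through the cleaning rules, scores the construct axis,
    and fits the lead-outcome fixed-effects model.
    """
    spec = SyntheticSpec(seed=seed, **spec_kwargs)
    space, anchors = make_space(spec)
    posts, panel, _ = make_panel(spec, space, anchors)
    construct = spec.constructs[0].name
    pos = next(a for a in anchors if a.construct == construct and a.pole == "pos")
    neg = next(a for a in anchors if a.construct == construct and a.pole == "neg")
    by_user: dict[str, list] = {}
    for p in posts:
        by_user.setdefault(p.user_id, []).append(p)
    records = []
    for ps in by_user.values():
        records.extend(aggregate_week(ps, _REGISTRATION))
    axis = make_axis(construct, pos, neg, space)
    scores = score_user_weeks(records, {construct: axis}, space)
    fit = estimate_focal_beta(scores, panel, construct, controls=[])
    return float(fit.params[construct]), float(fit.clustered_se[construct])


def recovery_rate(n_seeds: int = 100, base_seed: int = 0, **spec_kwargs) -> float:
    """Share of synthetic worlds in which the pipeline recovers a
    positive, significant (|t| > 1.96) coefficient on the planted
    construct.  Default worlds: 300 users, 8 weeks, true beta 0.5."""
    hits = 0
    for i in range(n_seeds):
        beta, se = pipeline_beta(base_seed + i, **spec_kwargs)
        if beta > 0 and beta / se > 1.96:
            hits += 1
    return hits / n_seeds


def ci_coverage(
    n_reps: int = 200,
    beta: float = 0.5,
    n_users: int = 300,
    n_weeks: int = 8,
    base_seed: int = 0,
) -> float:
    """Fraction of replications whose 95% cluster-robust CI covers the
    true coefficient, on exactly observed numeric panels."""
    covered = 0
    for i in range(n_reps):
        rows = make_numeric_panel(n_users, n_weeks, beta, seed=base_seed + i)
        fit = fe_regression(rows, "y_lead", ["x"])
        ci = fit.conf_int().loc["x"]
        if ci["lower"] <= beta <= ci["upper"]:
            covered += 1
    return covered / n_reps


def simex_improvement_rate(
    n_reps: int = 50,
    beta: float = 0.5,
    reliability: float = 0.7,
    n_users: int = 500,
    n_weeks: int = 8,
    n_sim: int = 30,
    base_seed: int = 0,
) -> tuple[float, float, float]:
    """Classical errors-in-variables study: share of replications where
    the SIMEX-corrected coefficient is closer to the truth than the
    naive one, plus mean naive and mean corrected estimates."""
    wins = 0
    naives = []
    correcteds = []
    for i in range(n_reps):
        rows, sigma_u2 = make_eiv_rows(
            n_users, n_weeks, beta, reliability, seed=base_seed + i
        )
        cfg = SimexConfig(error_variance=sigma_u2, n_sim=n_sim, seed=base_seed + i)
        res = simex(rows, "y_lead", "x_obs", [], cfg)
        naives.append(res.naive_beta)
        correcteds.append(res.corrected_beta)
        if abs(res.corrected_beta - beta) < abs(res.naive_beta - beta):
            wins += 1
    return wins / n_reps, float(np.mean(naives)), float(np.mean(correcteds))


def drift_axis_cosines(
    noise_sds: tuple[float, ...] = (0.0, 0.2, 0.5, 1.0),
    n_reps: int = 10,
    seed: int = 0,
    **spec_kwargs,
) -> list[float]:
    """Mean axis-stability cosine when the period space is the reference
    plus isotropic noise of increasing sd (after Procrustes alignment).
    Expected to decrease monotonically in the noise level."""
    spec = SyntheticSpec(seed=seed, **spec_kwargs)
    space, anchors = make_space(spec)
    construct = spec.constructs[0].name
    pos = next(a for a in anchors if a.construct == construct and a.pole == "pos")
    neg = next(a for a in anchors if a.construct == construct and a.pole == "neg")
    rng = np.random.default_rng(seed + 1)
    means = []
    for sd in noise_sds:
        cosines = []
        for _ in range(n_reps):
            noisy = EmbeddingSpace(
                list(space.tokens),
                space.vectors + rng.normal(0, sd, size=space.vectors.shape),
                source_tag=f"drift-{sd}",
            )
            aligned = orthogonal_procrustes(noisy, space, shared_vocab=list(space.tokens))
            cosines.append(axis_stability(aligned.aligned_space, space, pos, neg))
        means.append(float(np.mean(cosines)))
    return means
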