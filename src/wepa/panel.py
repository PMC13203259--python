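"""Criterion-validity panel: variable construction, fixed-effects
estimation with user-clustered standard errors, effect-size conversion,
and robustness utilities.

The estimand is the within-user association between a construct score
expressed in week t and (log) exercise duration in week t+1:

    ex_dur[i, t+1] = a + b * construct[i, t] + g' controls[i, t] + mu_i + e[i, t]

estimated by the within (entity-demeaned) estimator, absorbing the
individual effect mu_i, with one-way cluster-robust covariance at the
user level.  Because the outcome is ln(minutes + 1) and predictors are
z-standardized, b converts to an approximate semi-elasticity
100*(exp(b) - 1) percent per standard deviation, and to raw minutes per
week against a reference mean duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RegressionResult",
    "winsorize",
    "prepare_variables",
    "lead_outcome",
    "standardize",
    "fe_regression",
    "semi_elasticity",
    "minutes_equivalent",
    "collinearity_diagnostics",
    "coefficient_difference_test",
    "relative_week_trajectory",
    "sparsity_subsets",
    "estimate_focal_beta",
    "anchor_perturbation_sweep",
    "deviation_percent",
]


@dataclass
class RegressionResult:
    params: pd.Series
    clustered_se: pd.Series
    tstats: pd.Series
    pvalues: pd.Series
    n_obs: int
    n_users: int
    within_r2: float

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(0.5 + level / 2)
        lo = self.params - z * self.clustered_se
        hi = self.params + z * self.clustered_se
        return pd.DataFrame({"lower": lo, "upper": hi})


def winsorize(values, pct: float = 1.0) -> np.ndarray:
    """Clamp both tails at the pct-th / (100-pct)-th percentiles.

    ``pct`` is in percent (1.0 means 1% winsorization each tail);
    record order is preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot winsorize an empty sequence")
    if not 0 <= pct < 50:
        raise ValueError("pct must be in [0, 50)")
    if pct == 0:
        return values.copy()
    lo, hi = np.percentile(values, [pct, 100 - pct])
    return np.clip(values, lo, hi)


def prepare_variables(
    raw: pd.DataFrame,
    count_cols: tuple[str, ...] = ("ex_minutes", "soc_engage_raw", "soc_feedback_raw"),
) -> pd.DataFrame:
    """Build the Table-3-style panel columns from raw weekly sums.

    Applies ln(x+1) to exercise minutes and the two social counts,
    yielding ``ex_dur``, ``soc_engage`` and ``soc_feedback``, and the
    first difference ``dur_chg`` = ex_dur[t] - ex_dur[t-1] within user
    (NaN in a user's first observed week or after a gap, since the lag
    must be the adjacent week).  Negative raw counts are rejected.
    """
    df = raw.sort_values(["user_id", "week_index"]).reset_index(drop=True).copy()
    for col in count_cols:
        if col not in df.columns:
            continue
        if (df[col] < 0).any():
            raise ValueError(f"negative raw counts in {col!r}")
    if "ex_minutes" in df.columns:
        df["ex_dur"] = np.log1p(df["ex_minutes"])
    if "soc_engage_raw" in df.columns:
        df["soc_engage"] = np.log1p(df["soc_engage_raw"])
    if "soc_feedback_raw" in df.columns:
        df["soc_feedback"] = np.log1p(df["soc_feedback_raw"])
    grp = df.groupby("user_id", sort=False)
    lag_week = grp["week_index"].shift(1)
    lag_dur = grp["ex_dur"].shift(1)
    adjacent = lag_week == df["week_index"] - 1
    df["dur_chg"] = np.where(adjacent, df["ex_dur"] - lag_dur, np.nan)
    return df


def lead_outcome(
    panel: pd.DataFrame, outcome: str = "ex_dur", lead_col: str | None = None
) -> pd.DataFrame:
    """Pair regressors at week t with the outcome at week t+1.

    A row survives only when the same user is observed in the strictly
    consecutive next week; a user's last observed week yields no row.
    """
    lead_col = lead_col or f"{outcome}_lead"
    df = panel.sort_values(["user_id", "week_index"]).reset_index(drop=True).copy()
    grp = df.groupby("user_id", sort=False)
    next_week = grp["week_index"].shift(-1)
    next_out = grp[outcome].shift(-1)
    keep = next_week == df["week_index"] + 1
    df[lead_col] = np.where(keep, next_out, np.nan)
    return df.loc[keep].reset_index(drop=True)


def standardize(
    df: pd.DataFrame, cols: list[str], winsor_pct: float = 1.0
) -> pd.DataFrame:
    """Winsorize then z-standardize each named column over the sample.

    Applied to the final estimation sample so coefficients read as
    per-standard-deviation effects in the fitted model.
    """
    out = df.copy()
    for col in cols:
        x = winsorize(out[col].to_numpy(float), winsor_pct)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance after winsorization")
        out[col] = (x - x.mean()) / sd
    return out


def _demean_within(df: pd.DataFrame, cols: list[str], entity: str) -> pd.DataFrame:
    return df[cols] - df.groupby(entity, sort=False)[cols].transform("mean")


def fe_regression(
    rows: pd.DataFrame,
    outcome: str,
    regressors: list[str],
    entity: str = "user_id",
) -> RegressionResult:
    """Within (entity-demeaned) least squares with one-way cluster-robust
    standard errors at the entity level.

    The small-sample correction is G/(G-1) * (n-1)/(n-k) with k counting
    the slope coefficients plus the absorbed entity effects.  A regressor
    that is constant within every entity is absorbed by the fixed effect
    and rejected by name; any other rank deficiency raises a singular-
    design error.
    """
    df = rows.dropna(subset=[outcome, *regressors]).copy()
    counts = df.groupby(entity, sort=False)[outcome].transform("size")
    df = df.loc[counts >= 2]
    if df.empty:
        raise ValueError("no entity contributes >= 2 usable rows")
    dem = _demean_within(df, [outcome, *regressors], entity)
    X = dem[regressors].to_numpy(float)
    y = dem[outcome].to_numpy(float)
    n, k_x = X.shape
    # a regressor constant within each entity loses all variance on
    # demeaning (up to float rounding relative to its original scale)
    orig_var = df[regressors].to_numpy(float).var(axis=0)
    dead = [
        r
        for r, v, ov in zip(regressors, X.var(axis=0), orig_var)
        if v <= 1e-10 * max(ov, 1e-30)
    ]
    if dead:
        raise ValueError(
            f"regressor(s) constant within every entity: {dead}; "
            "absorbed by the fixed effects"
        )
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k_x:
        raise np.linalg.LinAlgError("singular demeaned design matrix")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta

    groups = df[entity].to_numpy()
    _, group_idx = np.unique(groups, return_inverse=True)
    G = group_idx.max() + 1
    # score sums per cluster: S_g = X_g' u_g
    S = np.zeros((G, k_x))
    np.add.at(S, group_idx, X * resid[:, None])
    meat = S.T @ S
    k_total = k_x + G  # slopes + absorbed entity effects
    dof_corr = (G / (G - 1)) * ((n - 1) / max(n - k_total, 1))
    V = dof_corr * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(V))

    tss = float(y @ y)
    rss = float(resid @ resid)
    within_r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    params = pd.Series(beta, index=regressors)
    se_s = pd.Series(se, index=regressors)
    t = params / se_s
    # t reference with G-1 df, the usual clustered inference choice
    p = pd.Series(
        2 * scipy.stats.t.sf(np.abs(t.to_numpy()), df=max(G - 1, 1)),
        index=regressors,
    )
    return RegressionResult(
        params=params,
        clustered_se=se_s,
        tstats=t,
        pvalues=p,
        n_obs=n,
        n_users=int(G),
        within_r2=within_r2,
    )


def semi_elasticity(beta: float) -> float:
    """Percent change in the raw outcome per 1-SD predictor change when
    the outcome is log-transformed: 100*(exp(beta) - 1)."""
    return 100.0 * (np.exp(beta) - 1.0)


def minutes_equivalent(beta: float, ref_mean: float) -> float:
    """Raw minutes-per-week equivalent of a coefficient, against a
    reference mean weekly duration (before log transform)."""
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return ref_mean * (np.exp(beta) - 1.0)


def collinearity_diagnostics(X: pd.DataFrame) -> dict:
    """Variance inflation factors and condition indices.

    VIF_j = 1/(1 - R2_j) from regressing column j on the remaining
    columns (with intercept); exactly collinear columns flag as inf.
    Condition indices are ratios of the largest singular value of the
    z-standardized design to each singular value.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least two columns")
    M = X.to_numpy(float)
    if M.shape[0] <= M.shape[1]:
        raise ValueError("need more rows than columns")
    vifs = {}
    for j, col in enumerate(cols):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(M.shape[0]), np.delete(M, j, axis=1)])
        bj, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        fitted = Xj @ bj
        ss_res = float(((yj - fitted) ** 2).sum())
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        vifs[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
    s = np.linalg.svd(Z, compute_uv=False)
    cond = s.max() / np.where(s > 0, s, np.nan)
    return {"vif": pd.Series(vifs), "condition_indices": cond}


def coefficient_difference_test(
    b1: float, se1: float, b2: float, se2: float
) -> tuple[float, float]:
    """z-test for equality of coefficients from independent subsamples:
    z = (b1 - b2)/sqrt(se1^2 + se2^2), two-sided normal p."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def relative_week_trajectory(
    scores: pd.DataFrame,
    construct: str,
    score_col: str = "wepa_score",
    window: int = 3,
) -> pd.DataFrame:
    """Aggregate standardized scores by relative week and smooth.

    Scores are z-standardized with the full-sample mean/sd, averaged per
    week since registration, then smoothed with a centered moving
    average whose window shrinks to the available neighbors at the
    series edges.
    """
    df = scores
    if "construct" in df.columns:
        df = df.loc[df["construct"] == construct]
    x = df[score_col].to_numpy(float)
    sd = np.nanstd(x, ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance scores; trajectory undefined")
    z = (x - np.nanmean(x)) / sd
    tmp = pd.DataFrame(
        {"relative_week": df["week_index"].to_numpy(), "z": z,
         "user_id": df["user_id"].to_numpy()}
    ).dropna(subset=["z"])
    agg = (
        tmp.groupby("relative_week")
        .agg(mean_standardized_score=("z", "mean"), n_users_observed=("user_id", "nunique"))
        .reset_index()
        .sort_values("relative_week")
        .reset_index(drop=True)
    )
    agg["smoothed_score"] = (
        agg["mean_standardized_score"]
        .rolling(window=window, center=True, min_periods=1)
        .mean()
    )
    agg.insert(0, "construct", construct)
    return agg


def sparsity_subsets(
    panel: pd.DataFrame, col: str = "valid_str_len"
) -> dict[str, pd.DataFrame]:
    """Named valid-token-length subsets used in the sparsity sensitivity
    analysis: at least 5 tokens; short (0, 20); long >= 20."""
    v = panel[col]
    return {
        "ge5": panel.loc[v >= 5].reset_index(drop=True),
        "short_0_20": panel.loc[(v > 0) & (v < 20)].reset_index(drop=True),
        "ge20": panel.loc[v >= 20].reset_index(drop=True),
    }


def estimate_focal_beta(
    score_df: pd.DataFrame,
    panel: pd.DataFrame,
    focal: str,
    controls: list[str],
    winsor_pct: float = 1.0,
) -> RegressionResult:
    """Merge per-user-week scores into the behavioral panel, lead the
    outcome, standardize predictors on the estimation sample, and fit the
    focal fixed-effects model."""
    s = score_df.loc[score_df["construct"] == focal, ["user_id", "week_index", "wepa_score"]]
    merged = panel.merge(s, on=["user_id", "week_index"], how="inner")
    merged = merged.rename(columns={"wepa_score": focal})
    rows = lead_outcome(merged, outcome="ex_dur")
    rows = rows.dropna(subset=[focal, *controls, "ex_dur_lead"])
    rows = standardize(rows, [focal, *controls], winsor_pct)
    return fe_regression(rows, "ex_dur_lead", [focal, *controls])


def deviation_percent(beta_perturbed: float, beta_baseline: float) -> float:
    """Relative coefficient deviation, 100*|b_r - b_0|/|b_0|."""
    if beta_baseline == 0:
        raise ValueError("baseline coefficient is zero")
    return 100.0 * abs(beta_perturbed - beta_baseline) / abs(beta_baseline)


def anchor_perturbation_sweep(
    anchors_pos,
    anchors_neg,
    space,
    records,
    panel: pd.DataFrame,
    controls: list[str],
    n_pairs_removed: tuple[int, ...] = (1, 2, 3),
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly remove positive-negative anchor pairs, rebuild the axis,
    rescore, re-estimate the focal model, and report the coefficient
    deviation from the unperturbed baseline for each condition."""
    from .axes import AnchorSet, make_axis
    from .scoring import score_user_weeks

    rng = np.random.default_rng(seed)
    construct = anchors_pos.construct

    def beta_for(pos: AnchorSet, neg: AnchorSet) -> float:
        axis = make_axis(construct, pos, neg, space)
        scores = score_user_weeks(records, {construct: axis}, space)
        return float(estimate_focal_beta(scores, panel, construct, controls).params[construct])

    beta0 = beta_for(anchors_pos, anchors_neg)
    rows = [{"n_pairs_removed": 0, "beta": beta0, "deviation_pct": 0.0}]
    for r in n_pairs_removed:
        if len(anchors_pos.words) - r < 2 or len(anchors_neg.words) - r < 2:
            raise ValueError(f"removing {r} pairs would exhaust a pole")
        drop_pos = rng.choice(len(anchors_pos.words), size=r, replace=False)
        drop_neg = rng.choice(len(anchors_neg.words), size=r, replace=False)
        pos = AnchorSet(
            construct, "pos",
            tuple(w for i, w in enumerate(anchors_pos.words) if i not in set(drop_pos)),
        )
        neg = AnchorSet(
            construct, "neg",
            tuple(w for i, w in enumerate(anchors_neg.words) if i not in set(drop_neg)),
        )
        beta_r = beta_for(pos, neg)
        rows.append(
            {
                "n_pairs_removed": r,
                "beta": beta_r,
                "deviation_pct": deviation_percent(beta_r, beta0),
            }
        )
    return pd.DataFrame(rows)
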