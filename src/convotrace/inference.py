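"""Statistical modelling of conversation enjoyment.

The analysis treats conversations as level-1 units nested in persons
(level 2) and asks whether five conversation-level properties — length,
percentage of speaking time, turn-taking rate, and variability in volume
and pitch — predict the post-conversation enjoyment rating.  Predictors are
z-scored over all retained conversations and entered simultaneously into a
linear mixed model with a person-level random intercept (REML by default).

Because average and variability of an acoustic family are typically highly
collinear in this kind of data, the model uses the variability member of
each family; :func:`collinearity_guard` reports the observed mean/SD
correlations that motivate the choice.

Fixed-effect t-tests use between-within (containment-style) degrees of
freedom: level-1 effects are tested against n_obs - n_groups - p1 df,
level-2 effects against n_groups - p2 - 1 df.  Other df conventions exist
and can yield different small-sample p-values; the one used here is
reported in every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError, FixedEffect, MixedModelFit

__all__ = [
    "MODEL_PREDICTORS",
    "zscore_predictors",
    "correlation_table",
    "collinearity_guard",
    "fit_hlm",
    "extended_hlm",
    "group_compare",
]

#: The five conversational fixed effects, in reporting order.
MODEL_PREDICTORS = ("length_min", "pct_speaking", "turn_rate_per_min",
                    "vol_sd_db", "pitch_sd_hz")

BIG5 = ("openness", "conscientiousness", "extraversion",
        "agreeableness", "neuroticism")


def zscore_predictors(features: pd.DataFrame,
                      columns=MODEL_PREDICTORS,
                      within: str | None = None) -> pd.DataFrame:
    """Z-score the given columns (sample-SD convention).

    Grand-mean standardization over all rows by default; ``within`` names a
    grouping column for within-person centering/scaling instead (a
    different estimand, exposed but not the default).
    """
    out = features.copy()
    for col in columns:
        if col not in out.columns:
            raise DataError(f"missing predictor column {col!r}")
        if within is None:
            x = out[col].astype(float)
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise DataError(f"zero-variance column {col!r}")
            out[col] = (x - x.mean()) / sd
        else:
            def _z(x):
                sd = x.std(ddof=1)
                if not np.isfinite(sd) or sd == 0:
                    raise DataError(f"zero-variance column {col!r} "
                                    f"within a group")
                return (x - x.mean()) / sd
            out[col] = out.groupby(within)[col].transform(_z)
    return out


def correlation_table(features: pd.DataFrame,
                      columns=MODEL_PREDICTORS) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    df = n - 2 per pair (complete rows for that pair).  The table is
    returned in long symmetric form.
    """
    if len(features) < 3:
        raise DataError("need at least 3 rows for correlations")
    rows = []
    for a in columns:
        for b in columns:
            x = features[a].astype(float)
            y = features[b].astype(float)
            ok = ~(x.isna() | y.isna())
            n = int(ok.sum())
            if n < 3:
                raise DataError(f"too few complete rows for ({a}, {b})")
            if x[ok].std(ddof=1) == 0 or y[ok].std(ddof=1) == 0:
                raise DataError(f"undefined correlation: constant column in "
                                f"({a}, {b})")
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"x": a, "y": b, "r": float(r), "df": n - 2,
                         "p": float(p)})
    return pd.DataFrame(rows)


def collinearity_guard(features: pd.DataFrame,
                       threshold: float = 0.8,
                       paper_faithful: bool = True) -> dict:
    """Report mean/variability collinearity per acoustic family and choose
    the predictor set.

    In faithful mode the variability members (vol_sd_db, pitch_sd_hz) are
    always selected — matching the published analysis choice — and the
    observed correlations are logged; otherwise a family whose |r| exceeds
    ``threshold`` drops its mean member.
    """
    fams = {"volume": ("vol_mean_db", "vol_sd_db"),
            "pitch": ("pitch_mean_hz", "pitch_sd_hz")}
    report = {}
    predictors = list(MODEL_PREDICTORS)
    for fam, (mcol, scol) in fams.items():
        if mcol not in features.columns or scol not in features.columns:
            raise DataError(f"need both {mcol} and {scol} columns")
        ok = ~(features[mcol].isna() | features[scol].isna())
        r, p = stats.pearsonr(features.loc[ok, mcol],
                              features.loc[ok, scol])
        collinear = abs(r) > threshold
        report[fam] = {"r_mean_sd": float(r), "p": float(p),
                       "collinear": bool(collinear)}
        if not paper_faithful and not collinear:
            predictors.append(mcol)
    return {"families": report, "predictors": predictors,
            "mode": "paper_faithful" if paper_faithful else "threshold"}


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def _bw_df(n_obs: int, n_groups: int, n_l1: int, n_l2: int) -> tuple:
    df_within = max(n_obs - n_groups - n_l1, 1)
    df_between = max(n_groups - n_l2 - 1, 1)
    return df_within, df_between


def fit_hlm(data: pd.DataFrame,
            outcome: str = "rating",
            predictors=MODEL_PREDICTORS,
            group_col: str = "participant_id",
            reml: bool = True,
            level2_predictors=()) -> MixedModelFit:
    """Fit the two-level random-intercept model with simultaneous fixed
    effects.

    ``predictors`` vary at level 1 (conversation); ``level2_predictors``
    are person-level covariates (constant within group).  All predictors
    are assumed already standardized/coded by the caller.  A fit whose
    random-intercept variance collapses to the boundary is flagged
    ``singular`` but still returned.
    """
    import statsmodels.api as sm

    cols = list(predictors) + list(level2_predictors)
    for c in cols + [outcome, group_col]:
        if c not in data.columns:
            raise DataError(f"missing column {c!r}")
    d = data.dropna(subset=cols + [outcome]).copy()
    n_obs = len(d)
    groups = d[group_col].to_numpy()
    n_groups = len(np.unique(groups))
    if n_obs < n_groups + len(cols) + 2:
        raise DataError("too few observations for the requested model")

    const = [c for c in cols if d[c].astype(float).std(ddof=1) == 0]
    if const:
        raise DataError(f"unidentifiable constant predictor columns: {const}")

    exog = sm.add_constant(d[cols].astype(float), prepend=True)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(d[outcome].astype(float), exog, groups=groups)
        for method in (None, "powell", "nm"):
            try:
                result = model.fit(reml=reml, **(
                    {"method": method} if method else {}))
            except np.linalg.LinAlgError:
                continue
            if result.converged:
                break
        if result is None:
            raise DataError("mixed-model optimization failed on every "
                            "method")
        # polish: restart from the previous solution until the objective
        # is stationary — the default stopping rule is loose enough to
        # leave order-dependent wobble on flat likelihoods
        for _ in range(20):
            ll_prev = result.llf
            try:
                nxt = model.fit(start_params=result.params, reml=reml)
            except np.linalg.LinAlgError:
                break
            if not np.isfinite(nxt.llf) or nxt.llf < ll_prev - 1e-10:
                break
            result = nxt
            if abs(result.llf - ll_prev) < 1e-10:
                break

    re_var = float(result.cov_re.iloc[0, 0])
    resid_var = float(result.scale)
    singular = re_var < 1e-8 * max(resid_var, 1e-12)

    df_w, df_b = _bw_df(n_obs, n_groups, len(predictors),
                        len(level2_predictors))

    with warnings.catch_warnings():
        # SEs at a boundary fit (random-intercept variance ~ 0) can have a
        # non-PSD covariance; they come out NaN and are reported as such
        warnings.simplefilter("ignore", RuntimeWarning)
        bse_fe = result.bse_fe

    def _fe(name: str, df: float) -> FixedEffect:
        beta = float(result.fe_params[name])
        se = float(bse_fe[name])
        t = beta / se if se > 0 else float("nan")
        p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else float("nan")
        return FixedEffect(name=name, beta=beta, se=se, t=t, df=df, p=p)

    fixed = {c: _fe(c, df_w) for c in predictors}
    fixed.update({c: _fe(c, df_b) for c in level2_predictors})
    return MixedModelFit(
        fixed_effects=fixed,
        intercept=_fe("const", df_b),
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_obs=n_obs, n_groups=n_groups,
        converged=bool(result.converged),
        method="reml" if reml else "ml",
        singular=singular,
    )


def extended_hlm(data: pd.DataFrame,
                 participants: pd.DataFrame,
                 outcome: str = "rating",
                 predictors=MODEL_PREDICTORS,
                 group_col: str = "participant_id",
                 reml: bool = True) -> MixedModelFit:
    """The conversational model plus person-level covariates (Big Five,
    age, gender) as additional fixed effects.

    Continuous covariates are z-scored over participants; gender is coded
    female = 1, male = 0.  Constant covariates are unidentifiable and
    raise :class:`DataError` naming the columns.
    """
    cov_cols = [f"big5_{t}" for t in BIG5] + ["age", "gender"]
    missing = [c for c in cov_cols if c not in participants.columns]
    if missing:
        raise DataError(f"participant table lacks columns: {missing}")
    pt = participants.copy()
    pt["gender"] = (pt["gender"].astype(str).str.lower()
                    .map({"female": 1.0, "f": 1.0, "male": 0.0, "m": 0.0}))
    const = [c for c in cov_cols
             if pt[c].astype(float).std(ddof=1) == 0
             or pt[c].isna().all()]
    if const:
        raise DataError(f"unidentifiable constant covariate columns: {const}")
    for c in cov_cols:
        if c == "gender":
            continue
        x = pt[c].astype(float)
        pt[c] = (x - x.mean()) / x.std(ddof=1)
    merged = data.merge(pt[[group_col] + cov_cols], on=group_col,
                        validate="many_to_one")
    return fit_hlm(merged, outcome=outcome, predictors=predictors,
                   group_col=group_col, reml=reml,
                   level2_predictors=cov_cols)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def group_compare(data: pd.DataFrame,
                  grouping: str,
                  value_cols,
                  groups: tuple | None = None,
                  participant_level: bool = False,
                  participant_col: str = "participant_id") -> pd.DataFrame:
    """Two-sample Student t-tests per feature between two groups.

    Between-person contrasts (e.g. gender) should aggregate to participant
    means first (``participant_level=True``); within-dataset contrasts such
    as tie type compare conversation-level rows directly.
    """
    d = data.copy()
    if participant_level:
        d = (d.groupby([participant_col, grouping], as_index=False)
             [list(value_cols)].mean())
    levels = groups if groups is not None else \
        tuple(pd.unique(d[grouping].dropna()))[:2]
    if len(levels) < 2:
        raise DataError(f"grouping {grouping!r} has a single level")
    a = d[d[grouping] == levels[0]]
    b = d[d[grouping] == levels[1]]
    if a.empty or b.empty:
        raise DataError(f"empty group among {levels}")
    rows = []
    for col in value_cols:
        x = a[col].dropna().astype(float)
        y = b[col].dropna().astype(float)
        t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append({"feature": col, "group_a": str(levels[0]),
                     "group_b": str(levels[1]),
                     "mean_a": float(x.mean()), "mean_b": float(y.mean()),
                     "t": float(t), "df": len(x) + len(y) - 2,
                     "p": float(p)})
    return pd.DataFrame(rows)
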