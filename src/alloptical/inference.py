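"""Session-level inference linking photostimulation effects to behavior.

Two photostimulation conditions (contra-biased and ipsi-biased target groups)
are run in every session, so within-session effects are isolated by
mean-centering the two condition points per session before correlating.  A
multiple linear regression with z-scored inputs summarises which
photostimulation covariates predict the perceptual bias, and a control-trial
resampling scheme builds the null distribution of the bias-vs-activation
correlation by repeatedly drawing "fake photostimulation" subsamples from the
control threshold-stimulus trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .roc import ranksum_z_matrix
from .simulate import SessionTrialData

__all__ = [
    "mean_center",
    "pearson_with_fit",
    "zscored_mlr",
    "MlrResult",
    "ResamplingNull",
    "resampling_null",
    "RankDeficientDesignError",
]


class RankDeficientDesignError(ValueError):
    """Raised when the regression design matrix is not full rank."""


def mean_center(df: pd.DataFrame, session_col: str, value_cols) -> pd.DataFrame:
    """Subtract the within-session mean of each variable (two rows/session).

    Sessions without exactly two condition rows are dropped (logged via the
    returned frame simply not containing them).  The centered pair sums to 0
    per session for every column; applying the operation twice is a no-op.
    """
    value_cols = list(value_cols)
    counts = df.groupby(session_col)[value_cols[0]].transform("size")
    kept = df[counts == 2].copy()
    for col in value_cols:
        kept[col] = kept[col] - kept.groupby(session_col)[col].transform("mean")
    return kept


def pearson_with_fit(x, y) -> dict:
    """Pearson r with p-value, least-squares line and 95% band half-width.

    Returns slope/intercept of the fit line and the half-width of the 95%
    confidence band at the mean of x (from the regression standard error).
    Zero variance in either variable raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    se = np.sqrt((resid**2).sum() / (x.size - 2)) / np.sqrt(x.size)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "band_halfwidth": float(tcrit * se),
        "n": int(x.size),
    }


@dataclass
class MlrResult:
    coefficients: pd.Series       # standardized betas, indexed by predictor
    t_values: pd.Series
    p_values: pd.Series
    conf_int: pd.DataFrame        # 95% CI per coefficient
    n: int
    r_squared: float


def zscored_mlr(predictors: pd.DataFrame, response) -> MlrResult:
    """OLS of the z-scored response on z-scored predictors (plus intercept).

    Standardizing makes the coefficients comparable across predictors and
    invariant to affine rescaling of the raw inputs; with a single predictor
    the coefficient equals the Pearson correlation.  A rank-deficient design
    raises :class:`RankDeficientDesignError` naming the offending columns.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(y)):
        raise ValueError("predictors and response must be finite")
    sds = X.std(ddof=1)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise RankDeficientDesignError(f"zero-variance predictors: {dead}")
    Z = (X - X.mean()) / sds
    if np.linalg.matrix_rank(Z.to_numpy()) < p:
        corr = Z.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (corr.index[i], corr.columns[j])
            for i, j in zip(*np.nonzero(corr.values > 1 - 1e-10))
            if i < j
        ]
        raise RankDeficientDesignError(f"collinear predictors: {pairs}")
    zy = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(zy, sm.add_constant(Z)).fit()
    keep = Z.columns
    ci = model.conf_int().loc[keep]
    ci.columns = ["lo", "hi"]
    return MlrResult(
        coefficients=model.params[keep],
        t_values=model.tvalues[keep],
        p_values=model.pvalues[keep],
        conf_int=ci,
        n=n,
        r_squared=float(model.rsquared),
    )


# ---------------------------------------------------------------------------
# control-trial resampling null
# ---------------------------------------------------------------------------


@dataclass
class ResamplingNull:
    null_r: np.ndarray
    observed_r: float
    percentile: float             # mid-p percentile of observed within null
    n_iterations: int


def _report_rate(reports: np.ndarray) -> float:
    dec = reports != "none"
    if not dec.any():
        return float("nan")
    return float((reports[dec] == "contra").mean())


def _activated_count(cond_resp: np.ndarray, ref_resp: np.ndarray, alpha: float) -> int:
    """Number of targets significantly activated in cond vs. reference.

    Uses the vectorized normal-approximation rank-sum so that observed and
    resampled counts inside the null loop are computed identically.
    """
    z = ranksum_z_matrix(cond_resp, ref_resp)
    return int((z > stats.norm.ppf(1 - alpha)).sum())


def _mean_centered_r(points: list[tuple[float, float]], n_conditions: int = 2) -> float:
    arr = np.asarray(points, dtype=float).reshape(-1, n_conditions, 2)
    centered = arr - arr.mean(axis=1, keepdims=True)
    flat = centered.reshape(-1, 2)
    if np.std(flat[:, 0]) == 0 or np.std(flat[:, 1]) == 0:
        return float("nan")
    return float(stats.pearsonr(flat[:, 0], flat[:, 1])[0])


def resampling_null(
    sessions: list[SessionTrialData],
    n_iter: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ResamplingNull:
    """Null distribution of the activation-vs-bias correlation.

    For each iteration and session, two subsamples of the control TS trials
    are drawn with replacement, sized to the two photostimulation conditions,
    to form a "fake TS+PS" dataset: the choice deviation of each subsample
    from the full control set plays the role of the perceptual bias, and the
    number of targets whose subsampled responses significantly exceed the
    full control set (same one-tailed activation test as the real analysis)
    plays the role of the activated-target count.  The correlation across all
    mean-centered fake points is recorded per iteration; the observed
    correlation from the real photostimulation conditions is located in this
    distribution with the mid-p convention.

    Sessions whose control trial count is below a condition's trial count are
    skipped.
    """
    rng = np.random.default_rng(seed)
    usable = [
        s
        for s in sessions
        if all(
            s.ts_target_responses.shape[1] >= r.shape[1] for r in s.cond_target_responses
        )
    ]
    if not usable:
        raise ValueError("no session has enough control TS trials")

    observed_pts = []
    base_rates = []
    for s in usable:
        base = _report_rate(s.ts_reports)
        base_rates.append(base)
        for rep, resp in zip(s.cond_reports, s.cond_target_responses):
            dp = _report_rate(rep) - base
            count = _activated_count(resp, s.ts_target_responses, alpha)
            observed_pts.append((count, dp))
    observed_r = _mean_centered_r(observed_pts)

    null_r = np.empty(n_iter)
    for it in range(n_iter):
        pts = []
        for s, base in zip(usable, base_rates):
            n_ts = s.ts_target_responses.shape[1]
            for resp in s.cond_target_responses:
                k = resp.shape[1]
                idx = rng.integers(0, n_ts, size=k)
                dp = _report_rate(s.ts_reports[idx]) - base
                count = _activated_count(
                    s.ts_target_responses[:, idx], s.ts_target_responses, alpha
                )
                pts.append((count, dp))
        null_r[it] = _mean_centered_r(pts)
    # drop degenerate iterations (no variance in the fake counts)
    null_r = null_r[np.isfinite(null_r)]
    below = (null_r < observed_r).sum()
    ties = (null_r == observed_r).sum()
    percentile = 100.0 * (below + 0.5 * ties) / max(null_r.size, 1)
    return ResamplingNull(
        null_r=null_r, observed_r=observed_r, percentile=float(percentile),
        n_iterations=n_iter,
    )
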