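"""Psychometric fitting, threshold calibration and choice/bias metrics.

The psychometric function is the 4-parameter logistic

    y(x) = floor + (ceiling - floor) / (1 + exp(-slope * (x - x50)))

fit by least squares to P(report contra) as a function of the bilateral
stimulus difference; the threshold stimulus (TS) is the stimulus value at
which the fitted curve crosses 50% (undefined when 0.5 lies outside
[floor, ceiling]).  Choice metrics distinguish the perceptual report (which
whisker the animal reported) from the motor lick side; the two coincide for
symmetric-trained animals and are inverted for asymmetric training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PsychometricFit",
    "BehaviorMetrics",
    "sigmoid4",
    "fit_psychometric",
    "threshold_stimulus",
    "choice_metrics",
    "fooling_index",
    "opto_bias",
]


def sigmoid4(x, floor, ceiling, x50, slope):
    """4-parameter logistic psychometric function."""
    return floor + (ceiling - floor) / (1.0 + np.exp(-slope * (np.asarray(x, float) - x50)))


@dataclass
class PsychometricFit:
    floor: float
    ceiling: float
    x50: float
    slope: float
    ts: float                 # threshold stimulus; NaN when undefined
    ts_defined: bool
    residual_ss: float
    success: bool

    def predict(self, x):
        return sigmoid4(x, self.floor, self.ceiling, self.x50, self.slope)


@dataclass
class BehaviorMetrics:
    p_report_contra: float
    p_lick_contra: float
    p_miss: float
    n_decisions: int
    n_trials: int


def threshold_stimulus(floor: float, ceiling: float, x50: float, slope: float) -> float:
    """Invert the fitted sigmoid at y = 0.5; NaN if 0.5 is out of range."""
    if not (min(floor, ceiling) < 0.5 < max(floor, ceiling)) or slope == 0:
        return float("nan")
    return x50 - np.log((ceiling - floor) / (0.5 - floor) - 1.0) / slope


def fit_psychometric(
    stimulus_levels, n_report_contra, n_decisions
) -> PsychometricFit:
    """Fit the 4-parameter sigmoid to per-level choice counts.

    ``stimulus_levels`` are bilateral stimulus differences (contra - ipsi);
    ``n_report_contra`` and ``n_decisions`` are per-level counts with miss
    trials already excluded.  Needs at least 4 levels.  Initialisation comes
    from the data quantiles; floor and ceiling are bounded to [0, 1].
    """
    x = np.asarray(stimulus_levels, dtype=float)
    k = np.asarray(n_report_contra, dtype=float)
    m = np.asarray(n_decisions, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 stimulus levels")
    if np.any(m <= 0):
        raise ValueError("every level needs at least one decision trial")
    y = k / m
    order = np.argsort(x)
    x, y, m = x[order], y[order], m[order]
    span = x[-1] - x[0] or 1.0
    p0 = [max(y.min(), 1e-3), min(y.max(), 1 - 1e-3), float(np.median(x)), 4.0 / span]
    try:
        popt, _ = curve_fit(
            sigmoid4,
            x,
            y,
            p0=p0,
            sigma=1.0 / np.sqrt(m),
            bounds=([0.0, 0.0, x[0] - span, 1e-6], [1.0, 1.0, x[-1] + span, 1e6]),
            maxfev=20000,
        )
        success = True
    except RuntimeError:
        return PsychometricFit(*(float("nan"),) * 4, float("nan"), False, float("nan"), False)
    floor, ceiling, x50, slope = map(float, popt)
    resid = y - sigmoid4(x, *popt)
    ts = threshold_stimulus(floor, ceiling, x50, slope)
    return PsychometricFit(
        floor=floor,
        ceiling=ceiling,
        x50=x50,
        slope=slope,
        ts=ts,
        ts_defined=bool(np.isfinite(ts)),
        residual_ss=float((resid**2 * m).sum()),
        success=success,
    )


def choice_metrics(trial_table: pd.DataFrame, mask=None) -> BehaviorMetrics:
    """Report/lick/miss rates over a condition slice of the trial table.

    ``p_report_contra`` and ``p_lick_contra`` are over decision (non-miss)
    trials; ``p_miss`` is over all trials in the slice.  Zero decision trials
    yield NaN rates.
    """
    df = trial_table if mask is None else trial_table.loc[np.asarray(mask)]
    n_all = len(df)
    dec = df[~df["miss"].astype(bool)]
    n_dec = len(dec)
    return BehaviorMetrics(
        p_report_contra=float((dec["report"] == "contra").mean()) if n_dec else float("nan"),
        p_lick_contra=float((dec["lick"] == "contra").mean()) if n_dec else float("nan"),
        p_miss=float(df["miss"].astype(bool).mean()) if n_all else float("nan"),
        n_decisions=n_dec,
        n_trials=n_all,
    )


def fooling_index(led_trials: pd.DataFrame, include_misses: bool = True) -> float:
    """P(contra report) - P(ipsi report) on optogenetic-stimulation-only trials.

    With ``include_misses`` (default) the denominator is all stimulation-only
    trials, so high miss rates yield small indices; setting it False restricts
    to decision trials.  NaN when the slice is empty.
    """
    df = led_trials
    if not include_misses:
        df = df[~df["miss"].astype(bool)]
    n = len(df)
    if n == 0:
        return float("nan")
    return float(((df["report"] == "contra").sum() - (df["report"] == "ipsi").sum()) / n)


def opto_bias(
    ts_trials: pd.DataFrame, ts_opto_trials: pd.DataFrame, min_trials: int = 5
) -> dict:
    """Photostimulation-evoked choice bias and reaction-time shifts on TS trials.

    dP = P(report contra | TS+opto) - P(report contra | TS), misses excluded;
    dRT is computed separately for contra-report and ipsi-report trials as
    mean RT(TS+opto) - mean RT(TS).  Conditions below ``min_trials`` decision
    trials give NaN.
    """
    out = {"delta_p": float("nan"), "delta_rt_contra_ms": float("nan"),
           "delta_rt_ipsi_ms": float("nan")}
    a = ts_trials[~ts_trials["miss"].astype(bool)]
    b = ts_opto_trials[~ts_opto_trials["miss"].astype(bool)]
    if len(a) >= min_trials and len(b) >= min_trials:
        out["delta_p"] = float(
            (b["report"] == "contra").mean() - (a["report"] == "contra").mean()
        )
        for side, key in (("contra", "delta_rt_contra_ms"), ("ipsi", "delta_rt_ipsi_ms")):
            rt_a = a.loc[a["report"] == side, "rt_ms"].dropna()
            rt_b = b.loc[b["report"] == side, "rt_ms"].dropna()
            if len(rt_a) and len(rt_b):
                out[key] = float(rt_b.mean() - rt_a.mean())
    return out
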