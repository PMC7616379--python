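"""ROC/AUC statistics, significance classification and ensemble assignment.

Single-neuron selectivity and choice-related metrics are all expressed as the
area under the ROC curve (AUC) for discriminating two sets of trial-evoked
responses: 0.5 means the two trial types are indistinguishable to an ideal
observer, 1.0 means perfect separation in the positive direction.  Selectivity
compares contralateral vs. ipsilateral unilateral whisker trials; choice
probability (CP), action probability (AP) and detect probability (DP) compare
threshold-stimulus trials split by perceptual report, lickport side, and
lick vs. miss respectively; whisker responsiveness compares threshold-stimulus
and catch trials and is rescaled to [-1, 1] so the sign encodes positive vs.
negative stimulus modulation.

Significance of a directional difference uses a one-tailed Wilcoxon rank-sum
(Mann-Whitney) test at P < 0.05 per direction, uncorrected across neurons:
detected fractions are meant to be compared against the nominal per-direction
false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc",
    "auc_matrix",
    "ranksum_z_matrix",
    "classify_selectivity",
    "SelectivityResult",
    "choice_probability",
    "roc_timecourse",
    "whisker_responsiveness",
]

#: kind -> (positive label, negative label) conventions used by
#: :func:`choice_probability` when labels are strings.
_KIND_LABELS = {
    "CP": ("contra", "ipsi"),   # perceptual report
    "AP": ("contra", "ipsi"),   # lickport side
    "DP": ("lick", "miss"),     # any lick vs. miss
}


def auc(pos, neg) -> float:
    """Area under the ROC curve for ``pos`` vs. ``neg`` responses.

    Equals the Mann-Whitney U statistic normalised by ``n_pos * n_neg``:
    the fraction of (pos, neg) pairs with pos > neg, counting ties as 1/2.
    Returns NaN if either class is empty.
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for many units at once.

    Parameters
    ----------
    pos, neg : (n_units, n_pos) and (n_units, n_neg) response matrices.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n_pos, n_neg = pos.shape[1], neg.shape[1]
    x = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(x, axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def ranksum_z_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise rank-sum z-score (normal approximation, tie-corrected).

    Positive z means ``pos`` responses tend to exceed ``neg``.  This is the
    vectorized test used inside heavy resampling loops; the scalar per-neuron
    analyses use :func:`scipy.stats.mannwhitneyu` directly.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n_pos, n_neg = pos.shape[1], neg.shape[1]
    n = n_pos + n_neg
    x = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(x, axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    mu = n_pos * n_neg / 2.0
    # tie-exact variance from the midranks: Var(U) = n1 n2 / (N (N-1)) *
    # (sum r_i^2 - N (N+1)^2 / 4); reduces to the usual formula without ties
    s2 = (ranks**2).sum(axis=1) - n * (n + 1) ** 2 / 4.0
    sigma2 = n_pos * n_neg * s2 / (n * (n - 1))
    sigma = np.sqrt(np.maximum(sigma2, np.finfo(float).tiny))
    # continuity correction toward the null
    cc = np.clip(u - mu, -0.5, 0.5)
    return (u - mu - cc) / sigma


@dataclass(frozen=True)
class SelectivityResult:
    """Outcome of the directional selectivity classification for one neuron."""

    label: str                # 'contra-coding' | 'ipsi-coding' | 'non-coding'
    auc: float
    p_contra: float           # one-tailed P for contra > ipsi
    p_ipsi: float             # one-tailed P for ipsi > contra
    insufficient_trials: bool = False


def classify_selectivity(
    contra, ipsi, alpha: float = 0.05, min_trials: int = 5
) -> SelectivityResult:
    """Classify a neuron as contra-coding / ipsi-coding / non-coding.

    Two one-tailed Wilcoxon rank-sum tests (each at ``alpha``, uncorrected)
    compare evoked responses on contra vs. ipsi trials; the neuron is
    contra-coding if the contra>ipsi tail is significant, ipsi-coding if the
    ipsi>contra tail is, otherwise non-coding.  With ``alpha`` < 0.5 the two
    calls cannot both fire.
    """
    contra = np.asarray(contra, dtype=float).ravel()
    ipsi = np.asarray(ipsi, dtype=float).ravel()
    contra = contra[~np.isnan(contra)]
    ipsi = ipsi[~np.isnan(ipsi)]
    score = auc(contra, ipsi)
    if contra.size < min_trials or ipsi.size < min_trials:
        return SelectivityResult("non-coding", score, 1.0, 1.0, True)
    p_c = stats.mannwhitneyu(contra, ipsi, alternative="greater").pvalue
    p_i = stats.mannwhitneyu(contra, ipsi, alternative="less").pvalue
    if p_c < alpha:
        label = "contra-coding"
    elif p_i < alpha:
        label = "ipsi-coding"
    else:
        label = "non-coding"
    return SelectivityResult(label, score, float(p_c), float(p_i))


def choice_probability(responses, labels, kind: str = "CP") -> float:
    """AUC of single-trial responses with respect to behavioral labels.

    ``kind`` selects the label convention: CP uses perceptual report
    ('contra' vs 'ipsi'), AP uses lickport side ('contra' vs 'ipsi'), DP uses
    'lick' vs 'miss'.  Scores > 0.5 indicate larger responses on the positive
    class (contra report / contra lickport / lick).  Returns NaN if a label
    class is absent.
    """
    kind = kind.upper()
    if kind not in _KIND_LABELS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_KIND_LABELS)}")
    responses = np.asarray(responses, dtype=float).ravel()
    labels = np.asarray(labels)
    pos_label, neg_label = _KIND_LABELS[kind]
    if labels.dtype == bool:
        pos_mask = labels
        neg_mask = ~labels
    else:
        pos_mask = labels == pos_label
        neg_mask = labels == neg_label
    return auc(responses[pos_mask], responses[neg_mask])


def roc_timecourse(
    frames: np.ndarray, labels, kind: str = "CP", smooth: int = 1
) -> np.ndarray:
    """Per-frame AUC time course from a (trials x frames) matrix.

    ``smooth`` > 1 applies a centred boxcar to the resulting trace (the
    underlying bin width stays one frame).
    """
    frames = np.asarray(frames, dtype=float)
    out = np.array(
        [choice_probability(frames[:, f], labels, kind) for f in range(frames.shape[1])]
    )
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        out = np.convolve(out, kernel, mode="same")
    return out


def whisker_responsiveness(ts_responses, catch_responses) -> float:
    """Signed whisker-responsiveness score in [-1, 1].

    ``2 * (AUC(TS, catch) - 0.5)``: positive when threshold-stimulus trials
    evoke larger responses than catch trials, negative for suppression.
    """
    return 2.0 * (auc(ts_responses, catch_responses) - 0.5)


def ensemble_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-neuron ROC metrics into the ensembles table."""
    return pd.DataFrame(rows)
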