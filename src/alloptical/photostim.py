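"""Photostimulation responsiveness mapping, target parsing and effect metrics.

Neurons are parsed into per-group target zones (within a lateral radius of a
spiral-scan site) and the remaining "network"; per-neuron activation or
suppression between two trial conditions is decided with one-tailed Wilcoxon
rank-sum tests at P < 0.05 per tail.  Higher-level summaries cover the
sensory-photostimulation interaction: the linear-sum deficit (measured
TS+PS response minus the sum of the separate TS and PS responses, a proxy for
sensory-evoked suppression of photostimulation responses), the suppression of
whisker responses in network neurons including its dependence on the number
of nearby activated targets, bilateral suppression of unilateral responses,
and follower-selectivity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roc import auc

__all__ = [
    "TargetSpec",
    "map_ps_responsive",
    "select_target_groups",
    "parse_targets",
    "classify_activation",
    "classify_activation_matrix",
    "net_population_change",
    "linear_sum_deficit",
    "network_sensory_suppression",
    "bilateral_suppression",
    "follower_selectivity_summary",
]


@dataclass
class TargetSpec:
    """One photostimulation target group."""

    group: str                       # 'contra' or 'ipsi' bias
    neuron_ids: np.ndarray
    spiral_sites_um: np.ndarray      # (n_targets, 2)
    spiral_diameter_um: float = 15.0
    target_zone_radius_um: float = 15.0


def map_ps_responsive(
    baseline: np.ndarray, evoked: np.ndarray, alpha: float = 0.05, min_repeats: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Flag photostimulation-responsive cells.

    baseline / evoked: (n_neurons, n_repeats) mean dF/F in the 1 s
    pre-stimulus and the 0.5-1 s post-stimulus windows across stimulation
    repeats.  A cell is responsive when the one-tailed rank-sum increase test
    gives p < alpha.  Returns (flags, p_values); emits a warning-flag array is
    not needed — fewer than ``min_repeats`` repeats raises a UserWarning.
    """
    baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
    evoked = np.atleast_2d(np.asarray(evoked, dtype=float))
    if baseline.shape[0] != evoked.shape[0]:
        raise ValueError("baseline and evoked must cover the same neurons")
    if min(baseline.shape[1], evoked.shape[1]) < min_repeats:
        import warnings

        warnings.warn(
            f"fewer than {min_repeats} stimulation repeats; responsiveness flags unreliable",
            stacklevel=2,
        )
    p = np.array(
        [
            stats.mannwhitneyu(evoked[i], baseline[i], alternative="greater").pvalue
            for i in range(baseline.shape[0])
        ]
    )
    return p < alpha, p


def select_target_groups(
    responsive: np.ndarray,
    selectivity_auc: np.ndarray,
    centroids_um: np.ndarray,
    n: int = 30,
    target_zone_radius_um: float = 15.0,
) -> tuple[TargetSpec, TargetSpec]:
    """Design the contra-biased and ipsi-biased target groups.

    Among photostimulation-responsive neurons, the contra-biased group is the
    ``n`` with the highest stimulus-selectivity AUC and the ipsi-biased group
    the ``n`` lowest; ties at a boundary break by neuron id (stable).  Spiral
    sites are placed at the chosen somata.
    """
    responsive = np.asarray(responsive, dtype=bool)
    selectivity_auc = np.asarray(selectivity_auc, dtype=float)
    centroids_um = np.asarray(centroids_um, dtype=float)
    ids = np.nonzero(responsive)[0]
    if ids.size < 2 * n:
        raise ValueError(
            f"need at least {2 * n} photostimulation-responsive neurons, found {ids.size}"
        )
    order = ids[np.lexsort((ids, selectivity_auc[ids]))]
    ipsi_ids = np.sort(order[:n])
    contra_ids = np.sort(order[-n:])
    def spec(group, members):
        return TargetSpec(
            group=group,
            neuron_ids=members,
            spiral_sites_um=centroids_um[members],
            target_zone_radius_um=target_zone_radius_um,
        )
    return spec("contra", contra_ids), spec("ipsi", ipsi_ids)


def parse_targets(
    roi_centroids_um: np.ndarray,
    spiral_sites: dict[str, np.ndarray],
    radius_um: float = 15.0,
) -> pd.DataFrame:
    """Partition neurons into per-group target zones and network.

    A neuron belongs to a group's target zone iff its lateral (2-D Euclidean)
    distance to that group's nearest spiral site is <= radius (inclusive
    boundary); a neuron inside both groups' radius goes to the nearer site.
    Returns a DataFrame with columns ``zone`` ('contra'/'ipsi'/'network') and
    ``nearest_spiral_um`` per neuron.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    xy = np.asarray(roi_centroids_um, dtype=float)
    groups = list(spiral_sites)
    mindist = {}
    for g in groups:
        sites = np.asarray(spiral_sites[g], dtype=float)
        if sites.size == 0:
            mindist[g] = np.full(xy.shape[0], np.inf)
        else:
            d = np.linalg.norm(xy[:, None, :] - sites[None, :, :], axis=2)
            mindist[g] = d.min(axis=1)
    dmat = np.column_stack([mindist[g] for g in groups])
    nearest = dmat.min(axis=1)
    nearest_group = np.array(groups, dtype=object)[dmat.argmin(axis=1)]
    zone = np.where(nearest <= radius_um, nearest_group, "network")
    return pd.DataFrame({"zone": zone, "nearest_spiral_um": nearest})


def classify_activation(
    responses_ref, responses_cond, alpha: float = 0.05
) -> tuple[str, float, float]:
    """'activated' | 'suppressed' | 'none' for one neuron between conditions.

    Activated if the condition responses significantly exceed the reference
    (one-tailed rank-sum p < alpha), suppressed if significantly below; the
    two labels are mutually exclusive for alpha < 0.5.  Returns
    (label, p_activated, p_suppressed); an empty condition yields
    ('none', nan, nan).
    """
    a = np.asarray(responses_ref, dtype=float).ravel()
    b = np.asarray(responses_cond, dtype=float).ravel()
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return "none", float("nan"), float("nan")
    p_up = stats.mannwhitneyu(b, a, alternative="greater").pvalue
    p_down = stats.mannwhitneyu(b, a, alternative="less").pvalue
    if p_up < alpha:
        return "activated", float(p_up), float(p_down)
    if p_down < alpha:
        return "suppressed", float(p_up), float(p_down)
    return "none", float(p_up), float(p_down)


def classify_activation_matrix(
    ref: np.ndarray, cond: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Vector of activation labels for many neurons (rows)."""
    return np.array(
        [classify_activation(ref[i], cond[i], alpha)[0] for i in range(ref.shape[0])],
        dtype=object,
    )


def net_population_change(summary: dict | pd.Series) -> int:
    """Activated minus suppressed counts over targets and followers."""
    return int(
        summary["n_activated_targets"]
        + summary["n_activated_followers"]
        - summary["n_suppressed_targets"]
        - summary["n_suppressed_followers"]
    )


def linear_sum_deficit(
    resp_ts: np.ndarray,
    resp_ps: np.ndarray,
    resp_tsps: np.ndarray,
    classes: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.Series | None]:
    """Measured TS+PS response minus the linear sum of TS and PS responses.

    All inputs are per-neuron mean evoked responses; neurons with any missing
    condition are excluded (NaN in the output).  Negative values indicate
    sensory-evoked suppression of the photostimulation response.  If
    ``classes`` is given, also returns the group mean per ensemble class.
    """
    resp_ts = np.asarray(resp_ts, dtype=float)
    resp_ps = np.asarray(resp_ps, dtype=float)
    resp_tsps = np.asarray(resp_tsps, dtype=float)
    deficit = resp_tsps - (resp_ts + resp_ps)
    group_means = None
    if classes is not None:
        df = pd.DataFrame({"deficit": deficit, "cls": np.asarray(classes)})
        group_means = df.dropna().groupby("cls")["deficit"].mean()
    return deficit, group_means


def network_sensory_suppression(
    resp_ts: np.ndarray,
    resp_tsps: np.ndarray,
    centroids_um: np.ndarray,
    activated_target_xy_um: np.ndarray,
    neighbor_radius_um: float = 200.0,
    bins: tuple[int, ...] = (0, 3, 6, 10, 15, 10_000),
) -> pd.DataFrame:
    """Photostimulation-evoked change of the whisker response in network cells.

    Per (TS-responsive network) neuron: delta = mean(TS+PS) - mean(TS),
    proportional change delta / mean(TS) (undefined and flagged when the TS
    response is <= 0), and the number of activated target neurons within the
    (inclusive) neighbour radius.  A coarse binned summary by neighbour count
    can be derived from the returned table.
    """
    resp_ts = np.asarray(resp_ts, dtype=float)
    resp_tsps = np.asarray(resp_tsps, dtype=float)
    xy = np.asarray(centroids_um, dtype=float)
    tgt = np.asarray(activated_target_xy_um, dtype=float).reshape(-1, 2)
    delta = resp_tsps - resp_ts
    with np.errstate(divide="ignore", invalid="ignore"):
        proportional = np.where(resp_ts > 0, delta / resp_ts, np.nan)
    if tgt.shape[0]:
        d = np.linalg.norm(xy[:, None, :] - tgt[None, :, :], axis=2)
        n_near = (d <= neighbor_radius_um).sum(axis=1)
    else:
        n_near = np.zeros(xy.shape[0], dtype=int)
    out = pd.DataFrame(
        {
            "delta_ts": delta,
            "proportional_change": proportional,
            "proportional_defined": resp_ts > 0,
            "n_activated_targets_near": n_near,
        }
    )
    out["neighbor_bin"] = pd.cut(out["n_activated_targets_near"], bins=list(bins),
                                 right=False, include_lowest=True)
    return out


def bilateral_suppression(
    evoked: np.ndarray,
    trial_types: np.ndarray,
    classes: np.ndarray,
    contra_type: str = "x3_contra",
    ipsi_type: str = "x3_ipsi",
    bilat_type: str = "x3_bilat",
) -> pd.Series:
    """Bilateral minus preferred-unilateral response per ensemble class.

    evoked: (n_neurons, n_trials); the preferred unilateral stimulus is the
    contra 100% stimulus for contra-coding neurons and the ipsi 100% stimulus
    for ipsi-coding neurons.  Suppression by the non-preferred concurrent
    stimulus shows up as negative values.  Classes without members give NaN.
    """
    evoked = np.asarray(evoked, dtype=float)
    trial_types = np.asarray(trial_types)
    classes = np.asarray(classes)
    m_c = np.nanmean(evoked[:, trial_types == contra_type], axis=1)
    m_i = np.nanmean(evoked[:, trial_types == ipsi_type], axis=1)
    m_b = np.nanmean(evoked[:, trial_types == bilat_type], axis=1)
    pref = np.where(classes == "ipsi-coding", m_i, m_c)
    diff = m_b - pref
    out = {}
    for cls in ("contra-coding", "ipsi-coding", "non-coding"):
        members = classes == cls
        out[cls] = float(np.nanmean(diff[members])) if members.any() else float("nan")
    return pd.Series(out, name="bilateral_minus_preferred")


def follower_selectivity_summary(
    activation_labels: np.ndarray,
    selectivity_auc: np.ndarray,
    follower_mask: np.ndarray,
) -> pd.Series:
    """Mean selectivity AUC of activated and of suppressed followers.

    ``follower_mask`` must already exclude both target groups' zone members.
    Classes with no members yield NaN.
    """
    labels = np.asarray(activation_labels)
    sel = np.asarray(selectivity_auc, dtype=float)
    mask = np.asarray(follower_mask, dtype=bool)
    out = {}
    for key, lab in (("activated_follower_auc", "activated"),
                     ("suppressed_follower_auc", "suppressed")):
        members = mask & (labels == lab)
        out[key] = float(np.nanmean(sel[members])) if members.any() else float("nan")
    return pd.Series(out)
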