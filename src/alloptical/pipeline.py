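"""Session-level orchestration: preprocessing, ensembles, photostimulation
summaries, behavior metrics and the cross-session effect table.

This module glues the primitive operations together in the order a session is
analysed: raw fluorescence -> neuropil-corrected dF/F -> evoked responses ->
ROC ensembles -> per-condition photostimulation summaries -> behavior
metrics -> one row per photostimulation condition for the session-level
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bhv
from . import photostim as ps
from . import roc
from . import traces as tr
from .simulate import SessionBundle, SessionTrialData

__all__ = [
    "PipelineConfig",
    "PreprocessedSession",
    "preprocess_session",
    "compute_ensembles",
    "summarize_photostim",
    "behavior_summary",
    "session_effects",
    "collect_trial_data",
    "run_session_inference",
]


@dataclass
class PipelineConfig:
    """Analysis switches; defaults follow the documented design decisions."""

    alpha: float = 0.05
    min_trials_per_side: int = 5
    target_zone_radius_um: float = 15.0
    neighbor_radius_um: float = 200.0
    activation_reference: str = "ts"      # 'ts' (TS vs TS+PS) or 'catch' (catch vs PS)
    neuropil_per_trial: bool = False      # session-level regression by default
    neuropil_max_fit_samples: int = 40_000  # frame subsampling cap for the IRLS fit
    fooling_include_misses: bool = True
    resampling_iterations: int = 10_000
    baseline_window: tuple[int, int] = tr.BASELINE_WINDOW
    response_window: tuple[int, int] = tr.RESPONSE_WINDOW


@dataclass
class PreprocessedSession:
    tensor: tr.TraceTensor
    neuropil: tr.NeuropilModel
    evoked: np.ndarray                    # (n_neurons, n_trials)
    qc: pd.DataFrame                      # excluded-trial log


def preprocess_session(
    bundle: SessionBundle, cfg: PipelineConfig | None = None
) -> PreprocessedSession:
    """Neuropil correction + dF/F + evoked extraction for one session.

    The neuropil coefficient is estimated per neuron on the concatenated
    full-session traces (lower variance than per-trial fits), the scaled
    neuropil is subtracted, each trial is dF/F-normalised to its 1 s baseline
    and the evoked response is the 0.5-1 s post-stimulus window mean.
    """
    cfg = cfg or PipelineConfig()
    soma = bundle.raw_soma
    npil = bundle.raw_neuropil
    n, n_trials, n_frames = soma.shape
    if cfg.neuropil_per_trial:
        coefs = np.zeros((n, n_trials))
        for t in range(n_trials):
            coefs[:, t] = tr.estimate_neuropil_coefficients(
                soma[:, t, :], npil[:, t, :]
            ).coefficient
        model = tr.NeuropilModel(coefficient=coefs.mean(axis=1), raw_slope=coefs.mean(axis=1))
        corrected = soma - coefs[:, :, None] * npil
    else:
        flat_soma = soma.reshape(n, -1)
        flat_npil = npil.reshape(n, -1)
        total = flat_soma.shape[1]
        if total > cfg.neuropil_max_fit_samples:
            stride = int(np.ceil(total / cfg.neuropil_max_fit_samples))
            flat_soma = flat_soma[:, ::stride]
            flat_npil = flat_npil[:, ::stride]
        model = tr.estimate_neuropil_coefficients(flat_soma, flat_npil)
        corrected = tr.subtract_neuropil(soma, npil, model.coefficient)
    frame_rate = getattr(bundle.config, "frame_rate", tr.FRAME_RATE)
    onset = getattr(bundle.config, "stim_onset_frame", tr.STIM_ONSET_FRAME)
    tensor = tr.compute_dff(
        corrected,
        baseline_window=cfg.baseline_window,
        response_window=cfg.response_window,
        frame_rate=frame_rate,
        stim_onset_frame=onset,
    )
    evoked = tr.evoked_response(tensor)
    qc = pd.DataFrame(
        {
            "trial_id": bundle.trial_table["trial_id"],
            "excluded": ~tensor.valid_trials,
            "reason": np.where(~tensor.valid_trials, "nonpositive baseline F0", ""),
        }
    )
    return PreprocessedSession(tensor=tensor, neuropil=model, evoked=evoked, qc=qc)


def _trial_masks(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    tt = trials["trial_type"].to_numpy()
    pg = trials["ps_group"].fillna("").to_numpy()
    return {
        "ts": tt == "ts",
        "catch": tt == "catch",
        "uni_contra": tt == "uni_contra",
        "uni_ipsi": tt == "uni_ipsi",
        "ps_contra": (tt == "ps") & (pg == "contra"),
        "ps_ipsi": (tt == "ps") & (pg == "ipsi"),
        "tsps_contra": (tt == "ts_ps") & (pg == "contra"),
        "tsps_ipsi": (tt == "ts_ps") & (pg == "ipsi"),
    }


def compute_ensembles(
    evoked: np.ndarray, trials: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-neuron ROC metrics and ensemble classification.

    Stimulus selectivity compares unilateral contra vs. ipsi trial responses;
    CP/AP use control threshold-stimulus trials split by perceptual report /
    lickport side; DP compares lick vs. miss threshold trials; whisker
    responsiveness compares TS with catch trials on the signed [-1, 1] scale.
    """
    cfg = cfg or PipelineConfig()
    masks = _trial_masks(trials)
    reports = trials["report"].to_numpy()
    licks = trials["lick"].to_numpy()
    miss = trials["miss"].to_numpy(dtype=bool)
    ts = masks["ts"]
    rows = []
    for i in range(evoked.shape[0]):
        resp = evoked[i]
        sel = roc.classify_selectivity(
            resp[masks["uni_contra"]],
            resp[masks["uni_ipsi"]],
            alpha=cfg.alpha,
            min_trials=cfg.min_trials_per_side,
        )
        cp = roc.choice_probability(resp[ts & ~miss], reports[ts & ~miss], "CP")
        ap = roc.choice_probability(resp[ts & ~miss], licks[ts & ~miss], "AP")
        dp_labels = np.where(miss[ts], "miss", "lick")
        dp = roc.choice_probability(resp[ts], dp_labels, "DP")
        wr = roc.whisker_responsiveness(resp[ts], resp[masks["catch"]])
        p_wr = (
            stats.mannwhitneyu(
                resp[ts], resp[masks["catch"]], alternative="greater"
            ).pvalue
            if ts.any() and masks["catch"].any()
            else np.nan
        )
        rows.append(
            {
                "neuron": i,
                "selectivity_auc": sel.auc,
                "class": sel.label,
                "p_contra": sel.p_contra,
                "p_ipsi": sel.p_ipsi,
                "cp": cp,
                "ap": ap,
                "dp": dp,
                "whisker_responsiveness": wr,
                "p_ts_responsive": p_wr,
            }
        )
    return pd.DataFrame(rows)


def summarize_photostim(
    evoked: np.ndarray,
    trials: pd.DataFrame,
    roi_centroids: pd.DataFrame,
    spiral_sites: pd.DataFrame,
    ensembles: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition photostimulation summary and per-neuron labels.

    For each target group g, neurons are tested for activation/suppression on
    TS+PS(g) trials against control TS trials (the default reference;
    ``activation_reference='catch'`` switches to PS(g) vs. catch).  Zone
    membership comes from spiral proximity; followers are neurons outside
    both groups' zones.
    """
    cfg = cfg or PipelineConfig()
    masks = _trial_masks(trials)
    xy = roi_centroids[["x_um", "y_um"]].to_numpy()
    sites = {
        g: spiral_sites.loc[spiral_sites["group"] == g, ["x_um", "y_um"]].to_numpy()
        for g in ("contra", "ipsi")
    }
    zones = ps.parse_targets(xy, sites, radius_um=cfg.target_zone_radius_um)
    sel_auc = ensembles["selectivity_auc"].to_numpy()
    classes = ensembles["class"].to_numpy()
    ts_responsive = (ensembles["p_ts_responsive"].to_numpy() < cfg.alpha)

    p_report_ts = bhv.choice_metrics(trials, masks["ts"]).p_report_contra
    summary_rows, label_rows = [], []
    for g in ("contra", "ipsi"):
        if cfg.activation_reference == "catch":
            ref_mask, cond_mask = masks["catch"], masks[f"ps_{g}"]
        else:
            ref_mask, cond_mask = masks["ts"], masks[f"tsps_{g}"]
        labels = np.array(
            [
                ps.classify_activation(evoked[i, ref_mask], evoked[i, cond_mask], cfg.alpha)[0]
                for i in range(evoked.shape[0])
            ],
            dtype=object,
        )
        in_zone = (zones["zone"] == g).to_numpy()
        follower = (zones["zone"] == "network").to_numpy()
        counts = {
            "n_activated_targets": int(((labels == "activated") & in_zone).sum()),
            "n_suppressed_targets": int(((labels == "suppressed") & in_zone).sum()),
            "n_activated_followers": int(((labels == "activated") & follower).sum()),
            "n_suppressed_followers": int(((labels == "suppressed") & follower).sum()),
        }
        # linear-sum deficit for this group's zone members, by ensemble class
        m_ts = np.nanmean(evoked[:, masks["ts"]], axis=1)
        m_ps = np.nanmean(evoked[:, masks[f"ps_{g}"]], axis=1) if masks[f"ps_{g}"].any() else np.full(evoked.shape[0], np.nan)
        m_tsps = np.nanmean(evoked[:, masks[f"tsps_{g}"]], axis=1) if masks[f"tsps_{g}"].any() else np.full(evoked.shape[0], np.nan)
        deficit, deficit_by_class = ps.linear_sum_deficit(
            m_ts[in_zone], m_ps[in_zone], m_tsps[in_zone], classes[in_zone]
        )
        # network whisker-response suppression
        net_ts_resp = follower & ts_responsive
        act_target_xy = xy[(labels == "activated") & in_zone]
        net_tbl = ps.network_sensory_suppression(
            m_ts[net_ts_resp],
            m_tsps[net_ts_resp],
            xy[net_ts_resp],
            act_target_xy,
            neighbor_radius_um=cfg.neighbor_radius_um,
        )
        follower_sel = ps.follower_selectivity_summary(labels, sel_auc, follower)
        p_report_cond = bhv.choice_metrics(trials, cond_mask).p_report_contra
        row = {
            "condition": g,
            **counts,
            "net_change": ps.net_population_change(counts),
            "target_group_selectivity": float(np.nanmean(sel_auc[in_zone])) if in_zone.any() else np.nan,
            "mean_linear_sum_deficit": float(np.nanmean(deficit)),
            "deficit_contra_coding": float(deficit_by_class.get("contra-coding", np.nan)),
            "deficit_ipsi_coding": float(deficit_by_class.get("ipsi-coding", np.nan)),
            "deficit_non_coding": float(deficit_by_class.get("non-coding", np.nan)),
            "network_delta_ts": float(net_tbl["delta_ts"].mean()) if len(net_tbl) else np.nan,
            "network_proportional_change": float(net_tbl["proportional_change"].mean()) if len(net_tbl) else np.nan,
            "activated_follower_auc": float(follower_sel["activated_follower_auc"]),
            "suppressed_follower_auc": float(follower_sel["suppressed_follower_auc"]),
            "delta_p": p_report_cond - p_report_ts,
            "n_cond_trials": int(cond_mask.sum()),
            "n_ts_trials": int(masks["ts"].sum()),
        }
        summary_rows.append(row)
        for i in range(evoked.shape[0]):
            label_rows.append(
                {
                    "neuron": i,
                    "condition": g,
                    "zone": zones["zone"].iloc[i],
                    "activation": labels[i],
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(label_rows)


def behavior_summary(
    trials: pd.DataFrame, cfg: PipelineConfig | None = None
) -> tuple[pd.DataFrame, bhv.PsychometricFit | None, dict]:
    """Behavior metrics per condition, psychometric fit and opto-bias stats."""
    cfg = cfg or PipelineConfig()
    masks = _trial_masks(trials)
    rows = []
    for name, mask in masks.items():
        if not mask.any():
            continue
        m = bhv.choice_metrics(trials, mask)
        rows.append(
            {
                "condition": name,
                "p_report_contra": m.p_report_contra,
                "p_lick_contra": m.p_lick_contra,
                "p_miss": m.p_miss,
                "n_decisions": m.n_decisions,
                "n_trials": m.n_trials,
            }
        )
    metrics = pd.DataFrame(rows)

    # psychometric fit on whisker trials grouped by stimulus difference
    whisker = trials[
        trials["trial_type"].isin(["ts", "uni_contra", "uni_ipsi"]) & ~trials["miss"].astype(bool)
    ]
    fit = None
    grouped = whisker.assign(diff=whisker["stim_contra"] - whisker["stim_ipsi"]).groupby("diff")
    levels = grouped.size()
    if len(levels) >= 4:
        fit = bhv.fit_psychometric(
            levels.index.to_numpy(),
            grouped.apply(lambda d: (d["report"] == "contra").sum(), include_groups=False).to_numpy(),
            levels.to_numpy(),
        )
    extras = {}
    ps_only = trials[trials["trial_type"] == "ps"]
    extras["fooling_index"] = bhv.fooling_index(
        ps_only, include_misses=cfg.fooling_include_misses
    )
    tsps = trials[trials["trial_type"] == "ts_ps"]
    extras["opto_bias"] = bhv.opto_bias(trials[trials["trial_type"] == "ts"], tsps)
    return metrics, fit, extras


def session_effects(
    summaries: dict[int, pd.DataFrame]
) -> pd.DataFrame:
    """Stack per-session photostimulation summaries into the effect table."""
    rows = []
    for session_id, summary in summaries.items():
        s = summary.copy()
        s.insert(0, "session", session_id)
        rows.append(s)
    return pd.concat(rows, ignore_index=True)


def collect_trial_data(
    evoked: np.ndarray, trials: pd.DataFrame, target_ids: np.ndarray
) -> SessionTrialData:
    """Evoked-level bundle for the control-trial resampling null."""
    masks = _trial_masks(trials)
    reports = trials["report"].to_numpy()
    return SessionTrialData(
        ts_reports=reports[masks["ts"]],
        ts_target_responses=evoked[np.asarray(target_ids)][:, masks["ts"]],
        cond_reports=[reports[masks["tsps_contra"]], reports[masks["tsps_ipsi"]]],
        cond_target_responses=[
            evoked[np.asarray(target_ids)][:, masks["tsps_contra"]],
            evoked[np.asarray(target_ids)][:, masks["tsps_ipsi"]],
        ],
    )


def run_session_inference(effects: pd.DataFrame) -> dict:
    """Cross-session correlations and the z-scored regression summary.

    Emits both the raw across-condition correlation between the activated
    target count and the perceptual bias and the mean-centered (within
    session) version, plus the standardized multiple regression of bias on
    target/follower counts and target-group selectivity.
    """
    from . import inference as inf

    out = {}
    try:
        out["raw"] = inf.pearson_with_fit(
            effects["n_activated_targets"], effects["delta_p"]
        )
    except ValueError as err:
        out["raw"] = {"error": str(err)}
    cols = [
        "delta_p",
        "n_activated_targets",
        "n_activated_followers",
        "n_suppressed_followers",
        "target_group_selectivity",
    ]
    centered = inf.mean_center(effects[["session"] + cols], "session", cols)
    try:
        out["mean_centered"] = inf.pearson_with_fit(
            centered["n_activated_targets"], centered["delta_p"]
        )
    except ValueError as err:
        out["mean_centered"] = {"error": str(err)}
    try:
        mlr = inf.zscored_mlr(centered[cols[1:]], centered["delta_p"])
        out["mlr"] = {
            "coefficients": mlr.coefficients.to_dict(),
            "t_values": mlr.t_values.to_dict(),
            "p_values": mlr.p_values.to_dict(),
            "n": mlr.n,
            "r_squared": mlr.r_squared,
        }
    except ValueError as err:  # pragma: no cover - degenerate designs
        out["mlr"] = {"error": str(err)}
    return out
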