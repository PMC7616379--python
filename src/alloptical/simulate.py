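"""Synthetic all-optical session generator with known ground truth.

The generator emulates the statistical structure of a two-photon
imaging + targeted photostimulation session in barrel-cortex L2/3 during a
bilateral whisker discrimination task:

* 30 Hz trial-aligned fluorescence, 210 frames per trial (1 s pre-stimulus,
  6 s post), ~250 neurons in a 470x470 um field of view;
* sparse contra- and ipsi-selective ensembles (~14% of neurons each) whose
  stimulus-locked calcium events scale with deflection intensity; the
  remaining neurons are stimulus-non-coding;
* calcium transients built by passing discrete events through a
  single-exponential GCaMP6s-like kernel (instantaneous rise, slow decay),
  with additive per-frame noise and a shared neuropil trace mixed into every
  somatic signal with a known coefficient;
* two 30-neuron photostimulation target groups (contra-biased / ipsi-biased
  selectivity) with variable per-neuron opsin efficacy; sensory input
  suppresses photostimulation responses multiplicatively, sparing strongly
  whisker-responsive cells; photostimulation in turn suppresses the
  surrounding network with a spatial length scale, preferentially hitting
  neurons tuned opposite to the stimulated group;
* choices drawn from a logistic model whose bias term is proportional to the
  number of activated target neurons on that trial (known coefficient, used
  by the parameter-recovery tests).

All randomness derives from the single session seed via ``SeedSequence``
sub-streams, so equal seeds give byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SessionBundle",
    "ConfigurationError",
    "generate_session",
    "generate_choices",
    "generate_video_features",
    "simulate_effect_sessions",
    "SessionTrialData",
]

TRIAL_TYPES = (
    "ts",          # bilateral threshold stimulus
    "ts_ps",       # threshold stimulus + targeted photostimulation
    "ps",          # photostimulation only
    "catch",       # no stimulus
    "uni_contra",  # unilateral contra whisker
    "uni_ipsi",    # unilateral ipsi whisker
)

X3_TYPES = ("x3_contra", "x3_ipsi", "x3_bilat")  # passive x3 mapping block


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


def _default_trial_mix() -> dict[str, float]:
    # TS+PS ~15%, TS ~15%, PS ~15%, catch ~15%, unilateral whisker ~40%
    return {
        "ts_ps": 0.15,
        "ts": 0.15,
        "ps": 0.15,
        "catch": 0.15,
        "uni_contra": 0.20,
        "uni_ipsi": 0.20,
    }


@dataclass
class SimConfig:
    """Configuration of a synthetic session (defaults = study conditions)."""

    # imaging geometry / timing
    n_neurons: int = 250
    fov_size_um: float = 470.0
    frame_rate: float = 30.0
    n_frames_per_trial: int = 210
    stim_onset_frame: int = 30
    # functional composition
    frac_contra_coding: float = 0.14
    frac_ipsi_coding: float = 0.14
    contra_amp_mean: float = 0.18     # dF/F, preferred 100% unilateral stimulus
    ipsi_amp_mean: float = 0.12
    amp_shape: float = 4.0            # gamma shape of across-neuron amplitudes
    trial_gain_sd: float = 0.3        # multiplicative trial-to-trial variability
    bilateral_ipsi_attenuation: float = 0.7   # ipsi-coding loss on bilateral trials
    bilateral_contra_attenuation: float = 0.1
    # calcium / noise model
    kernel_tau_s: float = 1.0
    noise_sd: float = 0.04            # dF/F units per frame
    neuropil_coeff_true: float = 0.7
    neuropil_sd_f: float = 8.0        # neuropil fluctuation SD, raw F units
    baseline_f_mean: float = 100.0
    spont_rate_hz: float = 0.05
    spont_amp: float = 0.10
    # photostimulation
    n_targets_per_group: int = 30
    target_zone_radius_um: float = 15.0
    opsin_frac_range: tuple[float, float] = (0.4, 0.9)
    opsin_eff_high: float = 0.9
    opsin_eff_low: float = 0.0
    # fraction of designated targets with functional opsin, drawn per group:
    # photostim response mapping is an imperfect predictor of task-time
    # responsiveness, so a variable share of each 30-neuron group fails to fire
    target_responder_range: tuple[float, float] = (0.4, 0.95)
    responders_per_group: int | None = None   # force exact responder counts
    n_offtarget_in_zones: int = 10
    ps_amp_mean: float = 0.30
    selection_noise: float = 0.08     # noise on the target-selection score
    # sensory <-> photostim interaction
    suppression_strength: float = 0.4          # of PS response on TS+PS trials
    sparing_scale: float = 0.035               # dF/F of TS drive that fully spares
    network_suppression_strength: float = 0.03
    suppression_lengthscale_um: float = 200.0
    cross_inhibition: float = 1.0
    frac_excited_followers: float = 0.15
    follower_exc_amp: float = 0.15
    # behavior
    bias_coeff_true: float = 0.025    # logit of P(report contra) per activated target
    stim_sensitivity: float = 4.0     # logit per unit of stimulus difference
    contingency: str = "symmetric"
    p_miss: float = 0.10
    p_miss_no_stim: float = 0.90
    mean_rt_ms: float = 1662.0
    sd_rt_ms: float = 142.0
    ts_level: float = 0.5
    unilateral_levels: tuple[float, ...] = (0.25, 0.5, 1.0)
    # trial structure
    trial_mix: dict[str, float] = field(default_factory=_default_trial_mix)
    n_trials: int = 300
    n_x3_trials_per_type: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons <= 0 or self.n_trials <= 0 or self.n_targets_per_group <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0.0 <= self.neuropil_coeff_true <= 1.0:
            raise ConfigurationError("neuropil_coeff_true must lie in [0, 1]")
        if self.frac_contra_coding + self.frac_ipsi_coding > 1.0:
            raise ConfigurationError("coding fractions sum to more than 1")
        mix_sum = sum(self.trial_mix.values())
        if mix_sum > 1.0 + 1e-9:
            raise ConfigurationError(f"trial_mix sums to {mix_sum:.3f} > 1")
        unknown = set(self.trial_mix) - set(TRIAL_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown trial types in mix: {sorted(unknown)}")
        if self.contingency not in ("symmetric", "asymmetric"):
            raise ConfigurationError("contingency must be 'symmetric' or 'asymmetric'")
        if 2 * self.n_targets_per_group > self.n_neurons:
            raise ConfigurationError("need at least 2 * n_targets_per_group neurons")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_class: np.ndarray            # 'contra' | 'ipsi' | 'non' per neuron
    true_amp: np.ndarray              # preferred-stimulus dF/F event amplitude
    true_auc_like: np.ndarray         # noiseless selectivity score in [0, 1]
    opsin_efficacy: np.ndarray        # per-trial activation probability
    true_ps_responder: np.ndarray     # bool per neuron
    target_ids: dict[str, np.ndarray]  # group -> designated target neuron ids
    true_activated_count: dict[str, int]  # responders among designated targets
    ps_amp: np.ndarray
    spare_gain: np.ndarray            # multiplicative PS gain on TS+PS trials
    n_activated_per_trial: np.ndarray  # designated targets activated, per trial
    bias_coeff_true: float
    neuropil_coeff_true: float

    def to_jsonable(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
            elif isinstance(val, dict):
                out[key] = {
                    k: (v.tolist() if isinstance(v, np.ndarray) else int(v))
                    for k, v in val.items()
                }
            else:
                out[key] = val
        return out


@dataclass
class SessionBundle:
    """One complete synthetic session."""

    trial_table: pd.DataFrame
    raw_soma: np.ndarray              # (n_neurons, n_trials, n_frames), raw F
    raw_neuropil: np.ndarray
    roi_centroids: pd.DataFrame       # columns id, x_um, y_um
    spiral_sites: pd.DataFrame        # columns group, x_um, y_um
    video_features: pd.DataFrame
    ground_truth: GroundTruth
    config: SimConfig


def _largest_remainder_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    keys = list(mix)
    raw = np.array([mix[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i % len(keys)]] += 1
    return dict(zip(keys, base.astype(int)))


def generate_choices(
    trial_stimuli: np.ndarray,
    activated_count: np.ndarray,
    bias_coeff: float,
    contingency: str = "symmetric",
    *,
    stim_sensitivity: float = 4.0,
    p_miss: float = 0.0,
    p_miss_no_stim: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw perceptual reports, lick sides and misses for a set of trials.

    P(report contra) = logistic(k * (contra - ipsi) + beta * activated_count).
    The lick side follows the report through the learned contingency
    (asymmetric training inverts the mapping); misses are drawn independently
    of the stimulus.  Returns a DataFrame with columns report / lick / miss.
    """
    rng = rng or np.random.default_rng()
    stim = np.asarray(trial_stimuli, dtype=float)
    if stim.ndim != 2 or stim.shape[1] != 2:
        raise ValueError("trial_stimuli must be (n_trials, 2): contra, ipsi")
    activated_count = np.broadcast_to(
        np.asarray(activated_count, dtype=float), (stim.shape[0],)
    )
    if np.any(activated_count < 0):
        raise ValueError("activated_count must be non-negative")
    if contingency not in ("symmetric", "asymmetric"):
        raise ValueError("contingency must be 'symmetric' or 'asymmetric'")
    if p_miss_no_stim is None:
        p_miss_no_stim = p_miss
    logit = stim_sensitivity * (stim[:, 0] - stim[:, 1]) + bias_coeff * activated_count
    p_contra = 1.0 / (1.0 + np.exp(-logit))
    report_contra = rng.random(stim.shape[0]) < p_contra
    has_stim = (stim > 0).any(axis=1)
    miss = rng.random(stim.shape[0]) < np.where(has_stim, p_miss, p_miss_no_stim)
    report = np.where(report_contra, "contra", "ipsi").astype(object)
    if contingency == "symmetric":
        lick = report.copy()
    else:
        lick = np.where(report_contra, "ipsi", "contra").astype(object)
    report[miss] = "none"
    lick[miss] = "none"
    return pd.DataFrame({"report": report, "lick": lick, "miss": miss})


def _build_trial_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = _largest_remainder_counts(cfg.trial_mix, cfg.n_trials)
    rows = []
    levels = np.array(cfg.unilateral_levels, dtype=float)
    for ttype, n in counts.items():
        for i in range(n):
            stim_c = stim_i = 0.0
            ps_group = ""
            if ttype == "ts":
                stim_c = stim_i = cfg.ts_level
            elif ttype == "ts_ps":
                stim_c = stim_i = cfg.ts_level
                ps_group = "contra" if i % 2 == 0 else "ipsi"
            elif ttype == "ps":
                ps_group = "contra" if i % 2 == 0 else "ipsi"
            elif ttype == "uni_contra":
                stim_c = levels[i % len(levels)]
            elif ttype == "uni_ipsi":
                stim_i = levels[i % len(levels)]
            rows.append((ttype, stim_c, stim_i, ps_group))
    for ttype in (X3_TYPES if cfg.n_x3_trials_per_type > 0 else ()):
        for _ in range(cfg.n_x3_trials_per_type):
            stim_c = 1.0 if ttype in ("x3_contra", "x3_bilat") else 0.0
            stim_i = 1.0 if ttype in ("x3_ipsi", "x3_bilat") else 0.0
            rows.append((ttype, stim_c, stim_i, ""))
    table = pd.DataFrame(rows, columns=["trial_type", "stim_contra", "stim_ipsi", "ps_group"])
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "trial_id", np.arange(len(table)))
    return table


def generate_session(config: SimConfig) -> SessionBundle:
    """Generate a complete synthetic session (deterministic given the seed)."""
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_cells, rng_trials, rng_choice, rng_traces, rng_video = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = cfg.n_neurons

    # --- neurons: classes, amplitudes, geometry -------------------------------
    n_contra = int(round(cfg.frac_contra_coding * n))
    n_ipsi = int(round(cfg.frac_ipsi_coding * n))
    perm = rng_cells.permutation(n)
    true_class = np.full(n, "non", dtype=object)
    true_class[perm[:n_contra]] = "contra"
    true_class[perm[n_contra : n_contra + n_ipsi]] = "ipsi"
    true_amp = np.zeros(n)
    is_c = true_class == "contra"
    is_i = true_class == "ipsi"
    true_amp[is_c] = rng_cells.gamma(cfg.amp_shape, cfg.contra_amp_mean / cfg.amp_shape, is_c.sum())
    true_amp[is_i] = rng_cells.gamma(cfg.amp_shape, cfg.ipsi_amp_mean / cfg.amp_shape, is_i.sum())
    true_auc_like = np.full(n, 0.5)
    true_auc_like[is_c] = 0.5 + np.minimum(0.45, true_amp[is_c])
    true_auc_like[is_i] = 0.5 - np.minimum(0.45, true_amp[is_i])
    centroids = rng_cells.uniform(0.0, cfg.fov_size_um, size=(n, 2))

    # --- opsin efficacy and target-group design ------------------------------
    frac_high = rng_cells.uniform(*cfg.opsin_frac_range)
    high = rng_cells.random(n) < frac_high
    efficacy = np.where(high, cfg.opsin_eff_high, cfg.opsin_eff_low)
    ps_amp = rng_cells.gamma(cfg.amp_shape, cfg.ps_amp_mean / cfg.amp_shape, n)
    score = true_auc_like + rng_cells.normal(0.0, cfg.selection_noise, n)
    cand_sorted = np.lexsort((np.arange(n), score))
    contra_targets = np.sort(cand_sorted[-cfg.n_targets_per_group :])
    ipsi_targets = np.sort(cand_sorted[: cfg.n_targets_per_group])
    target_ids = {"contra": contra_targets, "ipsi": ipsi_targets}
    # per-group responder fraction: mapping-based target selection is an
    # imperfect predictor of task-time photostimulation responsiveness
    for group, ids in target_ids.items():
        if cfg.responders_per_group is not None:
            efficacy[ids] = cfg.opsin_eff_low
            chosen = rng_cells.choice(ids, size=cfg.responders_per_group, replace=False)
            efficacy[chosen] = cfg.opsin_eff_high
        else:
            r_group = rng_cells.uniform(*cfg.target_responder_range)
            fires = rng_cells.random(ids.size) < r_group
            efficacy[ids] = np.where(fires, cfg.opsin_eff_high, cfg.opsin_eff_low)
    responder = efficacy >= 0.5
    true_activated_count = {g: int(responder[ids].sum()) for g, ids in target_ids.items()}

    # place a configurable number of extra (non-target) neurons inside target
    # zones to emulate imperfect spiral specificity
    all_targets = np.concatenate([contra_targets, ipsi_targets])
    non_target = np.setdiff1d(np.arange(n), all_targets)
    n_off = min(cfg.n_offtarget_in_zones, non_target.size)
    if n_off > 0:
        off_ids = rng_cells.choice(non_target, size=n_off, replace=False)
        host = rng_cells.choice(all_targets, size=n_off, replace=True)
        angle = rng_cells.uniform(0, 2 * np.pi, n_off)
        radius = rng_cells.uniform(0, 0.7 * cfg.target_zone_radius_um, n_off)
        centroids[off_ids, 0] = np.clip(
            centroids[host, 0] + radius * np.cos(angle), 0, cfg.fov_size_um
        )
        centroids[off_ids, 1] = np.clip(
            centroids[host, 1] + radius * np.sin(angle), 0, cfg.fov_size_um
        )

    spiral_rows = []
    for group, ids in target_ids.items():
        for i in ids:
            spiral_rows.append((group, centroids[i, 0], centroids[i, 1]))
    spirals = pd.DataFrame(spiral_rows, columns=["group", "x_um", "y_um"])

    # --- trials ---------------------------------------------------------------
    table = _build_trial_table(cfg, rng_trials)
    n_trials = len(table)
    stim_c = table["stim_contra"].to_numpy()
    stim_i = table["stim_ipsi"].to_numpy()
    ps_group = table["ps_group"].to_numpy()

    # per-trial photostimulation outcomes for zone members (targets and any
    # off-target neurons sitting inside a spiral's activation radius)
    dist = np.linalg.norm(
        centroids[:, None, :] - spirals[["x_um", "y_um"]].to_numpy()[None, :, :], axis=2
    )
    zone_member = {
        g: np.nonzero(
            (dist[:, (spirals["group"] == g).to_numpy()] <= cfg.target_zone_radius_um).any(axis=1)
        )[0]
        for g in ("contra", "ipsi")
    }
    activated = np.zeros((n, n_trials), dtype=bool)
    for g in ("contra", "ipsi"):
        trials_g = np.nonzero(ps_group == g)[0]
        members = zone_member[g]
        if trials_g.size and members.size:
            draw = rng_trials.random((members.size, trials_g.size))
            activated[np.ix_(members, trials_g)] = draw < efficacy[members, None]
    n_act_per_trial = np.zeros(n_trials, dtype=int)
    for g in ("contra", "ipsi"):
        trials_g = ps_group == g
        n_act_per_trial[trials_g] = activated[target_ids[g]][:, trials_g].sum(axis=0)

    # --- choices --------------------------------------------------------------
    choices = generate_choices(
        np.column_stack([stim_c, stim_i]),
        n_act_per_trial,
        cfg.bias_coeff_true,
        cfg.contingency,
        stim_sensitivity=cfg.stim_sensitivity,
        p_miss=cfg.p_miss,
        p_miss_no_stim=cfg.p_miss_no_stim,
        rng=rng_choice,
    )
    table = pd.concat([table, choices], axis=1)
    rt = rng_choice.normal(cfg.mean_rt_ms, cfg.sd_rt_ms, n_trials)
    rt = np.clip(rt, 300.0, None)
    rt[table["miss"].to_numpy()] = np.nan
    table["rt_ms"] = rt
    correct = np.where(
        stim_c == stim_i,
        "threshold",
        np.where(
            (stim_c > stim_i) == (table["report"] == "contra"), "correct", "incorrect"
        ),
    ).astype(object)
    correct[table["miss"].to_numpy()] = "miss"
    table["outcome"] = correct
    table["contingency"] = cfg.contingency

    # --- event amplitudes -----------------------------------------------------
    bilateral = (stim_c > 0) & (stim_i > 0)
    pref_int = np.zeros((n, n_trials))
    pref_int[is_c] = stim_c[None, :]
    pref_int[is_i] = stim_i[None, :]
    gain = np.clip(
        rng_traces.normal(1.0, cfg.trial_gain_sd, size=(n, n_trials)), 0.0, None
    )
    sens = true_amp[:, None] * pref_int * gain
    att = np.ones((n, n_trials))
    att[np.ix_(is_i, bilateral)] = 1.0 - cfg.bilateral_ipsi_attenuation
    att[np.ix_(is_c, bilateral)] = 1.0 - cfg.bilateral_contra_attenuation
    sens *= att

    # sensory drive on a TS trial determines how much a target is spared from
    # sensory-evoked suppression of its photostimulation response
    sens_ts = true_amp * cfg.ts_level
    sens_ts[is_i] *= 1.0 - cfg.bilateral_ipsi_attenuation
    sens_ts[is_c] *= 1.0 - cfg.bilateral_contra_attenuation
    q = np.clip(sens_ts / cfg.sparing_scale, 0.0, 1.0)
    spare_gain = 1.0 - cfg.suppression_strength * (1.0 - q)

    ps_event = ps_amp[:, None] * activated
    is_tsps = (table["trial_type"] == "ts_ps").to_numpy()
    ps_event[:, is_tsps] *= spare_gain[:, None]

    # network suppression by photostimulation: distance-decaying drive from the
    # activated targets, stronger onto neurons tuned opposite the target group
    signed_sel = 2.0 * (true_auc_like - 0.5)
    group_sel = {g: float(signed_sel[ids].mean()) for g, ids in target_ids.items()}
    supp = np.zeros((n, n_trials))
    exc = np.zeros((n, n_trials))
    follower_coupling = {}
    for g in ("contra", "ipsi"):
        trials_g = np.nonzero(ps_group == g)[0]
        if trials_g.size == 0:
            continue
        members = zone_member[g]
        act_g = activated[np.ix_(target_ids[g], trials_g)]
        w_dist = np.exp(-dist[:, (spirals["group"] == g).to_numpy()] / cfg.suppression_lengthscale_um)
        drive = w_dist[:, : len(target_ids[g])] @ act_g  # (n_neurons, n_trials_g)
        # cross-ensemble inhibition: followers tuned opposite to the stimulated
        # group's selectivity direction are suppressed more strongly
        direction = np.sign(group_sel[g]) or 1.0
        cross_w = 1.0 + cfg.cross_inhibition * np.maximum(0.0, -signed_sel * direction)
        red = (
            cfg.network_suppression_strength
            * drive
            / cfg.n_targets_per_group
            * cross_w[:, None]
        )
        red[members] = 0.0  # stimulated-zone cells are handled by spare_gain
        supp[:, trials_g] += red
        # a sparse set of positively coupled followers
        coupled = rng_cells.random(n) < cfg.frac_excited_followers
        coupled[members] = False
        amp_fc = rng_cells.exponential(cfg.follower_exc_amp, n) * coupled
        follower_coupling[g] = amp_fc
        exc[:, trials_g] += amp_fc[:, None] * (drive / max(1, len(target_ids[g])))

    evoked_amp = sens + ps_event + exc - supp
    evoked_amp = np.maximum(evoked_amp, -0.15)  # bounded negative dF/F excursion

    # --- build traces ---------------------------------------------------------
    F = cfg.n_frames_per_trial
    events = np.zeros((n, n_trials, F))
    events[:, :, cfg.stim_onset_frame] = evoked_amp
    # spontaneous events (homogeneous Poisson per neuron-trial)
    lam = cfg.spont_rate_hz * F / cfg.frame_rate
    n_spont = rng_traces.poisson(lam, size=(n, n_trials))
    total = int(n_spont.sum())
    if total > 0:
        idx_n, idx_t = np.nonzero(n_spont)
        reps = n_spont[idx_n, idx_t]
        flat_n = np.repeat(idx_n, reps)
        flat_t = np.repeat(idx_t, reps)
        frames = rng_traces.integers(0, F, size=total)
        amps = rng_traces.exponential(cfg.spont_amp, size=total)
        np.add.at(events, (flat_n, flat_t, frames), amps)
    decay = np.exp(-1.0 / (cfg.kernel_tau_s * cfg.frame_rate))
    dff_true = lfilter([1.0], [1.0, -decay], events, axis=2)

    f0 = rng_traces.lognormal(np.log(cfg.baseline_f_mean), 0.3, n)
    # shared neuropil: slow fluctuations around a constant level, raw F units
    white = rng_traces.normal(0.0, 1.0, size=(n_trials, F))
    slow = lfilter([1.0], [1.0, -np.exp(-1.0 / (0.3 * cfg.frame_rate))], white, axis=1)
    sd = slow.std() or 1.0
    neuropil_common = 50.0 + cfg.neuropil_sd_f * slow / sd
    soma = (
        f0[:, None, None] * (1.0 + dff_true)
        + cfg.neuropil_coeff_true * neuropil_common[None, :, :]
        + rng_traces.normal(0.0, 1.0, size=(n, n_trials, F)) * (cfg.noise_sd * f0)[:, None, None]
    )
    # per-ROI neuropil measurement noise scales with the imaging noise level
    np_noise = 12.5 * cfg.noise_sd
    neuropil = neuropil_common[None, :, :] + rng_traces.normal(
        0.0, 1.0, size=(n, n_trials, F)
    ) * np_noise

    rois = pd.DataFrame(
        {"id": np.arange(n), "x_um": centroids[:, 0], "y_um": centroids[:, 1]}
    )
    video = generate_video_features(
        table,
        n_frames=F,
        frame_rate=cfg.frame_rate,
        stim_onset_frame=cfg.stim_onset_frame,
        rng=rng_video,
    )
    gt = GroundTruth(
        true_class=true_class.astype(str),
        true_amp=true_amp,
        true_auc_like=true_auc_like,
        opsin_efficacy=efficacy,
        true_ps_responder=responder,
        target_ids={g: ids.astype(int) for g, ids in target_ids.items()},
        true_activated_count=true_activated_count,
        ps_amp=ps_amp,
        spare_gain=spare_gain,
        n_activated_per_trial=n_act_per_trial,
        bias_coeff_true=cfg.bias_coeff_true,
        neuropil_coeff_true=cfg.neuropil_coeff_true,
    )
    return SessionBundle(
        trial_table=table,
        raw_soma=soma,
        raw_neuropil=neuropil,
        roi_centroids=rois,
        spiral_sites=spirals,
        video_features=video,
        ground_truth=gt,
        config=cfg,
    )


def generate_video_features(
    trial_table: pd.DataFrame,
    n_frames: int = 210,
    frame_rate: float = 30.0,
    stim_onset_frame: int = 30,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-trial motion and tongue-node tables mimicking videography output.

    Whisker-pad and body motion are elevated after the stimulus on whisker
    and lick trials, with the session-level 1-r normalisation applied (max
    over the session = 1).  The ten tongue-node likelihood columns satisfy the
    lick-detection rule (>= 7 nodes with likelihood >= 0.7) from the first
    frame at the trial's reaction time onward on lick trials, and never on
    miss trials.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    frames = np.arange(n_frames)
    for _, tr in trial_table.iterrows():
        base = np.abs(rng.normal(0.05, 0.02, (3, n_frames)))
        has_stim = (tr["stim_contra"] > 0) or (tr["stim_ipsi"] > 0)
        licked = tr["report"] in ("contra", "ipsi")
        if has_stim or licked:
            bump = 0.3 * np.exp(-np.maximum(frames - stim_onset_frame, 0) / (1.5 * frame_rate))
            bump[: stim_onset_frame] = 0.0
            base += bump[None, :]
        lik = rng.uniform(0.0, 0.3, (n_frames, 10))
        lick_frame = -1
        if licked and np.isfinite(tr["rt_ms"]):
            lick_frame = stim_onset_frame + int(round(tr["rt_ms"] / 1000.0 * frame_rate))
            if lick_frame < n_frames:
                n_hi = 8
                lik[lick_frame:, :n_hi] = rng.uniform(0.8, 1.0, (n_frames - lick_frame, n_hi))
        row = pd.DataFrame(
            {
                "trial_id": tr["trial_id"],
                "frame": frames,
                "whisk_contra": base[0],
                "whisk_ipsi": base[1],
                "body": base[2],
            }
        )
        for k in range(10):
            row[f"tongue_{k}"] = lik[:, k]
        rows.append(row)
    video = pd.concat(rows, ignore_index=True)
    for col in ("whisk_contra", "whisk_ipsi", "body"):
        m = video[col].max()
        if m > 0:
            video[col] = video[col] / m
    return video


# ---------------------------------------------------------------------------
# lightweight evoked-level sessions for the session-level inference tests
# ---------------------------------------------------------------------------


@dataclass
class SessionTrialData:
    """Evoked-level data for one session, as consumed by the resampling null.

    Target responses are (n_targets, n_trials) evoked dF/F matrices; reports
    are object arrays in {'contra', 'ipsi', 'none'} ('none' = miss).
    """

    ts_reports: np.ndarray
    ts_target_responses: np.ndarray
    cond_reports: list[np.ndarray]
    cond_target_responses: list[np.ndarray]


def simulate_effect_sessions(
    n_sessions: int,
    bias_coeff: float,
    seed: int,
    n_targets_per_group: int = 30,
    n_ts_trials: int = 46,
    n_cond_trials: int = 23,
    noise_sd: float = 0.05,
    ps_amp: float = 0.3,
    opsin_frac_range: tuple[float, float] = (0.4, 0.9),
) -> list[SessionTrialData]:
    """Sessions at the evoked-response level (no calcium traces).

    Each session has a control threshold-stimulus (TS) condition and two
    photostimulation conditions (one per target group).  Target evoked
    responses are baseline noise on TS trials plus a photostimulation
    transient for that group's responders on its own condition; perceptual
    reports follow the logistic choice model with the session's
    responder count as the activation regressor.
    """
    ss = np.random.SeedSequence(seed)
    sessions = []
    for child in ss.spawn(n_sessions):
        rng = np.random.default_rng(child)
        n_tg = 2 * n_targets_per_group
        frac = rng.uniform(*opsin_frac_range, size=2)
        responder = np.zeros(n_tg, dtype=bool)
        responder[:n_targets_per_group] = rng.random(n_targets_per_group) < frac[0]
        responder[n_targets_per_group:] = rng.random(n_targets_per_group) < frac[1]
        ts_resp = rng.normal(0.0, noise_sd, (n_tg, n_ts_trials))
        ts_rep = np.where(rng.random(n_ts_trials) < 0.5, "contra", "ipsi").astype(object)
        cond_resp, cond_rep = [], []
        for g in range(2):
            sel = slice(g * n_targets_per_group, (g + 1) * n_targets_per_group)
            resp = rng.normal(0.0, noise_sd, (n_tg, n_cond_trials))
            resp[sel] += ps_amp * responder[sel][:, None]
            n_act = int(responder[sel].sum())
            p = 1.0 / (1.0 + np.exp(-bias_coeff * n_act))
            rep = np.where(rng.random(n_cond_trials) < p, "contra", "ipsi").astype(object)
            cond_resp.append(resp)
            cond_rep.append(rep)
        sessions.append(
            SessionTrialData(
                ts_reports=ts_rep,
                ts_target_responses=ts_resp,
                cond_reports=cond_rep,
                cond_target_responses=cond_resp,
            )
        )
    return sessions
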