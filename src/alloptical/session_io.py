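"""On-disk session format and report writers.

A session directory holds:

* ``trials.csv``      — one row per trial (behavior + stimulus columns)
* ``traces.h5``       — datasets ``/soma``, ``/neuropil`` and, after
  preprocessing, ``/dff``; attributes ``frame_rate`` and ``stim_onset_frame``
* ``rois.csv``        — ROI centroids (id, x_um, y_um; origin FOV top-left)
* ``spirals.csv``     — photostimulation spiral sites per target group
* ``video.csv``       — per-trial per-frame motion and tongue-node features
* ``ground_truth.json`` / ``config.json`` — synthetic sessions only

All CSVs are UTF-8, comma-separated with a header row; coordinates in
micrometres, times in milliseconds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import GroundTruth, SessionBundle, SimConfig
from .traces import TraceTensor

__all__ = [
    "SchemaError",
    "write_session",
    "read_session",
    "write_dff",
    "read_dff",
    "write_report",
]

TRIAL_COLUMNS = [
    "trial_id",
    "trial_type",
    "stim_contra",
    "stim_ipsi",
    "ps_group",
    "report",
    "lick",
    "miss",
    "rt_ms",
    "outcome",
    "contingency",
]
ROI_COLUMNS = ["id", "x_um", "y_um"]
SPIRAL_COLUMNS = ["group", "x_um", "y_um"]


class SchemaError(ValueError):
    """A required file or column is missing or malformed."""


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def write_session(directory, bundle: SessionBundle) -> Path:
    """Write a session bundle to a directory (created if needed)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.trial_table.to_csv(d / "trials.csv", index=False)
    bundle.roi_centroids.to_csv(d / "rois.csv", index=False)
    bundle.spiral_sites.to_csv(d / "spirals.csv", index=False)
    bundle.video_features.to_csv(d / "video.csv", index=False)
    cfg = bundle.config
    with h5py.File(d / "traces.h5", "w") as f:
        f.create_dataset("soma", data=bundle.raw_soma, compression="gzip", compression_opts=1)
        f.create_dataset("neuropil", data=bundle.raw_neuropil, compression="gzip", compression_opts=1)
        f.attrs["frame_rate"] = cfg.frame_rate
        f.attrs["stim_onset_frame"] = cfg.stim_onset_frame
    (d / "ground_truth.json").write_text(
        json.dumps(bundle.ground_truth.to_jsonable(), indent=1)
    )
    cfg_dict = dataclasses.asdict(cfg)
    (d / "config.json").write_text(json.dumps(cfg_dict, indent=1))
    return d


def _ground_truth_from_json(payload: dict) -> GroundTruth:
    arrays = {
        k: np.asarray(v)
        for k, v in payload.items()
        if isinstance(v, list)
    }
    return GroundTruth(
        true_class=arrays["true_class"].astype(str),
        true_amp=arrays["true_amp"].astype(float),
        true_auc_like=arrays["true_auc_like"].astype(float),
        opsin_efficacy=arrays["opsin_efficacy"].astype(float),
        true_ps_responder=arrays["true_ps_responder"].astype(bool),
        target_ids={k: np.asarray(v, dtype=int) for k, v in payload["target_ids"].items()},
        true_activated_count={k: int(v) for k, v in payload["true_activated_count"].items()},
        ps_amp=arrays["ps_amp"].astype(float),
        spare_gain=arrays["spare_gain"].astype(float),
        n_activated_per_trial=arrays["n_activated_per_trial"].astype(int),
        bias_coeff_true=float(payload["bias_coeff_true"]),
        neuropil_coeff_true=float(payload["neuropil_coeff_true"]),
    )


def read_session(directory) -> SessionBundle:
    """Read a session directory back into a bundle (lossless round trip)."""
    d = Path(directory)
    trials = pd.read_csv(d / "trials.csv", keep_default_na=False, na_values=[""])
    _require_columns(trials, TRIAL_COLUMNS, "trials.csv")
    trials["ps_group"] = trials["ps_group"].fillna("").astype(str)
    trials["miss"] = trials["miss"].astype(bool)
    rois = pd.read_csv(d / "rois.csv")
    _require_columns(rois, ROI_COLUMNS, "rois.csv")
    spirals = pd.read_csv(d / "spirals.csv")
    _require_columns(spirals, SPIRAL_COLUMNS, "spirals.csv")
    video_path = d / "video.csv"
    video = pd.read_csv(video_path) if video_path.exists() else pd.DataFrame()
    with h5py.File(d / "traces.h5", "r") as f:
        soma = f["soma"][...]
        neuropil = f["neuropil"][...]
    cfg_path = d / "config.json"
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        fields = {f.name for f in dataclasses.fields(SimConfig)}
        kwargs = {k: v for k, v in raw.items() if k in fields}
        for key in ("opsin_frac_range", "unilateral_levels"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        config = SimConfig(**kwargs)
    else:
        config = SimConfig(n_neurons=soma.shape[0], n_trials=soma.shape[1])
    gt_path = d / "ground_truth.json"
    ground_truth = (
        _ground_truth_from_json(json.loads(gt_path.read_text())) if gt_path.exists() else None
    )
    return SessionBundle(
        trial_table=trials,
        raw_soma=soma,
        raw_neuropil=neuropil,
        roi_centroids=rois,
        spiral_sites=spirals,
        video_features=video,
        ground_truth=ground_truth,
        config=config,
    )


def write_dff(directory, tensor: TraceTensor, qc: pd.DataFrame | None = None) -> None:
    """Append the preprocessed dF/F tensor (and QC table) to a session dir."""
    d = Path(directory)
    with h5py.File(d / "traces.h5", "a") as f:
        if "dff" in f:
            del f["dff"]
        f.create_dataset("dff", data=tensor.dff, compression="gzip", compression_opts=1)
        f.attrs["frame_rate"] = tensor.frame_rate
        f.attrs["stim_onset_frame"] = tensor.stim_onset_frame
        f["dff"].attrs["baseline_window"] = tensor.baseline_window
        f["dff"].attrs["response_window"] = tensor.response_window
        f["dff"].attrs["valid_trials"] = tensor.valid_trials.astype(np.uint8)
    if qc is not None:
        qc.to_csv(d / "qc_trials.csv", index=False)


def read_dff(directory) -> TraceTensor:
    d = Path(directory)
    with h5py.File(d / "traces.h5", "r") as f:
        if "dff" not in f:
            raise SchemaError("traces.h5 has no /dff dataset; run preprocessing first")
        dff = f["dff"][...]
        tensor = TraceTensor(
            dff=dff,
            frame_rate=float(f.attrs["frame_rate"]),
            stim_onset_frame=int(f.attrs["stim_onset_frame"]),
            baseline_window=tuple(int(x) for x in f["dff"].attrs["baseline_window"]),
            response_window=tuple(int(x) for x in f["dff"].attrs["response_window"]),
            valid_trials=f["dff"].attrs["valid_trials"].astype(bool),
        )
    return tensor


def write_report(directory, results: dict) -> Path:
    """Write analysis outputs: DataFrames to CSV, dicts/dataclasses to JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(d / f"{name}.csv", index=False)
        else:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                obj = dataclasses.asdict(obj)
            def _default(o):
                if isinstance(o, np.ndarray):
                    return o.tolist()
                if isinstance(o, (np.integer, np.floating)):
                    return o.item()
                raise TypeError(f"not JSON serializable: {type(o)}")
            (d / f"{name}.json").write_text(json.dumps(obj, indent=1, default=_default))
    return d
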