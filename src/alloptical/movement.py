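"""Video-derived behavioral features: motion energy, lick detection, movement ROC.

Motion is quantified from frame-to-frame pixel correlation within a camera
ROI: consecutive frames without movement correlate near r = 1, so motion is
summarised as 1 - r, normalised to the session maximum.  Licking outside the
response window is read from a pose-estimation tongue-node table: a frame is
a lick frame when at least 7 of the 10 tongue-node likelihoods reach 0.7
(both thresholds inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import roc

__all__ = ["motion_energy", "normalize_session", "detect_licks", "movement_roc"]

TONGUE_COLUMNS = [f"tongue_{k}" for k in range(10)]
LICK_MIN_NODES = 7
LICK_MIN_LIKELIHOOD = 0.7


def motion_energy(frames: np.ndarray, roi: tuple[slice, slice] | None = None) -> np.ndarray:
    """Per-transition motion trace 1 - corr(frame[t], frame[t+1]) within an ROI.

    ``frames`` is (n_frames, H, W); returns n_frames - 1 values (>= 0, up to 2
    for anti-correlated frames).  Constant frames have undefined correlation;
    those transitions are set to 0.  Luminance scaling of the frames does not
    change the result.  Session-max normalisation is applied separately by
    :func:`normalize_session` so the maximum over a session is 1.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need at least two 2-D frames")
    if roi is not None:
        frames = frames[:, roi[0], roi[1]]
    if frames[0].size == 0:
        raise ValueError("empty ROI")
    flat = frames.reshape(frames.shape[0], -1)
    a = flat[:-1] - flat[:-1].mean(axis=1, keepdims=True)
    b = flat[1:] - flat[1:].mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, 1.0)
    return 1.0 - r


def normalize_session(motion: np.ndarray) -> np.ndarray:
    """Scale a session's motion values so the maximum is 1 (zero-motion safe)."""
    motion = np.asarray(motion, dtype=float)
    m = np.nanmax(motion) if motion.size else 0.0
    return motion / m if m > 0 else motion


def detect_licks(tongue_table: pd.DataFrame) -> np.ndarray:
    """Binary lick flag per frame from the 10 tongue-node likelihood columns.

    A frame is positive iff >= 7 node likelihoods are >= 0.7 (inclusive); the
    rule is monotone in every likelihood.  Missing or extra tongue columns
    raise a schema error.
    """
    cols = [c for c in tongue_table.columns if c.startswith("tongue_")]
    if sorted(cols) != sorted(TONGUE_COLUMNS):
        raise ValueError(
            f"expected exactly the 10 columns {TONGUE_COLUMNS}, found {sorted(cols)}"
        )
    lik = tongue_table[TONGUE_COLUMNS].to_numpy(dtype=float)
    return (lik >= LICK_MIN_LIKELIHOOD).sum(axis=1) >= LICK_MIN_NODES


def movement_roc(motion: np.ndarray, labels, kind: str = "DP") -> np.ndarray:
    """AUC time course of a (trials x frames) motion matrix vs. trial labels.

    Delegates to the same ROC machinery used for neural responses, one frame
    bin at a time.
    """
    return roc.roc_timecourse(np.asarray(motion, dtype=float), labels, kind)
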