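"""Neuropil correction, trial normalisation (dF/F) and evoked-response extraction.

Conventions (frames are 0-based, windows half-open):

* trials are 210 frames at 30 Hz: 1 s pre-stimulus + 6 s post-stimulus,
  stimulus onset at frame 30;
* the baseline window is frames [0, 30) (the 1 s pre-stimulus mean defines F0);
* the evoked-response window is frames [45, 60): 15 frames covering
  0.5-1.0 s post-stimulus, i.e. after the 0.5 s stimulus ends and before
  licking can contaminate the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceTensor",
    "NeuropilModel",
    "DegenerateFitError",
    "estimate_neuropil_coefficient",
    "estimate_neuropil_coefficients",
    "subtract_neuropil",
    "compute_dff",
    "evoked_response",
    "pixel_sta_stamp",
]

BASELINE_WINDOW = (0, 30)
RESPONSE_WINDOW = (45, 60)
N_FRAMES = 210
FRAME_RATE = 30.0
STIM_ONSET_FRAME = 30


class DegenerateFitError(ValueError):
    """Raised when a neuropil regression cannot be fit (constant regressor)."""


@dataclass
class TraceTensor:
    """Trial-aligned dF/F with its frame/window bookkeeping.

    dff has shape (n_neurons, n_trials, n_frames); ``valid_trials`` marks
    trials whose baseline fluorescence was usable for every neuron.
    """

    dff: np.ndarray
    frame_rate: float = FRAME_RATE
    stim_onset_frame: int = STIM_ONSET_FRAME
    baseline_window: tuple[int, int] = BASELINE_WINDOW
    response_window: tuple[int, int] = RESPONSE_WINDOW
    valid_trials: np.ndarray | None = None

    def __post_init__(self):
        self.dff = np.asarray(self.dff, dtype=float)
        if self.valid_trials is None:
            self.valid_trials = np.ones(self.dff.shape[1], dtype=bool)
        b0, b1 = self.baseline_window
        r0, r1 = self.response_window
        if not (0 <= b0 < b1 <= self.dff.shape[2]):
            raise ValueError("baseline window outside trace")
        if not (b1 <= r0 < r1 <= self.dff.shape[2]):
            raise ValueError("response window must follow the baseline inside the trace")


@dataclass
class NeuropilModel:
    """Per-neuron neuropil contamination coefficients and fit diagnostics."""

    coefficient: np.ndarray          # clipped to [0, 1]
    raw_slope: np.ndarray            # unclipped IRLS slope
    n_iterations: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_weight: np.ndarray = field(default_factory=lambda: np.array([]))


def _irls_slopes(
    soma: np.ndarray,
    neuropil: np.ndarray,
    tuning: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized robust simple regression of soma on neuropil (per row).

    Iteratively reweighted least squares with Tukey bisquare weights
    (tuning constant 4.685), intercept included, scale from the MAD of the
    residuals.  Operates on (n_units, n_samples) matrices so one call covers
    every neuron in a session.
    """
    soma = np.atleast_2d(np.asarray(soma, dtype=float))
    neuropil = np.atleast_2d(np.asarray(neuropil, dtype=float))
    n_units, n_samples = soma.shape
    slopes = np.zeros(n_units)
    iters = np.zeros(n_units, dtype=int)
    w = np.ones_like(soma)
    prev = np.full(n_units, np.inf)
    for it in range(max_iter):
        sw = w.sum(axis=1, keepdims=True)
        xbar = (w * neuropil).sum(axis=1, keepdims=True) / sw
        ybar = (w * soma).sum(axis=1, keepdims=True) / sw
        dx = neuropil - xbar
        dy = soma - ybar
        sxx = (w * dx * dx).sum(axis=1)
        sxy = (w * dx * dy).sum(axis=1)
        slopes = sxy / sxx
        intercept = (ybar - slopes[:, None] * xbar)
        resid = soma - (intercept + slopes[:, None] * neuropil)
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1)
        scale = np.where(scale <= 0, np.std(resid, axis=1) + 1e-12, scale)
        u = resid / (tuning * scale[:, None])
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        # guard: if everything got zero weight fall back to uniform
        dead = w.sum(axis=1) == 0
        if dead.any():
            w[dead] = 1.0
        iters[:] = it + 1
        if np.all(np.abs(slopes - prev) < tol * np.maximum(1.0, np.abs(slopes))):
            break
        prev = slopes.copy()
    mean_w = w.mean(axis=1)
    return slopes, iters, mean_w


def estimate_neuropil_coefficients(
    soma: np.ndarray, neuropil: np.ndarray
) -> NeuropilModel:
    """Robust-regression neuropil coefficients for many neurons at once.

    soma / neuropil: (n_neurons, n_samples) full-session (concatenated)
    fluorescence.  The slope of soma on neuropil is estimated per neuron by
    bisquare IRLS and clipped to [0, 1].
    """
    soma = np.atleast_2d(np.asarray(soma, dtype=float))
    neuropil = np.atleast_2d(np.asarray(neuropil, dtype=float))
    if soma.shape != neuropil.shape:
        raise ValueError("soma and neuropil must have the same shape")
    if soma.shape[1] < 100:
        raise ValueError("need at least 100 samples to fit the neuropil model")
    if np.any(neuropil.std(axis=1) <= 1e-12):
        raise DegenerateFitError("constant neuropil trace: coefficient undefined")
    slopes, iters, mean_w = _irls_slopes(soma, neuropil)
    return NeuropilModel(
        coefficient=np.clip(slopes, 0.0, 1.0),
        raw_slope=slopes,
        n_iterations=iters,
        mean_weight=mean_w,
    )


def estimate_neuropil_coefficient(soma, neuropil) -> float:
    """Scalar convenience wrapper around :func:`estimate_neuropil_coefficients`."""
    model = estimate_neuropil_coefficients(
        np.asarray(soma, dtype=float)[None, :], np.asarray(neuropil, dtype=float)[None, :]
    )
    return float(model.coefficient[0])


def subtract_neuropil(soma, neuropil, c) -> np.ndarray:
    """corrected = soma - c * neuropil (elementwise; c broadcasts per neuron)."""
    soma = np.asarray(soma, dtype=float)
    neuropil = np.asarray(neuropil, dtype=float)
    if soma.shape != neuropil.shape:
        raise ValueError("soma and neuropil must have the same shape")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("neuropil coefficient must lie in [0, 1]")
    if c.ndim == 1:
        c = c.reshape((-1,) + (1,) * (soma.ndim - 1))
    return soma - c * neuropil


def compute_dff(
    corrected: np.ndarray,
    baseline_window: tuple[int, int] = BASELINE_WINDOW,
    response_window: tuple[int, int] = RESPONSE_WINDOW,
    frame_rate: float = FRAME_RATE,
    stim_onset_frame: int = STIM_ONSET_FRAME,
    eps_fraction: float = 1e-6,
) -> TraceTensor:
    """Per-trial dF/F normalisation of neuropil-corrected traces.

    F0 is the mean over the baseline window of each (neuron, trial) trace and
    dF/F = (F - F0) / F0.  Trials where any neuron's F0 falls at or below
    ``eps_fraction`` times the session median fluorescence are flagged invalid
    and excluded from downstream statistics rather than offset-corrected
    (adding an offset would bias the dF/F ratio).
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.ndim == 2:  # single neuron: trials x frames
        corrected = corrected[None, ...]
    b0, b1 = baseline_window
    f0 = corrected[:, :, b0:b1].mean(axis=2)
    eps = eps_fraction * max(abs(float(np.median(corrected))), 1e-300)
    bad = f0 <= eps
    valid_trials = ~bad.any(axis=0)
    f0_safe = np.where(bad, 1.0, f0)
    dff = (corrected - f0_safe[:, :, None]) / f0_safe[:, :, None]
    dff[bad, :] = np.nan
    return TraceTensor(
        dff=dff,
        frame_rate=frame_rate,
        stim_onset_frame=stim_onset_frame,
        baseline_window=baseline_window,
        response_window=response_window,
        valid_trials=valid_trials,
    )


def evoked_response(
    tensor: TraceTensor | np.ndarray,
    trials=None,
    response_window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Mean dF/F in the evoked window per neuron per trial.

    ``trials`` optionally restricts (and orders) the trial axis; an empty
    selection yields an empty (n_neurons, 0) result.  Returns shape
    (n_neurons, n_selected_trials).
    """
    if isinstance(tensor, TraceTensor):
        dff = tensor.dff
        window = response_window or tensor.response_window
    else:
        dff = np.asarray(tensor, dtype=float)
        if dff.ndim == 2:
            dff = dff[None, ...]
        window = response_window or RESPONSE_WINDOW
    r0, r1 = window
    if trials is not None:
        trials = np.asarray(trials)
        dff = dff[:, trials, :]
    return dff[:, :, r0:r1].mean(axis=2)


def pixel_sta_stamp(
    movie: np.ndarray,
    trials,
    centroid_px: tuple[float, float],
    um_per_px: float = 470.0 / 512.0,
    stamp_um: float = 50.0,
    baseline_window: tuple[int, int] = BASELINE_WINDOW,
    response_window: tuple[int, int] = RESPONSE_WINDOW,
) -> np.ndarray:
    """Stimulus-triggered-average pixel stamp around one cell.

    ``movie`` is (n_trials, n_frames, H, W) raw fluorescence.  Each trial is
    dF/F-normalised to its 1 s pre-stimulus baseline; the response image is
    the mean over the 0.5-1 s post-stimulus window, averaged over ``trials``,
    then cropped to a square mini-FOV of side ``round(stamp_um / um_per_px)``
    pixels (54 px for 50 um at the 470/512 um/px calibration) with the cell at
    pixel (side//2, side//2).  Cells near the edge are zero-padded.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 4:
        raise ValueError("movie must be (trials, frames, H, W)")
    n_trials, n_frames, h, w = movie.shape
    cy, cx = centroid_px
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("centroid outside movie")
    trials = np.asarray(trials)
    b0, b1 = baseline_window
    r0, r1 = response_window
    sub = movie[trials]
    f0 = sub[:, b0:b1].mean(axis=1, keepdims=True)
    f0 = np.where(np.abs(f0) < 1e-12, 1.0, f0)
    dff = (sub - f0) / f0
    response = dff[:, r0:r1].mean(axis=(0, 1))
    side = int(round(stamp_um / um_per_px))
    half = side // 2
    stamp = np.zeros((side, side), dtype=float)
    cy_i, cx_i = int(round(cy)), int(round(cx))
    y0, y1 = cy_i - half, cy_i - half + side
    x0, x1 = cx_i - half, cx_i - half + side
    sy0, sy1 = max(0, -y0), side - max(0, y1 - h)
    sx0, sx1 = max(0, -x0), side - max(0, x1 - w)
    stamp[sy0:sy1, sx0:sx1] = response[max(0, y0):min(h, y1), max(0, x0):min(w, x1)]
    return stamp
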