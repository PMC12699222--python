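"""Epoch-level processing and the single-trial GLM.

The analysis regresses single-trial voltage at one electrode against the
trial-wise regressors — validity, the model-derived cue predictability
muhat1(t), and their interaction — independently at every time point, then
averages the resulting regression-weight (beta) time courses over fixed
measurement windows:

* P3a amplitude: FCz, 358 ± 40 ms (centred on the grand-average peak);
* P3b onset (early build-up slope): CPz, 200–300 ms;
* P3b amplitude: CPz, 400–600 ms.

Validity is coded ±0.5 (valid = +0.5) and belief is centred per subject,
which keeps main effects and the interaction near-orthogonal; the conversion
from a forward model formulated with 0/1 validity coding and raw belief is
the usual linear reparameterization (see :func:`convert_coefficients`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EpochArray

__all__ = [
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "REGRESSORS",
    "baseline_correct",
    "reject_epochs_jointprob",
    "grand_average_peak",
    "build_design_matrix",
    "single_trial_glm",
    "window_average",
    "convert_coefficients",
]

REGRESSORS = ("intercept", "validity", "belief", "interaction")


@dataclass(frozen=True)
class WindowSpec:
    name: str
    channel: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("window start must precede end")


DEFAULT_WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec("p3a_amp", "FCz", 318.0, 398.0),
    WindowSpec("p3b_onset", "CPz", 200.0, 300.0),
    WindowSpec("p3b_amp", "CPz", 400.0, 600.0),
)


def baseline_correct(epochs: EpochArray, baseline: tuple[float, float] = (-200.0, 0.0)) -> EpochArray:
    """Subtract the per-trial, per-channel mean over the baseline interval.

    The default baseline is the 200 ms immediately preceding the target (the
    full pre-stimulus span of the epoch container); cue-locked containers may
    pass any interval inside their span.
    """
    times = epochs.times_ms
    lo, hi = baseline
    mask = (times >= lo) & (times <= hi)
    if not mask.any() or lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"baseline {baseline} outside epoch span "
                         f"[{times[0]:.1f}, {times[-1]:.1f}] ms")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochArray(
        data=epochs.data - mean, srate_hz=epochs.srate_hz,
        t0_ms=epochs.t0_ms, channel_names=epochs.channel_names,
    )


def reject_epochs_jointprob(epochs: EpochArray, z_thresh: float = 5.0) -> np.ndarray:
    """Flag improbable epochs by their joint data probability.

    A Gaussian density is fitted per channel/sample across epochs; each
    epoch's score is the mean negative log-density of its samples, and epochs
    scoring more than ``z_thresh`` SDs above the mean score are flagged.
    This is a Gaussian surrogate for the kernel-density joint-probability
    criterion of common EEG toolboxes.

    Returns a boolean mask, True = reject.
    """
    x = epochs.data
    if x.shape[0] < 10:
        raise ValueError("joint-probability rejection needs >= 10 epochs")
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    sd = np.where(sd <= 0, 1.0, sd)
    z2 = ((x - mu) / sd) ** 2
    score = 0.5 * z2.mean(axis=(1, 2))  # neg log-density up to a constant
    s_sd = score.std(ddof=1)
    if s_sd == 0:
        return np.zeros(x.shape[0], dtype=bool)
    return score > score.mean() + z_thresh * s_sd


def grand_average_peak(
    epoch_list: list[EpochArray], channel: str, search: tuple[float, float] = (250.0, 450.0)
) -> float:
    """Latency (ms) of the grand-average maximum at a channel.

    Averages within subject over trials, then across subjects, and returns
    the latency of the maximum inside the search interval.  Ties break to the
    earliest sample.
    """
    if not epoch_list:
        raise ValueError("no epochs given")
    times = epoch_list[0].times_ms
    ci = list(epoch_list[0].channel_names).index(channel)
    grand = np.mean([e.data[:, ci, :].mean(axis=0) for e in epoch_list], axis=0)
    mask = (times >= search[0]) & (times <= search[1])
    if not mask.any():
        raise ValueError("search interval outside epoch span")
    idx = np.flatnonzero(mask)
    return float(times[idx[np.argmax(grand[idx])]])


def build_design_matrix(validity, belief) -> pd.DataFrame:
    """Single-trial design: intercept, validity ±0.5, subject-centred belief,
    and their product."""
    validity = np.asarray(validity, dtype=float)
    belief = np.asarray(belief, dtype=float)
    if len(validity) != len(belief):
        raise ValueError("validity and belief lengths differ")
    v = validity - 0.5
    b = belief - belief.mean()
    return pd.DataFrame(
        {"intercept": np.ones(len(v)), "validity": v, "belief": b,
         "interaction": v * b}
    )


def single_trial_glm(epochs: EpochArray, design: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Per-timepoint ordinary least squares of voltage on the design matrix.

    Returns a DataFrame (rows = time points, index = time in ms, columns =
    regressors) of beta estimates at the requested channel.
    """
    X = design.to_numpy(dtype=float)
    if len(design) != epochs.data.shape[0]:
        raise ValueError("design rows do not match epoch count")
    if len(design) < 10 * X.shape[1]:
        raise ValueError(
            f"too few trials ({len(design)}) for {X.shape[1]} regressors "
            f"(need >= {10 * X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending column(s) for the caller
        redundant = [
            col for j, col in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient: column(s) "
                         f"{redundant} are collinear with the others")
    ci = list(epochs.channel_names).index(channel)
    Y = epochs.data[:, ci, :]  # trials x time
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(betas.T, index=epochs.times_ms, columns=design.columns)


def window_average(betas: pd.DataFrame, window: WindowSpec) -> pd.Series:
    """Mean beta per regressor over samples with start <= t <= end (ms)."""
    times = betas.index.to_numpy(dtype=float)
    mask = (times >= window.start_ms) & (times <= window.end_ms)
    if not mask.any():
        raise ValueError(f"window {window.name} contains no samples")
    out = betas.loc[mask].mean(axis=0)
    out.name = window.name
    return out


def convert_coefficients(a0: float, a_v: float, a_p: float, a_int: float,
                         belief_mean: float) -> dict[str, float]:
    """Map forward-model coefficients (0/1 validity, raw belief) onto the
    expectation of the GLM betas under ±0.5 validity and centred belief.

    With V* = V - 1/2 and B* = B - mean(B):
    amplitude = (a0 + a_v/2 + (a_p + a_int/2) * mB) + (a_v + a_int * mB) V*
                + (a_p + a_int/2) B* + a_int V* B*,  mB = belief_mean.
    """
    return {
        "intercept": a0 + a_v / 2.0 + (a_p + a_int / 2.0) * belief_mean,
        "validity": a_v + a_int * belief_mean,
        "belief": a_p + a_int / 2.0,
        "interaction": a_int,
    }
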