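"""Per-epoch wake/sleep features from an actigraphy trace.

Two features are computed on a 30-s epoch grid:

* **mACT** -- mean activity count: the mean, over an epoch's frame
  transitions, of the per-frame count of non-zero motion estimates.  High
  during gross body movement, near zero in quiet sleep -- but also near
  zero during "motionless wake".
* **pSLP** -- "possibility of being asleep": the natural log of one plus
  the distance (in epochs) from each epoch to its nearest *high-activity*
  epoch, smoothed with a centered moving average.  An epoch is
  high-activity when its mACT exceeds the 95th percentile of mACT over the
  whole recording.  pSLP is small near movement bursts, so motionless wake
  epochs sandwiched between bursts still score "probably awake".

Both features are Min-Max normalized to [0, 1] *within each recording* to
remove between-infant amplitude differences; no cross-recording statistics
are ever used, so subject-wise cross-validation cannot leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidInputError
from .motion import ActigraphySignal

__all__ = [
    "EpochGrid",
    "FeatureTable",
    "epoch_mact",
    "high_activity_mask",
    "pslp_raw",
    "min_max_normalize",
    "compute_features",
]

HIGH_ACTIVITY_PERCENTILE = 95.0
SMOOTHING_WINDOW_MIN = 10.0


@dataclass(frozen=True)
class EpochGrid:
    """Non-overlapping epoch windows over a frame-transition index axis.

    Epoch ``i`` covers transitions ``[i*frames_per_epoch,
    (i+1)*frames_per_epoch)``; a trailing partial epoch is discarded.
    """

    epoch_length_s: float = 30.0
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0 or self.frame_rate <= 0:
            raise InvalidInputError("epoch length and frame rate must be positive")
        if self.frames_per_epoch < 1:
            raise InvalidInputError("epoch shorter than one frame transition")

    @property
    def frames_per_epoch(self) -> int:
        return int(round(self.epoch_length_s * self.frame_rate))

    def n_epochs(self, signal_length: int) -> int:
        return signal_length // self.frames_per_epoch


@dataclass
class FeatureTable:
    """Per-epoch raw and normalized features plus recording-level metadata."""

    mact_raw: np.ndarray
    pslp_raw: np.ndarray
    mact_norm: np.ndarray
    pslp_norm: np.ndarray
    high_activity_threshold: float
    high_activity_mask: np.ndarray
    epoch_length_s: float = 30.0
    degenerate_flags: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.mact_raw)

    def to_frame(self, labels: np.ndarray | None = None) -> pd.DataFrame:
        idx = np.arange(self.n_epochs)
        df = pd.DataFrame(
            {
                "epoch_index": idx,
                "onset_s": idx * self.epoch_length_s,
                "mact_raw": self.mact_raw,
                "pslp_raw": self.pslp_raw,
                "mact_norm": self.mact_norm,
                "pslp_norm": self.pslp_norm,
                "high_activity": self.high_activity_mask.astype(int),
            }
        )
        df["label"] = labels if labels is not None else ""
        return df


def epoch_mact(signal: ActigraphySignal, grid: EpochGrid,
               binary: bool = False) -> np.ndarray:
    """Mean activity count per epoch.

    With ``binary=True`` the per-frame activity is first reduced to the
    indicator ``activity > 0``, giving the fraction of frames with any
    motion instead of the mean moving-block count.
    """
    fpe = grid.frames_per_epoch
    x = np.asarray(signal.activity, dtype=float)
    if len(x) < fpe:
        raise InsufficientDataError(
            f"signal has {len(x)} samples, need at least {fpe} for one epoch"
        )
    n_ep = len(x) // fpe
    trimmed = x[: n_ep * fpe]
    if binary:
        trimmed = (trimmed > 0).astype(float)
    return trimmed.reshape(n_ep, fpe).mean(axis=1)


def high_activity_mask(mact: np.ndarray,
                       percentile: float = HIGH_ACTIVITY_PERCENTILE) -> tuple[float, np.ndarray]:
    """Threshold mACT at its within-recording percentile (default 95th).

    The threshold uses linear interpolation between order statistics; the
    mask is strict (``mact > theta``), so a constant recording has an
    all-false mask.
    """
    mact = np.asarray(mact, dtype=float)
    if mact.size == 0:
        raise InvalidInputError("need at least one epoch")
    theta = float(np.percentile(mact, percentile))
    return theta, mact > theta


def _nearest_true_distance(mask: np.ndarray) -> np.ndarray:
    """Distance in epochs from each position to the nearest True.

    Linear two-pass scan; all-False input yields ``len(mask)`` everywhere.
    """
    n = len(mask)
    big = n  # sentinel exceeding any realizable distance
    d = np.full(n, big, dtype=float)
    last = -big
    for i in range(n):
        if mask[i]:
            last = i
        d[i] = i - last
    nxt = 2 * big
    for i in range(n - 1, -1, -1):
        if mask[i]:
            nxt = i
        d[i] = min(d[i], nxt - i)
    return np.minimum(d, big)


def pslp_raw(mask: np.ndarray, grid: EpochGrid,
             smoothing_window_min: float = SMOOTHING_WINDOW_MIN) -> tuple[np.ndarray, bool]:
    """Smoothed log-distance to the nearest high-activity epoch.

    ``u_i = ln(1 + d_i)`` with ``d`` in whole epochs, then a centered
    moving average with half-width ``round(smoothing_window_min * 60 /
    (2 * epoch_length_s))`` epochs (21-epoch window at the defaults),
    truncated at the recording edges.

    Returns the smoothed values and a degenerate flag which is True when
    the mask has no high-activity epoch (pSLP is then the uninformative
    constant ``ln(1 + n_epochs)``).
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(mask)
    if n == 0:
        raise InvalidInputError("empty high-activity mask")
    if not mask.any():
        return np.full(n, np.log1p(n)), True
    u = np.log1p(_nearest_true_distance(mask))
    h = int(round(smoothing_window_min * 60.0 / (2.0 * grid.epoch_length_s)))
    if h <= 0:
        return u, False
    smoothed = (
        pd.Series(u).rolling(window=2 * h + 1, center=True, min_periods=1).mean().to_numpy()
    )
    return smoothed, False


def min_max_normalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rescale to [0, 1] by (x - min) / (max - min).

    A constant vector maps to all zeros with the degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidInputError("need at least one value")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def compute_features(signal: ActigraphySignal,
                     grid: EpochGrid | None = None,
                     percentile: float = HIGH_ACTIVITY_PERCENTILE,
                     smoothing_window_min: float = SMOOTHING_WINDOW_MIN,
                     binary_mact: bool = False) -> FeatureTable:
    """Run the full per-recording feature pipeline: mACT, the
    high-activity mask, pSLP, and within-recording Min-Max normalization.
    """
    if grid is None:
        grid = EpochGrid(frame_rate=signal.frame_rate)
    mact = epoch_mact(signal, grid, binary=binary_mact)
    theta, mask = high_activity_mask(mact, percentile)
    pslp, pslp_degenerate = pslp_raw(mask, grid, smoothing_window_min)
    mact_norm, mact_degenerate = min_max_normalize(mact)
    pslp_norm, pslp_norm_degenerate = min_max_normalize(pslp)
    return FeatureTable(
        mact_raw=mact,
        pslp_raw=pslp,
        mact_norm=mact_norm,
        pslp_norm=pslp_norm,
        high_activity_threshold=theta,
        high_activity_mask=mask,
        epoch_length_s=grid.epoch_length_s,
        degenerate_flags={
            "pslp_no_high_activity": pslp_degenerate,
            "mact_constant": mact_degenerate,
            "pslp_constant": pslp_norm_degenerate,
        },
    )
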