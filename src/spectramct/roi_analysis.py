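"""ROI-based image-quality and enhancement metrics.

Contrast enhancement is quantified per analysis channel on named regions of
interest:

* CNR (contrast-to-noise ratio): difference of tumor and background-muscle
  mean attenuation, normalized by the background standard deviation.
* SNR (signal-to-noise ratio): background mean over background standard
  deviation — a pure image-quality figure computed on muscle only.

Standard deviations are sample (ddof=1) throughout; this choice is recorded
in the stats metadata.  A right-tailed Wilcoxon rank-sum test checks
whether the tumor ROI's median attenuation significantly exceeds the
muscle ROI's.  For small samples the null distribution is enumerated
exactly over all rank splits (mid-ranks for ties); otherwise a normal
approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import ndtr

from .spectral_core import ConfigurationError, SpectralVolume, usable_channels

__all__ = [
    "ROIStats",
    "ChannelMetrics",
    "RankSumResult",
    "DegenerateBackgroundError",
    "roi_stats",
    "cnr",
    "snr",
    "ranksum_right",
    "midranks",
]

DDOF = 1  # sample standard deviation everywhere


class DegenerateBackgroundError(ValueError):
    """Background ROI has zero variance; CNR/SNR undefined."""


@dataclass
class ROIStats:
    """Per-channel first-order statistics of one ROI (attenuation, cm^-1)."""

    name: str
    n_voxels: int
    mean: np.ndarray
    std: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    ddof: int = DDOF


@dataclass
class ChannelMetrics:
    cnr: np.ndarray
    snr: np.ndarray
    signal_roi: str
    background_roi: str


def _masked_channels(v: SpectralVolume, mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != v.spatial_shape:
        raise ConfigurationError(
            f"{what} mask shape {mask.shape} != volume grid {v.spatial_shape}"
        )
    if not mask.any():
        raise ValueError(f"{what} mask is empty")
    return usable_channels(v)[mask]  # (n_voxels, 3)


def roi_stats(v: SpectralVolume, mask: np.ndarray, name: str = "roi") -> ROIStats:
    """First-order statistics over the usable channels of one ROI."""
    vals = _masked_channels(v, mask, name)
    return ROIStats(
        name=name,
        n_voxels=vals.shape[0],
        mean=vals.mean(axis=0),
        std=vals.std(axis=0, ddof=DDOF) if vals.shape[0] > 1 else np.zeros(3),
        median=np.median(vals, axis=0),
        q1=np.percentile(vals, 25, axis=0),
        q3=np.percentile(vals, 75, axis=0),
    )


def cnr(v: SpectralVolume, signal: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-channel CNR = (mean_signal - mean_background) / std_background.

    Sign is preserved; a tumor darker than muscle yields negative CNR.
    """
    sig = _masked_channels(v, signal, "signal")
    bg = _masked_channels(v, background, "background")
    bg_std = bg.std(axis=0, ddof=DDOF) if bg.shape[0] > 1 else np.zeros(3)
    if np.any(bg_std <= 0):
        raise DegenerateBackgroundError("background std is zero in some channel")
    return (sig.mean(axis=0) - bg.mean(axis=0)) / bg_std


def snr(v: SpectralVolume, background: np.ndarray) -> np.ndarray:
    """Per-channel SNR = mean / std over the background-muscle ROI."""
    bg = _masked_channels(v, background, "background")
    bg_std = bg.std(axis=0, ddof=DDOF) if bg.shape[0] > 1 else np.zeros(3)
    if np.any(bg_std <= 0):
        raise DegenerateBackgroundError("background std is zero in some channel")
    return bg.mean(axis=0) / bg_std


# ---------------------------------------------------------------------------
# Right-tailed Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with tied values sharing their average (mid-) rank."""
    values = np.asarray(values, dtype=np.float64)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@dataclass
class RankSumResult:
    statistic: float      # rank sum of the first (tumor) sample
    p_value: float        # right tail: alternative "tumor median greater"
    method: str           # "exact" | "normal"
    n: int
    m: int


def ranksum_right(
    tumor_values,
    muscle_values,
    exact_cutoff: int = 10,
    max_enumeration: int = 5_000_000,
) -> RankSumResult:
    """Right-tailed Wilcoxon rank-sum test of tumor vs muscle values.

    Tests the alternative that the tumor distribution is stochastically
    greater (its median exceeds the muscle median).  The statistic is the
    mid-rank sum of the tumor sample.  When ``min(n, m) <= exact_cutoff``
    (and the number of rank splits is tractable) the p-value is the exact
    permutation tail probability P(W >= w_obs) over all C(n+m, n) splits;
    otherwise a tie-corrected normal approximation with a 0.5 continuity
    correction is used.
    """
    x = np.asarray(tumor_values, dtype=np.float64).ravel()
    y = np.asarray(muscle_values, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    w_obs = float(ranks[:n].sum())

    if min(n, m) <= exact_cutoff and math.comb(n + m, min(n, m)) <= max_enumeration:
        k = min(n, m)
        total = math.comb(n + m, k)
        if k == n:
            # count splits whose tumor rank sum is >= observed
            hits = sum(
                1 for idx in combinations(range(n + m), k)
                if ranks[list(idx)].sum() >= w_obs - 1e-9
            )
        else:
            # enumerate the smaller (muscle) side; W_x = S_total - W_y
            s_total = ranks.sum()
            hits = sum(
                1 for idx in combinations(range(n + m), k)
                if s_total - ranks[list(idx)].sum() >= w_obs - 1e-9
            )
        return RankSumResult(w_obs, hits / total, "exact", n, m)

    mean_w = n * (n + m + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    N = n + m
    var_w = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_w <= 0:
        # all values tied: no evidence either way
        return RankSumResult(w_obs, 1.0, "normal", n, m)
    z = (w_obs - mean_w - 0.5) / math.sqrt(var_w)
    return RankSumResult(w_obs, float(1.0 - ndtr(z)), "normal", n, m)
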