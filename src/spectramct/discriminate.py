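"""Tumor discrimination from first-order attenuation statistics.

Detailed tumor vasculature is below the resolution of live-animal micro-CT,
but its imprint on the contrast-agent distribution is not: per channel, the
mean attenuation over the tumor volume tracks the average amount of agent
(perfusion), while the standard deviation tracks the heterogeneity of its
distribution — for a non-diffusible nanoparticle agent, richer vasculature
means more bright vessel voxels among unenhanced tissue and hence a larger
standard deviation.

The paired design puts both tumor models in every animal and scans them
simultaneously, so per-animal differences cancel.  For each channel and
each feature (mean, std) the per-mouse paired differences
D_i = X_A,i - X_B,i are tested with:

* a one-sample Kolmogorov-Smirnov normality check on the standardized
  differences against N(0, 1) (asymptotic p-value; the Lilliefors
  correction for estimated parameters is available but off by default,
  matching the plain one-sample usage being emulated);
* the paired t-test, t = (Dbar - mu_D) / (S_D / sqrt(n)) ~ t_{n-1} under
  H0: mu_D = 0, with S_D the sample standard deviation of the differences
  and a two-sided p-value P(|t_{n-1}| > |t_obs|) computed through the
  regularized incomplete beta function.

The report also decides 2-D linear separability of the two models in each
channel's (mean, std) plane by exact convex-hull disjointness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, kolmogorov, ndtr
from shapely.geometry import MultiPoint

from .spectral_core import ConfigurationError, SpectralVolume
from .roi_analysis import DDOF, _masked_channels

__all__ = [
    "TumorFeatures",
    "NormalityResult",
    "PairedTestResult",
    "DegenerateVarianceError",
    "tumor_features",
    "ks_normality",
    "paired_t_test",
    "student_t_sf",
    "linearly_separable",
    "DiscriminationReport",
    "discrimination_report",
]


class DegenerateVarianceError(ValueError):
    """Zero variance where a test statistic needs a positive one."""


@dataclass
class TumorFeatures:
    """Per-channel mean/std attenuation (cm^-1) over one full tumor mask."""

    tumor_id: str
    mouse_id: str
    model: str
    mean: np.ndarray   # (3,) usable channels
    std: np.ndarray    # (3,) sample std
    n_voxels: int = 0
    partial_coverage: bool = False


def tumor_features(
    v: SpectralVolume,
    tumor_mask: np.ndarray,
    tumor_id: str = "tumor",
    mouse_id: str = "mouse",
    model: str = "",
) -> TumorFeatures:
    """Extract mean and sample std per usable channel over a tumor mask.

    Tumors touching the axial (z) boundary of the grid are flagged as
    partially covered — a circular scan's limited axial field of view can
    truncate them — but are not excluded.
    """
    vals = _masked_channels(v, tumor_mask, "tumor")
    mask = np.asarray(tumor_mask).astype(bool)
    partial = bool(mask[:, :, 0].any() or mask[:, :, -1].any())
    return TumorFeatures(
        tumor_id=tumor_id,
        mouse_id=mouse_id,
        model=model,
        mean=vals.mean(axis=0),
        std=vals.std(axis=0, ddof=DDOF) if vals.shape[0] > 1 else np.zeros(3),
        n_voxels=vals.shape[0],
        partial_coverage=partial,
    )


# ---------------------------------------------------------------------------
# One-sample KS normality check
# ---------------------------------------------------------------------------

@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    standardized: bool
    n: int
    lilliefors: bool = False


def ks_normality(d, standardize: bool = True, lilliefors: bool = False) -> NormalityResult:
    """One-sample Kolmogorov-Smirnov check of normality.

    The data are standardized (sample mean and std removed) and compared to
    the standard normal CDF Phi.  The sup-distance over the order
    statistics z_(1) <= ... <= z_(n) is

        D = max_i max( i/n - Phi(z_(i)), Phi(z_(i)) - (i-1)/n ),

    with the p-value from the asymptotic Kolmogorov distribution of
    sqrt(n) * D.  Because standardizing estimates the null parameters the
    plain p-value is conservative; ``lilliefors=True`` switches to the
    Lilliefors table-based p-value instead.
    """
    d = np.asarray(d, dtype=np.float64).ravel()
    if d.size < 3:
        raise ValueError("need at least 3 values for a normality check")
    sd = d.std(ddof=DDOF)
    if sd == 0:
        raise DegenerateVarianceError("constant input: normality undefined")
    z = (d - d.mean()) / sd if standardize else d
    n = z.size
    zs = np.sort(z)
    cdf = ndtr(zs)
    i = np.arange(1, n + 1)
    stat = float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(d, dist="norm", pvalmethod="table")
        p = float(p)
    else:
        p = float(kolmogorov(math.sqrt(n) * stat))
    return NormalityResult(statistic=stat, p_value=p, standardized=standardize,
                           n=n, lilliefors=lilliefors)


# ---------------------------------------------------------------------------
# Paired t-test via the regularized incomplete beta function
# ---------------------------------------------------------------------------

def student_t_sf(t: float, df: int) -> float:
    """P(T > t) for Student's t with ``df`` degrees of freedom.

    Uses the identity P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2) with I the
    regularized incomplete beta function, which ties the p-value directly
    to a well-conditioned special function.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if t == 0:
        return 0.5
    two_sided = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    one_sided = 0.5 * two_sided
    return one_sided if t > 0 else 1.0 - one_sided


@dataclass
class PairedTestResult:
    """Result of the paired t-test on differences D_i = X1_i - X2_i."""

    n: int
    differences: np.ndarray
    mean_difference: float     # Dbar
    std_difference: float      # S_D, sample std of the differences
    t: float
    df: int
    p_value: float             # two-sided
    alpha: float
    reject: bool


def paired_t_test(x1, x2, alpha: float = 0.05, mu_d: float = 0.0) -> PairedTestResult:
    """Two-sided paired t-test of H0: mu_D = mu_d on paired observations.

    t = (Dbar - mu_d) / (S_D / sqrt(n)) with df = n - 1 and
    p = P(|t_{n-1}| > |t_obs|).  Raises on length mismatch and on S_D = 0
    (a constant shift between the samples carries no usable variance).
    """
    x1 = np.asarray(x1, dtype=np.float64).ravel()
    x2 = np.asarray(x2, dtype=np.float64).ravel()
    if x1.size != x2.size:
        raise ValueError(f"length mismatch: {x1.size} vs {x2.size}")
    n = x1.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x1 - x2
    d_bar = float(d.mean())
    s_d = float(d.std(ddof=1))
    if s_d == 0:
        raise DegenerateVarianceError("paired differences have zero variance")
    t = (d_bar - mu_d) / (s_d / math.sqrt(n))
    p = 2.0 * student_t_sf(abs(t), n - 1)
    return PairedTestResult(
        n=n, differences=d, mean_difference=d_bar, std_difference=s_d,
        t=float(t), df=n - 1, p_value=min(p, 1.0), alpha=alpha,
        reject=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# Linear separability and the cohort report
# ---------------------------------------------------------------------------

def linearly_separable(points_a: np.ndarray, points_b: np.ndarray) -> bool:
    """Exact 2-D linear separability via convex-hull disjointness.

    Two finite point sets admit a separating line iff their convex hulls do
    not intersect.  Intended for the small cohorts of a paired design
    (n <= ~12 per side); degenerate hulls (points, segments) are handled.
    """
    a = np.asarray(points_a, dtype=np.float64).reshape(-1, 2)
    b = np.asarray(points_b, dtype=np.float64).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both point sets must be non-empty")
    hull_a = MultiPoint([tuple(p) for p in a]).convex_hull
    hull_b = MultiPoint([tuple(p) for p in b]).convex_hull
    return not hull_a.intersects(hull_b)


@dataclass
class DiscriminationReport:
    """Paired-test and separability summary over a cohort of tumors."""

    model_a: str
    model_b: str
    n_pairs: int
    alpha: float
    features: pd.DataFrame        # one row per tumor, scatter-ready
    tests: pd.DataFrame           # one row per (channel, feature)
    separable: dict[int, bool]    # channel -> separability in (mean, std)
    separable_highlight: bool     # channels 1 and 2 jointly separable
    partial_coverage: list[str]


def discrimination_report(
    features: list[TumorFeatures],
    model_a: str,
    model_b: str,
    alpha: float = 0.05,
    lilliefors: bool = False,
) -> DiscriminationReport:
    """Run the full discrimination pipeline on extracted tumor features.

    Requires every mouse to contribute exactly one tumor of each model.
    Per channel and per feature (mean, std): KS normality of the paired
    differences, then the paired t-test.  Separability is evaluated in each
    channel's (mean, std) plane; the highlighted flag reports channels 1
    and 2 jointly (both planes separable).
    """
    by_mouse: dict[str, dict[str, TumorFeatures]] = {}
    for f in features:
        if f.model not in (model_a, model_b):
            raise ConfigurationError(f"feature with unknown model {f.model!r}")
        slot = by_mouse.setdefault(f.mouse_id, {})
        if f.model in slot:
            raise ValueError(f"mouse {f.mouse_id!r} has two {f.model!r} tumors")
        slot[f.model] = f
    incomplete = [m for m, s in by_mouse.items() if len(s) != 2]
    if incomplete:
        raise ValueError(f"unpaired design: mice {incomplete} lack one model")
    mice = sorted(by_mouse)
    if len(mice) < 2:
        raise ValueError("need at least 2 mice for a paired test")

    rows = []
    for f in features:
        for c in range(3):
            rows.append({
                "mouse": f.mouse_id, "tumor": f.tumor_id, "model": f.model,
                "channel": c + 1, "mean": f.mean[c], "std": f.std[c],
                "n_voxels": f.n_voxels,
            })
    feat_df = pd.DataFrame(rows)

    tests = []
    for c in range(3):
        for feat in ("mean", "std"):
            xa = np.array([getattr(by_mouse[m][model_a], feat)[c] for m in mice])
            xb = np.array([getattr(by_mouse[m][model_b], feat)[c] for m in mice])
            ks = ks_normality(xa - xb, lilliefors=lilliefors)
            tt = paired_t_test(xa, xb, alpha=alpha)
            tests.append({
                "channel": c + 1, "feature": feat,
                "ks_statistic": ks.statistic, "ks_p": ks.p_value,
                "normality_ok": ks.p_value > alpha,
                "t": tt.t, "df": tt.df, "p": tt.p_value,
                "mean_difference": tt.mean_difference,
                "std_difference": tt.std_difference,
                "reject": tt.reject,
            })
    tests_df = pd.DataFrame(tests)

    separable = {}
    for c in range(3):
        pts_a = np.array([[by_mouse[m][model_a].mean[c], by_mouse[m][model_a].std[c]]
                          for m in mice])
        pts_b = np.array([[by_mouse[m][model_b].mean[c], by_mouse[m][model_b].std[c]]
                          for m in mice])
        separable[c + 1] = linearly_separable(pts_a, pts_b)

    partial = sorted(
        f"{f.mouse_id}/{f.tumor_id}" for f in features if f.partial_coverage
    )
    return DiscriminationReport(
        model_a=model_a, model_b=model_b, n_pairs=len(mice), alpha=alpha,
        features=feat_df, tests=tests_df, separable=separable,
        separable_highlight=separable[1] and separable[2],
        partial_coverage=partial,
    )
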