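"""Method-agreement statistics for paired T1W / two-point-Dixon percents.

Covers the full diagnostic toolkit for inter-method discrepancy:

* unpaired (pooled-variance) Student t comparison of method samples;
* Bland-Altman 95% limits of agreement with a proportional-bias test
  (Pearson correlation of difference against mean).  The difference
  convention is ``d = 2PD − T1W``, so T1W overestimation at high fat
  content shows up as a *negative* proportional-bias correlation;
* ICC(2,1): two-way random-effects, absolute-agreement, single-measure
  intraclass correlation, from the ANOVA mean-squares plug-in;
* the boundary-value analysis: the T1W intensity whose exceedance
  fraction reproduces a muscle's Dixon percent, and the correlation of
  the IntraMAT discrepancy with the threshold/boundary intensity gap;
* subtraction-method SNR from a difference of two acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image import Image2D

__all__ = [
    "PairedSample", "TTestResult", "BlandAltmanResult", "ICCResult",
    "BoundaryValueResult", "SNRResult",
    "unpaired_t_test", "bland_altman", "icc_2_1", "boundary_value",
    "make_boundary_record", "discrepancy_analysis", "snr_subtraction",
    "corner_rois", "compare_groups", "bland_altman_plot",
]


@dataclass
class PairedSample:
    """Both methods' IntraMAT percents for one (subject, muscle)."""

    subject: str | int
    muscle: str | int
    t1w_percent: float
    dixon_percent: float


@dataclass
class TTestResult:
    t: float
    p: float
    df: float


@dataclass
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_bias_r: float   # NaN when the differences have no spread
    proportional_bias_p: float

    @property
    def proportional_bias(self) -> bool:
        """Proportional bias declared at two-tailed p < 0.05."""
        return bool(np.isfinite(self.proportional_bias_p)
                    and self.proportional_bias_p < 0.05)


@dataclass
class ICCResult:
    value: float
    var_subjects: float
    var_sessions: float
    var_residual: float
    n_subjects: int
    k_sessions: int


@dataclass
class BoundaryValueResult:
    """Per-(subject, muscle) threshold-equivalence record.

    ``boundary_value`` is the T1W intensity whose exceedance fraction
    equals the Dixon percent.  ``delta_intensity = boundary − threshold``
    and ``delta_intramat = dixon − t1w``: when the working threshold sits
    below the boundary, T1W over-counts fat, so large positive intensity
    gaps pair with strongly negative IntraMAT differences.
    """

    subject: str | int
    muscle: str | int
    t1w_threshold: float
    boundary_value: float
    delta_intensity: float
    delta_intramat: float


@dataclass
class SNRResult:
    roi: int
    signal_mean: float
    diff_sd: float
    snr: float   # signal_mean / (diff_sd / sqrt(2)); inf when diff_sd == 0


def unpaired_t_test(x: Sequence[float], y: Sequence[float],
                    welch: bool = False) -> TTestResult:
    """Two-sample Student t-test (pooled variance; Welch via flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) + y.var(ddof=1) == 0:
        raise ValueError("degenerate samples: zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if welch else float(x.size + y.size - 2)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df)


def bland_altman(pairs: Iterable[PairedSample] | None = None, *,
                 t1w: Sequence[float] | None = None,
                 dixon: Sequence[float] | None = None,
                 direction: str = "dixon-t1w") -> BlandAltmanResult:
    """Bland-Altman agreement of the two methods.

    Accepts either an iterable of :class:`PairedSample` or the two value
    arrays.  Differences follow ``direction`` (default ``dixon-t1w``,
    i.e. d = 2PD − T1W); limits of agreement are mean ± 1.96 SD, and
    proportional bias is the Pearson correlation of d against the pair
    mean (NaN sentinel when the differences have zero variance).
    """
    if pairs is not None:
        pairs = list(pairs)
        t1w = [p.t1w_percent for p in pairs]
        dixon = [p.dixon_percent for p in pairs]
    a = np.asarray(t1w, dtype=float)
    b = np.asarray(dixon, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be two equal-length 1-D arrays")
    if a.size < 3:
        raise ValueError("Bland-Altman needs n >= 3 pairs")
    if direction == "dixon-t1w":
        d = b - a
    elif direction == "t1w-dixon":
        d = a - b
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    mean_pair = (a + b) / 2.0
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd > 0 and mean_pair.std() > 0:
        r, p = stats.pearsonr(d, mean_pair)
        r, p = float(r), float(p)
    else:
        r, p = math.nan, math.nan
    return BlandAltmanResult(n=a.size, mean_diff=md, sd_diff=sd,
                             loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd,
                             proportional_bias_r=r, proportional_bias_p=p)


def icc_2_1(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a complete subjects × sessions matrix.  From the
    two-way ANOVA mean squares (rows MSR, columns MSC, residual MSE):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x sessions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance in the ratings")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(value=float(icc),
                     var_subjects=float(max(msr - mse, 0.0) / k),
                     var_sessions=float(max(msc - mse, 0.0) / n),
                     var_residual=float(mse),
                     n_subjects=n, k_sessions=k)


def boundary_value(t1w_image: Image2D, muscle_mask: np.ndarray,
                   target_percent: float) -> float:
    """T1W intensity whose exceedance fraction matches a target percent.

    Returns the smallest masked intensity ``t`` such that the fraction of
    mask pixels strictly above ``t`` is at most ``target_percent/100``
    (the (1 − target/100) empirical quantile under the same strict
    exceedance rule the T1W classifier uses).  Re-thresholding at the
    returned value reproduces the target within one pixel quantum.
    """
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    if not muscle_mask.any():
        raise ValueError("empty muscle mask")
    if not 0.0 <= target_percent <= 100.0:
        raise ValueError("target percent must lie in [0, 100]")
    vals = np.sort(t1w_image.data[muscle_mask])[::-1]  # descending
    n = vals.size
    j = min(int(np.floor(target_percent / 100.0 * n)), n - 1)
    return float(vals[j])


def make_boundary_record(subject: str | int, muscle: str | int,
                         t1w_image: Image2D, muscle_mask: np.ndarray,
                         t1w_threshold: float, t1w_percent: float,
                         dixon_percent: float) -> BoundaryValueResult:
    """Assemble a threshold-equivalence record for one (subject, muscle)."""
    bv = boundary_value(t1w_image, muscle_mask, dixon_percent)
    return BoundaryValueResult(
        subject=subject, muscle=muscle,
        t1w_threshold=float(t1w_threshold), boundary_value=bv,
        delta_intensity=bv - float(t1w_threshold),
        delta_intramat=float(dixon_percent) - float(t1w_percent),
    )


def discrepancy_analysis(records: Sequence[BoundaryValueResult]
                         ) -> tuple[float, float]:
    """Pearson correlation of ΔIntraMAT against Δintensity across records."""
    if len(records) < 3:
        raise ValueError("need >= 3 records")
    di = np.array([r.delta_intensity for r in records], dtype=float)
    dm = np.array([r.delta_intramat for r in records], dtype=float)
    if di.std() == 0 or dm.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(dm, di)
    return float(r), float(p)


def corner_rois(shape: tuple[int, int], size: int,
                margin: int = 0) -> list[tuple[int, int, int]]:
    """Four same-size square ROIs at the image corners (ROI 1–4).

    Ordered top-left, top-right, bottom-left, bottom-right; each entry is
    ``(row0, col0, size)``.  The numbering is a package convention — the
    corners carry no anatomical meaning of their own.
    """
    h, w = shape
    if 2 * (margin + size) > min(h, w):
        raise ValueError("corner ROIs would overlap or leave the image")
    m = margin
    return [(m, m, size), (m, w - m - size, size),
            (h - m - size, m, size), (h - m - size, w - m - size, size)]


def snr_subtraction(img_a: Image2D, img_b: Image2D,
                    rois: Sequence[tuple[int, int, int]]) -> list[SNRResult]:
    """Subtraction-method SNR per ROI.

    For each ROI: signal = mean of (a+b)/2, noise sd = SD of (a−b), and
    SNR = signal / (noise sd / √2).  A zero difference SD (e.g. the two
    images are identical) yields the infinite-SNR sentinel.
    """
    if img_a.shape != img_b.shape:
        raise ValueError("images must share geometry")
    out = []
    for i, (r0, c0, size) in enumerate(rois, start=1):
        if r0 < 0 or c0 < 0 or r0 + size > img_a.shape[0] or c0 + size > img_a.shape[1]:
            raise ValueError(f"ROI {i} outside image bounds")
        a = img_a.data[r0:r0 + size, c0:c0 + size]
        b = img_b.data[r0:r0 + size, c0:c0 + size]
        signal = float(((a + b) / 2.0).mean())
        diff_sd = float((a - b).std(ddof=1))
        snr = math.inf if diff_sd == 0 else signal / (diff_sd / math.sqrt(2.0))
        out.append(SNRResult(roi=i, signal_mean=signal, diff_sd=diff_sd, snr=snr))
    return out


def compare_groups(df: pd.DataFrame, value: str = "intramat_percent",
                   group: str = "group", muscle: str = "muscle",
                   method: str = "method", welch: bool = False) -> pd.DataFrame:
    """Per-(muscle, method) group comparison, mirroring a cohort table.

    Expects a tidy frame with one row per (subject, muscle, method) and a
    two-level group column; returns one row per muscle × method with each
    group's mean ± SD and range plus the unpaired t-test.
    """
    groups = sorted(df[group].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    rows = []
    for (mus, met), sub in df.groupby([muscle, method], sort=True):
        g0 = sub.loc[sub[group] == groups[0], value].to_numpy(dtype=float)
        g1 = sub.loc[sub[group] == groups[1], value].to_numpy(dtype=float)
        res = unpaired_t_test(g0, g1, welch=welch)
        rows.append({
            muscle: mus, method: met,
            f"{groups[0]}_mean": g0.mean(), f"{groups[0]}_sd": g0.std(ddof=1),
            f"{groups[0]}_min": g0.min(), f"{groups[0]}_max": g0.max(),
            f"{groups[1]}_mean": g1.mean(), f"{groups[1]}_sd": g1.std(ddof=1),
            f"{groups[1]}_min": g1.min(), f"{groups[1]}_max": g1.max(),
            "t": res.t, "p": res.p, "significant": res.p < 0.05,
        })
    return pd.DataFrame(rows)


def bland_altman_plot(result: BlandAltmanResult, t1w: Sequence[float],
                      dixon: Sequence[float], path: str,
                      title: str = "") -> None:
    """Write a Bland-Altman scatter (difference vs mean) to ``path``."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    a = np.asarray(t1w, dtype=float)
    b = np.asarray(dixon, dtype=float)
    d = b - a
    m = (a + b) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=18, color="k")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.axhline(result.mean_diff, color="C0", label="mean difference")
    for lim in (result.loa_low, result.loa_high):
        ax.axhline(lim, color="C0", ls="--", lw=0.9)
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("2PD − T1W (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
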