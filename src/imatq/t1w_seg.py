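"""T1-weighted IntraMAT quantification by reference-ROI Otsu thresholding.

The T1W pipeline mirrors the manual protocol used on 3 T thigh images:
six 25-mm² regions of interest — three on the vastus intermedius (pure
skeletal muscle) and three on subcutaneous adipose tissue — supply a
pooled pixel-intensity histogram; Otsu's criterion picks the threshold
separating the muscle and fat classes; the mean threshold of three
independent ROI placements is applied to every analyzed muscle of the
subject.  Pixels at or below the threshold count as skeletal muscle,
pixels above it as intramuscular adipose tissue (IntraMAT), and

    IntraMAT content (%) = n_fat / (n_muscle + n_fat) × 100.

Manual ROI placement is irreproducible, so placement here is randomized
over fully interior, non-overlapping sites; trial-to-trial threshold
variation therefore mimics tracing-induced error while staying seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import Image2D, LabelMask
from .phantom import SUBCUT_FAT, VI

__all__ = [
    "ROI", "ROISet", "HistogramModel", "ThresholdResult", "MuscleQuant",
    "place_rois", "build_reference_histogram", "otsu_threshold",
    "threshold_trials", "quantify_t1w", "compute_csa",
]


@dataclass
class ROI:
    tag: str          # "muscle_reference" | "fat_reference"
    anchor: tuple[int, int]   # top-left pixel (row, col), 0-based
    side: int         # square edge, pixels

    @property
    def center(self) -> tuple[int, int]:
        return (self.anchor[0] + self.side // 2, self.anchor[1] + self.side // 2)

    def pixels(self, image: Image2D) -> np.ndarray:
        r, c = self.anchor
        return image.data[r:r + self.side, c:c + self.side].ravel()


@dataclass
class ROISet:
    """Reference regions: three on pure muscle, three on subcutaneous fat."""

    rois: list[ROI]
    area_mm2: float = 25.0

    def __iter__(self):
        return iter(self.rois)

    def pooled_pixels(self, image: Image2D) -> np.ndarray:
        return np.concatenate([roi.pixels(image) for roi in self.rois])


@dataclass
class HistogramModel:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.bin_edges[0]), float(self.bin_edges[-1])


@dataclass
class ThresholdResult:
    trials: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.trials))

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class MuscleQuant:
    muscle: int | str
    n_muscle_pixels: int      # intensity <= threshold
    n_fat_pixels: int         # intensity >  threshold
    intramat_percent: float
    csa_cm2: float


def _square_side(area_mm2: float, spacing: float) -> int:
    return max(1, int(np.floor(np.sqrt(area_mm2) / spacing + 0.5)))


def place_rois(labels: LabelMask, rng: np.random.Generator,
               muscle_label: int = VI, fat_label: int = SUBCUT_FAT,
               n_per_tag: int = 3, roi_area_mm2: float = 25.0) -> ROISet:
    """Randomly place square reference ROIs fully inside their labels.

    Each ROI is a square of side ``round(sqrt(area)/spacing)`` pixels
    (25 mm² → 5×5 px at 1 mm spacing).  ROIs of the same tag must not
    overlap; placement is deterministic under a seeded generator.

    Raises
    ------
    ValueError
        If a label cannot host ``n_per_tag`` disjoint interior squares.
    """
    side = _square_side(roi_area_mm2, labels.spacing)
    out: list[ROI] = []
    for label, tag in ((muscle_label, "muscle_reference"),
                       (fat_label, "fat_reference")):
        region = labels.region(label)
        if min(region.shape) < side:
            raise ValueError(f"label {label} too small to host a {side}px ROI")
        windows = sliding_window_view(region, (side, side))
        valid = windows.all(axis=(2, 3))
        anchors = np.argwhere(valid)
        if len(anchors) < n_per_tag:
            raise ValueError(
                f"label {label} too small to host {n_per_tag} interior ROIs"
            )
        chosen: list[np.ndarray] = []
        for idx in rng.permutation(len(anchors)):
            cand = anchors[idx]
            if all(max(abs(int(cand[0]) - int(a[0])), abs(int(cand[1]) - int(a[1]))) >= side
                   for a in chosen):
                chosen.append(cand)
                if len(chosen) == n_per_tag:
                    break
        if len(chosen) < n_per_tag:
            raise ValueError(
                f"label {label} cannot host {n_per_tag} non-overlapping ROIs"
            )
        out.extend(ROI(tag, (int(a[0]), int(a[1])), side) for a in chosen)
    return ROISet(out, roi_area_mm2)


def build_reference_histogram(image: Image2D, rois: ROISet,
                              n_bins: int = 256) -> HistogramModel:
    """Histogram of the pooled intensities of all reference ROIs."""
    pooled = rois.pooled_pixels(image)
    if not np.all(np.isfinite(pooled)):
        raise ValueError("non-finite intensities inside the reference ROIs")
    vmin, vmax = float(pooled.min()), float(pooled.max())
    if vmax == vmin:
        raise ValueError("degenerate intensity range: all ROI pixels equal")
    counts, edges = np.histogram(pooled, bins=n_bins, range=(vmin, vmax))
    return HistogramModel(edges, counts, pooled.size)


def otsu_threshold(hist: HistogramModel) -> float:
    """Threshold maximizing between-class variance ω₀ω₁(μ₀−μ₁)².

    Returns the upper edge of the winning bin ``k*`` (class 0 = bins
    0..k*, class 1 = the rest); ties break toward the lowest cut.  Cuts
    whose floating-point objectives are indistinguishable from the
    maximum are re-compared in exact rational arithmetic, so the
    tie-break is the mathematical one, not a rounding accident.
    """
    c = hist.counts.astype(float)
    if int(np.count_nonzero(c)) < 2:
        raise ValueError("histogram needs at least two nonempty bins")
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    w = np.cumsum(c)
    m = np.cumsum(c * centers)
    total_w, total_m = w[-1], m[-1]
    w0, m0 = w[:-1], m[:-1]
    w1 = total_w - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total_m - m0) / w1
        objective = w0 * w1 * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0)
    objective[~valid] = -np.inf
    best = objective.max()
    near = np.flatnonzero(valid & (objective >= best * (1.0 - 1e-9)))
    if len(near) > 1:
        k = _exact_otsu_argmax(hist.counts, centers, near)
    else:
        k = int(near[0])
    return float(hist.bin_edges[k + 1])


def _exact_otsu_argmax(counts: np.ndarray, centers: np.ndarray,
                       candidates: np.ndarray) -> int:
    """Exact rational comparison of near-tied cuts; lowest index wins ties."""
    from fractions import Fraction

    cf = [Fraction(float(x)) for x in counts]
    xf = [Fraction(float(x)) for x in centers]
    tw = sum(cf)
    tm = sum(ci * xi for ci, xi in zip(cf, xf))
    best_obj, best_k = None, None
    for k in sorted(int(i) for i in candidates):
        w0 = sum(cf[:k + 1])
        w1 = tw - w0
        m0 = sum(ci * xi for ci, xi in zip(cf[:k + 1], xf))
        # sigma_b = w0*w1*(mu0-mu1)^2 = (m0*tw - w0*tm)^2 / (w0*w1)
        obj = (m0 * tw - w0 * tm) ** 2 / (w0 * w1)
        if best_obj is None or obj > best_obj:
            best_obj, best_k = obj, k
    return best_k


def threshold_trials(image: Image2D, labels: LabelMask,
                     rng: np.random.Generator, n_trials: int = 3,
                     n_bins: int = 256, **roi_kwargs) -> ThresholdResult:
    """Repeat ROI placement → histogram → Otsu; average the trials.

    One subject-level mean threshold serves all analyzed muscles.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trials = []
    for _ in range(n_trials):
        rois = place_rois(labels, rng, **roi_kwargs)
        hist = build_reference_histogram(image, rois, n_bins)
        trials.append(otsu_threshold(hist))
    return ThresholdResult(trials)


def quantify_t1w(image: Image2D, muscle_mask: np.ndarray, threshold: float,
                 muscle: int | str = "") -> MuscleQuant:
    """Classify muscle-mask pixels against a threshold and report IntraMAT.

    Pixels with intensity strictly above the threshold are IntraMAT;
    pixels at or below it are skeletal muscle.
    """
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    n = int(muscle_mask.sum())
    if n == 0:
        raise ValueError("empty muscle mask")
    vals = image.data[muscle_mask]
    n_fat = int(np.count_nonzero(vals > threshold))
    n_mus = n - n_fat
    return MuscleQuant(
        muscle=muscle,
        n_muscle_pixels=n_mus,
        n_fat_pixels=n_fat,
        intramat_percent=100.0 * n_fat / n,
        csa_cm2=compute_csa(muscle_mask, image.spacing),
    )


def compute_csa(mask: np.ndarray, spacing: float) -> float:
    """Cross-sectional area of a mask in cm² (pixel count × spacing² / 100)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    return n * spacing ** 2 / 100.0
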