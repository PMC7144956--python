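"""Synthetic mid-thigh phantom with exact, known ground truth.

Generates spatially matched T1-weighted and two-point-Dixon (water/fat)
axial slices of a parametric mid-thigh cross-section: four named muscle
compartments (vastus lateralis, vastus intermedius, adductor magnus,
biceps femoris long head) embedded in a filler-muscle interior, a
subcutaneous fat ring, a femur, and air background.  Intramuscular fat is
planted pixel-exactly (``round(p·N)`` fat pixels per muscle), so every
downstream stage can be validated against quantized ground truth rather
than an expected value.

The vastus intermedius is kept fat-free by construction: it is the pure
skeletal-muscle reference tissue on which the T1W reference ROIs are
placed.  A smooth multiplicative bias field (coil-shading surrogate) and
Gaussian (optionally Rician) noise corrupt the channels; both the field
and the per-pixel fat fraction are retained as ground truth.

Partial-volume model
--------------------
A band of configurable width around every fat cluster receives a mixed
fat fraction, decaying with Euclidean distance ``d`` from the cluster as
``(1 - d/(w+1)) ** partial_volume_exponent`` (linear ramp by default);
the voxel intensity is the consistent linear water/fat mix of that
fraction.  These mixed voxels are what drive the inter-method
discrepancy: the reference-ROI Otsu threshold settles at the upper edge
of the pure-muscle peak, so threshold binarization counts every mixed
voxel as fully fat while the Dixon ratio integrates its fat content
fractionally.  The band width — physically a property of the scanner's
point-spread function, hence constant across a cohort — is the knob for
synthetic proportional-bias experiments; width 0 gives pixel-exact
two-phase tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .image import Image2D, LabelMask

__all__ = [
    "BACKGROUND", "VL", "VI", "AM", "BFL", "SUBCUT_FAT", "FEMUR", "OTHER",
    "LABEL_NAMES", "NAME_TO_LABEL", "MUSCLES", "ANALYSIS_MUSCLES",
    "PhantomSpec", "PhantomSet",
    "default_geometry", "make_phantom", "sample_fat_mask", "apply_bias_field",
]

# Compartment ids (stable across the package; CSV outputs carry the names).
BACKGROUND = 0
VL = 1          # vastus lateralis
VI = 2          # vastus intermedius (pure-muscle reference)
AM = 3          # adductor magnus
BFL = 4         # biceps femoris, long head
SUBCUT_FAT = 5  # subcutaneous adipose ring
FEMUR = 6
OTHER = 7       # unmodelled interior musculature (filler)

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    VL: "VL",
    VI: "VI",
    AM: "AM",
    BFL: "BF-L",
    SUBCUT_FAT: "subcutaneous_fat",
    FEMUR: "femur",
    OTHER: "other_muscle",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

MUSCLES = (VL, VI, AM, BFL)
#: muscles quantified by both pipelines (VI is reference tissue, not analyzed)
ANALYSIS_MUSCLES = (VL, AM, BFL)

_SOFT_TISSUE = (VL, VI, AM, BFL, OTHER, SUBCUT_FAT)


def default_geometry() -> dict:
    """Parametric mid-thigh geometry, all entries in mm (row, col, semi-axes).

    Ellipses approximate a right mid-thigh: femur slightly anterior of
    centre wrapped by the vastus intermedius, vastus lateralis lateral,
    adductor magnus medial-posterior, biceps femoris long head posterior.
    """
    return {
        "thigh": (128.0, 128.0, 105.0, 95.0),
        "fat_ring_thickness": 10.0,
        VI: (100.0, 128.0, 32.0, 36.0),
        FEMUR: (100.0, 128.0, 13.0, 13.0),
        VL: (100.0, 175.0, 30.0, 22.0),
        AM: (150.0, 85.0, 32.0, 24.0),
        BFL: (175.0, 160.0, 26.0, 26.0),
    }


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic subject.

    Intensity units are arbitrary (a.u.); the defaults put pure muscle at
    100 and pure fat at 200 with noise sd 5 (5% of the muscle signal) —
    roughly the contrast and SNR regime of 3 T T1-weighted thigh imaging.
    Default per-muscle fat fractions sit at the cohort means reported for
    healthy adults (≈9–13%).
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_spacing: float = 1.0               # mm / pixel, isotropic
    geometry: dict = field(default_factory=default_geometry)
    muscle_mean_intensity: float = 100.0     # a.u.
    fat_mean_intensity: float = 200.0        # a.u.; must exceed muscle
    femur_intensity_factor: float = 0.4      # cortical bone, relative to muscle
    noise_sd: float = 5.0                    # a.u., all three channels
    fat_fractions: dict[int, float] = field(
        default_factory=lambda: {VL: 0.12, AM: 0.09, BFL: 0.13}
    )
    marbling_scale: float = 3.0              # mm, infiltration correlation length
    partial_volume_width: float = 2.5        # pixels; 0 disables the band
    partial_volume_exponent: float = 1.0     # shape of the band fat-fraction ramp
    bias_amplitude: float = 0.2              # peak multiplicative deviation from 1
    bias_scale: float = 50.0                 # mm, Gaussian σ of the field
    rician_noise: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.fat_mean_intensity <= self.muscle_mean_intensity:
            raise ValueError("fat_mean_intensity must exceed muscle_mean_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.partial_volume_width < 0:
            raise ValueError("partial_volume_width must be nonnegative")
        for m, p in self.fat_fractions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fat fraction for label {m} outside [0, 1]: {p}")
            if m == VI and p > 0:
                raise ValueError(
                    "vastus intermedius is the pure-muscle reference; "
                    "its fat fraction is fixed at 0"
                )


@dataclass
class PhantomSet:
    """One synthetic subject: channels, labels, and retained ground truth."""

    t1w: Image2D
    water: Image2D
    fat: Image2D
    labels: LabelMask
    truth_fat_fraction: Image2D   # per pixel, in [0, 1]
    truth_bias: Image2D           # multiplicative field applied to T1W
    truth_p: dict[int, float]     # muscle id -> realized fat-pixel fraction
    spec: PhantomSpec


def _ellipse_mask(shape: tuple[int, int], spacing: float,
                  cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rr * spacing - cr) / ar) ** 2 + ((cc_ * spacing - cc) / ac) ** 2 <= 1.0


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    geo = spec.geometry
    shape, sp = spec.image_size, spec.pixel_spacing
    cr, cc, ar, ac = geo["thigh"]
    if cr - ar < 0 or cr + ar > (shape[0] - 1) * sp or cc - ac < 0 or cc + ac > (shape[1] - 1) * sp:
        raise ValueError("geometry overflow: thigh ellipse does not fit the image")
    ring = geo["fat_ring_thickness"]
    outer = _ellipse_mask(shape, sp, cr, cc, ar, ac)
    inner = _ellipse_mask(shape, sp, cr, cc, ar - ring, ac - ring)

    labels = np.full(shape, BACKGROUND, dtype=np.int32)
    labels[outer] = SUBCUT_FAT
    labels[inner] = OTHER
    # paint order decides ownership of overlaps; VI last so its ring stays intact
    for lab in (AM, BFL, VL, VI):
        mask = _ellipse_mask(shape, sp, *geo[lab])
        if np.any(mask & ~inner):
            raise ValueError(
                f"geometry overflow: compartment {LABEL_NAMES[lab]} leaves the muscle fascia"
            )
        labels[mask] = lab
    femur = _ellipse_mask(shape, sp, *geo[FEMUR])
    if np.any(femur & ~inner):
        raise ValueError("geometry overflow: femur leaves the muscle fascia")
    labels[femur] = FEMUR
    return labels


def sample_fat_mask(region_mask: np.ndarray, p: float, marbling_scale: float,
                    rng: np.random.Generator, spacing: float = 1.0) -> np.ndarray:
    """Select exactly ``round(p·N)`` fat pixels inside a region.

    The selection takes the top-``k`` pixels of a Gaussian-smoothed noise
    field with correlation length ``marbling_scale`` (mm), which produces
    marbled clusters; ``marbling_scale = 0`` degenerates to i.i.d.
    selection.  Ties are broken by pixel index order (row-major), so the
    realized count is exact and reproducible.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("empty region")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"fat fraction outside [0, 1]: {p}")
    k = int(np.floor(p * n + 0.5))  # round half up: quantized ground truth
    out = np.zeros(region_mask.shape, dtype=bool)
    if k == 0:
        return out
    noise = rng.standard_normal(region_mask.shape)
    if marbling_scale > 0:
        fld = ndimage.gaussian_filter(noise, sigma=marbling_scale / spacing)
    else:
        fld = noise
    flat_idx = np.flatnonzero(region_mask.ravel())
    vals = fld.ravel()[flat_idx]
    order = np.argsort(-vals, kind="stable")
    out.ravel()[flat_idx[order[:k]]] = True
    return out


def apply_bias_field(image: Image2D, amplitude: float, scale_mm: float,
                     rng: np.random.Generator) -> tuple[Image2D, Image2D]:
    """Multiply an image by a smooth positive random field of mean 1.

    The field is the exponential of a Gaussian-smoothed noise field
    (σ = ``scale_mm``), linearly rescaled so that the mean is exactly 1
    and the peak deviation ``max|field − 1|`` equals ``amplitude``.  The
    underlying field's sign is chosen so the peak deviation is on the
    bright side (coil hot-spot), making ``max(field) = 1 + amplitude``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    shape, sp = image.shape, image.spacing
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale_mm / sp)
    raw -= raw.mean()
    if amplitude == 0 or not np.any(raw):
        fld = np.ones(shape)
    else:
        if -raw.min() > raw.max():     # put the dominant lobe on the bright side
            raw = -raw
        raw /= raw.max()
        e = np.exp(raw)                # right-skew: peak |deviation| is positive
        dev = e - e.mean()
        fld = 1.0 + amplitude * dev / np.abs(dev).max()
    return Image2D(image.data * fld, sp), Image2D(fld, sp)


def make_phantom(spec: PhantomSpec) -> PhantomSet:
    """Generate one synthetic subject; deterministic given ``spec.rng_seed``.

    Channel model (noiseless latent first):

    * per-pixel fat fraction ``ff``: 1 on planted fat pixels and the
      subcutaneous ring, a concave ramp on the partial-volume band,
      0 elsewhere;
    * T1W latent = ``muscle·(1−ff) + fat·ff`` over soft tissue;
    * Dixon ``water = S·(1−ff)``, ``fat = S·ff`` with a spatially uniform
      proton signal ``S`` over soft tissue, so the two channels conserve
      ``S`` pixelwise and the ratio-of-means percent equals the mean fat
      fraction exactly in the noiseless phantom;
    * T1W is multiplied by the bias field; all three channels then get
      independent Gaussian (optionally Rician) noise inside the body.
    """
    spec.validate()
    labels = _build_labels(spec)
    sp = spec.pixel_spacing
    rng = np.random.default_rng(spec.rng_seed)

    # --- plant intramuscular fat, muscle by muscle, in fixed label order
    fat_pixels = np.zeros(labels.shape, dtype=bool)
    truth_p: dict[int, float] = {}
    for m in sorted(set(MUSCLES) | set(spec.fat_fractions)):
        region = labels == m
        p = float(spec.fat_fractions.get(m, 0.0))
        if m == VI:
            p = 0.0  # pure-muscle reference tissue, by construction
        mask = sample_fat_mask(region, p, spec.marbling_scale, rng, sp)
        fat_pixels |= mask
        truth_p[m] = float(mask.sum() / region.sum())

    # --- per-pixel fat fraction with the partial-volume band
    ff = np.zeros(labels.shape)
    ff[fat_pixels] = 1.0
    ff[labels == SUBCUT_FAT] = 1.0
    w = spec.partial_volume_width
    if w > 0:
        dist = ndimage.distance_transform_edt(~(fat_pixels | (labels == SUBCUT_FAT)),
                                              sampling=1.0)
        lean = np.isin(labels, (VL, VI, AM, BFL, OTHER)) & ~fat_pixels
        band = lean & (dist > 0) & (dist <= w)
        ff[band] = (1.0 - dist[band] / (w + 1.0)) ** spec.partial_volume_exponent

    # --- noiseless latents
    mu, fa = spec.muscle_mean_intensity, spec.fat_mean_intensity
    soft = np.isin(labels, _SOFT_TISSUE)
    latent = np.zeros(labels.shape)
    latent[soft] = mu + (fa - mu) * ff[soft]
    latent[labels == FEMUR] = spec.femur_intensity_factor * mu

    s0 = mu  # uniform proton signal over soft tissue
    signal = np.where(soft, s0, 0.0)
    signal[labels == FEMUR] = 0.2 * s0
    water = signal * (1.0 - ff)
    fat_img = signal * ff

    # --- bias field (T1W only) and noise
    t1w_img, bias = apply_bias_field(Image2D(latent, sp), spec.bias_amplitude,
                                     spec.bias_scale, rng)
    t1w = t1w_img.data
    body = soft | (labels == FEMUR)
    if spec.noise_sd > 0:
        for channel in (t1w, water, fat_img):
            re = rng.normal(0.0, spec.noise_sd, labels.shape)
            if spec.rician_noise:
                im = rng.normal(0.0, spec.noise_sd, labels.shape)
                channel[body] = np.hypot(channel[body] + re[body], im[body])
            else:
                channel[body] += re[body]

    return PhantomSet(
        t1w=Image2D(t1w, sp),
        water=Image2D(water, sp),
        fat=Image2D(fat_img, sp),
        labels=LabelMask(labels, sp, dict(LABEL_NAMES)),
        truth_fat_fraction=Image2D(ff, sp),
        truth_bias=bias,
        truth_p=truth_p,
        spec=spec,
    )


def cohort_specs(base: PhantomSpec, n_subjects: int, rng: np.random.Generator,
                 fat_fraction_ranges: Mapping[int, tuple[float, float]] | None = None,
                 ) -> list[PhantomSpec]:
    """Per-subject specs with fat fractions drawn uniformly from ranges.

    Default ranges follow the spread observed across healthy younger and
    older adults: VL 5–25%, AM 4–20%, BF-L 5–40%.
    """
    if fat_fraction_ranges is None:
        fat_fraction_ranges = {VL: (0.05, 0.25), AM: (0.04, 0.20), BFL: (0.05, 0.40)}
    specs = []
    for _ in range(n_subjects):
        fracs = {m: float(rng.uniform(lo, hi))
                 for m, (lo, hi) in fat_fraction_ranges.items()}
        seed = int(rng.integers(0, 2**31 - 1))
        specs.append(replace(base, fat_fractions=fracs, rng_seed=seed))
    return specs
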