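# imatq

Quantification of **intramuscular adipose tissue (IntraMAT)** on axial
mid-thigh MR slices by two independent methods — T1-weighted histogram
thresholding and two-point Dixon fat–water imaging — together with the
agreement statistics that diagnose *why* the two methods disagree.

The package is aimed at muscle-imaging researchers who need a tested,
reproducible implementation of this dual-modality protocol, and a
ground-truth phantom to validate it against, without access to subject
MRI data.

## What it computes

For each muscle mask (vastus lateralis, adductor magnus, biceps femoris
long head) on one slice:

* **T1W pipeline** — N3-style multiplicative bias-field correction;
  six 25-mm² reference ROIs (three on the vastus intermedius, a pure
  skeletal-muscle reference, three on subcutaneous fat); Otsu threshold
  of the pooled 150-pixel reference histogram, averaged over three
  independent ROI placements; then per muscle

  `IntraMAT (%) = n_fat / (n_muscle + n_fat) × 100`

  with pixels above the subject-level threshold counting as fat, plus
  cross-sectional area (pixel count × spacing² / 100, cm²).

* **Dixon pipeline** — `IntraMAT (%) = 100 × fat_mean / (water_mean +
  fat_mean)` over the same mask (ratio of channel means), plus a
  per-pixel fat-fraction map for visualization.

* **Agreement suite** — unpaired Student t comparison; Bland-Altman
  95% limits of agreement with proportional-bias test (difference
  convention d = 2PD − T1W against the pair mean); ICC(2,1)
  reproducibility; the **boundary value** (the T1W intensity whose
  exceedance fraction reproduces the Dixon percent) and the correlation
  of ΔIntraMAT with the threshold/boundary intensity gap; and
  subtraction-method SNR from paired acquisitions.

* **Phantom generator** — parametric mid-thigh slices with exact-count
  fat infiltration (`round(p·N)` pixels per muscle), marbled cluster
  geometry, a partial-volume band, a smooth multiplicative bias field
  and Gaussian/Rician noise; every corruption is retained as ground
  truth, so each pipeline stage is testable without any download.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
import numpy as np
from imatq import (PhantomSpec, VL, AM, BFL, make_phantom, n3_correct,
                   threshold_trials, quantify_t1w, quantify_dixon)

spec = PhantomSpec(fat_fractions={VL: 0.12, AM: 0.09, BFL: 0.25}, rng_seed=42)
ph = make_phantom(spec)                       # T1W + Dixon channels + truth

corrected = n3_correct(ph.t1w).corrected      # remove the coil-shading field
rng = np.random.default_rng(0)
thr = threshold_trials(corrected, ph.labels, rng)   # mean of three Otsu trials
print(f"Otsu threshold (mean of 3 trials): {thr.mean:.1f} a.u.")
for m, name in ((VL, "VL"), (AM, "AM"), (BFL, "BF-L")):
    mask = ph.labels.region(m)
    t1 = quantify_t1w(corrected, mask, thr.mean, muscle=name)
    dx = quantify_dixon(ph.water, ph.fat, mask, muscle=name)
    print(f"{name:4s} T1W {t1.intramat_percent:5.1f}%  2PD {dx.intramat_percent:5.1f}%"
          f"  truth {100*ph.truth_p[m]:5.1f}%  CSA {t1.csa_cm2:5.1f} cm2")
```

prints

```
Otsu threshold (mean of 3 trials): 111.7 a.u.
VL   T1W  30.1%  2PD  21.2%  truth  12.0%  CSA  18.0 cm2
AM   T1W  22.0%  2PD  14.7%  truth   9.0%  CSA  24.0 cm2
BF-L T1W  50.4%  2PD  38.9%  truth  25.0%  CSA  21.1 cm2
```

Read the three columns against each other: the *truth* column is the
planted fraction of fully-fat pixels; both measurements sit above it
because this phantom has a partial-volume band (mixed voxels carry real
fat signal beyond the planted pixels), and **T1W sits above 2PD in every
muscle** because the Otsu threshold (111.7 a.u., the upper edge of the
muscle peak) counts every mixed voxel as fully fat, while the Dixon
ratio integrates them fractionally — the threshold-setting mechanism
behind the inter-method discrepancy.  With `partial_volume_width=0,
noise_sd=0, bias_amplitude=0`, both methods recover the truth to the
pixel quantum.

The same stages are available from a shell:

```bash
imat phantom --seed 17 --out subj01/
imat biascorrect subj01/t1w.nii --out subj01/corrected.nii
imat t1w   --image subj01/corrected.nii --labels subj01/labels.nii --seed 3 --out t1w.csv
imat dixon --water subj01/water.nii --fat subj01/fat.nii --labels subj01/labels.nii --out dixon.csv
imat agree --t1w t1w.csv --dixon dixon.csv --out report/
imat run   --config study.yaml --out report/     # end-to-end cohort
```

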