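# t1relax

Quantitative T1 relaxation mapping from an ordinary T1-weighted 3-D
gradient-echo (3DT1TFE / SPGR) acquisition — no dedicated relaxometry
sequence needed — plus a digital brain phantom for validation and the
longitudinal statistics used in two-timepoint MS atrophy studies.

## The problem

Chronic T1-hypointense MS lesions ("black holes") mark severe tissue
damage, but raw T1-weighted intensity has no absolute scale: the shades
of gray drift with scanner settings, so lesion evolution cannot be
compared across timepoints. The tissue property underneath — the T1
relaxation time, in ms — can. `t1relax` converts a routine T1-weighted
scan into a quantitative T1 map by calibrating the scanner against
reference tissues with known literature T1.

## The model

The steady-state spoiled gradient-echo magnitude signal is

```
S(T1) = k · (1 − E) · sin θ / (1 − E · cos θ),   E = exp(−TR / T1)
```

with TR the repetition time, θ the flip angle, and k a lumped scanner
constant (receiver gain, proton density, coil sensitivity). TE is
assumed ≪ T2. For 0 < θ ≤ 90° the signal is strictly decreasing in T1,
so once k is known every voxel inverts in closed form:

```
u = S / (k sin θ),   E = (1 − u) / (1 − u cos θ),   T1 = −TR / ln E
```

k is fitted by least squares to reference ROIs — normal-appearing white
matter (literature T1 = 810 ms at 3 T) and gray matter (1350 ms, Heschl
gyrus by convention) — via the closed form `k = Σ Sᵢfᵢ / Σ fᵢ²` with
`fᵢ = S(T1ᵢ; k = 1)`. Voxels whose intensity falls outside the
invertible range are flagged in a validity mask, never clamped.

## Worked example

```python
import numpy as np
from t1relax import (PhantomSpec, ImageVolume, generate_phantom,
                     derive_t1_map, roi_t1_stats)

ph = generate_phantom(PhantomSpec(shape=(64, 64, 64), lesion_count=5, seed=42))
t1map = derive_t1_map(ImageVolume(ph.signal), ph.spec.params,
                      ph.class_mask("wm"), ph.class_mask("gm"),
                      brain_mask=ph.brain_mask)
print(f"fitted k = {t1map.calibration.k:.6f}")
for name in ("wm", "gm", "lesion"):
    (s,) = roi_t1_stats(t1map, ph.class_mask(name))
    print(f"{name:>6}: n={s.n_voxels:6d}  mean T1 = {s.mean_t1:9.4f} ms  "
          f"SD = {s.sd_t1:.4f}  invalid = {s.pct_invalid:.0%}")
```

prints

```
fitted k = 100.000000
    wm: n= 42280  mean T1 =  810.0000 ms  SD = 0.0000  invalid = 0%
    gm: n= 50472  mean T1 = 1350.0000 ms  SD = 0.0000  invalid = 0%
lesion: n=   624  mean T1 = 1040.0000 ms  SD = 0.0000  invalid = 0%
```

— the noiseless phantom is recovered exactly: the calibration finds the
true scanner constant (k = 100) and every tissue class returns its
ground-truth T1 (WM 810 ms, GM 1350 ms, lesion 1040 ms) with no
invalid voxels inside the brain.

The same pipeline runs from the shell on NIfTI files:

```
t1relax phantom --shape 64,64,64 --lesions 5 --snr 40 --noise rician --seed 7 --out-dir ph/
t1relax derive --image scan.nii.gz --wm-mask wm.nii.gz --gm-mask gm.nii.gz \
               --tr 8 --flip 15 --ref-wm-t1 810 --ref-gm-t1 1350 \
               --out-dir out/
t1relax cohort-sim --n 20 --gm-change -2.24 --seed 7 --out cohort.csv
t1relax stats --cohort cohort.csv --correlate pbvc:gm_volume_change \
              --regress age,disease_duration,t2_lesion_volume --out report/
```

`cohort-sim` and `stats` cover the longitudinal side of such a study:
paired t-tests on compartment volumes and ROI T1 values, Spearman
correlation of compartment change against whole-brain percentage volume
change (PBVC; negative = loss), and univariate / multivariate OLS of
PBVC on clinical covariates.

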