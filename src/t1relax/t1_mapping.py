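"""Whole-volume T1 map derivation and ROI-level T1 statistics.

Given a T1-weighted magnitude volume plus reference white-matter and
gray-matter masks, the scanner constant k is calibrated from the mean
reference-ROI intensities and literature reference T1 values, and every
voxel (optionally restricted to a brain mask) is inverted through the
closed-form signal equation. Voxels whose intensity falls outside the
invertible range of the model (air background, flow artifacts) are
flagged in a validity mask rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import (
    Calibration,
    SequenceParams,
    T1_INVALID,
    TissueReference,
    calibrate_k,
    invert_signal,
)

__all__ = [
    "ImageVolume",
    "T1Map",
    "RoiT1Stats",
    "DEFAULT_REFERENCE_T1",
    "mean_roi_signal",
    "derive_t1_map",
    "roi_t1_stats",
]

#: Literature reference T1 values (ms) at 3 T used for calibration:
#: normal-appearing white matter and cortical gray matter (Heschl gyrus
#: by convention, a region not known to be affected in MS).
DEFAULT_REFERENCE_T1: dict[str, float] = {"wm": 810.0, "gm": 1350.0}


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D magnitude image grid with voxel spacing and world affine."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={vox.ndim}")
        # NaN is tolerated (masked as invalid downstream); infinities are not
        if np.any(np.isinf(vox)):
            raise ValueError("volume intensities must not be infinite")
        if np.any(vox < 0):
            raise ValueError("magnitude intensities must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 per axis, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass(frozen=True)
class T1Map:
    """Voxel-wise T1 relaxation map (ms) with its validity mask.

    ``t1`` holds NaN wherever ``valid_mask`` is False; the calibration
    and sequence parameters that produced the map travel with it.
    """

    t1: np.ndarray
    valid_mask: np.ndarray
    calibration: Calibration
    params: SequenceParams

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape


@dataclass(frozen=True)
class RoiT1Stats:
    """Per-ROI T1 summary: mean/SD over valid voxels only.

    ``mean_t1``/``sd_t1`` are None when the ROI contains no valid voxel
    (``pct_invalid == 1``). SD uses the sample (n-1) denominator; an ROI
    with a single valid voxel reports SD 0.
    """

    label: str
    n_voxels: int
    mean_t1: float | None
    sd_t1: float | None
    pct_invalid: float


def _as_bool_mask(mask, shape, name: str) -> np.ndarray:
    m = np.asarray(mask, dtype=float)
    if m.shape != tuple(shape):
        raise ValueError(f"{name} shape {m.shape} does not match volume {tuple(shape)}")
    # >0.5 after casting to real, tolerating probabilistic masks
    return m > 0.5


def mean_roi_signal(volume: ImageVolume, mask) -> float:
    """Arithmetic mean magnitude intensity under a binary mask."""
    m = _as_bool_mask(mask, volume.shape, "mask")
    n = int(m.sum())
    if n == 0:
        raise ValueError("mask selects no voxels")
    return float(np.asarray(volume.voxels, dtype=float)[m].mean())


def derive_t1_map(
    volume: ImageVolume,
    params: SequenceParams,
    wm_mask,
    gm_mask,
    brain_mask=None,
    reference_t1: dict[str, float] | None = None,
) -> T1Map:
    """Calibrate k from reference masks and invert the whole volume.

    Parameters
    ----------
    volume : ImageVolume
        T1-weighted magnitude volume (bias-corrected input assumed).
    params : SequenceParams
        TR / flip angle of the acquisition.
    wm_mask, gm_mask : array_like
        Non-empty, disjoint reference ROIs for normal-appearing white
        and gray matter.
    brain_mask : array_like, optional
        Restrict inversion to this mask; outside voxels are invalid.
    reference_t1 : dict, optional
        Literature T1 per reference label, keys ``"wm"`` and ``"gm"``
        (ms). Defaults to :data:`DEFAULT_REFERENCE_T1`.

    Returns
    -------
    T1Map
        Same grid shape as the input; NaN where inversion failed or
        outside the brain mask.
    """
    ref_t1 = dict(DEFAULT_REFERENCE_T1 if reference_t1 is None else reference_t1)
    wm = _as_bool_mask(wm_mask, volume.shape, "wm_mask")
    gm = _as_bool_mask(gm_mask, volume.shape, "gm_mask")
    if not wm.any():
        raise ValueError("wm_mask is empty")
    if not gm.any():
        raise ValueError("gm_mask is empty")
    if np.any(wm & gm):
        raise ValueError("wm_mask and gm_mask overlap")

    references = [
        TissueReference("NAWM", ref_t1["wm"], mean_roi_signal(volume, wm)),
        TissueReference("NAGM", ref_t1["gm"], mean_roi_signal(volume, gm)),
    ]
    calibration = calibrate_k(references, params)

    if brain_mask is None:
        brain = np.ones(volume.shape, dtype=bool)
    else:
        brain = _as_bool_mask(brain_mask, volume.shape, "brain_mask")

    t1 = np.full(volume.shape, T1_INVALID, dtype=float)
    signal = np.asarray(volume.voxels, dtype=float)
    t1[brain] = invert_signal(signal[brain], params, calibration.k)
    valid = brain & np.isfinite(t1)
    t1[~valid] = T1_INVALID
    return T1Map(t1=t1, valid_mask=valid, calibration=calibration, params=params)


def roi_t1_stats(t1map: T1Map, mask) -> list[RoiT1Stats]:
    """Per-label T1 mean/SD over the valid voxels of each ROI.

    ``mask`` may be binary (one ROI, label "roi") or an integer label
    map; label 0 is treated as background and skipped. Labels whose ROI
    contains no valid voxel yield a record with absent mean/SD instead
    of NaN arithmetic.
    """
    m = np.asarray(mask)
    if m.shape != t1map.shape:
        raise ValueError(f"mask shape {m.shape} does not match map {t1map.shape}")

    if m.dtype == bool or set(np.unique(m)).issubset({0, 1}):
        regions = [("roi", m > 0.5 if m.dtype != bool else m)]
    else:
        labels = [int(v) for v in np.unique(m) if v != 0]
        regions = [(str(v), m == v) for v in labels]

    out: list[RoiT1Stats] = []
    for label, region in regions:
        n = int(region.sum())
        if n == 0:
            continue
        valid = region & t1map.valid_mask
        nv = int(valid.sum())
        pct_invalid = 1.0 - nv / n
        if nv == 0:
            out.append(RoiT1Stats(label, n, None, None, 1.0))
            continue
        vals = t1map.t1[valid]
        sd = float(vals.std(ddof=1)) if nv > 1 else 0.0
        out.append(RoiT1Stats(label, n, float(vals.mean()), sd, pct_invalid))
    return out
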