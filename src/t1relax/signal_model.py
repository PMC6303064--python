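"""Spoiled gradient-echo (3DT1TFE / SPGR) signal model.

The steady-state magnitude signal of a spoiled gradient-recalled echo
acquisition with repetition time TR, tip angle theta and tissue
longitudinal relaxation time T1 is

    S(T1) = k * (1 - E) * sin(theta) / (1 - E * cos(theta)),
    E = exp(-TR / T1),

where ``k`` is a lumped scanner constant (receiver gain, proton density,
coil sensitivity). TE is assumed short relative to T2, so no transverse
decay term appears. For 0 < theta <= 90 degrees the signal is strictly
decreasing in T1, so the equation inverts uniquely in closed form:

    u = S / (k sin(theta)),  E = (1 - u) / (1 - u cos(theta)),
    T1 = -TR / ln(E),   valid when 0 < E < 1.

``calibrate_k`` fits the single scale ``k`` to one or more reference
tissues with known literature T1 and measured mean ROI intensity, by
linear least squares in signal space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueReference",
    "Calibration",
    "T1_INVALID",
    "forward_signal",
    "invert_signal",
    "calibrate_k",
]

#: Sentinel returned for a signal outside the invertible range of the model.
#: Downstream code masks these voxels; they are never clamped to a finite T1.
T1_INVALID: float = float("nan")


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition constants of the gradient-echo sequence.

    Parameters
    ----------
    tr : float
        Repetition time in ms. Must be > 0.
    te : float
        Echo time in ms. Carried for provenance only; the model assumes
        TE << T2 and never uses it numerically.
    flip_angle : float
        Tip angle in degrees, 0 < flip_angle <= 90.
    """

    tr: float = 8.0
    te: float = 3.6
    flip_angle: float = 15.0

    def __post_init__(self) -> None:
        if not (self.tr > 0):
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if not (self.te >= 0):
            raise ValueError(f"te must be >= 0, got {self.te}")
        if not (0 < self.flip_angle <= 90):
            raise ValueError(
                f"flip_angle must lie in (0, 90] degrees, got {self.flip_angle}"
            )

    @property
    def flip_rad(self) -> float:
        """Tip angle in radians."""
        return math.radians(self.flip_angle)


@dataclass(frozen=True)
class TissueReference:
    """A calibration reference tissue.

    Pairs a literature T1 (e.g. 810 ms for normal-appearing white matter,
    1350 ms for cortical gray matter at 3 T) with the measured mean
    magnitude intensity of the corresponding ROI on the scan being
    calibrated.
    """

    label: str
    reference_t1: float
    mean_signal: float

    def __post_init__(self) -> None:
        if not (self.reference_t1 > 0):
            raise ValueError(f"reference_t1 must be > 0, got {self.reference_t1}")
        if not (self.mean_signal > 0):
            raise ValueError(f"mean_signal must be > 0, got {self.mean_signal}")


@dataclass(frozen=True)
class Calibration:
    """Result of fitting the scanner constant ``k``.

    ``residuals[i]`` is the signal-space residual ``S_i - k * f_i`` for
    reference ``i``; with a single reference it is exactly zero. Nonzero
    residuals with several references indicate model violation (e.g.
    proton-density differences between the reference tissues).
    """

    k: float
    residuals: tuple[float, ...]
    references_used: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"calibrated k must be > 0, got {self.k}")


def forward_signal(t1, params: SequenceParams, k: float = 1.0):
    """Evaluate the spoiled gradient-echo signal equation.

    Parameters
    ----------
    t1 : float or array_like
        Longitudinal relaxation time(s) in ms, strictly positive.
    params : SequenceParams
        TR and flip angle of the acquisition.
    k : float
        Scanner scale constant, strictly positive.

    Returns
    -------
    float or ndarray
        Magnitude signal, same shape as ``t1``. Non-negative, and
        strictly decreasing in t1 for fixed ``params`` and ``k``.
    """
    t1_arr = np.asarray(t1, dtype=float)
    if not (k > 0):
        raise ValueError(f"k must be > 0, got {k}")
    if np.any(t1_arr <= 0):
        raise ValueError("t1 must be > 0 everywhere")
    e = np.exp(-params.tr / t1_arr)
    theta = params.flip_rad
    s = k * (1.0 - e) * math.sin(theta) / (1.0 - e * math.cos(theta))
    return float(s) if np.isscalar(t1) else s


def invert_signal(s, params: SequenceParams, k: float):
    """Closed-form inversion of :func:`forward_signal`.

    Signals outside the invertible range (too large for any positive T1,
    or non-positive) map to the NaN sentinel :data:`T1_INVALID`; they are
    never clamped to a finite value, because clamping would silently bias
    downstream ROI means.

    Parameters
    ----------
    s : float or array_like
        Measured magnitude signal(s).
    params : SequenceParams
        Acquisition constants used for the forward model.
    k : float
        Calibrated scanner constant, > 0.

    Returns
    -------
    float or ndarray
        T1 in ms where invertible, NaN elsewhere.
    """
    if not (k > 0):
        raise ValueError(f"k must be > 0, got {k}")
    s_arr = np.asarray(s, dtype=float)
    theta = params.flip_rad
    with np.errstate(divide="ignore", invalid="ignore"):
        u = s_arr / (k * math.sin(theta))
        e = (1.0 - u) / (1.0 - u * math.cos(theta))
        valid = (s_arr > 0) & np.isfinite(e) & (e > 0.0) & (e < 1.0)
        t1 = np.where(valid, -params.tr / np.log(np.where(valid, e, 0.5)), T1_INVALID)
    return float(t1) if np.isscalar(s) else t1


def calibrate_k(
    references: list[TissueReference], params: SequenceParams
) -> Calibration:
    """Fit the scanner constant ``k`` to one or more reference tissues.

    Minimizes the sum of squared signal residuals
    ``sum_i (S_i - k f_i)^2`` with ``f_i = forward_signal(T1_i, params, k=1)``,
    whose closed-form solution is ``k = sum(S_i f_i) / sum(f_i^2)``.

    With two references (the usual NAWM + NAGM pair) the single scale is
    overdetermined; residuals are reported per reference so that model
    violation is visible rather than silently absorbed.
    """
    if not references:
        raise ValueError("at least one TissueReference is required")
    f = np.array(
        [forward_signal(r.reference_t1, params, k=1.0) for r in references]
    )
    if np.any(f <= 0):
        bad = [r.label for r, fi in zip(references, f) if fi <= 0]
        raise ValueError(f"degenerate reference(s) with zero model signal: {bad}")
    s = np.array([r.mean_signal for r in references])
    k = float(np.dot(s, f) / np.dot(f, f))
    residuals = tuple(float(x) for x in (s - k * f))
    return Calibration(
        k=k,
        residuals=residuals,
        references_used=tuple(r.label for r in references),
    )
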